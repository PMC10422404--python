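"""End-to-end processing: raw session logs to section aggregates and reports.

Per trial: binocular blink detection (200 ms extension), interpolation and
smoothing of pupil traces, baseline correction against the 0.5-2 s window,
focus-offset computation, virtual-screen projection, adaptive fixation/
saccade detection, removal of blink and saccade samples from the focus
offset, Savitzky-Golay smoothing of the remainder, and 10-s sectioning.
Across trials: per-participant median centering of the smoothed focus offset
and the between-condition statistical battery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import events as ev
from . import focus as fo
from . import pupil as pu
from . import stats as st
from .scene import POSTER_LABELS
from .types import OcularEvent, SessionLog, Trial, TrialUnusableError


@dataclass
class PipelineConfig:
    """Analysis parameters of the full chain (defaults as documented)."""

    blink_extend_s: float = pu.DEFAULT_BLINK_EXTENSION_S
    pupil_smooth_window: int = pu.DEFAULT_SMOOTH_WINDOW
    baseline_window_s: tuple[float, float] = pu.DEFAULT_BASELINE_WINDOW_S
    divisive_baseline: bool = False
    sg_window: int = fo.DEFAULT_SG_WINDOW
    sg_polyorder: int = fo.DEFAULT_SG_POLYORDER
    plane_distance_m: float = ev.DEFAULT_PLANE_DISTANCE_M
    dpi: int = ev.DEFAULT_DPI
    trim_quantile: float = ev.DEFAULT_TRIM_QUANTILE
    min_fixation_s: float = ev.DEFAULT_MIN_FIXATION_S
    velocity_n_sd: float = ev.DEFAULT_THRESHOLD_SD
    drop_samples: int = ev.DEFAULT_DROP_SAMPLES
    assume_uniform_rate: bool = False
    section_length_s: float = st.SECTION_LENGTH_S
    n_sections: int = st.N_SECTIONS


@dataclass
class ProcessedTrial:
    """All per-trial intermediate products needed for aggregation."""

    trial: Trial
    times: np.ndarray
    pupil: np.ndarray  # baseline-corrected combined pupil (mm)
    pupil_valid: np.ndarray  # False inside extended blinks
    focus_raw: np.ndarray
    focus_smoothed: np.ndarray  # Savitzky-Golay, before participant centering
    focus_valid: np.ndarray  # False in blinks, saccades, and invalid samples
    events: list[OcularEvent]  # blinks + fixations + saccades, time-sorted
    screen: ev.VirtualScreen
    head_angles_deg: np.ndarray  # per-step head-view rotation
    eye_angles_deg: np.ndarray  # per-step averaged-gaze-ray rotation

    @property
    def condition(self) -> str:
        return self.trial.condition

    @property
    def participant_id(self) -> str:
        return self.trial.participant_id


def process_trial(trial: Trial, config: PipelineConfig | None = None) -> ProcessedTrial:
    """Run the per-trial chain; raises :class:`TrialUnusableError` on broken data."""
    cfg = config or PipelineConfig()
    times = trial.times
    df = trial.samples

    pupil, valid, blinks = pu.process_pupil(
        df["pupil_L_mm"].to_numpy(dtype=float),
        df["pupil_R_mm"].to_numpy(dtype=float),
        times,
        extend_s=cfg.blink_extend_s,
        smooth_window=cfg.pupil_smooth_window,
        baseline_window=cfg.baseline_window_s,
        divisive=cfg.divisive_baseline,
    )

    offset, _d_surf, offset_ok = fo.compute_focus_offsets(trial)

    screen, gaze = ev.project_trial(
        trial,
        valid,
        distance_m=cfg.plane_distance_m,
        dpi=cfg.dpi,
        trim_quantile=cfg.trim_quantile,
    )
    gaze_events = ev.detect_fixations_saccades(
        gaze,
        n_sd=cfg.velocity_n_sd,
        min_fixation_s=cfg.min_fixation_s,
        drop_samples=cfg.drop_samples,
        assume_uniform_rate=cfg.assume_uniform_rate,
    )

    in_saccade = np.zeros(len(times), dtype=bool)
    for e in gaze_events:
        if e.kind == "saccade":
            in_saccade[e.start_index : e.end_index + 1] = True
    focus_valid = offset_ok & valid & ~in_saccade
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # short-segment window shrink is routine
        focus_smoothed = fo.smooth_focus_offset(
            np.where(focus_valid, offset, np.nan), cfg.sg_window, cfg.sg_polyorder
        )

    dirs_l = trial.vectors("gaze_dir_L")
    dirs_r = trial.vectors("gaze_dir_R")
    avg_dir = dirs_l + dirs_r
    avg_dir /= np.linalg.norm(avg_dir, axis=1, keepdims=True)
    eye_angles = st.rotation_angles_deg(avg_dir)
    blink_step = ~valid[1:] | ~valid[:-1]
    eye_angles[blink_step] = np.nan  # contaminated during lid closure
    head_angles = st.rotation_angles_deg(trial.vectors("head_view"))

    all_events = sorted(blinks + gaze_events, key=lambda e: e.start_index)
    return ProcessedTrial(
        trial=trial,
        times=times,
        pupil=pupil,
        pupil_valid=valid,
        focus_raw=offset,
        focus_smoothed=focus_smoothed,
        focus_valid=focus_valid,
        events=all_events,
        screen=screen,
        head_angles_deg=head_angles,
        eye_angles_deg=eye_angles,
    )


def center_focus_across_trials(processed: list[ProcessedTrial]) -> None:
    """Subtract each participant's median smoothed offset in place."""
    by_pid: dict[str, list[ProcessedTrial]] = {}
    for p in processed:
        by_pid.setdefault(p.participant_id, []).append(p)
    for pid, trials in by_pid.items():
        pooled = np.concatenate([t.focus_smoothed[t.focus_valid] for t in trials])
        pooled = pooled[np.isfinite(pooled)]
        if not len(pooled):
            warnings.warn(f"participant {pid!r} has no valid focus offsets", stacklevel=2)
            continue
        med = float(np.median(pooled))
        for t in trials:
            t.focus_smoothed = t.focus_smoothed - med


def trial_aggregates(p: ProcessedTrial, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Section a processed trial and aggregate every metric."""
    cfg = config or PipelineConfig()
    masks = st.section_slices(p.times, cfg.section_length_s, cfg.n_sections)
    rows = []
    for k, mask in enumerate(masks, start=1):
        row = st.aggregate_section(
            mask,
            p.times,
            p.events,
            p.pupil,
            p.pupil_valid,
            p.focus_smoothed if p.focus_smoothed is not None else p.focus_raw,
            p.head_angles_deg,
            p.eye_angles_deg,
        )
        row.update(
            participant=p.participant_id,
            condition=p.condition,
            section_index=k,
        )
        rows.append(row)
    cols = ["participant", "condition", "section_index", *st.METRIC_COLUMNS]
    return pd.DataFrame(rows)[cols]


@dataclass
class PipelineResult:
    aggregates: pd.DataFrame
    distraction: pd.DataFrame
    reports: dict[str, st.StatReport] = field(default_factory=dict)
    exclusions: list[str] = field(default_factory=list)


def distraction_table(trials: list[Trial]) -> pd.DataFrame:
    """Per participant x condition poster-gaze ratios (undefined rows excluded)."""
    rows = []
    for trial in trials:
        ratios = st.distraction_ratio(
            trial.samples["target_label"].to_numpy(dtype=object), POSTER_LABELS
        )
        if ratios is None:
            continue
        rows.append(
            {
                "participant": trial.participant_id,
                "condition": trial.condition,
                **ratios,
            }
        )
    return pd.DataFrame(rows, columns=["participant", "condition", *POSTER_LABELS])


def run_pipeline(
    sessions: list[SessionLog],
    config: PipelineConfig | None = None,
    run_battery: bool = True,
) -> PipelineResult:
    """Process a cohort of sessions into aggregates and statistical reports."""
    cfg = config or PipelineConfig()
    processed: list[ProcessedTrial] = []
    exclusions: list[str] = []
    usable_trials: list[Trial] = []
    for log in sessions:
        for trial in log.trials:
            try:
                processed.append(process_trial(trial, cfg))
                usable_trials.append(trial)
            except (TrialUnusableError, ValueError) as exc:
                exclusions.append(
                    f"{trial.participant_id}/{trial.condition}: {exc}"
                )
    center_focus_across_trials(processed)
    frames = [trial_aggregates(p, cfg) for p in processed]
    aggregates = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["participant", "condition", "section_index",
                                   *st.METRIC_COLUMNS])
    )
    reports = st.battery_over_aggregates(aggregates) if run_battery and len(aggregates) else {}
    return PipelineResult(
        aggregates=aggregates,
        distraction=distraction_table(usable_trials),
        reports=reports,
        exclusions=exclusions,
    )
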