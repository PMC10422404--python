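"""Synthetic VR gaze-session generator.

Emulates the statistical structure the analysis pipeline assumes: non-uniform
~90 Hz sampling, a fixation/saccade scanpath over the booth scene, blinks as
sentinel dropouts with corrupted pre/post pupil ramps, load-dependent pupil
dilation with reduced variability, and vergence noise producing a
surface-relative focus offset.  Load effects are injected as
condition-indexed parameters (there is no psychological model behind them);
the default profile is an inverted U peaking at the third condition.

Every load effect (pupil shift, pupil variability scaling, focus-offset
shift) is multiplied by a deterministic onset envelope that is zero through
the 0.5-2 s baseline window and ramps to one by 5 s, mirroring the sluggish
task-evoked pupillary response and making baseline correction a clean
reference.  The generator exposes envelope-weighted expected section effects
as ground truth for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .scene import EYE_HEIGHT, POSTER_LABELS, TARGET_LABEL, SceneModel, build_scene
from .types import CONDITIONS, PUPIL_SENTINEL, SAMPLE_COLUMNS, OcularEvent, SessionLog, Trial


def _per_condition(jpf: float, jpu: float, enf: float, enu: float) -> dict[str, float]:
    return dict(zip(CONDITIONS, (jpf, jpu, enf, enu)))


@dataclass
class GeneratorConfig:
    """All tunable knobs of the synthetic session generator.

    Defaults encode the study conditions: 90.26 Hz sampling with SD 5.81,
    trial-level pupil baselines spanning roughly 3.25-7.74 mm (mean 5.51,
    SD 0.93), a peak-condition pupil shift of 0.118 mm with the pupil
    variability scaled to 43% (57% reduction), and a peak focus-offset shift
    of 0.0729 (the ratio equivalent of 5.10 cm at the ~0.70 m typical
    surface distance).  Blink statistics are literature-typical defaults, not
    study-derived.
    """

    # --- sampling -----------------------------------------------------
    duration_s: float = 45.0
    sample_rate_hz: float = 90.26
    sample_rate_sd_hz: float = 5.81

    # --- per-condition load effects (inverted U, peak at EN-Familiar) --
    pupil_shift_mm: dict[str, float] = field(
        default_factory=lambda: _per_condition(0.0, 0.015, 0.118, 0.030)
    )
    pupil_variance_ratio: dict[str, float] = field(
        default_factory=lambda: _per_condition(1.0, 0.95, 0.43, 0.90)
    )
    focus_shift_ratio: dict[str, float] = field(
        default_factory=lambda: _per_condition(0.0, 0.020, 0.0729, 0.030)
    )
    fixation_rate_multiplier: dict[str, float] = field(
        default_factory=lambda: _per_condition(1.0, 0.99, 0.81, 0.93)
    )
    distraction_prob: dict[str, float] = field(
        default_factory=lambda: _per_condition(0.12, 0.03, 0.04, 0.08)
    )

    # --- onset envelope (s) -------------------------------------------
    onset_start_s: float = 2.0
    onset_full_s: float = 5.0

    # --- pupil model (mm) ---------------------------------------------
    pupil_baseline_mean_mm: float = 5.51
    pupil_baseline_sd_mm: float = 0.93
    pupil_baseline_range_mm: tuple[float, float] = (3.4, 7.6)
    pupil_slow_sd_mm: float = 0.2285  # OU stationary SD; tau below
    pupil_slow_tau_s: float = 3.0
    pupil_fast_sd_mm: float = 0.03  # white measurement noise per eye pair
    pupil_eye_noise_sd_mm: float = 0.02  # independent per-eye component

    # --- vergence / focus offset --------------------------------------
    vergence_noise_coeff: float = 0.05  # ratio-noise SD per metre of d_S
    vergence_slow_sd: float = 0.03  # slow OU on the offset ratio
    vergence_slow_tau_s: float = 2.0
    vergence_bias_sd: float = 0.05  # per-participant constant offset

    # --- blinks --------------------------------------------------------
    blink_rate_hz: float = 0.12  # attention-suppressed blinking (~7/min)
    blink_duration_mean_s: float = 0.15
    blink_duration_sd_s: float = 0.05
    blink_flank_s: float = 0.35  # visible fixation time required around a blink
    # two blinks can flank one fixation piece, each trimming one extension;
    # the gap must leave a detectable fixation between them
    blink_min_gap_s: float = 0.75
    blink_saccadic_prob: float = 0.6  # chance a blink rides on a gaze shift
    blink_corrupt_window_s: float = 0.10
    blink_corrupt_dip_mm: float = 1.5
    blink_gaze_noise_deg: float = 3.0

    # --- scanpath ------------------------------------------------------
    fixation_duration_mean_s: float = 0.31
    fixation_duration_log_sd: float = 0.40
    fixation_duration_range_s: tuple[float, float] = (0.15, 1.5)
    saccade_duration_range_s: tuple[float, float] = (0.06, 0.10)
    refixation_min_m: float = 0.02
    fixation_drift_deg: float = 0.10  # slow tracker/ocular drift (angular)
    fixation_drift_tau_s: float = 0.3
    gaze_noise_deg: float = 0.06  # per-sample angular tracker noise

    # --- head ----------------------------------------------------------
    head_tracking: bool = True
    head_track_gain: float = 0.3  # head covers ~1/3 of gaze eccentricity
    head_sway_sd_m: float = 0.008
    head_sway_tau_s: float = 3.0
    head_track_tau_s: float = 1.0
    head_rot_noise_deg: float = 0.3
    ipd_m: float = 0.064

    def __post_init__(self) -> None:
        for name in ("pupil_variance_ratio", "fixation_rate_multiplier"):
            if any(v <= 0 for v in getattr(self, name).values()):
                raise ValueError(f"{name} entries must be > 0")
        if self.sample_rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("rates and durations must be > 0")

    # -- derived ground truth -------------------------------------------

    def envelope(self, t: np.ndarray) -> np.ndarray:
        """Deterministic load-onset envelope in [0, 1]."""
        t = np.asarray(t, dtype=float)
        span = self.onset_full_s - self.onset_start_s
        frac = np.clip((t - self.onset_start_s) / span, 0.0, 1.0)
        return 0.5 * (1.0 - np.cos(np.pi * frac))

    def envelope_mean(self, t_end: float = 40.0) -> float:
        """Time-average of the envelope over [0, t_end] (analysis window)."""
        grid = np.linspace(0.0, t_end, 4001)
        return float(np.trapezoid(self.envelope(grid), grid) / t_end)

    def expected_section_pupil_shift(self, condition: str, t_end: float = 40.0) -> float:
        """Envelope-weighted mean pupil shift (mm) over the analysis window."""
        return self.pupil_shift_mm[condition] * self.envelope_mean(t_end)

    def expected_section_focus_shift(self, condition: str, t_end: float = 40.0) -> float:
        """Envelope-weighted mean focus-offset shift (ratio) over the window."""
        return self.focus_shift_ratio[condition] * self.envelope_mean(t_end)

    def expected_pupil_variance_ratio(self, condition: str) -> float:
        # Both the slow and the fast pupil components are scaled by the
        # configured ratio, so within-section variance scales exactly.
        return self.pupil_variance_ratio[condition]

    # -- serialization ----------------------------------------------------

    def to_yaml(self, path) -> None:
        data = {
            k: (dict(v) if isinstance(v, dict) else list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("pupil_baseline_range_mm", "fixation_duration_range_s",
                    "saccade_duration_range_s"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def noise_free(cls, **overrides) -> "GeneratorConfig":
        """A deterministic-measurement variant: zero noise, uniform rate,
        static head.  Scanpath and blink scheduling stay stochastic."""
        base = dict(
            sample_rate_sd_hz=0.0,
            pupil_slow_sd_mm=0.0,
            pupil_fast_sd_mm=0.0,
            pupil_eye_noise_sd_mm=0.0,
            pupil_baseline_sd_mm=0.0,
            vergence_noise_coeff=0.0,
            vergence_slow_sd=0.0,
            vergence_bias_sd=0.0,
            blink_gaze_noise_deg=0.0,
            fixation_drift_deg=0.0,
            gaze_noise_deg=0.0,
            head_tracking=False,
            head_sway_sd_m=0.0,
            head_rot_noise_deg=0.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class TrialTruth:
    """Generator ground truth for one simulated trial.

    ``events`` uses the visible-evidence convention: a fixation interrupted
    by a blink is recorded as two fixation epochs around the blink.
    """

    events: list[OcularEvent]
    sample_kind: np.ndarray  # per-sample "fixation"/"saccade"/"blink"
    gazed_label: np.ndarray  # per-sample intended target label ('' in saccades)
    focus_delta: np.ndarray  # injected signed offset ratio per sample
    clean_pupil: np.ndarray  # combined pupil signal before artifacts (mm)

    def count(self, kind: str) -> int:
        return sum(1 for e in self.events if e.kind == kind)

    def of_kind(self, kind: str) -> list[OcularEvent]:
        return [e for e in self.events if e.kind == kind]


# ---------------------------------------------------------------------------
# internals


def _ou(rng: np.random.Generator, dt: np.ndarray, tau: float, sigma: float,
        ncols: int = 1) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path sampled at irregular steps."""
    n = len(dt) + 1
    out = np.empty((n, ncols))
    if sigma == 0.0:
        out[:] = 0.0
        return out[:, 0] if ncols == 1 else out
    phi = np.exp(-dt / tau)
    scale = sigma * np.sqrt(1.0 - phi**2)
    eps = rng.standard_normal((n, ncols))
    out[0] = sigma * eps[0]
    for i in range(1, n):
        out[i] = phi[i - 1] * out[i - 1] + scale[i - 1] * eps[i]
    return out[:, 0] if ncols == 1 else out


def _ema(x: np.ndarray, dt: np.ndarray, tau: float) -> np.ndarray:
    """Exponential moving average with time constant tau (rows of x)."""
    out = np.empty_like(x)
    out[0] = x[0]
    alpha = 1.0 - np.exp(-dt / tau)
    for i in range(1, len(x)):
        out[i] = out[i - 1] + alpha[i - 1] * (x[i] - out[i - 1])
    return out


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _saccade_progress(frac: np.ndarray) -> np.ndarray:
    """Normalized displacement under a symmetric triangular velocity profile."""
    frac = np.clip(frac, 0.0, 1.0)
    return np.where(frac < 0.5, 2.0 * frac**2, 1.0 - 2.0 * (1.0 - frac) ** 2)


@dataclass
class _Segment:
    kind: str  # "fixation" | "saccade"
    t0: float
    t1: float
    label: str
    p0: np.ndarray
    p1: np.ndarray


def _pick_fixation_point(rng, scene: SceneModel, label: str, head: np.ndarray,
                         prev: np.ndarray | None, min_dist: float) -> np.ndarray:
    for _ in range(20):
        if label == TARGET_LABEL:
            sphere = next(s for s in scene.surfaces if s.label == TARGET_LABEL)
            toward = _unit(head - sphere.center)
            tangent = rng.standard_normal(3) * 0.5
            tangent -= tangent @ toward * toward
            p = sphere.center + sphere.radius * _unit(toward + tangent)
        else:
            rect = next(s for s in scene.surfaces if s.label == label)
            fu = rng.uniform(-0.8, 0.8) * rect.half_u
            fv = rng.uniform(-0.8, 0.8) * rect.half_v
            p = rect.center + fu * rect.u + fv * rect.v
        if prev is None or np.linalg.norm(p - prev) >= min_dist:
            return p
    return p  # accept the last draw if separation could not be met


def _build_scanpath(rng, cfg: GeneratorConfig, condition: str, scene: SceneModel,
                    head: np.ndarray) -> list[_Segment]:
    mult = cfg.fixation_rate_multiplier[condition]
    mean_dur = cfg.fixation_duration_mean_s / mult
    mu = math.log(mean_dur) - cfg.fixation_duration_log_sd**2 / 2.0
    lo, hi = cfg.fixation_duration_range_s
    p_distract = cfg.distraction_prob[condition]

    segments: list[_Segment] = []
    t = 0.0
    point = _pick_fixation_point(rng, scene, TARGET_LABEL, head, None, 0.0)
    label = TARGET_LABEL
    # a fixation fragment shorter than this at the trial cutoff would be
    # undetectable; the preceding fixation is extended instead
    min_tail = max(lo, 0.165)
    while t < cfg.duration_s:
        dur = float(np.clip(rng.lognormal(mu, cfg.fixation_duration_log_sd), lo, hi))
        segments.append(_Segment("fixation", t, t + dur, label, point, point))
        t += dur
        if t >= cfg.duration_s:
            break
        next_label = (
            str(rng.choice(POSTER_LABELS)) if rng.random() < p_distract else TARGET_LABEL
        )
        next_point = _pick_fixation_point(
            rng, scene, next_label, head, point, cfg.refixation_min_m
        )
        amp_deg = math.degrees(
            math.acos(
                float(np.clip(_unit(point - head) @ _unit(next_point - head), -1, 1))
            )
        )
        sd_lo, sd_hi = cfg.saccade_duration_range_s
        sdur = float(np.clip(0.021 + 0.0022 * amp_deg, sd_lo, sd_hi))
        if t + sdur + min_tail > cfg.duration_s:
            segments[-1].t1 = cfg.duration_s + 0.1
            break
        segments.append(_Segment("saccade", t, t + sdur, "", point, next_point))
        t += sdur
        point, label = next_point, next_label
    return segments


def _schedule_blinks(rng, cfg: GeneratorConfig, segments: list[_Segment],
                     t_end: float) -> list[tuple[float, float]]:
    """Blink onset/offset intervals.

    Two placement styles keep the ground truth exactly recoverable: a blink
    either sits fully inside one fixation (splitting it) or fully covers one
    saccade plus a sliver of its flanking fixations (occluding the gaze
    shift).  Either way at least ``blink_flank_s`` of each adjacent fixation
    stays visible, so detection after the blink extension never loses an
    epoch.  Placement is rejection-sampled against the scanpath; very high
    configured rates can saturate the eligible slots of a trial.
    """
    n_blinks = rng.poisson(cfg.blink_rate_hz * cfg.duration_s)
    flank = cfg.blink_flank_s
    fixations = [s for s in segments if s.kind == "fixation"]
    saccades = [
        (i, s) for i, s in enumerate(segments)
        if s.kind == "saccade" and 0 < i < len(segments) - 1
    ]
    blinks: list[tuple[float, float]] = []

    def separated(b0: float, b1: float) -> bool:
        return all(
            b0 - e > cfg.blink_min_gap_s or s - b1 > cfg.blink_min_gap_s
            for s, e in blinks
        )

    for _ in range(n_blinks):
        dur = float(
            np.clip(rng.normal(cfg.blink_duration_mean_s, cfg.blink_duration_sd_s),
                    0.06, 0.35)
        )
        for _try in range(120):
            if saccades and rng.random() < cfg.blink_saccadic_prob:
                i, sac = saccades[rng.integers(len(saccades))]
                slack = dur - (sac.t1 - sac.t0)
                if slack < 0.03:
                    continue
                prev_fix, next_fix = segments[i - 1], segments[i + 1]
                # choose the pre-saccade lead within the window that keeps
                # both flanking fixations visible
                lead_max = min(slack - 0.01, (sac.t0 - prev_fix.t0) - flank)
                lead_min = max(0.01, slack - ((min(next_fix.t1, t_end) - sac.t1) - flank))
                if lead_min > lead_max:
                    continue
                lead = rng.uniform(lead_min, lead_max)
                b0, b1 = sac.t0 - lead, sac.t0 - lead + dur
            else:
                fix = fixations[rng.integers(len(fixations))]
                lo = fix.t0 + flank
                hi = min(fix.t1, t_end) - flank - dur
                if hi <= lo:
                    continue
                b0 = rng.uniform(lo, hi)
                b1 = b0 + dur
            if separated(b0, b1):
                blinks.append((b0, b1))
                break
    blinks.sort()
    return blinks


def _truth_events(segments: list[_Segment], blinks: list[tuple[float, float]],
                  times: np.ndarray, t_end: float) -> tuple[list, np.ndarray, np.ndarray]:
    """Split fixations at blinks and map everything to sample indices."""
    intervals: list[tuple[str, float, float, str]] = []
    for seg in segments:
        t1 = min(seg.t1, t_end)
        if t1 <= seg.t0:
            continue
        # visible-evidence convention: subtract blink occlusion
        pieces = [(seg.t0, t1)]
        for b0, b1 in blinks:
            new = []
            for s, e in pieces:
                if b1 <= s or e <= b0:
                    new.append((s, e))
                    continue
                if s < b0:
                    new.append((s, b0))
                if b1 < e:
                    new.append((b1, e))
            pieces = new
        if seg.kind == "saccade":
            # a partially/fully occluded gaze shift leaves no recoverable
            # saccade; only an untouched one stays in the truth
            if pieces == [(seg.t0, t1)]:
                intervals.append(("saccade", seg.t0, t1, ""))
        else:
            for s, e in pieces:
                if e - s > 0.02:
                    intervals.append(("fixation", s, e, seg.label))
    for b0, b1 in blinks:
        intervals.append(("blink", b0, b1, ""))
    intervals.sort(key=lambda iv: iv[1])

    sample_kind = np.full(len(times), "", dtype=object)
    gazed = np.full(len(times), "", dtype=object)
    events = []
    for kind, t0, t1, label in intervals:
        i0 = int(np.searchsorted(times, t0, side="left"))
        i1 = int(np.searchsorted(times, t1, side="right")) - 1
        if i1 < i0:
            continue
        events.append(
            OcularEvent(kind, i0, i1, float(times[i0]), float(times[i1]), label)
        )
        if kind == "blink":
            sample_kind[i0 : i1 + 1] = "blink"
        else:
            mask = sample_kind[i0 : i1 + 1] == ""
            sample_kind[i0 : i1 + 1] = np.where(mask, kind, sample_kind[i0 : i1 + 1])
            if kind == "fixation":
                gazed[i0 : i1 + 1] = np.where(mask, label, gazed[i0 : i1 + 1])
    return events, sample_kind, gazed


def simulate_trial(
    config: GeneratorConfig,
    condition: str,
    participant_id: str,
    seed: int | np.random.SeedSequence,
    *,
    pupil_baseline_mm: float | None = None,
    vergence_bias: float | None = None,
    scene: SceneModel | None = None,
    presentation_index: int | None = None,
) -> tuple[Trial, TrialTruth]:
    """Simulate one listening phase; returns the trial and its ground truth."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    scene = scene or build_scene()
    cfg = config

    if pupil_baseline_mm is None:
        pupil_baseline_mm = float(
            np.clip(
                rng.normal(cfg.pupil_baseline_mean_mm, cfg.pupil_baseline_sd_mm),
                *cfg.pupil_baseline_range_mm,
            )
        )
    if vergence_bias is None:
        vergence_bias = float(rng.normal(0.0, cfg.vergence_bias_sd))

    # -- sample clock ----------------------------------------------------
    n_max = int(cfg.duration_s * (cfg.sample_rate_hz + 4 * cfg.sample_rate_sd_hz)) + 10
    rates = rng.normal(cfg.sample_rate_hz, cfg.sample_rate_sd_hz, n_max)
    rates = np.clip(rates, cfg.sample_rate_hz / 2.0, cfg.sample_rate_hz * 2.0)
    times = np.concatenate([[0.0], np.cumsum(1.0 / rates)])
    times = times[times <= cfg.duration_s]
    n = len(times)
    dt = np.diff(times)

    head_home = np.array([0.0, EYE_HEIGHT, 0.0])

    # -- scanpath and blinks ---------------------------------------------
    segments = _build_scanpath(rng, cfg, condition, scene, head_home)
    t_end = float(times[-1])
    blinks = _schedule_blinks(rng, cfg, segments, t_end)
    events, sample_kind, gazed = _truth_events(segments, blinks, times, t_end)

    # -- per-sample intended gaze point ----------------------------------
    g_base = np.empty((n, 3))
    for seg in segments:
        i0 = int(np.searchsorted(times, seg.t0, side="left"))
        i1 = int(np.searchsorted(times, min(seg.t1, t_end), side="right"))
        if i1 <= i0:
            continue
        if seg.kind == "fixation":
            g_base[i0:i1] = seg.p0
        else:
            frac = (times[i0:i1] - seg.t0) / (seg.t1 - seg.t0)
            g_base[i0:i1] = seg.p0 + _saccade_progress(frac)[:, None] * (seg.p1 - seg.p0)
    # angular gaze noise: tangential displacement scales with target distance
    rel_base = g_base - head_home
    d_base = np.linalg.norm(rel_base, axis=1)
    u_base = rel_base / d_base[:, None]
    wobble = np.zeros((n, 3))
    if cfg.fixation_drift_deg > 0:
        wobble += _ou(rng, dt, cfg.fixation_drift_tau_s,
                      math.radians(cfg.fixation_drift_deg), 3)
    if cfg.gaze_noise_deg > 0:
        wobble += rng.standard_normal((n, 3)) * math.radians(cfg.gaze_noise_deg)
    wobble -= np.einsum("ij,ij->i", wobble, u_base)[:, None] * u_base
    gaze_point = g_base + wobble * d_base[:, None]

    # -- head pose --------------------------------------------------------
    head_pos = head_home + _ou(rng, dt, cfg.head_sway_tau_s, cfg.head_sway_sd_m, 3)
    if cfg.head_tracking:
        forward = np.array([0.0, 0.0, 1.0])
        blend = _unit(
            (1.0 - cfg.head_track_gain) * forward
            + cfg.head_track_gain * _unit(gaze_point - head_pos)
        )
        view = _unit(_ema(blend, dt, cfg.head_track_tau_s))
        if cfg.head_rot_noise_deg > 0:
            ang = math.radians(cfg.head_rot_noise_deg)
            view = _unit(view + _ou(rng, dt, 1.0, ang, 3))
    else:
        view = np.tile([0.0, 0.0, 1.0], (n, 1))
    world_up = np.array([0.0, 1.0, 0.0])
    right = _unit(np.cross(np.broadcast_to(world_up, view.shape), view))
    up = _unit(np.cross(view, right))

    # -- combined gaze ray and surface hit --------------------------------
    u_comb = _unit(gaze_point - head_pos)
    surf_comb, labels = scene.cast_rays(head_pos, u_comb)
    d_surf = np.linalg.norm(surf_comb - head_pos, axis=1)
    d_ref = np.where(np.isfinite(d_surf), d_surf,
                     np.linalg.norm(gaze_point - head_pos, axis=1))

    # -- vergence: place the focus point along the combined ray -----------
    env = cfg.envelope(times)
    delta = (
        vergence_bias
        + env * cfg.focus_shift_ratio[condition]
        + _ou(rng, dt, cfg.vergence_slow_tau_s, cfg.vergence_slow_sd)
    )
    if cfg.vergence_noise_coeff > 0:
        delta = delta + rng.standard_normal(n) * (cfg.vergence_noise_coeff * d_ref)
    focus = head_pos + u_comb * (d_ref * (1.0 + delta))[:, None]

    # -- per-eye rays ------------------------------------------------------
    origin_l = head_pos - 0.5 * cfg.ipd_m * right
    origin_r = head_pos + 0.5 * cfg.ipd_m * right
    dir_l = _unit(focus - origin_l)
    dir_r = _unit(focus - origin_r)
    surf_l, _ = scene.cast_rays(origin_l, dir_l)
    surf_r, _ = scene.cast_rays(origin_r, dir_r)

    # -- pupil --------------------------------------------------------------
    ratio = cfg.pupil_variance_ratio[condition]
    slow = _ou(rng, dt, cfg.pupil_slow_tau_s, cfg.pupil_slow_sd_mm)
    fast = rng.standard_normal(n) * cfg.pupil_fast_sd_mm if cfg.pupil_fast_sd_mm else 0.0
    signal = (
        pupil_baseline_mm
        + env * cfg.pupil_shift_mm[condition]
        + env * math.sqrt(ratio) * (slow + fast)
    )
    eye_noise = (
        rng.standard_normal((n, 2)) * cfg.pupil_eye_noise_sd_mm
        if cfg.pupil_eye_noise_sd_mm
        else np.zeros((n, 2))
    )
    pupil_l = signal + eye_noise[:, 0]
    pupil_r = signal + eye_noise[:, 1]

    # -- blink artifacts -----------------------------------------------------
    closed = np.zeros(n, dtype=bool)
    for b0, b1 in blinks:
        closed |= (times >= b0) & (times <= b1)
        for lo, hi, anchor in ((b0 - cfg.blink_corrupt_window_s, b0, b0),
                               (b1, b1 + cfg.blink_corrupt_window_s, b1)):
            m = (times >= lo) & (times <= hi) & ~((times >= b0) & (times <= b1))
            w = 1.0 - np.abs(times[m] - anchor) / cfg.blink_corrupt_window_s
            pupil_l[m] -= cfg.blink_corrupt_dip_mm * w
            pupil_r[m] -= cfg.blink_corrupt_dip_mm * w
    pupil_l = np.where(closed, PUPIL_SENTINEL, pupil_l)
    pupil_r = np.where(closed, PUPIL_SENTINEL, pupil_r)
    if closed.any():
        surf_comb[closed] = np.nan
        surf_l[closed] = np.nan
        surf_r[closed] = np.nan
        focus[closed] = np.nan
        labels[closed] = ""
        if cfg.blink_gaze_noise_deg > 0:
            ang = math.radians(cfg.blink_gaze_noise_deg)
            k = int(closed.sum())
            dir_l[closed] = _unit(dir_l[closed] + ang * rng.standard_normal((k, 3)))
            dir_r[closed] = _unit(dir_r[closed] + ang * rng.standard_normal((k, 3)))

    # -- assemble -------------------------------------------------------------
    data: dict[str, np.ndarray] = {"time_s": times}
    for prefix, arr in (
        ("head_pos", head_pos), ("head_view", view), ("head_up", up),
        ("gaze_origin_L", origin_l), ("gaze_origin_R", origin_r),
        ("gaze_dir_L", dir_l), ("gaze_dir_R", dir_r),
        ("surface_point_L", surf_l), ("surface_point_R", surf_r),
        ("focus_point", focus),
    ):
        for j, ax in enumerate("xyz"):
            data[f"{prefix}_{ax}"] = arr[:, j]
    data["pupil_L_mm"] = pupil_l
    data["pupil_R_mm"] = pupil_r
    data["target_label"] = labels
    df = pd.DataFrame(data, columns=SAMPLE_COLUMNS)

    trial = Trial(
        participant_id=participant_id,
        condition=condition,
        samples=df,
        presentation_index=presentation_index,
    )
    truth = TrialTruth(
        events=events,
        sample_kind=sample_kind,
        gazed_label=gazed,
        focus_delta=np.asarray(delta, dtype=float),
        clean_pupil=np.asarray(signal, dtype=float),
    )
    return trial, truth


def simulate_session(
    config: GeneratorConfig,
    participant_id: str,
    seed: int | np.random.SeedSequence,
    conditions: Sequence[str] = CONDITIONS,
) -> tuple[SessionLog, dict[str, TrialTruth]]:
    """Simulate one participant: one trial per condition in random order.

    The participant's pupil baseline and vergence bias are drawn once and
    shared across their trials.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(conditions) + 1)
    rng = np.random.default_rng(children[0])
    baseline = float(
        np.clip(
            rng.normal(config.pupil_baseline_mean_mm, config.pupil_baseline_sd_mm),
            *config.pupil_baseline_range_mm,
        )
    )
    bias = float(rng.normal(0.0, config.vergence_bias_sd))
    order = rng.permutation(len(conditions))
    scene = build_scene()

    trials: list[Trial] = [None] * len(conditions)  # type: ignore[list-item]
    truths: dict[str, TrialTruth] = {}
    for slot, cond_idx in enumerate(order):
        condition = conditions[cond_idx]
        trial, truth = simulate_trial(
            config,
            condition,
            participant_id,
            children[1 + cond_idx],
            pupil_baseline_mm=baseline,
            vergence_bias=bias,
            scene=scene,
            presentation_index=slot + 1,
        )
        trials[cond_idx] = trial
        truths[condition] = truth
    log = SessionLog(
        participant_id=participant_id,
        trials=list(trials),
        metadata={"nominal_rate_hz": config.sample_rate_hz, "device": "synthetic"},
    )
    return log, truths


def simulate_cohort(
    config: GeneratorConfig,
    n_participants: int,
    seed: int | np.random.SeedSequence,
) -> list[tuple[SessionLog, dict[str, TrialTruth]]]:
    """Simulate a cohort of participants with independent sub-seeds."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(ss.spawn(n_participants)):
        out.append(simulate_session(config, f"P{i + 1:02d}", child))
    return out
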