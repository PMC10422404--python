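"""Canonical data model for VR eye-tracking sessions.

A trial's samples live in a :class:`pandas.DataFrame` with the fixed wide
column schema in :data:`SAMPLE_COLUMNS` (one row per synchronized binocular
sample).  Dataclass wrappers carry trial/session metadata and enforce the
structural invariants; heavy numerics operate on the underlying arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

#: The four listening conditions, ordered by intended difficulty.
CONDITIONS: tuple[str, ...] = (
    "JP-Familiar",
    "JP-Unfamiliar",
    "EN-Familiar",
    "EN-Unfamiliar",
)

#: Sentinel written by the eye tracker for closed eyes or measurement errors.
PUPIL_SENTINEL = -1.0

#: Physiologically plausible pupil diameter range (mm); values outside are
#: treated as invalid just like the sentinel.
PUPIL_RANGE_MM = (1.0, 10.0)


def _vec3(prefix: str) -> list[str]:
    return [f"{prefix}_{ax}" for ax in "xyz"]


#: Exact column order of the session CSV (one row per sample).
SAMPLE_COLUMNS: list[str] = (
    ["time_s"]
    + _vec3("head_pos")
    + _vec3("head_view")
    + _vec3("head_up")
    + _vec3("gaze_origin_L")
    + _vec3("gaze_origin_R")
    + _vec3("gaze_dir_L")
    + _vec3("gaze_dir_R")
    + _vec3("surface_point_L")
    + _vec3("surface_point_R")
    + _vec3("focus_point")
    + ["pupil_L_mm", "pupil_R_mm", "target_label"]
)

#: Columns that may legitimately be empty (ray hit nothing / blink).
OPTIONAL_VECTOR_PREFIXES = ("surface_point_L", "surface_point_R", "focus_point")

#: Unit-norm tolerance for direction/view/up vectors.
UNIT_NORM_TOL = 1e-6


class SchemaError(ValueError):
    """The tabular log does not match the documented column schema."""


class ValidationError(ValueError):
    """A sample or trial violates a structural invariant."""


class TrialUnusableError(ValueError):
    """A trial contains no usable data (e.g. every pupil sample invalid)."""


@dataclass
class GazeSample:
    """One synchronized binocular eye + head sample.

    3D quantities are in metres in a right-handed, y-up world frame; pupil
    diameters in mm with ``-1`` as the invalid sentinel.  Optional points are
    ``None`` when the corresponding ray hit nothing.
    """

    time: float
    head_pos: np.ndarray
    head_view: np.ndarray
    head_up: np.ndarray
    gaze_origin_L: np.ndarray
    gaze_origin_R: np.ndarray
    gaze_dir_L: np.ndarray
    gaze_dir_R: np.ndarray
    surface_point_L: np.ndarray | None
    surface_point_R: np.ndarray | None
    focus_point: np.ndarray | None
    pupil_L_mm: float
    pupil_R_mm: float
    target_label: str = ""

    @classmethod
    def from_row(cls, row: pd.Series) -> "GazeSample":
        def vec(prefix: str) -> np.ndarray:
            return np.array([row[f"{prefix}_{ax}"] for ax in "xyz"], dtype=float)

        def optvec(prefix: str) -> np.ndarray | None:
            v = vec(prefix)
            return None if np.isnan(v).all() else v

        return cls(
            time=float(row["time_s"]),
            head_pos=vec("head_pos"),
            head_view=vec("head_view"),
            head_up=vec("head_up"),
            gaze_origin_L=vec("gaze_origin_L"),
            gaze_origin_R=vec("gaze_origin_R"),
            gaze_dir_L=vec("gaze_dir_L"),
            gaze_dir_R=vec("gaze_dir_R"),
            surface_point_L=optvec("surface_point_L"),
            surface_point_R=optvec("surface_point_R"),
            focus_point=optvec("focus_point"),
            pupil_L_mm=float(row["pupil_L_mm"]),
            pupil_R_mm=float(row["pupil_R_mm"]),
            target_label="" if pd.isna(row["target_label"]) else str(row["target_label"]),
        )


def pupil_valid(values: np.ndarray) -> np.ndarray:
    """Boolean mask of pupil samples that are physiologically valid.

    Invalid means the ``-1`` sentinel, NaN, or a value outside
    :data:`PUPIL_RANGE_MM`.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = PUPIL_RANGE_MM
    with np.errstate(invalid="ignore"):
        return (values >= lo) & (values <= hi)


@dataclass
class Trial:
    """One participant x audio-condition listening phase."""

    participant_id: str
    condition: str
    samples: pd.DataFrame
    presentation_index: int | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )

    @property
    def times(self) -> np.ndarray:
        return self.samples["time_s"].to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def duration(self) -> float:
        t = self.times
        return float(t[-1] - t[0])

    def vectors(self, prefix: str) -> np.ndarray:
        """(n, 3) float array for a 3D column group such as ``head_pos``."""
        cols = [f"{prefix}_{ax}" for ax in "xyz"]
        return self.samples[cols].to_numpy(dtype=float)


@dataclass
class SessionLog:
    """All trials of one participant, at most one per condition."""

    participant_id: str
    trials: list[Trial] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __iter__(self) -> Iterator[Trial]:
        return iter(self.trials)

    def trial(self, condition: str) -> Trial:
        for t in self.trials:
            if t.condition == condition:
                return t
        raise KeyError(condition)


@dataclass
class OcularEvent:
    """A blink, fixation, or saccade with inclusive sample-index bounds."""

    kind: str  # "blink" | "fixation" | "saccade"
    start_index: int
    end_index: int
    start_time: float
    end_time: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("blink", "fixation", "saccade"):
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.start_index > self.end_index:
            raise ValidationError("event start_index exceeds end_index")
        if self.end_time < self.start_time:
            raise ValidationError("event end_time precedes start_time")

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index + 1

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start_time + self.end_time)


def validate_samples(df: pd.DataFrame) -> None:
    """Check sample-level invariants of a trial frame; raise on violation."""
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValidationError("non-finite timestamps")
    if len(t) >= 2:
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise ValidationError(
                f"timestamps not strictly increasing at row {int(bad[0]) + 1}"
            )
    for prefix in ("head_view", "head_up", "gaze_dir_L", "gaze_dir_R"):
        v = df[[f"{prefix}_{ax}" for ax in "xyz"]].to_numpy(dtype=float)
        norms = np.linalg.norm(v, axis=1)
        off = np.abs(norms - 1.0) > UNIT_NORM_TOL
        if off.any():
            raise ValidationError(
                f"{prefix} is not unit-norm at row {int(np.nonzero(off)[0][0])}"
            )
    for col in ("pupil_L_mm", "pupil_R_mm"):
        p = df[col].to_numpy(dtype=float)
        ok = pupil_valid(p) | (p == PUPIL_SENTINEL)
        if not ok.all():
            raise ValidationError(
                f"{col} outside [{PUPIL_RANGE_MM[0]}, {PUPIL_RANGE_MM[1]}] mm and not "
                f"the {PUPIL_SENTINEL} sentinel at row {int(np.nonzero(~ok)[0][0])}"
            )


def validate_trial(trial: Trial) -> None:
    """Check trial-level invariants (ordering, minimum length, samples)."""
    if trial.n_samples < 2:
        raise ValidationError("a trial needs at least 2 samples")
    validate_samples(trial.samples)


def validate_session(log: SessionLog) -> None:
    seen: set[str] = set()
    for trial in log.trials:
        if trial.condition in seen:
            raise ValidationError(
                f"more than one trial for condition {trial.condition!r}"
            )
        seen.add(trial.condition)
        if trial.participant_id != log.participant_id:
            raise ValidationError("trial participant_id differs from session")
        validate_trial(trial)


def events_to_frame(events: Sequence[OcularEvent]) -> pd.DataFrame:
    """Tabulate events (one row each) for CSV export."""
    return pd.DataFrame(
        {
            "kind": [e.kind for e in events],
            "start_index": [e.start_index for e in events],
            "end_index": [e.end_index for e in events],
            "start_time": [e.start_time for e in events],
            "end_time": [e.end_time for e in events],
            "duration": [e.duration for e in events],
            "label": [e.label for e in events],
        }
    )
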