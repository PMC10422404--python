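"""Focus offset: surface-normalized binocular gaze-depth displacement.

The focus point is where the left and right gaze rays come closest to each
other.  Its signed displacement from the gazed-at surface point, projected
onto the gaze direction and divided by the surface distance, is the focus
offset: zero when fixating the surface, positive when looking "through" it
(focus behind the surface), negative when converging in front of it.
Division by surface distance makes the metric dimensionless and invariant
to uniformly rescaling the scene about the head.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.signal import savgol_filter

from .types import GazeSample, Trial

#: Below this angle between the two gaze directions the rays are treated as
#: parallel and the sample is invalid (the closest point is unstable).
MIN_VERGENCE_ANGLE_DEG = 0.1

DEFAULT_SG_WINDOW = 201
DEFAULT_SG_POLYORDER = 3


@dataclass
class FocusOffsetSample:
    """One focus-offset observation."""

    time: float
    offset: float  # dimensionless signed ratio
    surface_distance: float  # m
    ray_gap: float  # m, minimal distance between the two gaze rays
    valid: bool


def closest_point_between_rays(
    origin1: np.ndarray,
    dir1: np.ndarray,
    origin2: np.ndarray,
    dir2: np.ndarray,
    min_angle_deg: float = MIN_VERGENCE_ANGLE_DEG,
) -> tuple[np.ndarray, float, bool]:
    """Closed-form least-distance point between two rays.

    Returns ``(midpoint, gap, valid)`` where midpoint is halfway between the
    closest point pair and gap their distance.  ``valid`` is False for
    near-parallel directions (angle below ``min_angle_deg``) or when a
    closest-approach parameter is negative (divergent rays); the returned
    midpoint is then the unconstrained solution and should not be used.
    """
    o1 = np.asarray(origin1, dtype=float)
    o2 = np.asarray(origin2, dtype=float)
    d1 = np.asarray(dir1, dtype=float)
    d2 = np.asarray(dir2, dtype=float)
    n1 = np.linalg.norm(d1)
    n2 = np.linalg.norm(d2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("zero-length ray direction")
    d1 = d1 / n1
    d2 = d2 / n2
    b = float(d1 @ d2)
    if abs(b) >= math.cos(math.radians(min_angle_deg)):
        return 0.5 * (o1 + o2), float("nan"), False
    r = o1 - o2
    d = float(d1 @ r)
    e = float(d2 @ r)
    denom = 1.0 - b * b
    s = (b * e - d) / denom
    t = (e - b * d) / denom
    p1 = o1 + s * d1
    p2 = o2 + t * d2
    midpoint = 0.5 * (p1 + p2)
    gap = float(np.linalg.norm(p1 - p2))
    return midpoint, gap, bool(s >= 0.0 and t >= 0.0)


def compute_focus_offset(sample: GazeSample, head: np.ndarray | None = None) -> FocusOffsetSample:
    """Focus offset of a single gaze sample.

    The gazed surface point S is the midpoint of the per-eye surface
    collision points (or the existing one when an eye's ray hit nothing);
    the focus point F is taken from the sample or recomputed as the closest
    point between the gaze rays.  With H the head position and u the unit
    vector toward S, the offset is ``((F - H)@u - |S - H|) / |S - H|``.
    """
    head = np.asarray(sample.head_pos if head is None else head, dtype=float)
    pts = [p for p in (sample.surface_point_L, sample.surface_point_R) if p is not None]
    if not pts:
        return FocusOffsetSample(sample.time, float("nan"), float("nan"), float("nan"), False)
    surface = np.mean(pts, axis=0)
    gap = float("nan")
    if sample.focus_point is not None:
        focus = np.asarray(sample.focus_point, dtype=float)
    else:
        focus, gap, ok = closest_point_between_rays(
            sample.gaze_origin_L, sample.gaze_dir_L,
            sample.gaze_origin_R, sample.gaze_dir_R,
        )
        if not ok:
            return FocusOffsetSample(sample.time, float("nan"), float("nan"), gap, False)
    d_s = float(np.linalg.norm(surface - head))
    if d_s <= 0.0:
        return FocusOffsetSample(sample.time, float("nan"), d_s, gap, False)
    u = (surface - head) / d_s
    d_f = float((focus - head) @ u)
    offset = (d_f - d_s) / d_s
    return FocusOffsetSample(sample.time, offset, d_s, gap, math.isfinite(offset))


def compute_focus_offsets(trial: Trial) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-sample focus offsets for a whole trial.

    Returns ``(offset, surface_distance, valid)`` arrays; samples without a
    surface hit or focus point are invalid (NaN offset), never zero-filled.
    """
    head = trial.vectors("head_pos")
    surf_l = trial.vectors("surface_point_L")
    surf_r = trial.vectors("surface_point_R")
    focus = trial.vectors("focus_point")
    ok_l = np.isfinite(surf_l).all(axis=1)
    ok_r = np.isfinite(surf_r).all(axis=1)
    n = len(head)
    surface = np.full((n, 3), np.nan)
    both = ok_l & ok_r
    surface[both] = 0.5 * (surf_l[both] + surf_r[both])
    surface[ok_l & ~ok_r] = surf_l[ok_l & ~ok_r]
    surface[ok_r & ~ok_l] = surf_r[ok_r & ~ok_l]
    rel = surface - head
    d_s = np.linalg.norm(rel, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = rel / d_s[:, None]
        d_f = np.einsum("ij,ij->i", focus - head, u)
        offset = (d_f - d_s) / d_s
    valid = np.isfinite(offset) & (d_s > 0)
    offset = np.where(valid, offset, np.nan)
    return offset, d_s, valid


def smooth_focus_offset(
    series: np.ndarray,
    window: int = DEFAULT_SG_WINDOW,
    polyorder: int = DEFAULT_SG_POLYORDER,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Savitzky-Golay smoothing applied per contiguous valid segment.

    Invalid samples (NaN, or flagged by ``valid``) stay absent — segments are
    smoothed independently, never bridged.  A segment shorter than the window
    uses the largest odd window that fits (with the polynomial order capped
    below it), with a warning.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than the window")
    series = np.asarray(series, dtype=float)
    mask = np.isfinite(series)
    if valid is not None:
        mask &= np.asarray(valid, dtype=bool)
    out = np.full(series.shape, np.nan)
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    warned = False
    for k in range(0, len(idx), 2):
        i0, i1 = int(idx[k]), int(idx[k + 1])
        seg = series[i0:i1]
        w = min(window, len(seg) if len(seg) % 2 else len(seg) - 1)
        if w < window and not warned:
            warnings.warn(
                f"segment of {len(seg)} samples shorter than SG window {window}; "
                f"using window {w}",
                stacklevel=2,
            )
            warned = True
        if w < 2:
            out[i0:i1] = seg
            continue
        p = min(polyorder, w - 1)
        out[i0:i1] = savgol_filter(seg, w, p)
    return out


def center_per_participant(
    series_by_participant: Mapping[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Subtract each participant's median valid offset from their series.

    Participants with no valid data are excluded with a warning.  The median
    of each returned series is zero over its valid samples.
    """
    out: dict[str, np.ndarray] = {}
    for pid, values in series_by_participant.items():
        values = np.asarray(values, dtype=float)
        finite = np.isfinite(values)
        if not finite.any():
            warnings.warn(f"participant {pid!r} has no valid focus-offset data; excluded",
                          stacklevel=2)
            continue
        out[pid] = values - float(np.median(values[finite]))
    return out
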