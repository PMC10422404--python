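"""Virtual-screen gaze projection and adaptive fixation/saccade detection.

3D gaze is intersected with a plane 3 m ahead in the user's head space,
expressed in a per-trial virtual screen sized from the trimmed spread of the
intersection points (150 dpi), and classified into fixations and saccades
with a per-trial adaptive velocity threshold (iterative mean + 3 SD outlier
clipping, an I-VT construction) that uses the actual, non-uniform sample
timestamps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import OcularEvent, Trial

DEFAULT_PLANE_DISTANCE_M = 3.0
DEFAULT_DPI = 150
DEFAULT_TRIM_QUANTILE = 0.0025
DEFAULT_MIN_FIXATION_S = 0.100
DEFAULT_THRESHOLD_SD = 3.0
DEFAULT_DROP_SAMPLES = 3
#: Physical floor on the adaptive threshold: gaze slower than this is never a
#: saccade.  Keeps numerical jitter from registering when the velocity
#: distribution collapses to (near) zero variance.
MIN_THRESHOLD_PX_S = 1.0
MAX_GAZE_ANGLE_DEG = 89.0
METERS_PER_INCH = 0.0254


@dataclass
class VirtualScreen:
    """Per-trial head-space projection screen (origin top-left, y down)."""

    distance_m: float
    width_m: float
    height_m: float
    dpi: int
    x_min_m: float  # left bound of the trimmed, median-centered cloud
    y_max_m: float  # top bound (y up in plane coordinates)

    @property
    def width_px(self) -> float:
        return self.width_m / METERS_PER_INCH * self.dpi

    @property
    def height_px(self) -> float:
        return self.height_m / METERS_PER_INCH * self.dpi


@dataclass
class ScreenGaze:
    """Per-sample pixel gaze positions on the virtual screen."""

    time: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray


def combined_gaze_ray(
    head_pos: np.ndarray, focus_point: np.ndarray, min_dist_m: float = 1e-3
) -> np.ndarray | None:
    """Unit direction of the combined gaze ray from head to focus point."""
    head_pos = np.asarray(head_pos, dtype=float)
    focus_point = np.asarray(focus_point, dtype=float)
    rel = focus_point - head_pos
    norm = np.linalg.norm(rel)
    if not np.isfinite(norm) or norm < min_dist_m:
        return None
    return rel / norm


def combined_gaze_rays(trial: Trial, min_dist_m: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized combined rays for a trial: (directions, valid mask)."""
    head = trial.vectors("head_pos")
    focus = trial.vectors("focus_point")
    rel = focus - head
    norm = np.linalg.norm(rel, axis=1)
    valid = np.isfinite(norm) & (norm >= min_dist_m)
    with np.errstate(invalid="ignore", divide="ignore"):
        dirs = rel / norm[:, None]
    dirs[~valid] = np.nan
    return dirs, valid


def _orthonormal_frame(view: np.ndarray, up: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    view = view / np.linalg.norm(view, axis=-1, keepdims=True)
    up = up - np.einsum("ij,ij->i", up, view)[:, None] * view
    up = up / np.linalg.norm(up, axis=-1, keepdims=True)
    right = np.cross(up, view)
    return right, up, view


def project_to_plane(
    dirs: np.ndarray,
    head_view: np.ndarray,
    head_up: np.ndarray,
    distance_m: float = DEFAULT_PLANE_DISTANCE_M,
) -> tuple[np.ndarray, np.ndarray]:
    """Intersect gaze directions with the head-space plane.

    The plane is orthogonal to ``head_view`` at ``distance_m``; coordinates
    are metres along the head frame's right/up axes (up re-orthogonalized
    against view).  Gaze more than 89 degrees off the view axis (or behind
    it) is invalid.  Returns ``(points_m, valid)`` with points of shape (n, 2).
    """
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    head_view = np.atleast_2d(np.asarray(head_view, dtype=float))
    head_up = np.atleast_2d(np.asarray(head_up, dtype=float))
    right, up, view = _orthonormal_frame(head_view, head_up)
    z = np.einsum("ij,ij->i", dirs, view)
    x = np.einsum("ij,ij->i", dirs, right)
    y = np.einsum("ij,ij->i", dirs, up)
    min_z = np.cos(np.radians(MAX_GAZE_ANGLE_DEG))
    valid = np.isfinite(z) & (z > min_z)
    with np.errstate(invalid="ignore", divide="ignore"):
        px = distance_m * x / z
        py = distance_m * y / z
    points = np.column_stack([px, py])
    points[~valid] = np.nan
    return points, valid


def fit_virtual_screen(
    points_m: np.ndarray,
    times: np.ndarray | None = None,
    trim_quantile: float = DEFAULT_TRIM_QUANTILE,
    dpi: int = DEFAULT_DPI,
    distance_m: float = DEFAULT_PLANE_DISTANCE_M,
) -> tuple[VirtualScreen, ScreenGaze]:
    """Size the per-trial virtual screen and map gaze to pixel coordinates.

    Points are median-centered per axis; per axis the screen bounds are the
    ``trim_quantile`` and ``1 - trim_quantile`` quantiles of the centered
    coordinates, so a handful of extreme outliers does not inflate the
    screen.  All points (including the trimmed-for-sizing ones) are mapped to
    pixels at ``dpi``; the y axis is flipped to the screen convention
    (origin top-left, y down).
    """
    points = np.asarray(points_m, dtype=float)
    valid = np.isfinite(points).all(axis=1)
    if valid.sum() < 10:
        raise ValueError("need at least 10 valid gaze points to size the screen")
    centered = points - np.nanmedian(points[valid], axis=0)
    lo = np.nanquantile(centered[valid], trim_quantile, axis=0)
    hi = np.nanquantile(centered[valid], 1.0 - trim_quantile, axis=0)
    extent = hi - lo
    if np.any(extent <= 0):
        raise ValueError("degenerate gaze spread: screen would have zero extent")
    screen = VirtualScreen(
        distance_m=float(distance_m),
        width_m=float(extent[0]),
        height_m=float(extent[1]),
        dpi=int(dpi),
        x_min_m=float(lo[0]),
        y_max_m=float(hi[1]),
    )
    scale = dpi / METERS_PER_INCH
    x_px = (centered[:, 0] - lo[0]) * scale
    y_px = (hi[1] - centered[:, 1]) * scale  # flip: screen y grows downward
    if times is None:
        times = np.arange(len(points), dtype=float)
    gaze = ScreenGaze(
        time=np.asarray(times, dtype=float), x_px=x_px, y_px=y_px, valid=valid
    )
    return screen, gaze


def gaze_velocity(
    gaze: ScreenGaze, assume_uniform_rate: bool = False
) -> np.ndarray:
    """Per-sample gaze speed in px/s (NaN where undefined).

    ``v[i]`` covers the interval from sample ``i - 1`` to ``i``; it is NaN at
    the first sample of each contiguous valid run.  With
    ``assume_uniform_rate`` the interval durations are replaced by the trial
    mean (the end-point rescaling compatibility mode).
    """
    t = gaze.time
    n = len(t)
    v = np.full(n, np.nan)
    dx = np.diff(gaze.x_px)
    dy = np.diff(gaze.y_px)
    dt = np.diff(t)
    if assume_uniform_rate and n > 1:
        dt = np.full(n - 1, (t[-1] - t[0]) / (n - 1))
    ok = gaze.valid[1:] & gaze.valid[:-1] & (dt > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        speed = np.hypot(dx, dy) / dt
    v[1:][ok] = speed[ok]
    return v


def adaptive_velocity_threshold(
    velocities: np.ndarray,
    n_sd: float = DEFAULT_THRESHOLD_SD,
    max_iter: int = 20,
) -> float:
    """Iterative outlier-clipped velocity threshold (mean + n_sd * SD).

    The threshold is re-estimated on sub-threshold samples until it stops
    changing or ``max_iter`` iterations.  With zero velocity variance the
    threshold collapses to the common value, so any strictly larger velocity
    still counts as a saccade.
    """
    v = np.asarray(velocities, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("inf")
    thr = float(np.mean(v) + n_sd * np.std(v))
    for _ in range(max_iter):
        sub = v[v <= thr]
        if sub.size == 0:
            break
        new = float(np.mean(sub) + n_sd * np.std(sub))
        if new == thr:
            break
        thr = new
    return max(thr, MIN_THRESHOLD_PX_S)


def detect_fixations_saccades(
    gaze: ScreenGaze,
    *,
    n_sd: float = DEFAULT_THRESHOLD_SD,
    min_fixation_s: float = DEFAULT_MIN_FIXATION_S,
    drop_samples: int = DEFAULT_DROP_SAMPLES,
    max_iter: int = 20,
    assume_uniform_rate: bool = False,
) -> list[OcularEvent]:
    """Adaptive I-VT classification of a trial's screen gaze.

    Velocities are computed with the actual timestamps; one threshold is
    estimated per trial by iterative mean + ``n_sd`` SD clipping.
    Sub-threshold runs lasting at least ``min_fixation_s`` become fixations,
    super-threshold runs become saccades.  Events are mapped back to sample
    indices with inward rounding (a saccade cedes its boundary samples to the
    neighboring fixations), so events never overlap; events spanning
    ``drop_samples`` samples or fewer are dropped.  Invalid (blink) spans
    break events.
    """
    t = gaze.time
    n = len(t)
    if n < 2 or not gaze.valid.any() or t[gaze.valid][-1] - t[gaze.valid][0] < 1.0:
        raise ValueError("need at least 1 s of valid data")
    v = gaze_velocity(gaze, assume_uniform_rate=assume_uniform_rate)
    thr = adaptive_velocity_threshold(v, n_sd=n_sd, max_iter=max_iter)

    events: list[OcularEvent] = []
    mask = gaze.valid.astype(np.int8)
    bounds = np.flatnonzero(np.diff(np.concatenate([[0], mask, [0]])))
    for k in range(0, len(bounds), 2):
        s0, s1 = int(bounds[k]), int(bounds[k + 1]) - 1  # inclusive segment
        if s1 <= s0:
            continue
        iv = np.arange(s0 + 1, s1 + 1)  # interval j covers samples (j-1, j)
        sup = v[iv] > thr
        run_edges = np.flatnonzero(np.diff(np.concatenate([[-1], sup.view(np.int8), [-1]])))
        starts = run_edges[:-1]
        for a, bnd in zip(starts, run_edges[1:]):
            j0, j1 = int(iv[a]), int(iv[bnd - 1])
            if sup[a]:  # saccade: inward rounding cedes boundary samples
                # the motion spans samples j0-1..j1; drop sub-resolution events
                if (j1 - j0 + 2) <= drop_samples:
                    continue
                i0, i1 = j0, max(j1 - 1, j0)
                events.append(
                    OcularEvent("saccade", i0, i1, float(t[i0]), float(t[i1]))
                )
            else:  # fixation owns its boundary samples
                i0, i1 = j0 - 1, j1
                if i1 - i0 + 1 <= drop_samples:
                    continue
                if t[i1] - t[i0] < min_fixation_s:
                    continue
                events.append(
                    OcularEvent("fixation", i0, i1, float(t[i0]), float(t[i1]))
                )
    events.sort(key=lambda e: e.start_index)
    return events


def project_trial(
    trial: Trial,
    valid: np.ndarray | None = None,
    *,
    distance_m: float = DEFAULT_PLANE_DISTANCE_M,
    dpi: int = DEFAULT_DPI,
    trim_quantile: float = DEFAULT_TRIM_QUANTILE,
) -> tuple[VirtualScreen, ScreenGaze]:
    """Full projection chain for a trial: combined ray, plane, screen fit.

    ``valid`` can pre-mask samples (e.g. extended blinks) before the screen
    is sized.
    """
    dirs, ray_ok = combined_gaze_rays(trial)
    points, plane_ok = project_to_plane(
        dirs, trial.vectors("head_view"), trial.vectors("head_up"), distance_m
    )
    ok = ray_ok & plane_ok
    if valid is not None:
        ok &= np.asarray(valid, dtype=bool)
    points[~ok] = np.nan
    return fit_virtual_screen(
        points, trial.times, trim_quantile=trim_quantile, dpi=dpi, distance_m=distance_m
    )
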