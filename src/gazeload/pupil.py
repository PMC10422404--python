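"""Pupil time-series cleaning: blink detection, interpolation, smoothing,
baseline correction, and binocular combination.

Blinks are defined as maximal runs of invalid samples (the ``-1`` sentinel or
values outside the physiological range), extended 200 ms before and after to
cover lid-closure artifacts, and merged when their extended spans touch.
All steps work on the trial's actual (non-uniform) timestamps.
"""

from __future__ import annotations

import numpy as np

from .types import OcularEvent, TrialUnusableError, pupil_valid

DEFAULT_BLINK_EXTENSION_S = 0.2
DEFAULT_BASELINE_WINDOW_S = (0.5, 2.0)
DEFAULT_SMOOTH_WINDOW = 5


def _invalid_runs(invalid: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive index bounds of maximal runs of True."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], invalid.view(np.int8), [0]])))
    return [(int(idx[i]), int(idx[i + 1] - 1)) for i in range(0, len(idx), 2)]


def detect_blinks_from_mask(
    invalid: np.ndarray, times: np.ndarray, extend_s: float = DEFAULT_BLINK_EXTENSION_S
) -> list[OcularEvent]:
    """Blink events from a per-sample invalidity mask.

    Each maximal invalid run becomes a blink, extended ``extend_s`` backward
    and forward in time (clipped to the trial bounds) and expressed in sample
    indices via the actual timestamps; blinks whose extended spans touch or
    overlap are merged.
    """
    invalid = np.asarray(invalid, dtype=bool)
    times = np.asarray(times, dtype=float)
    if len(invalid) != len(times):
        raise ValueError("mask and times must have equal length")
    if invalid.all():
        raise TrialUnusableError("every sample is invalid")
    spans = []
    for i0, i1 in _invalid_runs(invalid):
        spans.append((times[i0] - extend_s, times[i1] + extend_s))
    merged: list[list[float]] = []
    for t0, t1 in spans:
        if merged and t0 <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], t1)
        else:
            merged.append([t0, t1])
    events = []
    for t0, t1 in merged:
        i0 = int(np.searchsorted(times, t0, side="left"))
        i1 = int(np.searchsorted(times, t1, side="right")) - 1
        i0, i1 = max(i0, 0), min(i1, len(times) - 1)
        events.append(OcularEvent("blink", i0, i1, float(times[i0]), float(times[i1])))
    return events


def detect_blinks(
    pupil: np.ndarray, times: np.ndarray, extend_s: float = DEFAULT_BLINK_EXTENSION_S
) -> list[OcularEvent]:
    """Blink events from one eye's pupil trace (sentinel/range invalidity)."""
    return detect_blinks_from_mask(~pupil_valid(pupil), times, extend_s)


def detect_blinks_binocular(
    pupil_l: np.ndarray,
    pupil_r: np.ndarray,
    times: np.ndarray,
    extend_s: float = DEFAULT_BLINK_EXTENSION_S,
) -> list[OcularEvent]:
    """One blink set per trial: a sample is invalid when either eye is."""
    invalid = ~pupil_valid(pupil_l) | ~pupil_valid(pupil_r)
    return detect_blinks_from_mask(invalid, times, extend_s)


def blink_mask(events: list[OcularEvent], n: int) -> np.ndarray:
    """Per-sample True inside any (extended) blink."""
    mask = np.zeros(n, dtype=bool)
    for e in events:
        if e.kind == "blink":
            mask[e.start_index : e.end_index + 1] = True
    return mask


def interpolate_blinks(
    series: np.ndarray, events: list[OcularEvent]
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly bridge blink spans; works for 1D series and (n, k) points.

    Samples inside each blink are replaced by linear interpolation between
    the last valid sample before and the first valid sample after the span
    (component-wise for points).  Blinks touching the trial edges are filled
    by nearest-valid constant extension.  Returns ``(filled, validity)``
    where validity flags the untouched samples.
    """
    arr = np.array(series, dtype=float)
    flat = arr.ndim == 1
    if flat:
        arr = arr[:, None]
    n = len(arr)
    mask = blink_mask(events, n)
    for e in events:
        if e.kind != "blink":
            continue
        i0, i1 = e.start_index, e.end_index
        if i0 > n - 1 or i1 < 0:
            raise ValueError("blink event outside series bounds")
        left = i0 - 1
        right = i1 + 1
        if left < 0 and right > n - 1:
            raise TrialUnusableError("no valid anchor on either side of a blink")
        if left < 0:
            arr[i0 : i1 + 1] = arr[right]
        elif right > n - 1:
            arr[i0 : i1 + 1] = arr[left]
        else:
            frac = np.linspace(0.0, 1.0, i1 - i0 + 3)[1:-1, None]
            arr[i0 : i1 + 1] = arr[left] + frac * (arr[right] - arr[left])
    if flat:
        arr = arr[:, 0]
    return arr, ~mask


def smooth_pupil(series: np.ndarray, window: int = DEFAULT_SMOOTH_WINDOW) -> np.ndarray:
    """Centered moving average; the window shrinks symmetrically at edges.

    At sample i the half-width is ``min(window // 2, i, n - 1 - i)`` so the
    kernel stays centered and a constant series passes through unchanged.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > n:
        raise ValueError("window larger than series")
    half = window // 2
    out = np.empty(n)
    if half:
        kernel = np.full(window, 1.0 / window)
        out[half : n - half] = np.convolve(series, kernel, mode="valid")
        for i in range(half):  # shrunk symmetric windows at both edges
            out[i] = series[: 2 * i + 1].mean()
            out[n - 1 - i] = series[n - 1 - 2 * i :].mean()
    else:
        out[:] = series
    return out


def baseline_correct(
    series: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float] = DEFAULT_BASELINE_WINDOW_S,
    validity: np.ndarray | None = None,
    divisive: bool = False,
) -> np.ndarray:
    """Subtract (or divide by) the mean over the per-trial reference window.

    The reference is the mean of valid samples with
    ``window[0] <= t <= window[1]``; subtractive by default.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    in_window = (times >= window[0]) & (times <= window[1])
    if validity is not None:
        in_window &= np.asarray(validity, dtype=bool)
    if not in_window.any():
        raise ValueError("baseline window contains no valid samples")
    ref = float(np.mean(series[in_window]))
    return series / ref if divisive else series - ref


def combine_eyes(
    left: np.ndarray,
    right: np.ndarray,
    strict_both: bool = False,
) -> np.ndarray:
    """Sample-wise binocular mean with single-eye fallback.

    Where both eyes are valid the mean is used; where exactly one is valid,
    that eye (unless ``strict_both``); where neither, NaN.  Validity here
    means finite — run this after blink interpolation, or on raw traces with
    the sentinel masked to NaN first.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left and right series must have equal length")
    ok_l = np.isfinite(left)
    ok_r = np.isfinite(right)
    out = np.full(left.shape, np.nan)
    both = ok_l & ok_r
    out[both] = 0.5 * (left[both] + right[both])
    if not strict_both:
        only_l = ok_l & ~ok_r
        only_r = ok_r & ~ok_l
        out[only_l] = left[only_l]
        out[only_r] = right[only_r]
    return out


def process_pupil(
    pupil_l: np.ndarray,
    pupil_r: np.ndarray,
    times: np.ndarray,
    *,
    extend_s: float = DEFAULT_BLINK_EXTENSION_S,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW_S,
    divisive: bool = False,
) -> tuple[np.ndarray, np.ndarray, list[OcularEvent]]:
    """Full per-trial pupil chain.

    Detect blinks binocularly, interpolate each eye across the extended
    spans, smooth each eye separately, combine eyes, baseline-correct.
    Returns ``(corrected, validity, blink_events)`` where validity is False
    inside extended blinks.
    """
    times = np.asarray(times, dtype=float)
    blinks = detect_blinks_binocular(pupil_l, pupil_r, times, extend_s)
    out = []
    for series in (pupil_l, pupil_r):
        s = np.asarray(series, dtype=float)
        filled, validity = interpolate_blinks(np.where(pupil_valid(s), s, np.nan), blinks)
        if np.isnan(filled).any():
            # stray invalid samples outside detected blinks cannot remain
            raise TrialUnusableError("invalid pupil samples outside blink spans")
        out.append(smooth_pupil(filled, smooth_window))
    combined = combine_eyes(out[0], out[1])
    corrected = baseline_correct(
        combined, times, baseline_window, validity=validity, divisive=divisive
    )
    return corrected, validity, blinks
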