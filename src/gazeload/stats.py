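"""Sectioning, per-section metric aggregates, the distraction ratio, and the
nonparametric statistical battery with effect sizes.

The statistical unit is the 10-s section aggregate.  The omnibus chain is
Shapiro-Wilk and Levene (assumption checks), Kruskal-Wallis across the four
listening conditions, and — only when the omnibus is significant — pairwise
Wilcoxon rank-sum tests with Benjamini-Hochberg adjustment and pooled-SD
Cohen's d.  Adjacent-pair comparisons use a normality-gated choice between
the paired t-test and the Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .types import CONDITIONS, OcularEvent, Trial

SECTION_LENGTH_S = 10.0
N_SECTIONS = 4

#: Metric columns of a section-aggregate table.
METRIC_COLUMNS = (
    "pupil_mean",
    "pupil_variance",
    "focus_offset_mean",
    "focus_offset_variance",
    "blink_count",
    "blink_duration_mean",
    "fixation_count",
    "fixation_duration_mean",
    "saccade_count",
    "saccade_duration_mean",
    "head_rotation_variance",
    "eye_rotation_variance",
)


class DegenerateDataError(ValueError):
    """The data admit no meaningful test (e.g. all values constant)."""


# ---------------------------------------------------------------------------
# sectioning and aggregation


def section_slices(
    times: np.ndarray,
    section_len_s: float = SECTION_LENGTH_S,
    n_sections: int = N_SECTIONS,
) -> list[np.ndarray]:
    """Boolean sample masks of the first ``n_sections`` contiguous windows.

    Samples are assigned by the half-open interval ``[k*L, (k+1)*L)`` from
    trial start; a trial shorter than ``n_sections * L`` is an error.
    """
    times = np.asarray(times, dtype=float)
    t0 = times[0]
    total = times[-1] - t0
    need = n_sections * section_len_s
    if total < need:
        raise ValueError(
            f"trial covers only {total:.1f} s; sectioning needs {need:.1f} s "
            f"({need - total:.1f} s short)"
        )
    rel = times - t0
    return [
        (rel >= k * section_len_s) & (rel < (k + 1) * section_len_s)
        for k in range(n_sections)
    ]


def rotation_angles_deg(vectors: np.ndarray) -> np.ndarray:
    """Angle (degrees) between consecutive samples' direction vectors."""
    v = np.asarray(vectors, dtype=float)
    v = v / np.linalg.norm(v, axis=1, keepdims=True)
    dots = np.clip(np.einsum("ij,ij->i", v[:-1], v[1:]), -1.0, 1.0)
    return np.degrees(np.arccos(dots))


def _mean_or_nan(x: np.ndarray) -> float:
    return float(np.mean(x)) if len(x) else float("nan")


def _var_or_nan(x: np.ndarray) -> float:
    return float(np.var(x, ddof=1)) if len(x) > 1 else float("nan")


def aggregate_section(
    mask: np.ndarray,
    times: np.ndarray,
    events: list[OcularEvent],
    pupil: np.ndarray,
    pupil_valid: np.ndarray,
    focus_offset: np.ndarray,
    head_angles_deg: np.ndarray,
    eye_angles_deg: np.ndarray,
) -> dict[str, float]:
    """Aggregate one 10-s section into the metric dictionary.

    Means/variances run over valid samples in the section (missing — NaN —
    when none); events are assigned to the section containing their temporal
    midpoint.  ``head_angles_deg``/``eye_angles_deg`` are per-step rotation
    angles aligned to the second sample of each step.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty section slice")
    t_lo = times[mask][0]
    t_hi = times[mask][-1]
    pv = mask & np.asarray(pupil_valid, dtype=bool)
    p = pupil[pv]
    f = focus_offset[mask]
    f = f[np.isfinite(f)]

    step_mask = mask[1:] & mask[:-1]  # steps fully inside the section
    head = head_angles_deg[step_mask[: len(head_angles_deg)]]
    eye = eye_angles_deg[step_mask[: len(eye_angles_deg)]]
    eye = eye[np.isfinite(eye)]

    out: dict[str, float] = {
        "pupil_mean": _mean_or_nan(p),
        "pupil_variance": _var_or_nan(p),
        "focus_offset_mean": _mean_or_nan(f),
        "focus_offset_variance": _var_or_nan(f),
        "head_rotation_variance": _var_or_nan(head),
        "eye_rotation_variance": _var_or_nan(eye),
    }
    for kind in ("blink", "fixation", "saccade"):
        durs = [
            e.duration
            for e in events
            if e.kind == kind and t_lo <= e.midpoint <= t_hi
        ]
        out[f"{kind}_count"] = float(len(durs))
        out[f"{kind}_duration_mean"] = _mean_or_nan(np.asarray(durs))
    return out


def distraction_ratio(
    target_labels: np.ndarray, posters: tuple[str, ...]
) -> dict[str, float] | None:
    """Per-poster share of poster-gaze samples, or None when undefined.

    Each poster's ratio is its sample count divided by the total count of
    samples on any poster; ratios sum to one when defined.  A trial with
    zero poster samples is undefined and excluded from the ratio analysis.
    """
    labels = np.asarray(target_labels, dtype=object)
    counts = {p: int(np.sum(labels == p)) for p in posters}
    unknown = set(np.unique(labels[np.isin(labels, ["", *posters], invert=True)]))
    unknown = {u for u in unknown if str(u).startswith("poster")}
    if unknown:
        raise ValueError(f"unknown poster label(s): {sorted(unknown)}")
    total = sum(counts.values())
    if total == 0:
        return None
    return {p: c / total for p, c in counts.items()}


# ---------------------------------------------------------------------------
# elementary statistics


def cohens_d(m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int) -> float:
    """Absolute standardized mean difference with pooled SD."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both groups")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if pooled_var == 0.0:
        if m1 == m2:
            return 0.0
        return float("inf")
    return abs(m1 - m2) / float(np.sqrt(pooled_var))


def cohens_d_from_samples(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return cohens_d(
        float(np.mean(x)), float(np.std(x, ddof=1)), len(x),
        float(np.mean(y)), float(np.std(y, ddof=1)), len(y),
    )


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up false-discovery-rate adjustment of a family of p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration for combined n <= 12, normal approximation with
    continuity correction otherwise.  Returns ``(U, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    method = "exact" if len(x) + len(y) <= 12 else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman_rho(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("rank correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# test-chain reports


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    statistic: float
    p_raw: float
    p_adjusted: float
    cohens_d: float
    summaries: dict[str, tuple[float, float, int]]  # group -> (M, SD, n)


@dataclass
class StatReport:
    """All stages of the statistical chain for one metric."""

    metric: str
    shapiro_w: float
    shapiro_p: float
    levene_stat: float
    levene_p: float
    omnibus_stat: float  # Kruskal-Wallis chi-squared
    omnibus_df: int
    omnibus_p: float
    pairwise: list[PairwiseResult] = field(default_factory=list)
    group_summaries: dict[str, tuple[float, float, int]] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.omnibus_p < 0.05


def _summaries(groups: dict[str, np.ndarray]) -> dict[str, tuple[float, float, int]]:
    return {
        g: (float(np.mean(v)), float(np.std(v, ddof=1)), len(v))
        for g, v in groups.items()
    }


def metric_battery(
    groups: dict[str, np.ndarray], metric: str, alpha: float = 0.05
) -> StatReport:
    """Run the full between-condition chain on one metric.

    ``groups`` maps condition name to its section-aggregate values.  Pairwise
    rank-sum tests (with BH adjustment and Cohen's d) run only when the
    Kruskal-Wallis omnibus is significant at ``alpha``.
    """
    groups = {g: np.asarray(v, dtype=float)[~np.isnan(np.asarray(v, dtype=float))]
              for g, v in groups.items()}
    groups = {g: v for g, v in groups.items() if len(v)}
    if len(groups) < 2 or any(len(v) < 3 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 3 values each")
    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        raise DegenerateDataError(f"metric {metric!r} is constant in all groups")
    sw_w, sw_p = sps.shapiro(pooled)
    lv_stat, lv_p = sps.levene(*groups.values())
    kw_stat, kw_p = sps.kruskal(*groups.values())
    report = StatReport(
        metric=metric,
        shapiro_w=float(sw_w),
        shapiro_p=float(sw_p),
        levene_stat=float(lv_stat),
        levene_p=float(lv_p),
        omnibus_stat=float(kw_stat),
        omnibus_df=len(groups) - 1,
        omnibus_p=float(kw_p),
        group_summaries=_summaries(groups),
    )
    if report.omnibus_p < alpha:
        names = [c for c in CONDITIONS if c in groups] + [
            g for g in groups if g not in CONDITIONS
        ]
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
        raw = []
        stats_u = []
        for a, b in pairs:
            u, p = rank_sum_test(groups[a], groups[b])
            raw.append(p)
            stats_u.append(u)
        adjusted = benjamini_hochberg(raw)
        for (a, b), u, p, q in zip(pairs, stats_u, raw, adjusted):
            report.pairwise.append(
                PairwiseResult(
                    pair=(a, b),
                    statistic=u,
                    p_raw=p,
                    p_adjusted=float(q),
                    cohens_d=cohens_d_from_samples(groups[a], groups[b]),
                    summaries=_summaries({a: groups[a], b: groups[b]}),
                )
            )
    return report


@dataclass
class AdjacentPairResult:
    pair: tuple[str, str]
    test: str  # "t" | "wilcoxon"
    statistic: float
    p_raw: float
    p_adjusted: float
    cohens_d: float
    shapiro_w: float
    shapiro_p: float
    levene_p: float | None
    summaries: dict[str, tuple[float, float, int]]


def adjacent_pair_battery(
    pairs: list[tuple[str, str, np.ndarray, np.ndarray]],
    paired: bool = True,
    normality_alpha: float = 0.05,
) -> list[AdjacentPairResult]:
    """Normality-gated adjacent-condition comparisons with BH adjustment.

    Each entry is ``(name_a, name_b, values_a, values_b)``.  When the
    Shapiro-Wilk test keeps normality, a (paired) t-test is used and a Levene
    statistic reported; otherwise the Wilcoxon test (signed-rank when paired,
    rank-sum otherwise).  The BH family is the whole set of comparisons.
    """
    results = []
    raw = []
    for name_a, name_b, a, b in pairs:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if paired and len(a) != len(b):
            raise ValueError(f"paired vectors for {name_a}/{name_b} differ in length")
        pooled = np.concatenate([a, b])
        sw_w, sw_p = sps.shapiro(pooled)
        levene_p: float | None = None
        if sw_p >= normality_alpha:
            lv = sps.levene(a, b)
            levene_p = float(lv.pvalue)
            if paired:
                stat, p = sps.ttest_rel(a, b)
            else:
                stat, p = sps.ttest_ind(a, b)
            test = "t"
        else:
            if paired:
                diff = a - b
                if np.all(diff == 0):
                    stat, p = 0.0, 1.0
                else:
                    stat, p = sps.wilcoxon(a, b)
            else:
                stat, p = rank_sum_test(a, b)
            test = "wilcoxon"
        raw.append(float(p))
        results.append(
            AdjacentPairResult(
                pair=(name_a, name_b),
                test=test,
                statistic=float(stat),
                p_raw=float(p),
                p_adjusted=float("nan"),
                cohens_d=cohens_d_from_samples(a, b),
                shapiro_w=float(sw_w),
                shapiro_p=float(sw_p),
                levene_p=levene_p,
                summaries=_summaries({name_a: a, name_b: b}),
            )
        )
    for r, q in zip(results, benjamini_hochberg(raw)):
        r.p_adjusted = float(q)
    return results


# ---------------------------------------------------------------------------
# batch helpers


def battery_over_aggregates(
    aggregates: pd.DataFrame, metrics=METRIC_COLUMNS, alpha: float = 0.05
) -> dict[str, StatReport]:
    """Run :func:`metric_battery` for every metric of an aggregate table.

    ``aggregates`` needs columns ``condition`` plus the metric columns;
    metrics that are degenerate (constant) are skipped.
    """
    reports: dict[str, StatReport] = {}
    for metric in metrics:
        if metric not in aggregates.columns:
            continue
        groups = {
            cond: chunk[metric].to_numpy(dtype=float)
            for cond, chunk in aggregates.groupby("condition", sort=False)
        }
        try:
            reports[metric] = metric_battery(groups, metric, alpha=alpha)
        except DegenerateDataError:
            continue
    return reports
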