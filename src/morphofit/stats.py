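"""Cohort statistics: stratified summaries and nonparametric tests.

The analysis convention: normality is screened with Shapiro–Wilk (recorded,
never used to switch tests — the data of interest are not normal); two
groups are compared with an unpaired Mann–Whitney U, more with
Kruskal–Wallis followed by Dunn's pairwise post-hoc z-tests with Bonferroni
adjustment; paired left/right data use the Wilcoxon matched-pairs
signed-rank test. All tests are two-sided with significance at p < 0.05 by
default. Summaries report mean ± SD per stratum even though the tests are
rank-based, mirroring how such cohorts are conventionally tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import PatientRecord

__all__ = [
    "StrataConfig",
    "GroupComparison",
    "PairedComparison",
    "compare_groups",
    "paired_compare",
    "stratified_summary",
    "age_band",
    "bmi_band",
]

AGE_BANDS = ((0.0, 18.0), (18.0, 45.0), (45.0, np.inf))
AGE_BAND_LABELS = ("0-18", "18-45", ">45")
BMI_BANDS = ((0.0, 18.5), (18.5, 25.0), (25.0, 30.0), (30.0, np.inf))
BMI_BAND_LABELS = ("<18.5", "18.5-24.9", "25-29.9", ">=30")


@dataclass(frozen=True)
class StrataConfig:
    """Stratification scheme: sex, half-open age bands, WHO BMI bands."""

    age_bands: tuple = AGE_BANDS
    age_labels: tuple = AGE_BAND_LABELS
    bmi_bands: tuple = BMI_BANDS
    bmi_labels: tuple = BMI_BAND_LABELS
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for bands in (self.age_bands, self.bmi_bands):
            for (lo1, hi1), (lo2, _) in zip(bands, bands[1:]):
                if hi1 != lo2:
                    raise ValueError("bands must partition the domain")


def age_band(age: float, config: StrataConfig | None = None) -> str:
    """Half-open band membership: an 18.0-year-old falls in [18, 45)."""
    config = config or StrataConfig()
    for (lo, hi), label in zip(config.age_bands, config.age_labels):
        if lo <= age < hi:
            return label
    raise ValueError(f"age {age} outside all bands")


def bmi_band(bmi: float, config: StrataConfig | None = None) -> str:
    config = config or StrataConfig()
    for (lo, hi), label in zip(config.bmi_bands, config.bmi_labels):
        if lo <= bmi < hi:
            return label
    raise ValueError(f"bmi {bmi} outside all bands")


@dataclass(frozen=True)
class GroupComparison:
    test: str                       # "mann-whitney" or "kruskal-wallis"
    statistic: float
    p_value: float
    significant: bool
    alpha: float
    group_sizes: dict
    normality: dict                 # group -> p or None (not assessable)
    pairwise: pd.DataFrame | None = None   # Dunn's table for > 2 groups


@dataclass(frozen=True)
class PairedComparison:
    statistic: float
    p_value: float
    significant: bool
    n_pairs: int
    n_zero_diffs: int
    all_zero: bool


def _normality(groups: dict) -> dict:
    out = {}
    for k, v in groups.items():
        if len(v) < 3 or np.ptp(v) == 0:
            out[k] = None  # not assessable
        else:
            out[k] = float(sps.shapiro(v).pvalue)
    return out


def _dunn_pairwise(groups: dict, alpha: float) -> pd.DataFrame:
    """Dunn's z-statistics on pooled ranks with tie correction; Bonferroni."""
    labels = list(groups)
    sizes = {k: len(groups[k]) for k in labels}
    pooled = np.concatenate([groups[k] for k in labels])
    ranks = sps.rankdata(pooled)
    N = len(pooled)
    mean_ranks = {}
    start = 0
    for k in labels:
        mean_ranks[k] = ranks[start:start + sizes[k]].mean()
        start += sizes[k]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12 * (N - 1))
    var_base = N * (N + 1) / 12 - tie_term
    m = len(labels) * (len(labels) - 1) // 2
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            se = np.sqrt(var_base * (1 / sizes[a] + 1 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2 * sps.norm.sf(abs(z))
            p_adj = min(1.0, p * m)
            rows.append({"group_a": a, "group_b": b, "z": float(z),
                         "p_raw": float(p), "p_adjusted": float(p_adj),
                         "significant": bool(p_adj < alpha)})
    return pd.DataFrame(rows)


def compare_groups(values: np.ndarray, group_labels, alpha: float = 0.05,
                   mw_method: str = "auto") -> GroupComparison:
    """Nonparametric comparison across groups.

    Two groups → two-sided Mann–Whitney U (``mw_method`` passes through to
    scipy: 'auto', 'exact' or 'asymptotic'); more → Kruskal–Wallis with
    Dunn's Bonferroni-adjusted pairwise post hoc. A Shapiro–Wilk screen is
    recorded per group (None when n < 3 or constant).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    uniq = list(dict.fromkeys(labels.tolist()))  # first-appearance order
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    groups = {k: values[labels == k] for k in uniq}
    if any(len(v) < 1 for v in groups.values()):
        raise ValueError("every group must have n >= 1")
    normality = _normality(groups)
    if len(uniq) == 2:
        a, b = groups[uniq[0]], groups[uniq[1]]
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=mw_method)
        return GroupComparison(
            test="mann-whitney", statistic=float(res.statistic),
            p_value=float(res.pvalue), significant=bool(res.pvalue < alpha),
            alpha=alpha, group_sizes={k: len(v) for k, v in groups.items()},
            normality=normality)
    res = sps.kruskal(*groups.values())
    pw = _dunn_pairwise(groups, alpha)
    return GroupComparison(
        test="kruskal-wallis", statistic=float(res.statistic),
        p_value=float(res.pvalue), significant=bool(res.pvalue < alpha),
        alpha=alpha, group_sizes={k: len(v) for k, v in groups.items()},
        normality=normality, pairwise=pw)


def paired_compare(left_values: np.ndarray, right_values: np.ndarray,
                   alpha: float = 0.05) -> PairedComparison:
    """Wilcoxon matched-pairs signed-rank test (zero differences dropped)."""
    left = np.asarray(left_values, dtype=float)
    right = np.asarray(right_values, dtype=float)
    if left.shape != right.shape:
        raise ValueError("paired samples must have equal length")
    if len(left) < 5:
        raise ValueError("need n >= 5 pairs")
    diffs = left - right
    n_zero = int((diffs == 0).sum())
    if n_zero == len(diffs):
        return PairedComparison(statistic=float("nan"), p_value=1.0,
                                significant=False, n_pairs=len(diffs),
                                n_zero_diffs=n_zero, all_zero=True)
    res = sps.wilcoxon(left, right, zero_method="wilcox",
                       alternative="two-sided")
    return PairedComparison(statistic=float(res.statistic),
                            p_value=float(res.pvalue),
                            significant=bool(res.pvalue < alpha),
                            n_pairs=len(diffs), n_zero_diffs=n_zero,
                            all_zero=False)


def stratified_summary(metric: dict[str, float],
                       cohort: list[PatientRecord],
                       by: str = "sex",
                       config: StrataConfig | None = None,
                       ) -> tuple[pd.DataFrame, GroupComparison | None]:
    """n / mean ± SD of a per-patient metric per stratum, with the test.

    ``metric`` maps patient_id to the value (e.g. total PRSP volume);
    ``by`` is 'sex', 'age' or 'bmi'. Empty strata are reported with n = 0
    and excluded from testing; a single populated stratum yields a summary
    only (test None).
    """
    config = config or StrataConfig()
    if by == "sex":
        strata = ("female", "male")
        def key(r):  # noqa: E306
            return r.sex
    elif by == "age":
        strata = config.age_labels
        def key(r):
            return age_band(r.age, config)
    elif by == "bmi":
        strata = config.bmi_labels
        def key(r):
            return bmi_band(r.bmi, config) if r.bmi is not None else None
    else:
        raise ValueError("by must be 'sex', 'age' or 'bmi'")
    buckets: dict[str, list[float]] = {s: [] for s in strata}
    for r in cohort:
        if r.patient_id not in metric:
            continue
        k = key(r)
        if k is not None:
            buckets[k].append(metric[r.patient_id])
    rows = []
    for s in strata:
        v = np.asarray(buckets[s])
        rows.append({"stratum": s, "n": len(v),
                     "mean": float(v.mean()) if len(v) else float("nan"),
                     "sd": float(v.std(ddof=1)) if len(v) > 1 else
                     (0.0 if len(v) == 1 else float("nan"))})
    table = pd.DataFrame(rows)
    populated = [s for s in strata if len(buckets[s]) > 0]
    comparison = None
    if len(populated) >= 2:
        values = np.concatenate([buckets[s] for s in populated])
        labels = np.concatenate([[s] * len(buckets[s]) for s in populated])
        comparison = compare_groups(values, labels, alpha=config.alpha)
    return table, comparison
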