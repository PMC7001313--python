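"""Cohort-level comparisons: VAF grouping, rank tests, survival curves.

Cases are split into a high-VAF group (ddPCR VAF strictly above 50%,
candidates for mutant allele specific imbalance) and a lower-VAF group.
Quantitative markers are compared by the two-sided Wilcoxon rank-sum test;
overall and progression-free survival by Kaplan–Meier product-limit curves
and the log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "classify_masi",
    "compare_groups",
    "km_logrank",
    "SurvivalCurve",
]

HIGH = "high"
LOWER = "lower"


def classify_masi(
    cases: pd.DataFrame, vaf_cutoff: float = 0.5
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Partition cases by the VAF > cutoff rule (strict inequality).

    Returns a copy of the table with a ``vaf_group`` column ("high" /
    "lower") plus the group counts.  A case at exactly the cutoff falls in
    the lower group.
    """
    if "vaf" not in cases.columns:
        raise ValueError("cohort table needs a 'vaf' column (fractions)")
    if cases["vaf"].isna().any():
        raise ValueError("every case needs a VAF")
    out = cases.copy()
    out["vaf_group"] = np.where(out["vaf"] > vaf_cutoff, HIGH, LOWER)
    counts = {
        HIGH: int((out["vaf_group"] == HIGH).sum()),
        LOWER: int((out["vaf_group"] == LOWER).sum()),
    }
    return out, counts


def compare_groups(
    values_a: np.ndarray | list[float],
    values_b: np.ndarray | list[float],
    method: str = "rank_sum",
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two independent groups.

    Exact null distribution for small samples without ties; mid-rank /
    normal approximation otherwise.  Returns (statistic, p_value) where the
    statistic is the Mann–Whitney U of the first group.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if method != "rank_sum":
        raise ValueError(f"unsupported method {method!r}")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class SurvivalCurve:
    """Kaplan–Meier product-limit curve for one group."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.survival)
        if s.size and (np.diff(s) > 1e-12).any():
            raise ValueError("survival must be non-increasing")


def _km_curve(times: np.ndarray, events: np.ndarray, label: str) -> SurvivalCurve:
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events, label=label)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_[label].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(
        kmf.survival_function_.index, method="ffill"
    ).to_numpy(dtype=float)
    return SurvivalCurve(times=grid, survival=surv, at_risk=at_risk)


def km_logrank(
    times_a: np.ndarray | list[float],
    events_a: np.ndarray | list[int],
    times_b: np.ndarray | list[float],
    events_b: np.ndarray | list[int],
) -> tuple[dict[str, SurvivalCurve], float, float]:
    """Kaplan–Meier curves per group and the two-sided log-rank test.

    Returns ({"a": curve, "b": curve}, chi_square, p_value).  The log-rank
    statistic has one degree of freedom and is symmetric in the group labels.
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    eb = np.asarray(events_b, dtype=int)
    if (ta < 0).any() or (tb < 0).any():
        raise ValueError("survival times must be >= 0")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group")
    curves = {"a": _km_curve(ta, ea, "a"), "b": _km_curve(tb, eb, "b")}
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return curves, float(res.test_statistic), float(res.p_value)
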