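"""Statistical battery applied to pipeline outputs.

Two-tailed Welch's t-test, paired/unpaired t-tests, one-way ANOVA with a
Bonferroni/Dunn-style post-hoc (pairwise t-tests on the pooled
within-group variance, p-values multiplied by the number of
comparisons), and the percentile summary used for box-whisker plots
(25th–75th box, 5th–95th whiskers). Welch, paired-t and the omnibus F
delegate to scipy.stats; the post-hoc table is assembled here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "PairwiseComparison",
    "AnovaResult",
    "welch_t",
    "paired_t",
    "anova_bonferroni_dunn",
    "box_whisker_summary",
]


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    df: float
    p_value: float
    groups: tuple[str, ...] = ()
    alpha: float = 0.05
    zero_variance: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_adjusted < alpha


@dataclass
class AnovaResult:
    omnibus: TestResult
    pairwise: list[PairwiseComparison] = field(default_factory=list)
    n_comparisons: int = 0


class BoxWhisker(NamedTuple):
    p5: float
    p25: float
    p50: float
    p75: float
    p95: float


def _check_sample(x, name: str, n_min: int = 2) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < n_min:
        raise ValueError(f"{name}: need a 1D sample with n >= {n_min}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name}: non-finite values")
    return arr


def welch_t(a, b, alpha: float = 0.05, alternative: str = "two-sided") -> TestResult:
    """Unequal-variance t-test with Welch–Satterthwaite degrees of freedom."""
    a = _check_sample(a, "a")
    b = _check_sample(b, "b")
    res = sps.ttest_ind(a, b, equal_var=False, alternative=alternative)
    stat = float(res.statistic)
    p = float(res.pvalue)
    if math.isnan(stat):  # both samples constant and equal
        stat, p = 0.0, 1.0
    return TestResult("welch_t", stat, float(res.df), p, alpha=alpha)


def paired_t(a, b, alpha: float = 0.05) -> TestResult:
    """Two-tailed paired t-test (one-sample t on the differences).

    Zero-variance differences need a convention: identical samples give
    t = 0, p = 1; a constant nonzero difference is maximally
    sign-consistent, so the sign-test bound p = 2^(1-n) is reported with
    the ``zero_variance`` flag set.
    """
    a = _check_sample(a, "a")
    b = _check_sample(b, "b")
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    d = a - b
    n = d.size
    if np.ptp(d) == 0:
        if d[0] == 0:
            return TestResult("paired_t", 0.0, n - 1, 1.0, alpha=alpha)
        return TestResult(
            "paired_t",
            math.copysign(math.inf, d[0]),
            n - 1,
            2.0 ** (1 - n),
            alpha=alpha,
            zero_variance=True,
        )
    res = sps.ttest_rel(a, b)
    return TestResult("paired_t", float(res.statistic), float(n - 1), float(res.pvalue), alpha=alpha)


def anova_bonferroni_dunn(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
    posthoc: str = "pooled",
) -> AnovaResult:
    """One-way ANOVA with Bonferroni-corrected pairwise comparisons.

    The post-hoc follows the Bonferroni/Dunn procedure: each pair is
    compared with a t statistic using the pooled within-group mean
    square (df = N - k), and raw p-values are multiplied by the number
    of comparisons, capped at 1. ``posthoc="welch"`` substitutes plain
    pairwise Welch tests with the same Bonferroni multiplication.
    """
    arrays = [_check_sample(g, f"group {i}") for i, g in enumerate(groups)]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    f_res = sps.f_oneway(*arrays)
    n_total = sum(a.size for a in arrays)
    df_between, df_within = k - 1, n_total - k
    f_stat = float(f_res.statistic)
    p = float(f_res.pvalue)
    if math.isnan(f_stat):  # all groups constant and equal
        f_stat, p = 0.0, 1.0
    omnibus = TestResult("anova_F", f_stat, df_between, p, tuple(labels), alpha)
    # pooled within-group mean square for the Dunn-style pairwise t
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_within
    pairs = list(itertools.combinations(range(k), 2))
    m = len(pairs)
    table = []
    for i, j in pairs:
        a, b = arrays[i], arrays[j]
        if posthoc == "pooled":
            se = math.sqrt(msw * (1 / a.size + 1 / b.size))
            if se == 0:
                t_stat, p_raw, df = 0.0, 1.0, float(df_within)
            else:
                t_stat = (a.mean() - b.mean()) / se
                df = float(df_within)
                p_raw = 2 * float(sps.t.sf(abs(t_stat), df_within))
        elif posthoc == "welch":
            r = welch_t(a, b)
            t_stat, df, p_raw = r.statistic, r.df, r.p_value
        else:
            raise ValueError(f"unknown posthoc {posthoc!r}")
        table.append(
            PairwiseComparison(
                labels[i], labels[j], float(t_stat), df, p_raw, min(1.0, m * p_raw)
            )
        )
    return AnovaResult(omnibus, table, m)


def box_whisker_summary(values) -> BoxWhisker:
    """5th/25th/50th/75th/95th percentiles by linear interpolation."""
    arr = _check_sample(values, "values", n_min=1)
    return BoxWhisker(*(float(v) for v in np.percentile(arr, [5, 25, 50, 75, 95])))
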