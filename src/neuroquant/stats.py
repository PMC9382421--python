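"""Statistical primitives used across the pipeline.

Thin, validated wrappers around SciPy: Pearson correlation with the two-sided
t-transform p-value, Pearson chi-square independence (no continuity correction
by default), one-way ANOVA with Tukey HSD post-test, and the unpaired
two-sample t test (pooled variance by default, Welch optional).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


class ConstantInputError(ValueError):
    """Raised when a statistic is undefined because an input has no variance."""


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r and the two-sided p from t = r*sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def chi2_independence(table, correction: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table.

    Returns (chi2, df, p).  Expected counts of zero are rejected with a hint
    to merge sparse categories.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must have at least 2 rows and 2 columns")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("table must contain non-negative integer counts")
    expected = sps.contingency.expected_freq(obs)
    if np.any(expected == 0):
        raise ValueError("expected count of 0; merge sparse categories before testing")
    chi2, p, df, _ = sps.chi2_contingency(obs, correction=correction)
    return float(chi2), int(df), float(p)


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    tukey_p: dict[tuple[int, int], float] = field(default_factory=dict)
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and self.f < 0:
            raise ValueError("F statistic must be non-negative")


def one_way_anova_tukey(groups) -> AnovaResult:
    """One-way ANOVA followed by Tukey's HSD post-test.

    ``tukey_p`` maps group-index pairs (i, j), i < j, to adjusted p-values
    from the studentized range distribution.  A design with zero within-group
    variance and equal means is flagged ``degenerate`` (F is 0/0).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need at least 2 groups with at least 2 values each")
    n_total = sum(a.size for a in arrays)
    df_between = len(arrays) - 1
    df_within = n_total - len(arrays)
    ssw = sum(np.sum((a - a.mean()) ** 2) for a in arrays)
    if ssw == 0:
        grand = np.concatenate(arrays).mean()
        ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
        if ssb == 0:
            return AnovaResult(np.nan, df_between, df_within, np.nan, degenerate=True)
        return AnovaResult(np.inf, df_between, df_within, 0.0, degenerate=True)
    f, p = sps.f_oneway(*arrays)
    hsd = sps.tukey_hsd(*arrays)
    tukey_p = {
        (i, j): float(hsd.pvalue[i, j])
        for i in range(len(arrays))
        for j in range(i + 1, len(arrays))
    }
    return AnovaResult(float(f), df_between, df_within, float(p), tukey_p)


def t_test_two_sample(a, b, welch: bool = False) -> tuple[float, float, float]:
    """Unpaired two-tailed t test; pooled variance unless ``welch`` is set.

    Returns (t, df, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        # identical constants: no evidence of a difference
        df = a.size + b.size - 2
        return 0.0, float(df), 1.0
    if not welch and np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ConstantInputError("zero pooled variance with unequal means")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)
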