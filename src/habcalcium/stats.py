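"""Shared nonparametric tests.

`rank_test` wraps the Wilcoxon signed-rank (paired) and rank-sum /
Mann-Whitney (unpaired) tests, using the exact null distribution at small
sample sizes (paired n <= 25 after dropping zeros; unpaired min(n) <= 10
and total <= 20) when the data permit, and the normal approximation with
tie/continuity correction otherwise. Zero differences are dropped for the
signed-rank test (Wilcoxon's original convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "rank_test", "adjust_bh"]

_ALTERNATIVES = {"two_sided": "two-sided", "less": "less", "greater": "greater"}


@dataclass
class TestResult:
    name: str
    sided: str
    statistic: float
    p_value: float
    n: tuple
    exact: bool
    undefined: bool = False

    def __post_init__(self) -> None:
        if not self.undefined and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def rank_test(a, b, paired: bool = False, sided: str = "two_sided") -> TestResult:
    """Rank test of sample ``a`` against sample ``b``.

    ``sided='less'`` tests the alternative that ``a`` is stochastically
    smaller than ``b`` (paired: the differences a - b are negative).
    Paired samples with all-zero differences yield an undefined result
    (flagged, p = NaN) rather than an exception.
    """
    if sided not in _ALTERNATIVES:
        raise ValueError(f"sided must be one of {sorted(_ALTERNATIVES)}")
    alt = _ALTERNATIVES[sided]
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired samples must have equal length")
        d = a - b
        d = d[d != 0]
        if d.size == 0:
            return TestResult("wilcoxon_signed_rank", sided, float("nan"), float("nan"),
                              (len(a), len(b)), exact=False, undefined=True)
        ties = len(np.unique(np.abs(d))) < d.size
        use_exact = d.size <= 25 and not ties
        res = sps.wilcoxon(d, alternative=alt, zero_method="wilcox",
                           method="exact" if use_exact else "approx",
                           correction=not use_exact)
        return TestResult("wilcoxon_signed_rank", sided, float(res.statistic),
                          float(res.pvalue), (len(a), len(b)), exact=use_exact)
    if a.size == 0 or b.size == 0:
        raise ValueError("each group needs at least one observation")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < pooled.size
    use_exact = min(a.size, b.size) <= 10 and a.size + b.size <= 20 and not ties
    res = sps.mannwhitneyu(a, b, alternative=alt,
                           method="exact" if use_exact else "asymptotic")
    return TestResult("wilcoxon_rank_sum", sided, float(res.statistic),
                      float(res.pvalue), (a.size, b.size), exact=use_exact)


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; off by default
    everywhere, as per-test p-values are reported)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
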