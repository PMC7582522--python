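"""Group-comparison statistics: normality-gated two-group tests, χ² for
class distributions, and Šidák-corrected critical values.

Each two-group comparison first tests both samples for normality with a
one-sample Kolmogorov–Smirnov test against a normal with the sample's own
mean and SD (a Lilliefors-style check: fitting the parameters makes the
nominal KS p-values conservative — documented, configurable gate).  If
both samples pass at the gate level the comparison uses a two-tailed
unpaired t-test, otherwise a Mann–Whitney U test.  Distributions over
classes are compared with a Pearson χ² test.  For families of m
comparisons the critical values are Šidák-corrected:
α_corr = 1 − (1 − α)^(1/m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

__all__ = [
    "GroupComparisonResult",
    "ks_normality",
    "compare_groups",
    "chi_square_distribution",
    "sidak_threshold",
    "sidak_thresholds",
    "significance_stars",
]

DEFAULT_FAMILY_ALPHAS = (0.05, 0.01, 0.001)


@dataclass
class GroupComparisonResult:
    test_used: str          # "t_test" or "mann_whitney_u"
    statistic: float
    p_value: float
    normality_p_a: float
    normality_p_b: float
    n_a: int
    n_b: int


def ks_normality(sample) -> float:
    """One-sample KS p-value against a normal with the sample mean and SD."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("normality test needs at least 3 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate (constant) sample")
    return float(_st.kstest(x, "norm", args=(x.mean(), sd)).pvalue)


def compare_groups(a, b, normality_alpha: float = 0.05) -> GroupComparisonResult:
    """Two-group comparison with the normality gate.

    Both samples are KS-tested; a two-tailed unpaired t-test is used iff
    both pass at ``normality_alpha``, otherwise a two-sided Mann–Whitney U.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    p_a = ks_normality(a)
    p_b = ks_normality(b)
    if p_a >= normality_alpha and p_b >= normality_alpha:
        res = _st.ttest_ind(a, b, equal_var=True)
        test = "t_test"
    else:
        res = _st.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann_whitney_u"
    return GroupComparisonResult(
        test_used=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        normality_p_a=p_a,
        normality_p_b=p_b,
        n_a=a.size,
        n_b=b.size,
    )


def chi_square_distribution(counts_a, counts_b, correction: bool = False):
    """Pearson χ² on the 2×k contingency table of two count vectors.

    Returns ``(statistic, p_value)``.  No continuity correction by default.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("count vectors must be 1-D and of equal length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    table = np.vstack([a, b])
    res = _st.chi2_contingency(table, correction=correction)
    if np.any(res.expected_freq <= 0):
        raise ValueError("zero expected count in the contingency table")
    return float(res.statistic), float(res.pvalue)


def sidak_threshold(alpha: float, m: int) -> float:
    """Šidák-corrected critical value 1 − (1 − α)^(1/m) for m comparisons."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not (isinstance(m, (int, np.integer)) and m >= 1):
        raise ValueError("m must be a positive integer")
    return float(1.0 - (1.0 - alpha) ** (1.0 / m))


def sidak_thresholds(m: int, family_alphas=DEFAULT_FAMILY_ALPHAS) -> dict[float, float]:
    """Corrected critical values for the standard significance levels."""
    return {a: sidak_threshold(a, m) for a in family_alphas}


def significance_stars(p: float, m: int = 1, family_alphas=DEFAULT_FAMILY_ALPHAS) -> str:
    """Star annotation under Šidák-corrected thresholds (\"\" if n.s.)."""
    thr = sidak_thresholds(m, family_alphas)
    stars = ""
    for n_star, alpha in enumerate(sorted(family_alphas, reverse=True), start=1):
        if p < thr[alpha]:
            stars = "*" * n_star
    return stars
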