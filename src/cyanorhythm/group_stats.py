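"""Pairwise strain-comparison cascade: Levene's test for equal variances,
then Student's t (equal variances) or Welch's t (unequal) on the means.

The variance gate uses classic mean-centered Levene (not Brown-Forsythe);
both tests are two-sided and a difference is called significant at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

from .errors import SampleError

ALPHA_DEFAULT = 0.05


@dataclass
class TestResult:
    levene_stat: float
    levene_p: float
    test_used: str  # "student" or "welch"
    t_stat: float
    p: float
    significant: bool


def _check(sample, name):
    arr = np.asarray(sample, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise SampleError(f"sample {name} needs n >= 2")
    return arr


def levene(a, b, center: str = "mean") -> tuple[float, float]:
    """Classic Levene W on absolute deviations from the group center
    (mean by default; 'median' gives Brown-Forsythe), p from F(1, n_a+n_b-2)."""
    a, b = _check(a, "a"), _check(b, "b")
    stat, p = _st.levene(a, b, center=center)
    return float(stat), float(p)


def two_sample_t(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t: pooled variance with df n_a+n_b-2 when
    equal_var, else Welch with Welch-Satterthwaite df.  Two constant samples
    with equal means return (0, 1) by convention."""
    a, b = _check(a, "a"), _check(b, "b")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = _st.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def compare_strains(a, b, alpha: float = ALPHA_DEFAULT) -> TestResult:
    """Full cascade: Levene first; Welch iff the variances differ at
    p < alpha, Student otherwise.  Significance of the mean test at p < alpha."""
    a, b = _check(a, "a"), _check(b, "b")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        lev_stat, lev_p = 0.0, 1.0  # no variance to compare
    else:
        lev_stat, lev_p = levene(a, b)
    use_welch = lev_p < alpha
    t, p = two_sample_t(a, b, equal_var=not use_welch)
    return TestResult(
        levene_stat=lev_stat,
        levene_p=lev_p,
        test_used="welch" if use_welch else "student",
        t_stat=t,
        p=p,
        significant=p < alpha,
    )
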