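"""Group-comparison statistics for bar-graph style data.

Experimental results in this field are usually reported as mean ± SEM with a
small per-group n (animals). This module provides the unpaired Student t test
on raw values, its reconstruction from published summary data (mean, SEM, n),
and Benjamini-Hochberg multiple-testing adjustment shared by the single-cell
and network modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSummary",
    "TTestResult",
    "t_from_raw",
    "t_from_summary",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class GroupSummary:
    """Published summary of one group: mean, standard error of the mean, n."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.sem <= 0:
            raise ValueError(f"sem must be positive, got {self.sem}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")

    @property
    def sd(self) -> float:
        """Sample standard deviation implied by the SEM."""
        return self.sem * np.sqrt(self.n)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def t_from_raw(a, b, variant: str = "student") -> TTestResult:
    """Unpaired two-sample t test on raw values.

    variant="student" is the pooled-variance test (the field's default for
    two-group bar graphs); variant="welch" does not assume equal variances.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    equal_var = variant == "student"
    if equal_var and np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) != np.mean(b):
            warnings.warn("zero pooled variance with unequal means: t is infinite")
            sign = np.sign(np.mean(a) - np.mean(b))
            return TTestResult(sign * np.inf, a.size + b.size - 2, 0.0)
        return TTestResult(0.0, a.size + b.size - 2, 1.0)
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


def t_from_summary(g1: GroupSummary, g2: GroupSummary) -> TTestResult:
    """Pooled Student t reconstructed from (mean, SEM, n) pairs.

    For n1 == n2 this reduces to t = (m1 - m2) / sqrt(sem1^2 + sem2^2), which
    is exactly the pooled two-sample statistic in that case. For unequal n the
    pooled variance is rebuilt from the implied SDs (with a warning, since
    published tables rarely make the pairing explicit).
    """
    n1, n2 = g1.n, g2.n
    df = n1 + n2 - 2
    if n1 != n2:
        warnings.warn("unequal group sizes: pooled variance reconstructed from SEMs")
    sp2 = ((n1 - 1) * g1.sd**2 + (n2 - 1) * g2.sd**2) / df
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t = (g1.mean - g2.mean) / se
    p = 2 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
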