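"""Two-sample method comparison: equal-n t test and variance-ratio F test.

For two analytical methods applied to the same preparation in n replicate
analyses each, the mean-difference statistic is

    t = |x̄₁ − x̄₂| · √n / √(s₁² + s₂²)

which for equal n coincides with the pooled two-sample t (df = 2n − 2),
and the precision comparison is the variance ratio F = s₁²/s₂² with the
larger variance in the numerator (df₁ = df₂ = n − 1).  Verdicts compare
against the two-sided t critical value and the upper-tail F critical
value at the chosen significance level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class MethodComparison:
    """t/F comparison of two equal-length replicate series."""

    n: int
    mean1: float
    mean2: float
    s1: float
    s2: float
    t_stat: float
    f_stat: float
    t_critical: float
    f_critical: float
    alpha: float
    significant_t: bool
    significant_f: bool

    def __post_init__(self):
        if self.f_stat < 1:
            raise ValueError("F must place the larger variance in the numerator")
        if self.t_stat < 0:
            raise ValueError("the |mean difference| t statistic cannot be negative")

    def summary(self) -> str:
        verdict_t = "significant" if self.significant_t else "not significant"
        verdict_f = "significant" if self.significant_f else "not significant"
        return "\n".join(
            [
                f"Method comparison, n = {self.n} per series, α = {self.alpha:g}",
                f"  means: {self.mean1:.1f} vs {self.mean2:.1f}; "
                f"SDs: {self.s1:.3g} vs {self.s2:.3g}",
                f"  t = {self.t_stat:.2f} vs t_crit(df={2 * self.n - 2}) = "
                f"{self.t_critical:.3f} → difference in means {verdict_t}",
                f"  F = {self.f_stat:.2f} vs F_crit(df={self.n - 1},{self.n - 1}) = "
                f"{self.f_critical:.2f} → difference in precision {verdict_f}",
            ]
        )

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean1": self.mean1,
            "mean2": self.mean2,
            "s1": self.s1,
            "s2": self.s2,
            "t": self.t_stat,
            "F": self.f_stat,
            "t_critical": self.t_critical,
            "F_critical": self.f_critical,
            "alpha": self.alpha,
            "significant_t": self.significant_t,
            "significant_f": self.significant_f,
        }


def _check_series(series1, series2) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(series1, dtype=float)
    b = np.asarray(series2, dtype=float)
    if a.size != b.size:
        raise ValueError("the two series must have the same number of results")
    if a.size < 2:
        raise ValueError("each series needs at least 2 results")
    return a, b


def t_statistic(series1: Sequence[float], series2: Sequence[float]) -> float:
    """Equal-n mean-difference statistic t = |Δx̄|·√n / √(s₁² + s₂²)."""
    a, b = _check_series(series1, series2)
    n = a.size
    s1, s2 = a.std(ddof=1), b.std(ddof=1)
    denom = np.sqrt(s1**2 + s2**2)
    if denom == 0:
        return 0.0 if a.mean() == b.mean() else float("inf")
    return float(abs(a.mean() - b.mean()) * np.sqrt(n) / denom)


def f_statistic(series1: Sequence[float], series2: Sequence[float]) -> float:
    """Variance ratio F = s₁²/s₂² with the larger variance on top (F ≥ 1)."""
    a, b = _check_series(series1, series2)
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    if min(v1, v2) == 0:
        raise ValueError("zero variance: the F ratio is undefined")
    return float(max(v1, v2) / min(v1, v2))


def compare(
    series1: Sequence[float], series2: Sequence[float], alpha: float = 0.05
) -> MethodComparison:
    """Full t/F comparison with critical values at the given level."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    a, b = _check_series(series1, series2)
    n = a.size
    t_stat = t_statistic(a, b)
    f_stat = f_statistic(a, b)
    t_crit = float(stats.t.ppf(1 - alpha / 2, 2 * n - 2))
    f_crit = float(stats.f.ppf(1 - alpha, n - 1, n - 1))
    return MethodComparison(
        n=int(n),
        mean1=float(a.mean()),
        mean2=float(b.mean()),
        s1=float(a.std(ddof=1)),
        s2=float(b.std(ddof=1)),
        t_stat=t_stat,
        f_stat=f_stat,
        t_critical=t_crit,
        f_critical=f_crit,
        alpha=alpha,
        significant_t=bool(t_stat > t_crit),
        significant_f=bool(f_stat > f_crit),
    )
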