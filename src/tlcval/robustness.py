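"""Saturated two-level robustness screen with half-normal diagnostics.

Seven method factors (chamber and sorbent type, plate activation
temperature, extraction time, chloroform and ethanol volumes, chamber
saturation time) are varied over two levels in eight runs — a saturated
2^(7−4) fractional factorial.  Each main effect is the difference between
the mean response at the factor's high and low levels.  Because the design
is saturated there is no error term; significance is judged graphically by
a half-normal plot of the ranked absolute effects (null effects fall on a
straight line through small quantiles) and practically by the coefficient
of variation of the eight responses against a threshold (5% in routine
use).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import datasets


@dataclass(frozen=True)
class FactorialDesign:
    """A ±1 two-level screening design with orthogonal, balanced columns."""

    matrix: np.ndarray
    factor_names: tuple[str, ...]

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=int)
        if m.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if not np.all(np.isin(m, (-1, 1))):
            raise ValueError("design entries must be ±1")
        if np.any(m.sum(axis=0) != 0):
            raise ValueError("each column must balance +1 and −1 levels")
        gram = m.T @ m
        if np.any(gram - np.diag(np.diag(gram))):
            raise ValueError("design columns must be mutually orthogonal")
        if len(self.factor_names) != m.shape[1]:
            raise ValueError("one name per factor column is required")
        object.__setattr__(self, "matrix", m)

    @property
    def n_runs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_factors(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class EffectTable:
    """Estimated main effects plus the response summary of the screen."""

    factor_names: tuple[str, ...]
    effects: np.ndarray  # signed, response units
    responses: np.ndarray
    mean: float
    variance: float
    sd: float
    cv: float

    @property
    def abs_effects(self) -> np.ndarray:
        return np.abs(self.effects)

    def effect(self, factor: str) -> float:
        return float(self.effects[self.factor_names.index(factor)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "factor": self.factor_names,
                "effect": self.effects,
                "abs_effect": self.abs_effects,
            }
        )

    def summary(self) -> str:
        lines = ["Robustness screen: main effects (response units)"]
        for name, e in zip(self.factor_names, self.effects):
            lines.append(f"  {name:<12s} E = {e:+8.3f}")
        lines.append(
            f"  responses: mean {self.mean:.1f}, variance {self.variance:.1f}, "
            f"SD {self.sd:.1f}, CV {self.cv:.2f}%"
        )
        return "\n".join(lines)


@dataclass(frozen=True)
class HalfNormalResult:
    """Ranked |effects| against half-normal quantiles, with the line fit."""

    factor_names: tuple[str, ...]  # sorted by |effect|, ascending
    abs_effects: np.ndarray
    rank_probabilities: np.ndarray
    quantiles: np.ndarray
    r_squared: float
    slope: float
    intercept: float
    undefined: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "factor": self.factor_names,
                "abs_effect": self.abs_effects,
                "rank_probability": self.rank_probabilities,
                "half_normal_quantile": self.quantiles,
            }
        )


@dataclass(frozen=True)
class RobustnessVerdict:
    robust: bool
    cv: float
    threshold: float
    messages: tuple[str, ...]


def build_design() -> FactorialDesign:
    """The method's 8-run, 7-factor saturated two-level design."""
    return FactorialDesign(
        matrix=datasets.design_matrix(),
        factor_names=tuple(f"X{i}" for i in range(1, 8)),
    )


def compute_effects(
    design: FactorialDesign, responses: Sequence[float]
) -> EffectTable:
    """Main effects E_j = mean(y | x_j = +1) − mean(y | x_j = −1)."""
    y = np.asarray(responses, dtype=float)
    if y.size != design.n_runs:
        raise ValueError(
            f"expected {design.n_runs} responses (one per run), got {y.size}"
        )
    m = design.matrix
    effects = np.array(
        [y[m[:, j] == 1].mean() - y[m[:, j] == -1].mean() for j in range(m.shape[1])]
    )
    sd = float(y.std(ddof=1))
    mean = float(y.mean())
    return EffectTable(
        factor_names=design.factor_names,
        effects=effects,
        responses=y,
        mean=mean,
        variance=sd**2,
        sd=sd,
        cv=100.0 * sd / mean,
    )


def half_normal_analysis(
    effects: EffectTable,
    rank_probability: str = "midpoint",
    through_origin: bool = False,
) -> HalfNormalResult:
    """Half-normal probability analysis of the absolute effects.

    |E| are ranked ascending; rank probabilities are p_i = (i−0.5)/m
    ("midpoint", the default) or the Blom variant (i−3/8)/(m+1/4); the
    half-normal quantile is q_i = Φ⁻¹((1+p_i)/2).  A straight line of |E|
    on q (free intercept by default) gives the R² diagnostic — real
    effects bend the top of the plot away from the line and lower R².
    """
    m = len(effects.effects)
    if m < 3:
        raise ValueError("half-normal analysis needs at least 3 factors")
    order = np.argsort(effects.abs_effects, kind="stable")
    abs_sorted = effects.abs_effects[order]
    names = tuple(effects.factor_names[i] for i in order)
    i = np.arange(1, m + 1)
    if rank_probability == "midpoint":
        p = (i - 0.5) / m
    elif rank_probability == "blom":
        p = (i - 3.0 / 8.0) / (m + 0.25)
    else:
        raise ValueError("rank_probability must be 'midpoint' or 'blom'")
    q = stats.norm.ppf((1 + p) / 2)
    if np.all(abs_sorted == 0):
        return HalfNormalResult(
            names, abs_sorted, p, q, float("nan"), float("nan"), float("nan"),
            undefined=True,
        )
    X = q[:, None] if through_origin else sm.add_constant(q)
    fit = sm.OLS(abs_sorted, X).fit()
    slope = float(fit.params[-1])
    intercept = 0.0 if through_origin else float(fit.params[0])
    # R² against the mean (not the uncentered variant) in both cases, so
    # the two conventions stay comparable.
    pred = slope * q + intercept
    ss_res = float(np.sum((abs_sorted - pred) ** 2))
    ss_tot = float(np.sum((abs_sorted - abs_sorted.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return HalfNormalResult(names, abs_sorted, p, q, r2, slope, intercept)


def robustness_verdict(
    effects: EffectTable, cv_threshold: float = 5.0
) -> RobustnessVerdict:
    """Pass/fail on the response CV, with per-factor magnitudes to inspect."""
    if cv_threshold <= 0:
        raise ValueError("cv_threshold must be positive")
    robust = effects.cv < cv_threshold
    messages = [
        f"response CV {effects.cv:.2f}% vs threshold {cv_threshold:.1f}% → "
        + ("robust" if robust else "NOT robust")
    ]
    top = int(np.argmax(effects.abs_effects))
    messages.append(
        f"largest effect: {effects.factor_names[top]} "
        f"(|E| = {effects.abs_effects[top]:.3f})"
    )
    return RobustnessVerdict(
        robust=robust, cv=effects.cv, threshold=cv_threshold,
        messages=tuple(messages),
    )


def plot_half_normal(result: HalfNormalResult, ax=None):
    """Half-normal probability plot (quantile vs |effect|) with the fit line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(result.quantiles, result.abs_effects)
    for q, e, name in zip(result.quantiles, result.abs_effects, result.factor_names):
        ax.annotate(name, (q, e), textcoords="offset points", xytext=(4, 2))
    if not result.undefined:
        qs = np.linspace(0, result.quantiles.max() * 1.05, 50)
        ax.plot(qs, result.intercept + result.slope * qs, "--")
        ax.set_title(f"Half-normal plot (R² = {result.r_squared:.3f})")
    ax.set_xlabel("half-normal quantile")
    ax.set_ylabel("|effect|")
    return ax
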