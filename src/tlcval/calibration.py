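"""Calibration: least-squares response curves, LOD/LOQ, quantitation.

The response model is the straight line A = a + b·x relating band area A
(AU) to the amount x applied per spot (µg/spot).  Linearity diagnostics
follow common ICH practice: correlation coefficient r, residual standard
deviation s (n−2 denominator), the regression F statistic and its p-value,
and a residual sign/runs summary.  Detection limits use the slope method,

    LOD = 3.3 σ / S        LOQ = 10 σ / S

with σ a response standard deviation and S the calibration slope.
Quantitation inverts the fitted line and a dilution chain converts the
per-spot amount back to mg per tablet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted straight-line calibration with its linearity diagnostics."""

    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    r: float
    s: float  # residual SD, n-2 denominator
    f_stat: float
    p_value: float
    n: int
    amount_range: tuple[float, float]

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("a calibration needs at least 3 points")
        if not abs(self.r) <= 1 + 1e-12:
            raise ValueError("|r| cannot exceed 1")
        if self.s < 0:
            raise ValueError("residual SD cannot be negative")

    def predict(self, amount):
        return self.intercept + self.slope * np.asarray(amount, dtype=float)

    def summary(self) -> str:
        a, b = self.intercept, self.slope
        lines = [
            "Calibration  A = a + b·x   (A: area AU, x: µg/spot)",
            f"  A = {a:.1f} (±{self.intercept_se:.1f}) + {b:.1f} (±{self.slope_se:.1f})·x",
            f"  n = {self.n}; r = {self.r:.4f}; s = {self.s:.1f}; "
            f"F = {self.f_stat:.1f}; p = {self.p_value:.2g}",
            f"  validated range: {self.amount_range[0]:.2f}–{self.amount_range[1]:.2f} µg/spot",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "intercept_se": self.intercept_se,
            "slope_se": self.slope_se,
            "r": self.r,
            "s": self.s,
            "F": self.f_stat,
            "p": self.p_value,
            "n": self.n,
            "range": list(self.amount_range),
        }


@dataclass(frozen=True)
class DetectionLimits:
    sigma: float
    slope: float
    lod: float
    loq: float


@dataclass(frozen=True)
class DilutionChain:
    """Ordered multiplicative factors taking µg/spot to µg/tablet.

    Each factor is a named dilution/aliquot step; the net factor is their
    product.  ``to_tablet_content`` applies the chain and converts µg→mg.
    """

    factors: tuple[tuple[str, float], ...]

    def __post_init__(self):
        for name, mult in self.factors:
            if mult <= 0:
                raise ValueError(f"chain factor {name!r} must be positive")

    @property
    def net_factor(self) -> float:
        return float(np.prod([m for _, m in self.factors]))

    def forward(self, amount_ug_per_spot: float) -> float:
        """µg/spot → mg/tablet."""
        if amount_ug_per_spot < 0:
            raise ValueError("amount must be non-negative")
        return amount_ug_per_spot * self.net_factor / 1000.0

    def inverse(self, content_mg_per_tablet: float) -> float:
        """mg/tablet → µg/spot (exact round trip of :meth:`forward`)."""
        return content_mg_per_tablet * 1000.0 / self.net_factor


#: Default chains of the tablet assay: a 5 µL spot from a 5 mL working
#: solution (×1000), then scale-up from the working solution to one tablet
#: (ASA: 8 µg/spot ↔ 500 mg/tablet; AA: 12.8 µg/spot ↔ 200 mg/tablet).
DEFAULT_CHAINS = {
    "ASA": DilutionChain(
        (("spot to working solution", 1000.0), ("working solution to tablet", 62.5))
    ),
    "AA": DilutionChain(
        (("spot to working solution", 1000.0), ("working solution to tablet", 15.625))
    ),
}


def fit_calibration(
    amounts: Sequence[float], areas: Sequence[float]
) -> CalibrationCurve:
    """Ordinary least squares of area on amount with linearity diagnostics."""
    x = np.asarray(amounts, dtype=float)
    a = np.asarray(areas, dtype=float)
    if x.size != a.size:
        raise ValueError("amounts and areas differ in length")
    if x.size < 3:
        raise ValueError("a calibration needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("amounts are constant; no calibration possible")
    res = sm.OLS(a, sm.add_constant(x)).fit()
    resid = res.resid
    n = x.size
    s = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    r = float(np.corrcoef(x, a)[0, 1]) if np.ptp(a) > 0 else 0.0
    return CalibrationCurve(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        intercept_se=float(res.bse[0]),
        slope_se=float(res.bse[1]),
        r=r,
        s=s,
        f_stat=float(res.fvalue),
        p_value=float(res.f_pvalue),
        n=n,
        amount_range=(float(x.min()), float(x.max())),
    )


def residual_diagnostics(
    curve: CalibrationCurve, amounts: Sequence[float], areas: Sequence[float]
) -> tuple[pd.DataFrame, dict]:
    """Residual table plus a sign summary for the linearity check.

    Returns the per-point residuals and a dict with the counts of points
    above/below the zero line and the number of sign runs — a one-sided
    run pattern signals curvature that plain r would miss.
    """
    x = np.asarray(amounts, dtype=float)
    a = np.asarray(areas, dtype=float)
    if x.size != a.size:
        raise ValueError("amounts and areas differ in length")
    resid = a - curve.predict(x)
    order = np.argsort(x)
    signs = np.sign(resid[order])
    nonzero = signs[signs != 0]
    runs = 1 + int(np.sum(nonzero[1:] != nonzero[:-1])) if nonzero.size else 0
    table = pd.DataFrame({"amount": x, "area": a, "residual": resid})
    summary = {
        "n_above": int(np.sum(resid > 0)),
        "n_below": int(np.sum(resid < 0)),
        "sign_runs": runs,
        "residual_sum": float(np.sum(resid)),
    }
    return table, summary


def detection_limits(sigma: float, slope: float) -> DetectionLimits:
    """Slope-method detection limits: LOD = 3.3σ/S, LOQ = 10σ/S."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if slope <= 0:
        raise ValueError("slope must be positive")
    return DetectionLimits(
        sigma=sigma, slope=slope, lod=3.3 * sigma / slope, loq=10.0 * sigma / slope
    )


def quantify(area: float, curve: CalibrationCurve) -> float:
    """Invert the calibration: x = (A − a) / b, warning outside the range."""
    if curve.slope == 0:
        raise ValueError("calibration slope is zero")
    amount = (area - curve.intercept) / curve.slope
    lo, hi = curve.amount_range
    if amount < 0:
        warnings.warn(
            f"area {area:.1f} AU lies below the intercept; negative amount "
            f"{amount:.3g} µg/spot",
            stacklevel=2,
        )
    elif not lo <= amount <= hi:
        warnings.warn(
            f"amount {amount:.3g} µg/spot falls outside the validated range "
            f"[{lo:.2f}, {hi:.2f}]",
            stacklevel=2,
        )
    return amount


def to_tablet_content(amount_ug_per_spot: float, chain: DilutionChain) -> float:
    """Convert a per-spot amount to mg of active substance per tablet."""
    return chain.forward(amount_ug_per_spot)
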