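"""Accuracy, precision and assay statistics for the tablet method.

Accuracy is expressed as spike recovery R% = 100·(found − baseline)/added,
precision as coefficients of variation (CV, sample SD with n−1 denominator
over the mean), and the tablet assay as a replicate summary against the
label claim with a two-sided Student-t confidence interval for the mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation, %: 100 · sample SD (n−1) / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV is undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


@dataclass(frozen=True)
class RecoveryResult:
    """Aggregated spike recovery at one addition level."""

    level: float  # % of nominal added
    recovery: float  # mean R%
    cv: float  # % over replicates
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("recovery needs at least 2 replicates")
        if self.cv < 0:
            raise ValueError("CV cannot be negative")


def recovery(
    found: Sequence[float],
    added: float,
    baseline_content: float,
    level: float = 100.0,
) -> RecoveryResult:
    """Recovery R% = 100·(found − baseline)/added, aggregated over replicates."""
    if added <= 0:
        raise ValueError("added amount must be positive")
    f = np.asarray(found, dtype=float)
    r = 100.0 * (f - baseline_content) / added
    mean_r = r.mean()
    cv_r = 100.0 * r.std(ddof=1) / mean_r if r.size > 1 and mean_r != 0 else 0.0
    return RecoveryResult(
        level=level, recovery=float(mean_r), cv=abs(float(cv_r)), n=int(r.size)
    )


def recovery_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-level recovery summary from a tidy spike table.

    Expects columns level_percent, baseline_mg, added_mg, found_mg (the
    simulator's recovery layout).
    """
    out = []
    for level, grp in df.groupby("level_percent"):
        res = recovery(
            grp["found_mg"],
            added=float(grp["added_mg"].iloc[0]),
            baseline_content=float(grp["baseline_mg"].iloc[0]),
            level=float(level),
        )
        out.append(
            {"level_percent": res.level, "recovery_percent": res.recovery,
             "cv_percent": res.cv, "n": res.n}
        )
    return pd.DataFrame(out)


@dataclass(frozen=True)
class PrecisionResult:
    amount_level: float
    intraday_cv: float
    interday_cv: float
    n_per_day: int
    n_days: int


def precision_table(df: pd.DataFrame) -> pd.DataFrame:
    """Intra-/inter-day CVs per amount level from a tidy replicate table.

    Intra-day (repeatability) is the mean of within-day CVs; inter-day
    (intermediate precision) is the CV over all values pooled across days.
    Expects columns amount_ug_per_spot, day, measured_ug_per_spot.
    """
    rows = []
    for amount, grp in df.groupby("amount_ug_per_spot"):
        within = [
            cv(day_grp["measured_ug_per_spot"])
            for _, day_grp in grp.groupby("day")
            if len(day_grp) >= 2
        ]
        res = PrecisionResult(
            amount_level=float(amount),
            intraday_cv=float(np.mean(within)) if within else float("nan"),
            interday_cv=cv(grp["measured_ug_per_spot"]),
            n_per_day=int(grp.groupby("day").size().iloc[0]),
            n_days=int(grp["day"].nunique()),
        )
        rows.append(
            {"amount_ug_per_spot": res.amount_level,
             "intraday_cv_percent": res.intraday_cv,
             "interday_cv_percent": res.interday_cv,
             "n_days": res.n_days, "n_per_day": res.n_per_day}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AssaySummary:
    """Replicate assay series summarised against the label claim."""

    values: tuple[float, ...]
    n: int
    mean: float
    minimum: float
    maximum: float
    variance: float
    sd: float
    cv: float
    ci_half_width: float
    confidence: float
    label_claim: float
    percent_of_label: float

    def summary(self) -> str:
        return "\n".join(
            [
                f"Assay of {self.n} replicates (label claim {self.label_claim:.0f} mg)",
                f"  mean {self.mean:.1f} mg  [min {self.minimum:.1f}, max {self.maximum:.1f}]",
                f"  variance {self.variance:.4g}  SD {self.sd:.3g}  CV {self.cv:.2f}%",
                f"  {self.confidence:.0f}% CI of the mean: "
                f"{self.mean:.1f} ± {self.ci_half_width:.1f} mg",
                f"  {self.percent_of_label:.1f}% of the label claim",
            ]
        )

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "min": self.minimum,
            "max": self.maximum,
            "variance": self.variance,
            "sd": self.sd,
            "cv_percent": self.cv,
            "ci_half_width": self.ci_half_width,
            "confidence_percent": self.confidence,
            "label_claim_mg": self.label_claim,
            "percent_of_label": self.percent_of_label,
        }


def assay_summary(
    values: Sequence[float], label_claim: float, confidence: float = 95.0
) -> AssaySummary:
    """Summarise a replicate assay series against the declared content.

    The confidence interval is mean ± t(1−α/2, n−1)·SD/√n; all statistics
    use the n−1 sample convention.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("an assay summary needs at least 2 replicates")
    if label_claim <= 0:
        raise ValueError("label claim must be positive")
    if not 0 < confidence < 100:
        raise ValueError("confidence must lie in (0, 100) percent")
    n = v.size
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    alpha = 1 - confidence / 100.0
    t_crit = float(stats.t.ppf(1 - alpha / 2, n - 1))
    return AssaySummary(
        values=tuple(float(x) for x in v),
        n=int(n),
        mean=mean,
        minimum=float(v.min()),
        maximum=float(v.max()),
        variance=sd**2,
        sd=sd,
        cv=float(100.0 * sd / mean),
        ci_half_width=t_crit * sd / np.sqrt(n),
        confidence=confidence,
        label_claim=label_claim,
        percent_of_label=100.0 * mean / label_claim,
    )
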