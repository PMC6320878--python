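"""Synthetic densitograms and validation experiments.

The generator emulates the study conditions of the tablet assay: Gaussian
analyte bands at the method's R_F positions on a 75 mm development
distance, a linear area-vs-amount response per analyte, additive Gaussian
signal noise over an optional drifting baseline, and the complete set of
validation experiments (calibration series, spike recoveries, intra/
inter-day precision, the 8-run robustness screen with injected factor
effects, and paired method-comparison series).  All randomness is driven
by explicit seeds so every table is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import datasets
from .calibration import DEFAULT_CHAINS, DilutionChain
from .densitometry import Densitogram, Spectrum


@dataclass(frozen=True)
class Analyte:
    """One simulated compound: where it migrates and how it responds.

    ``response_slope``/``response_intercept`` define the band area
    (AU) produced by an amount x µg/spot as intercept + slope·x; an
    analyte with amount 0 produces no band at all.
    """

    name: str
    rf_center: float
    band_sigma: float = 1.5
    response_slope: float = 1500.0
    response_intercept: float = 0.0
    lambda_max: float = 254.0

    def __post_init__(self):
        if not 0 < self.rf_center < 1:
            raise ValueError(f"{self.name}: rf_center must lie in (0, 1)")
        if self.band_sigma <= 0:
            raise ValueError(f"{self.name}: band_sigma must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic scanner and experiments."""

    analytes: tuple[Analyte, ...]
    front_distance: float = 75.0
    sampling_step: float = 0.1
    noise_sd: float = 2.0  # AU, on the sampled signal
    baseline: tuple[float, float] = (0.0, 0.0)  # offset AU, drift AU/mm
    seed: int = 0
    dilution_chains: Mapping[str, DilutionChain] = field(default_factory=dict)

    def __post_init__(self):
        if self.sampling_step <= 0:
            raise ValueError("sampling_step must be positive")
        if self.front_distance <= 0:
            raise ValueError("front_distance must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd cannot be negative")

    def analyte(self, name: str) -> Analyte:
        for a in self.analytes:
            if a.name == name:
                return a
        raise KeyError(f"unknown analyte {name!r}")


def study_config(seed: int = 0, noise_sd: float = 2.0) -> SimulationConfig:
    """The default configuration mirroring the published method.

    R_F 0.18 (AA), 0.56 (SA), 0.80 (ASA) on a 75 mm front; response lines
    from the published calibrations (ASA: 2547.7 + 1532.7·x, AA: 370.9 +
    1944.8·x AU); absorption maxima 200/268/299 nm; the tablet dilution
    chains mapping 8 µg/spot ↔ 500 mg (ASA) and 12.8 µg/spot ↔ 200 mg (AA).
    """
    cal = datasets.CALIBRATION_SUMMARY
    analytes = (
        Analyte(
            "AA",
            rf_center=datasets.RF_VALUES["AA"],
            response_slope=cal["AA"]["slope"],
            response_intercept=cal["AA"]["intercept"],
            lambda_max=datasets.LAMBDA_MAX_NM["AA"],
        ),
        Analyte(
            "SA",
            rf_center=datasets.RF_VALUES["SA"],
            response_slope=1800.0,
            response_intercept=0.0,
            lambda_max=datasets.LAMBDA_MAX_NM["SA"],
        ),
        Analyte(
            "ASA",
            rf_center=datasets.RF_VALUES["ASA"],
            response_slope=cal["ASA"]["slope"],
            response_intercept=cal["ASA"]["intercept"],
            lambda_max=datasets.LAMBDA_MAX_NM["ASA"],
        ),
    )
    return SimulationConfig(
        analytes=analytes,
        front_distance=datasets.FRONT_DISTANCE_MM,
        noise_sd=noise_sd,
        seed=seed,
        dilution_chains=dict(DEFAULT_CHAINS),
    )


@dataclass(frozen=True)
class ExperimentPlan:
    """One validation experiment to synthesise.

    kind ∈ {calibration, recovery, precision, robustness, comparison}.
    ``amounts`` carries µg/spot levels (calibration/precision), spike
    levels in percent of nominal (recovery), or is unused; robustness
    uses ``injected_effects`` (seven signed mg/tablet effects) around
    ``base_content``; comparison draws two normal series from
    ``series_means``/``series_sds``.
    """

    kind: str
    amounts: tuple[float, ...] = ()
    replicates: int = 1
    analyte: str = "ASA"
    injected_effects: tuple[float, ...] | None = None
    base_content: float | None = None
    series_means: tuple[float, float] | None = None
    series_sds: tuple[float, float] | None = None
    n_per_series: int = 10
    response_noise_sd: float = 300.0  # AU, on direct area responses
    cv_percent: float = 1.5  # relative noise of mg-scale experiments
    day_effect_cv: float = 1.0  # extra between-day CV (precision)
    n_days: int = 3

    _KINDS = ("calibration", "recovery", "precision", "robustness", "comparison")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown experiment kind {self.kind!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")
        if any(a <= 0 for a in self.amounts):
            raise ValueError("amounts must be strictly positive")
        if self.kind == "robustness":
            if self.injected_effects is None or len(self.injected_effects) != 7:
                raise ValueError("a robustness plan needs exactly 7 injected effects")
            if self.base_content is None:
                raise ValueError("a robustness plan needs a base_content")
        if self.kind == "comparison" and (
            self.series_means is None or self.series_sds is None
        ):
            raise ValueError("a comparison plan needs series_means and series_sds")


def make_densitogram(
    config: SimulationConfig,
    amounts: Mapping[str, float],
    seed: int | None = None,
    wavelength: float = 254.0,
) -> Densitogram:
    """Synthesise one scanner trace for the given per-analyte amounts.

    The signal is baseline offset + drift·x plus, for every analyte with a
    positive amount, a Gaussian band centred at rf_center·front_distance
    whose *area* equals response_intercept + response_slope·amount, plus
    i.i.d. N(0, noise_sd) noise.  Deterministic for a fixed seed.
    """
    for name, amount in amounts.items():
        if amount < 0:
            raise ValueError(f"negative amount for analyte {name!r}")
        config.analyte(name)  # raises for unknown names
    rng = np.random.default_rng(config.seed if seed is None else seed)
    x = np.arange(
        0.0, config.front_distance + config.sampling_step / 2, config.sampling_step
    )
    offset, drift = config.baseline
    y = offset + drift * x
    for name, amount in amounts.items():
        if amount == 0:
            continue
        a = config.analyte(name)
        area = a.response_intercept + a.response_slope * amount
        center = a.rf_center * config.front_distance
        y = y + (
            area
            / (a.band_sigma * np.sqrt(2 * np.pi))
            * np.exp(-((x - center) ** 2) / (2 * a.band_sigma**2))
        )
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, size=x.size)
    return Densitogram(
        x, y, wavelength=wavelength, front_distance=config.front_distance
    )


def make_spectrum(
    lambda_max: float,
    width: float = 25.0,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> Spectrum:
    """A synthetic UV spectrum: Gaussian absorption band on a 200–400 nm grid."""
    wl = np.arange(200.0, 401.0, 1.0) if grid is None else np.asarray(grid, float)
    ab = amplitude * np.exp(-((wl - lambda_max) ** 2) / (2 * width**2))
    if noise_sd > 0:
        ab = ab + np.random.default_rng(seed).normal(0.0, noise_sd, wl.size)
    return Spectrum(wl, ab)


def simulate_experiment(
    plan: ExperimentPlan, config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Synthesise the tidy result table of one validation experiment."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    dispatch = {
        "calibration": _sim_calibration,
        "recovery": _sim_recovery,
        "precision": _sim_precision,
        "robustness": _sim_robustness,
        "comparison": _sim_comparison,
    }
    return dispatch[plan.kind](plan, config, rng)


def _sim_calibration(plan, config, rng) -> pd.DataFrame:
    a = config.analyte(plan.analyte)
    rows = []
    for amount in plan.amounts:
        true_area = a.response_intercept + a.response_slope * amount
        for rep in range(plan.replicates):
            noise = rng.normal(0.0, plan.response_noise_sd) if plan.response_noise_sd else 0.0
            rows.append(
                {
                    "analyte": a.name,
                    "amount_ug_per_spot": amount,
                    "replicate": rep + 1,
                    "area_AU": true_area + noise,
                }
            )
    return pd.DataFrame(rows)


def _sim_recovery(plan, config, rng) -> pd.DataFrame:
    """Spike-recovery runs: levels are percent of the nominal content."""
    base = plan.base_content
    if base is None:
        base = datasets.LABEL_CLAIM_MG[plan.analyte]
    rows = []
    for level in plan.amounts or (50.0, 100.0, 150.0):
        added = base * level / 100.0
        for rep in range(plan.replicates):
            truth = base + added
            found = truth * (1 + rng.normal(0.0, plan.cv_percent / 100.0))
            rows.append(
                {
                    "analyte": plan.analyte,
                    "level_percent": level,
                    "replicate": rep + 1,
                    "baseline_mg": base,
                    "added_mg": added,
                    "found_mg": found,
                }
            )
    return pd.DataFrame(rows)


def _sim_precision(plan, config, rng) -> pd.DataFrame:
    """Repeatability/intermediate-precision runs over several days."""
    rows = []
    for amount in plan.amounts:
        for day in range(1, plan.n_days + 1):
            day_shift = rng.normal(0.0, plan.day_effect_cv / 100.0)
            for rep in range(plan.replicates):
                value = amount * (
                    1 + day_shift + rng.normal(0.0, plan.cv_percent / 100.0)
                )
                rows.append(
                    {
                        "analyte": plan.analyte,
                        "amount_ug_per_spot": amount,
                        "day": day,
                        "replicate": rep + 1,
                        "measured_ug_per_spot": value,
                    }
                )
    return pd.DataFrame(rows)


def _sim_robustness(plan, config, rng) -> pd.DataFrame:
    """Factorial responses y = base + Σ_j (E_j/2)·x_j + noise."""
    design = datasets.design_matrix()
    effects = np.asarray(plan.injected_effects, dtype=float)
    noise_sd = plan.base_content * plan.cv_percent / 100.0
    y = plan.base_content + design @ (effects / 2.0)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.size)
    df = pd.DataFrame(design, columns=[f"X{i}" for i in range(1, 8)])
    df.insert(0, "experiment", np.arange(1, 9))
    df["response_mg"] = y
    df["analyte"] = plan.analyte
    return df


def _sim_comparison(plan, config, rng) -> pd.DataFrame:
    """Two equal-n series with the requested means and SD scales.

    The standardised draws depend only on the seed, so shrinking the SDs
    shrinks the sample scatter proportionally (t grows as 1/sd).
    """
    n = plan.n_per_series
    rows = []
    for i, (mean, sd) in enumerate(zip(plan.series_means, plan.series_sds)):
        z = rng.standard_normal(n)
        values = mean + sd * z
        for v in values:
            rows.append({"method": f"method_{i + 1}", "value": v})
    return pd.DataFrame(rows)
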