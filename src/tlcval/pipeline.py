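"""End-to-end validation pipeline and the structured report it produces.

``run_pipeline`` chains the stages — synthetic densitograms → peak
quantification → calibration with detection limits → accuracy/precision →
replicate assay vs label claim → robustness screen → two-method
comparison — and returns a :class:`ValidationReport`, a pydantic model
whose JSON serialisation is deterministic for a fixed seed.  The
robustness, assay and comparison stages can run either on the published
study tables (the default: these numeric series were printed in full) or
on freshly simulated experiments.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

from . import calibration as cal
from . import comparison as cmp
from . import datasets, robustness, simulate, validation
from .densitometry import detect_peaks, spectral_scan


class RunConfig(BaseModel):
    """Configuration of one full validation run."""

    seed: int = 0
    alpha: float = 0.05
    cv_threshold: float = 5.0
    noise_sd: float = 2.0
    confidence: float = 95.0
    use_printed_tables: bool = True
    analytes: tuple[str, ...] = ("ASA", "AA")
    label_claims: dict[str, float] = Field(
        default_factory=lambda: dict(datasets.LABEL_CLAIM_MG)
    )
    calibration_amounts: dict[str, list[float]] = Field(
        default_factory=lambda: {
            "ASA": [1.50, 3.00, 4.50, 6.00, 7.50, 9.00],
            "AA": [1.50, 3.00, 4.50, 6.00, 7.50, 9.00, 10.50, 12.00, 13.50],
        }
    )
    lod_amounts: dict[str, list[float]] = Field(
        default_factory=lambda: {
            "ASA": [0.044, 0.088, 0.180],
            "AA": [0.090, 0.180, 0.300],
        }
    )
    precision_amounts: dict[str, list[float]] = Field(
        default_factory=lambda: {
            "ASA": [8.00, 4.80, 1.60],
            "AA": [12.80, 7.36, 2.56],
        }
    )
    #: Response SD (AU) of the low-range detection-limit calibrations;
    #: chosen so that 3.3σ/S lands at the method's detection limits
    #: (0.20 µg/spot for ASA, 0.25 for AA).
    lod_response_noise: dict[str, float] = Field(
        default_factory=lambda: {"ASA": 93.0, "AA": 147.0}
    )

    @field_validator("label_claims")
    @classmethod
    def _claims_positive(cls, v):
        for name, claim in v.items():
            if claim <= 0:
                raise ValueError(f"label claim for {name!r} must be positive")
        return v

    @field_validator("alpha")
    @classmethod
    def _alpha_open_unit(cls, v):
        if not 0 < v < 1:
            raise ValueError("alpha must lie in (0, 1)")
        return v

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls(**data)


class PeakRecord(BaseModel):
    analyte: Optional[str] = None
    rf: float
    apex_mm: float
    start_mm: float
    end_mm: float
    height_AU: float
    area_AU: float
    lambda_max_nm: Optional[float] = None
    purity_r_sm: Optional[float] = None
    purity_r_me: Optional[float] = None


class CalibrationBlock(BaseModel):
    analyte: str
    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    r: float
    s: float
    F: float
    p: float
    n: int
    range_ug_per_spot: tuple[float, float]
    residuals_above: int
    residuals_below: int
    lod_ug_per_spot: float
    loq_ug_per_spot: float


class AccuracyRow(BaseModel):
    analyte: str
    level_percent: float
    recovery_percent: float
    cv_percent: float
    n: int


class PrecisionRow(BaseModel):
    analyte: str
    amount_ug_per_spot: float
    intraday_cv_percent: float
    interday_cv_percent: float


class AssayBlock(BaseModel):
    series: str
    n: int
    mean_mg: float
    min_mg: float
    max_mg: float
    variance: float
    sd: float
    cv_percent: float
    ci_half_width_mg: float
    confidence_percent: float
    label_claim_mg: float
    percent_of_label: float


class RobustnessBlock(BaseModel):
    analyte: str
    factor_names: tuple[str, ...]
    effects: tuple[float, ...]
    abs_effects: tuple[float, ...]
    mean_mg: float
    variance: float
    sd: float
    cv_percent: float
    half_normal_r_squared: float
    rank_probabilities: tuple[float, ...]
    robust: bool
    messages: tuple[str, ...]


class ComparisonBlock(BaseModel):
    series1: str
    series2: str
    n: int
    mean1: float
    mean2: float
    s1: float
    s2: float
    t: float
    F: float
    t_critical: float
    F_critical: float
    alpha: float
    significant_t: bool
    significant_f: bool


class ValidationReport(BaseModel):
    """Full structured output of one validation run."""

    seed: int
    data_source: str  # "printed-tables" or "simulated"
    peaks: list[PeakRecord]
    calibrations: list[CalibrationBlock]
    accuracy: list[AccuracyRow]
    precision: list[PrecisionRow]
    assays: list[AssayBlock]
    robustness: list[RobustnessBlock]
    comparison: ComparisonBlock

    def to_json(self, indent: int = 2) -> str:
        # round-trip through dict to guarantee key order stability
        return json.dumps(self.model_dump(mode="json"), indent=indent, sort_keys=True)

    def render_text(self) -> str:
        """Plain-text tables mirroring the validation summary layout."""
        out = [f"Validation report (seed {self.seed}, data: {self.data_source})", ""]
        out.append("Detected bands:")
        for p in self.peaks:
            lam = f", λmax {p.lambda_max_nm:.0f} nm" if p.lambda_max_nm else ""
            out.append(
                f"  {p.analyte or '?':>4s}  R_F {p.rf:.2f}  area {p.area_AU:.0f} AU{lam}"
            )
        for c in self.calibrations:
            out += [
                "",
                f"Calibration {c.analyte}: A = {c.intercept:.1f} (±{c.intercept_se:.1f})"
                f" + {c.slope:.1f} (±{c.slope_se:.1f})·x",
                f"  n={c.n}, r={c.r:.4f}, s={c.s:.1f}, F={c.F:.1f}, "
                f"LOD {c.lod_ug_per_spot:.2f}, LOQ {c.loq_ug_per_spot:.2f} µg/spot",
            ]
        out.append("")
        out.append("Accuracy (spike recovery):")
        for r in self.accuracy:
            out.append(
                f"  {r.analyte} {r.level_percent:.0f}%: R = {r.recovery_percent:.1f}%"
                f", CV = {r.cv_percent:.2f}% (n={r.n})"
            )
        out.append("")
        out.append("Precision (CV %):")
        for r in self.precision:
            out.append(
                f"  {r.analyte} {r.amount_ug_per_spot:.2f} µg/spot: intra-day "
                f"{r.intraday_cv_percent:.2f}, inter-day {r.interday_cv_percent:.2f}"
            )
        for a in self.assays:
            out += [
                "",
                f"Assay {a.series}: mean {a.mean_mg:.1f} mg, variance {a.variance:.4g},"
                f" SD {a.sd:.3g}, CV {a.cv_percent:.2f}%",
                f"  {a.confidence_percent:.0f}% CI ± {a.ci_half_width_mg:.1f} mg; "
                f"{a.percent_of_label:.1f}% of the {a.label_claim_mg:.0f} mg label claim",
            ]
        for r in self.robustness:
            out += [
                "",
                f"Robustness {r.analyte}: CV {r.cv_percent:.2f}% "
                f"({'robust' if r.robust else 'NOT robust'}); "
                f"half-normal R² = {r.half_normal_r_squared:.3f}",
                "  effects: "
                + ", ".join(
                    f"{n}={e:+.3f}" for n, e in zip(r.factor_names, r.effects)
                ),
            ]
        c = self.comparison
        out += [
            "",
            f"Comparison {c.series1} vs {c.series2} (n={c.n}): "
            f"t = {c.t:.2f} (crit {c.t_critical:.3f}), "
            f"F = {c.F:.2f} (crit {c.F_critical:.2f}) → "
            + (
                "significant difference"
                if (c.significant_t or c.significant_f)
                else "no significant difference"
            ),
        ]
        return "\n".join(out)


def _child_seed(seed: int, stage: str) -> int:
    """Stable per-stage substream below 2**31 (process-independent)."""
    tag = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence([seed, tag])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> ValidationReport:
    """Execute every validation stage and assemble the report."""
    sim_cfg = simulate.study_config(seed=config.seed, noise_sd=config.noise_sd)

    # --- densitometry on a synthetic three-component scan -----------------
    amounts = {"AA": 12.8, "SA": 2.0, "ASA": 8.0}
    dgram = simulate.make_densitogram(
        sim_cfg, amounts, seed=_child_seed(config.seed, "densitogram")
    )
    peaks = detect_peaks(dgram)
    expected = sorted(datasets.RF_VALUES.items(), key=lambda kv: kv[1])
    peak_records = []
    for p in peaks:
        name = min(expected, key=lambda kv: abs(kv[1] - p.rf))[0]
        analyte = sim_cfg.analyte(name)
        spec_seed = _child_seed(config.seed, f"spectrum-{name}")
        apex_spec = simulate.make_spectrum(analyte.lambda_max)
        flank = simulate.make_spectrum(
            analyte.lambda_max, noise_sd=0.002, seed=spec_seed
        )
        purity = spectral_scan(flank, apex_spec, flank)
        peak_records.append(
            PeakRecord(
                analyte=name,
                rf=p.rf,
                apex_mm=p.apex,
                start_mm=p.start,
                end_mm=p.end,
                height_AU=p.height,
                area_AU=p.area,
                lambda_max_nm=purity.lambda_max,
                purity_r_sm=purity.r_sm,
                purity_r_me=purity.r_me,
            )
        )

    # --- calibration + detection limits ----------------------------------
    calibration_blocks = []
    for name in config.analytes:
        plan = simulate.ExperimentPlan(
            kind="calibration",
            analyte=name,
            amounts=tuple(config.calibration_amounts[name]),
            replicates=1,
        )
        table = simulate.simulate_experiment(
            plan, sim_cfg, seed=_child_seed(config.seed, f"calibration-{name}")
        )
        curve = cal.fit_calibration(table["amount_ug_per_spot"], table["area_AU"])
        _, resid_summary = cal.residual_diagnostics(
            curve, table["amount_ug_per_spot"], table["area_AU"]
        )
        low_plan = simulate.ExperimentPlan(
            kind="calibration",
            analyte=name,
            amounts=tuple(config.lod_amounts[name]),
            replicates=6,
            response_noise_sd=config.lod_response_noise.get(name, 100.0),
        )
        low_table = simulate.simulate_experiment(
            low_plan, sim_cfg, seed=_child_seed(config.seed, f"lod-{name}")
        )
        # σ: residual SD of the low-range curve; S: the (stable) main slope.
        low_curve = cal.fit_calibration(
            low_table["amount_ug_per_spot"], low_table["area_AU"]
        )
        limits = cal.detection_limits(sigma=low_curve.s, slope=curve.slope)
        calibration_blocks.append(
            CalibrationBlock(
                analyte=name,
                intercept=curve.intercept,
                slope=curve.slope,
                intercept_se=curve.intercept_se,
                slope_se=curve.slope_se,
                r=curve.r,
                s=curve.s,
                F=curve.f_stat,
                p=curve.p_value,
                n=curve.n,
                range_ug_per_spot=curve.amount_range,
                residuals_above=resid_summary["n_above"],
                residuals_below=resid_summary["n_below"],
                lod_ug_per_spot=limits.lod,
                loq_ug_per_spot=limits.loq,
            )
        )

    # --- accuracy (spike recovery) and precision --------------------------
    accuracy_rows = []
    precision_rows = []
    for name in config.analytes:
        rec_plan = simulate.ExperimentPlan(
            kind="recovery",
            analyte=name,
            amounts=(50.0, 100.0, 150.0),
            replicates=6,
        )
        rec_table = simulate.simulate_experiment(
            rec_plan, sim_cfg, seed=_child_seed(config.seed, f"recovery-{name}")
        )
        for _, row in validation.recovery_table(rec_table).iterrows():
            accuracy_rows.append(
                AccuracyRow(
                    analyte=name,
                    level_percent=row["level_percent"],
                    recovery_percent=row["recovery_percent"],
                    cv_percent=row["cv_percent"],
                    n=int(row["n"]),
                )
            )
        prec_plan = simulate.ExperimentPlan(
            kind="precision",
            analyte=name,
            amounts=tuple(config.precision_amounts[name]),
            replicates=3,
        )
        prec_table = simulate.simulate_experiment(
            prec_plan, sim_cfg, seed=_child_seed(config.seed, f"precision-{name}")
        )
        for _, row in validation.precision_table(prec_table).iterrows():
            precision_rows.append(
                PrecisionRow(
                    analyte=name,
                    amount_ug_per_spot=row["amount_ug_per_spot"],
                    intraday_cv_percent=row["intraday_cv_percent"],
                    interday_cv_percent=row["interday_cv_percent"],
                )
            )

    # --- assay series vs label claim --------------------------------------
    assay_blocks = []
    if config.use_printed_tables:
        series = {
            "ASA (TLC)": ("ASA", datasets.ASSAY_SERIES["ASA"]),
            "AA (TLC)": ("AA", datasets.ASSAY_SERIES["AA"]),
            "AA (iodometric)": ("AA", datasets.ASSAY_SERIES["AA_iodometric"]),
        }
    else:
        rng = np.random.default_rng(_child_seed(config.seed, "assay"))
        series = {}
        for name in config.analytes:
            claim = config.label_claims[name]
            vals = claim * (1 + rng.normal(0, 0.015, size=10))
            series[f"{name} (simulated)"] = (name, tuple(vals))
    for label, (name, values) in series.items():
        summ = validation.assay_summary(
            values, config.label_claims[name], confidence=config.confidence
        )
        assay_blocks.append(
            AssayBlock(
                series=label,
                n=summ.n,
                mean_mg=summ.mean,
                min_mg=summ.minimum,
                max_mg=summ.maximum,
                variance=summ.variance,
                sd=summ.sd,
                cv_percent=summ.cv,
                ci_half_width_mg=summ.ci_half_width,
                confidence_percent=summ.confidence,
                label_claim_mg=summ.label_claim,
                percent_of_label=summ.percent_of_label,
            )
        )

    # --- robustness screen -------------------------------------------------
    design = robustness.build_design()
    robustness_blocks = []
    for name in config.analytes:
        if config.use_printed_tables:
            responses = datasets.ROBUSTNESS_RESPONSES[name]
        else:
            plan = simulate.ExperimentPlan(
                kind="robustness",
                analyte=name,
                injected_effects=(0.0,) * 7,
                base_content=config.label_claims[name],
            )
            responses = simulate.simulate_experiment(
                plan, sim_cfg, seed=_child_seed(config.seed, f"robustness-{name}")
            )["response_mg"].to_numpy()
        effects = robustness.compute_effects(design, responses)
        half = robustness.half_normal_analysis(effects)
        verdict = robustness.robustness_verdict(effects, config.cv_threshold)
        robustness_blocks.append(
            RobustnessBlock(
                analyte=name,
                factor_names=effects.factor_names,
                effects=tuple(effects.effects),
                abs_effects=tuple(effects.abs_effects),
                mean_mg=effects.mean,
                variance=effects.variance,
                sd=effects.sd,
                cv_percent=effects.cv,
                half_normal_r_squared=half.r_squared,
                rank_probabilities=tuple(half.rank_probabilities),
                robust=verdict.robust,
                messages=verdict.messages,
            )
        )

    # --- two-method comparison ---------------------------------------------
    if config.use_printed_tables:
        s1 = datasets.ASSAY_SERIES["AA"]
        s2 = datasets.ASSAY_SERIES["AA_iodometric"]
        labels = ("AA (TLC)", "AA (iodometric)")
    else:
        plan = simulate.ExperimentPlan(
            kind="comparison",
            series_means=(203.2, 201.3),
            series_sds=(1.96, 2.51),
        )
        table = simulate.simulate_experiment(
            plan, sim_cfg, seed=_child_seed(config.seed, "comparison")
        )
        s1 = table.loc[table["method"] == "method_1", "value"].to_numpy()
        s2 = table.loc[table["method"] == "method_2", "value"].to_numpy()
        labels = ("method_1 (simulated)", "method_2 (simulated)")
    result = cmp.compare(s1, s2, alpha=config.alpha)
    comparison_block = ComparisonBlock(
        series1=labels[0],
        series2=labels[1],
        n=result.n,
        mean1=result.mean1,
        mean2=result.mean2,
        s1=result.s1,
        s2=result.s2,
        t=result.t_stat,
        F=result.f_stat,
        t_critical=result.t_critical,
        F_critical=result.f_critical,
        alpha=result.alpha,
        significant_t=result.significant_t,
        significant_f=result.significant_f,
    )

    return ValidationReport(
        seed=config.seed,
        data_source="printed-tables" if config.use_printed_tables else "simulated",
        peaks=peak_records,
        calibrations=calibration_blocks,
        accuracy=accuracy_rows,
        precision=precision_rows,
        assays=assay_blocks,
        robustness=robustness_blocks,
        comparison=comparison_block,
    )
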