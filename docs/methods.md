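# Methods

This note documents the models, conventions and design choices behind
`tlcval`, in the spirit of a statistical package's methods appendix.

## The measurement model

A developed TLC plate is scanned along one track; the scanner reports
absorbance (AU) versus position (mm from the application line).  We model
one track as

    y(z) = b₀ + b₁·z + Σ_k A_k · N(z; μ_k, σ_k) + ε(z),

where `N` is a unit-area Gaussian, `μ_k = R_F,k · z_front` places band k
at its retention factor times the solvent-front distance (75 mm), `A_k`
is the band area, and `ε ~ N(0, σ_noise²)` i.i.d. per sample.  Bands on
well-behaved silica tracks are near-symmetric, so a symmetric Gaussian is
used; an exponentially-modified shape was considered and deferred, since
no downstream statistic here depends on tailing.  The area responds
linearly to the amount x (µg/spot) applied: `A = a + b·x`, using the
method's published response lines (ASA: 2547.7 + 1532.7·x; AA: 370.9 +
1944.8·x AU).  An analyte with amount zero contributes no band (the
response intercept is a calibration artefact, not a blank signal).

### Generator defaults (the emulated study conditions)

| parameter | default | why |
|---|---|---|
| front distance | 75 mm | the method's development distance |
| sampling step | 0.1 mm | typical scanner data resolution (100 µm/step) |
| band σ | 1.5 mm | plausible TLC band width; true widths were never published |
| signal noise | 2 AU | gives band SNR in the hundreds, as in routine scans |
| area (response) noise | 300 AU | matches the published calibration residual SDs (314/427 AU) |
| low-range response noise | 93 AU (ASA), 147 AU (AA) | back-solved from the published LOD 0.20/0.25 µg/spot via LOD = 3.3σ/S |
| mg-scale experiment CV | 1.5% | the study's typical precision CVs (≈1–3%) |
| SA response slope | 1800 AU/µg | salicylic acid is monitored, never quantified; value only needs to produce a visible band |
| R_F | 0.18 (AA), 0.56 (SA), 0.80 (ASA) | the method's retention factors |
| λmax | 268 / 299 / 200 nm | the analytes' absorption maxima |

The generator reproduces the features the statistics depend on — band
position, linear response, additive noise, factorial structure — and not
plate-level artefacts (streaking, spot shape, matrix interference,
SA formation from ASA hydrolysis over time, between-plate response
drift).  Passing tests therefore demonstrate the *statistical* pipeline,
not chromatographic performance on real extracts.

Dilution chains: one 5 µL spot from a 5 mL working solution scales
amounts by 1000 (µg/spot → mg per 5 mL); the working-solution-to-tablet
factor is 62.5 for ASA (8 µg/spot ↔ 500 mg/tablet) and 15.625 for AA
(12.8 µg/spot ↔ 200 mg/tablet).  The chain is exact arithmetic, so the
round trip µg/spot → mg/tablet → µg/spot is lossless.  The study's
solution tables contain one internal inconsistency (an AA working
solution stated as 2.26 mg/5 mL where the precision levels imply
2.56 µg/spot); both numbers are exposed as plain configuration values
and the precision defaults use 12.80/7.36/2.56 µg/spot.

## Densitogram processing

*Baseline*: grey-scale morphological opening (erosion then dilation) over
a 10 mm window, with linear-extrapolation padding at the scan edges.
Opening follows constant or drifting backgrounds exactly and removes
features narrower than the window, so the residual under an isolated
band stays well below 5% of band height.

*Peak detection*: local maxima of the baseline-subtracted signal above
`min_snr` (default 10) times a robust noise scale — 1.4826 × MAD of the
outer 10% of the scan, which is insensitive to the bands themselves.
Apexes closer than 2 mm merge (noise must not split a band top).
Boundaries sit at the flanking local minima, falling back to the sample
where the signal drops below 1% of peak height; the scanner vendor's
exact rule is proprietary, and this combination is stable for both
isolated and partially fused bands.

*Integration*: plain trapezoid on the sampled grid over [start, end] —
deliberately no peak-model fitting, matching densitometer practice.  With
1%-height boundaries a Gaussian band loses ≈0.3% of its tail mass; the
closed-form checks in the tests therefore use explicit ±6σ bounds.

*Identity/purity*: λmax is read off the apex spectrum on its wavelength
grid; purity is the Pearson correlation of the start-vs-apex and
apex-vs-end spectra (r > 0.999 expected for a pure band).  Zero-variance
spectra make the correlation undefined and are flagged rather than
silently passed.

## Calibration and detection limits

Ordinary least squares with the usual simple-regression diagnostics:
Pearson r, residual SD `s` on n−2 degrees of freedom, and the regression
F = (r²/(1−r²))·(n−2) with its p-value.  No weighting or robust loss:
the response range here spans less than one decade and the method's own
practice is unweighted OLS.  Residual diagnostics report the counts
above/below zero and the number of sign runs ordered by amount — a long
one-sided run exposes curvature that r alone hides.

For LOD = 3.3σ/S and LOQ = 10σ/S, σ is taken as the residual SD of a
dedicated low-range calibration (amounts around the detection limit:
0.044–0.180 µg/spot ASA, 0.090–0.300 AA, six replicates each) and S as
the slope of the main calibration — the low-range slope estimate is far
too noisy to divide by, while the residual scatter there is exactly the
"SD of the response" the definition wants.  Whether σ should instead be
a blank SD is a recognised ambiguity of the slope method; the choice is
a plain function argument (`detection_limits(sigma, slope)`), so either
convention is one call away.  The ratio LOQ/LOD = 10/3.3 holds by
construction.

Inverse quantitation `x = (A − a)/b` warns (rather than errors) outside
the validated range, because over- or under-dosed tablets are precisely
what an assay must still report.

## Validation statistics

All sample statistics use n−1 denominators; this reproduces the study's
printed variances exactly (224.1, 69.6, 151.8, 3.85, 6.32).  Confidence
intervals use two-sided Student t quantiles computed from the
distribution (t(0.975, 9) = 2.262), never lookup tables.  Rounding to
table precision happens only in rendering; full precision is kept
internally.  One printed value is knowingly irreproducible: the ASA
assay CV appears as 2.09% where sd/mean gives 2.53% — the recomputed
value is reported.  Intra-day precision is the mean of within-day CVs;
inter-day precision is the CV of all values pooled across days (the
method reports plain CVs; no variance-component ANOVA is attempted).

## Robustness screen

The design is the standard 8-run saturated two-level fraction for seven
factors (2^(7−4)); columns are balanced and mutually orthogonal, which
makes each main effect `E_j = ȳ₊ − ȳ₋` identical to twice the OLS
coefficient of the ±1 regressor — a property the tests verify to 1e−9.
With all seven columns consumed by factors there is no error estimate,
hence the half-normal diagnostic: |E| ranked ascending against quantiles
`Φ⁻¹((1+p_i)/2)` with midpoint rank probabilities `p_i = (i−0.5)/m`
(Blom's `(i−3/8)/(m+1/4)` is available as an option).  The line is
fitted with a free intercept by default (through-origin is an option);
R² is computed about the mean in both cases so the conventions stay
comparable.  Because the published R² threshold depends on exactly these
unstated conventions, the R² is treated as a diagnostic, not a
reproduction target.  Effects are reported signed with magnitudes
alongside (published tables mix the two conventions).  The practical
verdict is the CV of the eight responses against a 5% threshold.

## Method comparison

The equal-n statistic `t = |x̄₁ − x̄₂|·√n/√(s₁² + s₂²)` is algebraically
the pooled two-sample t when both series have n results, so it is
referred to t with 2n−2 degrees of freedom; the published critical
values (2.101 at n = 10, and F(0.95; 9, 9) = 3.18 upper-tail for the
variance ratio) are reproduced by the scipy quantile functions.  The
variance ratio always places the larger variance in the numerator.  On
the built-in series the comparison gives t = 1.88 and F = 1.64, both
below their criticals — the two methods agree.  (The t printed in the
source tables is 1.89, an intermediate-rounding artefact; recomputing
from the full series gives 1.8836.)

## Pipeline and problem sizes

`run_pipeline` derives one child seed per stage from the run seed via
`SeedSequence` with a CRC32 stage tag, so reports are byte-identical for
a fixed configuration and seed, and stages are individually
reproducible.  The report is a pydantic model; its JSON schema ships in
`docs/report.schema.json`.

Simulation-based checks use deliberately modest sizes chosen for tight
sampling error at interactive speed: 10,000 replicates for the type-I
error of the comparison verdict (binomial SE ≈ 0.2% at p = 0.05), 2,000
replicates for the effect-estimator RMSE (≈1.6% relative SE against a
15% band), and 1,000 for assay parameter recovery.

## Known limitations

- Band widths, raw scans and the individual calibration points of the
  original study were never published; band-level quantities (R_S values,
  regression coefficient uncertainties) are validated against the
  generator's ground truth and closed forms, not against the instrument.
- Co-migrating bands are not deconvolved; fused peaks split at the
  valley between them.
- The factorial machinery is fixed to the 8×7 saturated design plus
  user-supplied ±1 matrices that pass the balance/orthogonality checks;
  there is no general fractional-factorial generator.
- No weighted/robust calibration and no per-plate calibration hierarchy.
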