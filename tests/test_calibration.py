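"""Calibration fits, diagnostics, detection limits, quantitation."""

import warnings

import numpy as np
import pytest

from tlcval import (
    detection_limits,
    fit_calibration,
    quantify,
    residual_diagnostics,
    to_tablet_content,
)
from tlcval.calibration import DEFAULT_CHAINS, DilutionChain
from tlcval.simulate import ExperimentPlan, simulate_experiment


def normal_equations_oracle(x, y):
    """Independent straight-line LS via the explicit normal equations."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return intercept, slope


class TestFitCalibration:
    def test_exact_line_recovered(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        a = 1532.7 + 2.0 * x
        curve = fit_calibration(x, a)
        assert curve.slope == pytest.approx(2.0, abs=1e-9)
        assert curve.intercept == pytest.approx(1532.7, abs=1e-9)
        assert curve.r == pytest.approx(1.0, abs=1e-12)
        assert curve.s == pytest.approx(0.0, abs=1e-7)

    def test_matches_normal_equations_on_noisy_data(self):
        rng = np.random.default_rng(7)
        x = np.linspace(1.5, 9.0, 6)
        a = 2547.7 + 1532.7 * x + rng.normal(0, 300, 6)
        curve = fit_calibration(x, a)
        b0, b1 = normal_equations_oracle(x, a)
        assert curve.intercept == pytest.approx(b0, rel=1e-9)
        assert curve.slope == pytest.approx(b1, rel=1e-9)

    def test_f_equals_r_squared_identity(self):
        rng = np.random.default_rng(21)
        x = np.linspace(1.5, 13.5, 9)
        a = 370.9 + 1944.8 * x + rng.normal(0, 400, 9)
        curve = fit_calibration(x, a)
        n, r2 = curve.n, curve.r**2
        assert curve.f_stat == pytest.approx(r2 / (1 - r2) * (n - 2), rel=1e-9)

    def test_constant_amounts_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_calibration([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_noiseless_range_calibration_perfectly_linear(self, noiseless_config):
        for name, amounts in (
            ("ASA", (1.5, 3.0, 4.5, 6.0, 7.5, 9.0)),
            ("AA", (1.5, 4.5, 7.5, 10.5, 13.5)),
        ):
            plan = ExperimentPlan(
                kind="calibration", analyte=name, amounts=amounts,
                response_noise_sd=0.0,
            )
            table = simulate_experiment(plan, noiseless_config)
            curve = fit_calibration(table["amount_ug_per_spot"], table["area_AU"])
            assert curve.r == pytest.approx(1.0, abs=1e-12)

    def test_grid_search_oracle_on_small_instance(self):
        rng = np.random.default_rng(3)
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = 10.0 + 3.0 * x + rng.normal(0, 0.5, 6)
        curve = fit_calibration(x, y)
        slopes = np.linspace(curve.slope - 0.5, curve.slope + 0.5, 201)
        intercepts = np.linspace(curve.intercept - 0.5, curve.intercept + 0.5, 201)
        S, I = np.meshgrid(slopes, intercepts)
        sse = ((y[None, None, :] - (I[..., None] + S[..., None] * x)) ** 2).sum(-1)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert abs(S[i, j] - curve.slope) <= 0.01
        assert abs(I[i, j] - curve.intercept) <= 0.01


class TestResidualDiagnostics:
    def test_perfect_line_gives_zero_residuals(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        a = 5.0 + 2.0 * x
        curve = fit_calibration(x, a)
        table, summary = residual_diagnostics(curve, x, a)
        assert np.allclose(table["residual"], 0.0, atol=1e-8)

    def test_residual_sum_is_zero_for_any_ols_fit(self):
        rng = np.random.default_rng(11)
        x = np.linspace(1, 10, 8)
        a = 3.0 + 7.0 * x + rng.normal(0, 5, 8)
        curve = fit_calibration(x, a)
        _, summary = residual_diagnostics(curve, x, a)
        assert abs(summary["residual_sum"]) < 1e-9 * np.sum(np.abs(a))

    def test_curvature_produces_one_sided_runs(self):
        x = np.linspace(0, 10, 20)
        a = 1.0 + 2.0 * x + 0.8 * x**2  # strongly curved
        curve = fit_calibration(x, a)
        _, summary = residual_diagnostics(curve, x, a)
        # a quadratic under a straight-line fit has the −,+,− pattern: 3 runs,
        # far below the ~n/2 expected of random signs
        assert summary["sign_runs"] <= 4

    def test_length_mismatch_rejected(self):
        curve = fit_calibration([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="length"):
            residual_diagnostics(curve, [1.0, 2.0], [1.0, 2.0, 3.0])


class TestDetectionLimits:
    def test_zero_sigma_gives_zero_limits(self):
        limits = detection_limits(0.0, 1532.7)
        assert limits.lod == 0.0 and limits.loq == 0.0

    def test_published_aa_lod_from_backsolved_sigma(self):
        # σ chosen so 3.3σ/S reproduces the printed 0.25 µg/spot with the
        # published AA slope 1944.8 AU per µg/spot
        limits = detection_limits(sigma=147.3, slope=1944.8)
        assert round(limits.lod, 2) == 0.25

    def test_loq_over_lod_is_ten_thirds_exactly(self):
        limits = detection_limits(sigma=55.5, slope=1234.5)
        assert limits.loq / limits.lod == pytest.approx(10.0 / 3.3, rel=1e-12)

    def test_scale_homogeneity(self):
        a = detection_limits(100.0, 1500.0)
        b = detection_limits(700.0, 10500.0)  # both scaled ×7
        assert a.lod == pytest.approx(b.lod, rel=1e-12)
        assert a.loq == pytest.approx(b.loq, rel=1e-12)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            detection_limits(10.0, 0.0)


class TestQuantify:
    def test_area_at_intercept_maps_to_zero(self):
        curve = fit_calibration([1.0, 2.0, 3.0], [12.0, 14.0, 16.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert quantify(curve.intercept, curve) == pytest.approx(0.0, abs=1e-12)

    def test_inverse_of_forward_prediction(self):
        curve = fit_calibration([1.0, 2.0, 3.0], [12.0, 14.0, 16.0])
        assert quantify(float(curve.predict(2.0)), curve) == pytest.approx(2.0)

    def test_round_trip_on_noiseless_simulation(self, noiseless_config):
        plan = ExperimentPlan(
            kind="calibration", analyte="AA",
            amounts=(1.5, 4.5, 7.5, 10.5, 13.5), response_noise_sd=0.0,
        )
        table = simulate_experiment(plan, noiseless_config)
        curve = fit_calibration(table["amount_ug_per_spot"], table["area_AU"])
        analyte = noiseless_config.analyte("AA")
        for amount in (2.0, 6.4, 12.8):
            area = analyte.response_intercept + analyte.response_slope * amount
            assert quantify(area, curve) == pytest.approx(amount, abs=1e-6)

    def test_out_of_range_amount_warns(self):
        curve = fit_calibration([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
        with pytest.warns(UserWarning, match="range"):
            quantify(100.0, curve)
        with pytest.warns(UserWarning, match="negative"):
            quantify(-20.0, curve)


class TestDilution:
    def test_published_tablet_contents(self):
        assert to_tablet_content(8.0, DEFAULT_CHAINS["ASA"]) == pytest.approx(500.0)
        assert to_tablet_content(12.8, DEFAULT_CHAINS["AA"]) == pytest.approx(200.0)
        assert to_tablet_content(0.0, DEFAULT_CHAINS["ASA"]) == 0.0

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            DilutionChain((("bad", -2.0),))
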