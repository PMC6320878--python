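"""Signal layer: baseline, detection, integration, R_F, resolution, purity."""

import numpy as np
import pytest

from tlcval import (
    Densitogram,
    Peak,
    detect_peaks,
    estimate_baseline,
    integrate_peak,
    make_densitogram,
    make_spectrum,
    resolution,
    retention_factor,
    spectral_scan,
)
from tlcval.simulate import Analyte, SimulationConfig


def gaussian_trace(centers, sigma=1.5, heights=None, step=0.1, span=75.0):
    x = np.arange(0.0, span + step / 2, step)
    y = np.zeros_like(x)
    heights = heights or [1.0] * len(centers)
    for c, h in zip(centers, heights):
        y += h * np.exp(-((x - c) ** 2) / (2 * sigma**2))
    return Densitogram(x, y)


class TestBaseline:
    def test_constant_signal_is_its_own_baseline(self):
        d = Densitogram(np.arange(0, 75.1, 0.1), np.full(751, 3.7))
        assert estimate_baseline(d) == pytest.approx(np.full(751, 3.7))

    def test_linear_drift_recovered(self):
        x = np.arange(0, 75.1, 0.1)
        drift = 2.0 + 0.5 * x
        base = estimate_baseline(Densitogram(x, drift))
        assert np.max(np.abs(base - drift)) <= 0.01 * np.max(drift)

    def test_baseline_under_band_stays_small(self):
        d = gaussian_trace([37.5], heights=[100.0])
        base = estimate_baseline(d)
        assert np.max(base) < 5.0  # < 5% of the 100 AU band height

    def test_oversized_window_rejected(self):
        d = gaussian_trace([37.5])
        with pytest.raises(ValueError, match="window"):
            estimate_baseline(d, window=1000.0)


class TestDetectPeaks:
    def test_three_band_scan_yields_method_rf_values(self, study_cfg):
        d = make_densitogram(study_cfg, {"AA": 8.0, "SA": 8.0, "ASA": 8.0}, seed=11)
        peaks = detect_peaks(d)
        assert len(peaks) == 3
        assert [p.rf for p in peaks] == pytest.approx([0.18, 0.56, 0.80], abs=0.01)

    def test_flat_zero_signal_gives_no_peaks(self):
        d = Densitogram(np.arange(0, 75.1, 0.1), np.zeros(751))
        assert detect_peaks(d) == []

    def test_apexes_within_one_sampling_step_of_truth(self):
        d = gaussian_trace([20.0, 50.0], heights=[10.0, 5.0])
        peaks = detect_peaks(d)
        assert len(peaks) == 2
        assert abs(peaks[0].apex - 20.0) <= d.step
        assert abs(peaks[1].apex - 50.0) <= d.step

    def test_every_detected_rf_is_in_unit_interval(self, study_cfg):
        d = make_densitogram(study_cfg, {"AA": 2.0, "SA": 1.0, "ASA": 2.0}, seed=3)
        assert all(0.0 <= p.rf <= 1.0 for p in detect_peaks(d))

    def test_peak_count_matches_bands_when_well_separated(self):
        # centers ≥ 6σ apart at high SNR → one peak per injected band
        for centers in ([15.0, 30.0, 45.0, 60.0], [10.0, 40.0], [37.5]):
            d = gaussian_trace(centers, sigma=1.5, heights=[50.0] * len(centers))
            assert len(detect_peaks(d)) == len(centers)

    def test_too_few_samples_rejected(self):
        d = Densitogram(np.array([0.0, 1.0]), np.array([0.0, 0.0]))
        with pytest.raises(ValueError, match="3 samples"):
            detect_peaks(d)


class TestIntegratePeak:
    def test_unit_gaussian_area_is_sqrt_two_pi(self):
        x = np.arange(0.0, 20.001, 0.01)
        y = np.exp(-((x - 10.0) ** 2) / 2.0)  # sigma = 1 mm, unit height
        d = Densitogram(x, y)
        p = Peak(start=4.0, apex=10.0, end=16.0, rf=0.5, height=1.0)
        assert integrate_peak(d, p) == pytest.approx(np.sqrt(2 * np.pi), rel=1e-3)

    def test_zero_signal_integrates_to_zero(self):
        d = Densitogram(np.arange(0, 75.1, 0.1), np.zeros(751))
        p = Peak(start=10.0, apex=20.0, end=30.0, rf=0.27, height=0.0)
        assert integrate_peak(d, p) == 0.0

    def test_doubling_amount_doubles_area_with_zero_intercept(self):
        cfg = SimulationConfig(
            analytes=(Analyte("X", rf_center=0.5, response_slope=1000.0),),
            noise_sd=0.0,
        )
        areas = []
        for amount in (2.0, 4.0):
            d = make_densitogram(cfg, {"X": amount})
            (p,) = detect_peaks(d)
            areas.append(p.area)
        assert areas[1] / areas[0] == pytest.approx(2.0, rel=5e-3)

    def test_area_additive_over_partition(self):
        d = gaussian_trace([37.5], heights=[20.0])
        whole = Peak(start=30.0, apex=37.5, end=45.0, rf=0.5, height=20.0)
        left = Peak(start=30.0, apex=33.0, end=37.5, rf=0.44, height=1.0)
        right = Peak(start=37.5, apex=40.0, end=45.0, rf=0.53, height=1.0)
        total = integrate_peak(d, whole)
        parts = integrate_peak(d, left) + integrate_peak(d, right)
        assert parts == pytest.approx(total, rel=1e-9)

    def test_out_of_range_bounds_rejected(self):
        d = gaussian_trace([37.5])
        with pytest.raises(ValueError, match="scan range"):
            integrate_peak(d, Peak(start=-5.0, apex=1.0, end=5.0, rf=0.01, height=1.0))


class TestRetentionFactor:
    @pytest.mark.parametrize(
        "apex,front,expected",
        [(13.5, 75.0, 0.18), (60.0, 75.0, 0.80), (0.0, 75.0, 0.0)],
    )
    def test_known_values(self, apex, front, expected):
        assert retention_factor(apex, front) == pytest.approx(expected)

    def test_apex_beyond_front_rejected(self):
        with pytest.raises(ValueError):
            retention_factor(80.0, 75.0)


class TestResolution:
    def test_identical_apexes_give_zero(self):
        p = Peak(start=10.0, apex=12.0, end=14.0, rf=0.16, height=1.0)
        q = Peak(start=10.0, apex=12.0, end=15.0, rf=0.16, height=1.0)
        assert resolution(p, q) == pytest.approx(2 * 0.0 / 9.0)

    def test_gaussians_4_sigma_apart_with_2_sigma_bounds(self):
        # widths = 4σ each; apex separation 4σ → R_S = 2·4σ/8σ = 1
        s = 1.5
        p = Peak(start=20 - 2 * s, apex=20.0, end=20 + 2 * s, rf=0.27, height=1.0)
        q = Peak(start=26 - 2 * s, apex=26.0, end=26 + 2 * s, rf=0.35, height=1.0)
        assert resolution(p, q) == pytest.approx(1.0)

    def test_scale_invariance(self):
        p = Peak(start=10.0, apex=12.0, end=14.0, rf=0.16, height=1.0)
        q = Peak(start=18.0, apex=20.0, end=23.0, rf=0.27, height=1.0)
        k = 3.0
        pk = Peak(start=10.0 * k, apex=12.0 * k, end=14.0 * k, rf=0.48, height=1.0)
        qk = Peak(start=18.0 * k, apex=20.0 * k, end=23.0 * k, rf=0.8, height=1.0)
        assert resolution(pk, qk) == pytest.approx(resolution(p, q))


class TestSpectralScan:
    def test_identical_spectra_fully_correlated(self):
        s = make_spectrum(268.0)
        purity = spectral_scan(s, s, s)
        assert purity.r_sm == pytest.approx(1.0)
        assert purity.r_me == pytest.approx(1.0)

    def test_lambda_max_read_from_apex_spectrum(self):
        purity = spectral_scan(
            make_spectrum(268.0), make_spectrum(268.0), make_spectrum(268.0)
        )
        assert purity.lambda_max == 268.0

    def test_small_noise_keeps_purity_above_0999(self):
        m = make_spectrum(268.0, amplitude=1.0)
        s = make_spectrum(268.0, amplitude=1.0, noise_sd=0.01, seed=1)  # SNR 100
        purity = spectral_scan(s, m, s)
        assert purity.r_sm > 0.999

    def test_constant_spectrum_flagged_undefined(self):
        flat = make_spectrum(268.0, amplitude=0.0)
        purity = spectral_scan(flat, make_spectrum(268.0), flat)
        assert purity.undefined
        assert np.isnan(purity.r_sm)
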