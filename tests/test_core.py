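"""Unit tests for the DCCC / MDC3 / dMDC3 estimators and baselines."""

import numpy as np
import pytest

import mdc3.core as core
from mdc3 import (
    DetrendConfig,
    FrequencyGrid,
    TimeSeries,
    dccc_at_scale,
    dmdc3,
    global_lagged_covariance,
    pearson_r,
    spectral_weights,
)
from mdc3.core import partition_windows, polynomial_detrend, windowed_lagged_covariance
from mdc3.exceptions import (
    DegenerateSignalError,
    DegenerateWindowError,
    InvalidInputError,
    InvalidParameterError,
    InvalidScaleError,
    NoValidScalesError,
)

from .conftest import coupled_pair
from . import oracles


class TestTypes:
    def test_timeseries_validation(self):
        with pytest.raises(InvalidInputError):
            TimeSeries([1.0], 100.0)
        with pytest.raises(InvalidInputError):
            TimeSeries([1.0, np.nan], 100.0)
        with pytest.raises(InvalidParameterError):
            TimeSeries([1.0, 2.0], 0.0)

    def test_grid_frequencies_and_scales(self):
        g = FrequencyGrid(0.5, 31.0, 0.5, 250.0)
        assert g.frequencies.size == 62
        assert g.frequencies[0] == 0.5 and g.frequencies[-1] == pytest.approx(31.0)
        assert g.scales[0] == 500 and g.scales[-1] == 8

    def test_grid_rejects_too_high_band(self):
        # 40 Hz at 250 Hz sampling gives 6-sample windows, below the minimum
        with pytest.raises(InvalidParameterError):
            FrequencyGrid(0.5, 40.0, 0.5, 250.0)
        with pytest.raises(InvalidParameterError):
            FrequencyGrid(0.5, 130.0, 0.5, 250.0)  # above Nyquist

    def test_detrend_config_validation(self):
        with pytest.raises(InvalidParameterError):
            DetrendConfig(degree=-1)


class TestPartitionWindows:
    @pytest.mark.parametrize(
        "n, s, expected_windows",
        [(4000, 500, 8), (10, 10, 1), (103, 10, 10)],
    )
    def test_window_count(self, n, s, expected_windows):
        windows = partition_windows(np.arange(n, dtype=float), s)
        assert windows.shape == (expected_windows, s)

    def test_remainder_is_discarded_from_the_tail(self):
        windows = partition_windows(np.arange(103, dtype=float), 10)
        assert windows[0, 0] == 0 and windows[-1, -1] == 99

    def test_invalid_scales(self):
        with pytest.raises(InvalidScaleError):
            partition_windows(np.arange(10.0), 11)
        with pytest.raises(InvalidScaleError):
            partition_windows(np.arange(10.0), 0)


class TestPolynomialDetrend:
    def test_exact_polynomial_gives_zero_residuals(self):
        t = np.arange(32, dtype=float)
        seg = 3.0 - 0.5 * t + 0.02 * t**2
        assert np.max(np.abs(polynomial_detrend(seg, 2))) < 1e-10

    def test_constant_segment_degree_zero(self):
        assert np.max(np.abs(polynomial_detrend(np.full(16, 7.0), 0))) < 1e-12

    def test_matches_normal_equations_oracle(self):
        seg = np.random.default_rng(42).standard_normal(16)
        expected = oracles.brute_polyfit_residuals(seg, 2)
        np.testing.assert_allclose(polynomial_detrend(seg, 2), expected, atol=1e-10)

    def test_residuals_sum_to_zero(self):
        seg = np.random.default_rng(1).standard_normal(64)
        for degree in (0, 1, 2, 3):
            assert abs(polynomial_detrend(seg, degree).sum()) < 1e-9

    def test_too_short_segment(self):
        with pytest.raises(DegenerateWindowError):
            polynomial_detrend(np.arange(3.0), 2)


class TestDCCCAtScale:
    def test_self_coupling_is_one(self, rng):
        x = rng.standard_normal(256)
        for s in (8, 16, 64, 256):
            assert dccc_at_scale(x, x, s) == pytest.approx(1.0, abs=1e-12)

    def test_sign_antisymmetry(self, rng):
        x = rng.standard_normal(256)
        assert dccc_at_scale(x, -x, 16) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_brute_force(self):
        x, y = coupled_pair(7, n=256, rho=0.6)
        expected = oracles.brute_dccc(x, y, 16, 2)
        assert dccc_at_scale(x, y, 16) == pytest.approx(expected, abs=1e-12)

    def test_bounded_on_random_pairs(self):
        for seed in range(10):
            x, y = coupled_pair(seed, n=200, rho=-0.4)
            for s in (8, 25, 100):
                assert -1.0 <= dccc_at_scale(x, y, s) <= 1.0

    def test_degenerate_signal(self):
        z = np.zeros(64)
        with pytest.raises(DegenerateSignalError):
            dccc_at_scale(z, z, 16)


class TestSpectralWeights:
    def test_single_frequency_weight_is_one(self, rng):
        x, y = rng.standard_normal((2, 1000))
        g = FrequencyGrid(2.0, 2.0, 1.0, 250.0)
        np.testing.assert_allclose(spectral_weights(x, y, g), [1.0])

    def test_weights_sum_to_one(self, rng, eeg_grid):
        x, y = rng.standard_normal((2, 1000))
        w = spectral_weights(x, y, eeg_grid)
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_sinusoid_dominates_its_own_frequency(self):
        t = np.arange(4000) / 1000.0
        x = np.sin(2 * np.pi * 2.0 * t)
        y = np.sin(2 * np.pi * 2.0 * t + 0.3)
        g = FrequencyGrid(0.5, 31.0, 0.5, 1000.0)
        w = spectral_weights(x, y, g)
        freqs = g.frequencies
        assert freqs[np.argmax(w)] == pytest.approx(2.0)

    def test_welch_option_also_normalizes(self, rng, eeg_grid):
        x, y = rng.standard_normal((2, 1000))
        w = spectral_weights(x, y, eeg_grid, DetrendConfig(welch_nperseg=256))
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_no_valid_scales(self, rng):
        x, y = rng.standard_normal((2, 7))  # shorter than the smallest scale
        g = FrequencyGrid(0.5, 31.0, 0.5, 250.0)
        with pytest.raises(NoValidScalesError):
            spectral_weights(x, y, g)


class TestMDC3:
    def test_self_coupling(self, rng, eeg_grid):
        x = rng.standard_normal(1000)
        assert core.mdc3(x, x, eeg_grid).value >= 1 - 1e-6

    def test_symmetry_exact(self, eeg_grid):
        x, y = coupled_pair(3, n=1000, rho=0.5)
        assert core.mdc3(x, y, eeg_grid).value == core.mdc3(y, x, eeg_grid).value

    def test_sign_antisymmetry(self, eeg_grid):
        x, y = coupled_pair(4, n=1000, rho=0.5)
        assert core.mdc3(x, -y, eeg_grid).value == pytest.approx(
            -core.mdc3(x, y, eeg_grid).value, abs=1e-12
        )

    def test_constant_profile_identity(self, monkeypatch, eeg_grid):
        # if every scale's DCCC equals c, the weighted Fisher average is c
        c = 0.37
        monkeypatch.setattr(core, "dccc_at_scale", lambda *a, **k: c)
        x, y = coupled_pair(5, n=1000, rho=0.5)
        assert core.mdc3(x, y, eeg_grid).value == pytest.approx(c, abs=1e-12)

    def test_matches_pseudocode_oracle_on_arfima_pair(self):
        from mdc3 import ARFIMAConfig, simulate_pair

        cfg = ARFIMAConfig(d=0.3, rho=0.5, length=1000, seed=99, regime="eeg_meg")
        a, b = simulate_pair(cfg)
        got = core.mdc3(a, b, cfg.frequency_grid()).value
        expected = oracles.brute_mdc3(a.values, b.values, 0.5, 31.0, 0.5, 250.0, 2)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_integrate_flag_changes_the_estimate(self, eeg_grid):
        x, y = coupled_pair(6, n=1000, rho=0.5)
        plain = core.mdc3(x, y, eeg_grid).value
        summed = core.mdc3(x, y, eeg_grid, DetrendConfig(integrate=True)).value
        assert plain != summed
        assert -1 < summed < 1

    def test_dropped_frequencies_are_reported(self, rng):
        g = FrequencyGrid(0.5, 31.0, 0.5, 250.0)
        x, y = rng.standard_normal((2, 300))  # scales 301..500 invalid
        res = core.mdc3(x, y, g)
        assert res.n_frequencies_used + len(res.dropped_frequencies) == 62
        assert len(res.dropped_frequencies) > 0


class TestWindowedLaggedCovariance:
    def test_pure_delay_peaks_at_minus_three(self):
        g = np.random.default_rng(8)
        x = g.standard_normal(32)
        y = np.concatenate([np.zeros(3), x[:-3]])
        lead = windowed_lagged_covariance(x, y, "leading")
        assert lead > 0
        assert lead == pytest.approx(
            oracles.brute_lagged_cov(x, y, "leading"), abs=1e-12
        )

    def test_all_zero_windows(self):
        z = np.zeros(16)
        assert windowed_lagged_covariance(z, z, "leading") == 0.0
        assert windowed_lagged_covariance(z, z, "lagging") == 0.0

    def test_matches_exhaustive_scan(self):
        g = np.random.default_rng(21)
        x, y = g.standard_normal((2, 32))
        for direction in ("leading", "lagging"):
            assert windowed_lagged_covariance(x, y, direction) == pytest.approx(
                oracles.brute_lagged_cov(x, y, direction), abs=1e-12
            )

    def test_window_too_short(self):
        with pytest.raises(InvalidScaleError):
            windowed_lagged_covariance([1.0], [1.0], "leading")

    def test_bad_direction(self):
        with pytest.raises(InvalidParameterError):
            windowed_lagged_covariance(np.zeros(8), np.zeros(8), "sideways")


class TestDMDC3:
    def test_delayed_copy_leads(self, eeg_grid):
        g = np.random.default_rng(31)
        x = g.standard_normal(2000)
        y = np.concatenate([np.zeros(2), x[:-2]])
        res = dmdc3(x, y, eeg_grid)
        assert res.leading > res.lagging

    def test_self_symmetry(self, eeg_grid):
        x = np.random.default_rng(32).standard_normal(1000)
        res = dmdc3(x, x, eeg_grid)
        assert res.leading == pytest.approx(res.lagging, abs=1e-12)

    def test_leading_lagging_duality(self, eeg_grid):
        x, y = coupled_pair(33, n=1000, rho=0.4)
        fwd = dmdc3(x, y, eeg_grid)
        rev = dmdc3(y, x, eeg_grid)
        assert fwd.leading == pytest.approx(rev.lagging, abs=1e-12)
        assert fwd.lagging == pytest.approx(rev.leading, abs=1e-12)

    def test_matches_brute_pipeline(self):
        x, y = coupled_pair(34, n=400, rho=0.5)
        grid = FrequencyGrid(2.0, 30.0, 4.0, 250.0)
        res = dmdc3(x, y, grid)
        lead, lag = oracles.brute_dmdc3(x, y, 2.0, 30.0, 4.0, 250.0, 2)
        assert res.leading == pytest.approx(lead, abs=1e-10)
        assert res.lagging == pytest.approx(lag, abs=1e-10)


class TestBaselines:
    def test_pearson_identities(self, rng):
        x = rng.standard_normal(100)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_pearson_hand_computed(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.0, 1.0, 2.0, 0.0])
        # centered cross-product 0.5, variances 5 and 2.75
        assert pearson_r(x, y) == pytest.approx(0.5 / np.sqrt(5 * 2.75), abs=1e-14)

    def test_pearson_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            pearson_r(np.full(10, 2.0), np.arange(10.0))

    def test_lg_pure_delay(self):
        g = np.random.default_rng(51)
        x = g.standard_normal(300)
        y = np.concatenate([np.zeros(4), x[:-4]])
        res = global_lagged_covariance(x, y)
        assert abs(res.leading) >= abs(res.lagging)

    def test_lg_all_zero_signals(self):
        z = np.zeros(64)
        res = global_lagged_covariance(z, z)
        assert res.leading == 0.0 and res.lagging == 0.0

    def test_lg_matches_exhaustive_scan(self):
        x, y = coupled_pair(52, n=128, rho=0.3)
        xd = oracles.brute_polyfit_residuals(x, 2)
        yd = oracles.brute_polyfit_residuals(y, 2)
        res = global_lagged_covariance(x, y)
        assert res.leading == pytest.approx(
            oracles.brute_lagged_cov(xd, yd, "leading"), abs=1e-12
        )
        assert res.lagging == pytest.approx(
            oracles.brute_lagged_cov(xd, yd, "lagging"), abs=1e-12
        )

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            pearson_r(np.zeros(5), np.zeros(6))
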