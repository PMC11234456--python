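"""Sensor-response estimation and the noise / lamp-variation fits.

The sweep-fixture generator is the oracle: datasets are forward-generated
from a known response, and the estimator must recover it.
"""

import numpy as np
import pytest

from msiox import calibration as cal
from msiox import synth
from msiox.camera import (N_BANDS, SensorResponse, default_noise_model,
                          default_optics, default_sensor_response)
from msiox.spectra import GRID_NM, Spectrum


def gaussian_response(peaks, width=6.0, n_bands=N_BANDS):
    r = np.zeros((n_bands, GRID_NM.size))
    for i, p in enumerate(peaks[:n_bands]):
        r[i] = np.exp(-0.5 * ((GRID_NM - p) / width) ** 2)
    return SensorResponse(r)


def max_normalized_mae(estimate, truth):
    a = estimate / estimate.max()
    b = truth / truth.max()
    return np.abs(a - b).mean()


@pytest.fixture(scope="module")
def optics():
    return default_optics()


@pytest.fixture(scope="module")
def true_response():
    return default_sensor_response()


@pytest.fixture(scope="module")
def clean_dataset(true_response, optics):
    return synth.generate_lctf_fixture(true_response, optics, noise_level=0.0)


class TestPenaltyVector:
    def test_constant_response_has_zero_smoothness_terms(self, clean_dataset):
        r = np.full(301, 0.5)
        chi = cal.penalty_vector(r, clean_dataset, band=0)
        m = clean_dataset.settings.size
        np.testing.assert_array_equal(chi[m:], 0.0)

    def test_zero_response_guarded(self, clean_dataset):
        chi = cal.penalty_vector(np.zeros(301), clean_dataset, band=0)
        m = clean_dataset.settings.size
        np.testing.assert_array_equal(chi[m:], 0.0)
        assert np.all(np.isfinite(chi))

    def test_intensity_residuals_vanish_at_scaled_truth(self, true_response,
                                                        clean_dataset):
        # the grand-mean normalization rescales the measured intensities;
        # the correspondingly scaled true response zeroes residual part (i)
        scale = 1.0 / clean_dataset.grand_mean * clean_dataset.meta.get("gain", 1000.0)
        r = true_response.r[2] * scale
        chi = cal.penalty_vector(r, clean_dataset, band=2)
        m = clean_dataset.settings.size
        assert np.abs(chi[:m]).max() < 1e-10

    def test_jacobian_matches_finite_differences(self, clean_dataset):
        rng = np.random.default_rng(0)
        r = rng.random(301) + 0.1
        jac = cal._penalty_jacobian(r, clean_dataset)
        f0 = cal.penalty_vector(r, clean_dataset, band=1)
        eps = 1e-7
        for k in (0, 150, 300):
            r2 = r.copy()
            r2[k] += eps
            fd = (cal.penalty_vector(r2, clean_dataset, band=1) - f0) / eps
            np.testing.assert_allclose(jac[:, k], fd, atol=1e-5)


class TestEstimateResponse:
    def test_noise_free_recovery_under_one_percent(self, true_response,
                                                   clean_dataset):
        result = cal.estimate_response(clean_dataset)
        for n in range(N_BANDS):
            err = max_normalized_mae(result.r_star.r[n], true_response.r[n])
            assert err < 0.01, f"band {n}: max-normalized MAE {err:.4f}"

    def test_noisy_recovery_degrades_gracefully(self, true_response, optics):
        noisy = synth.generate_lctf_fixture(true_response, optics,
                                            noise_level=0.01, seed=5)
        result = cal.estimate_response(noisy)
        for n in range(N_BANDS):
            err = max_normalized_mae(result.r_star.r[n], true_response.r[n])
            assert err < 0.03, f"band {n}: max-normalized MAE {err:.4f}"

    def test_lamp_intensity_invariance(self, true_response, optics,
                                       clean_dataset):
        brighter = cal.CalibrationDataset(I=2.0 * clean_dataset.I,
                                          R=2.0 * clean_dataset.R,
                                          settings=clean_dataset.settings)
        a = cal.estimate_response(clean_dataset)
        b = cal.estimate_response(brighter)
        for n in (0, 7, 15):
            np.testing.assert_allclose(a.r_star.r[n] / a.r_star.r[n].max(),
                                       b.r_star.r[n] / b.r_star.r[n].max(),
                                       atol=1e-6)

    def test_dual_peak_positions_recovered(self, optics):
        # dual-peak characteristic: prominent peak and a displaced secondary
        r = np.exp(-0.5 * ((GRID_NM - 560.0) / 5.0) ** 2) \
            + 0.5 * np.exp(-0.5 * ((GRID_NM - 530.0) / 5.0) ** 2)
        truth = SensorResponse(np.tile(r, (N_BANDS, 1)))
        ds = synth.generate_lctf_fixture(truth, optics, noise_level=0.01,
                                         seed=11)
        result = cal.estimate_response(ds)
        est = result.r_star.r[0]
        assert abs(GRID_NM[np.argmax(est)] - 560.0) <= 2.0
        window = (GRID_NM > 510) & (GRID_NM < 545)
        assert abs(GRID_NM[window][np.argmax(est[window])] - 530.0) <= 2.0

    def test_smoothness_penalty_reduces_high_frequency_energy(self,
                                                              true_response,
                                                              optics):
        noisy = synth.generate_lctf_fixture(true_response, optics,
                                            noise_level=0.02, seed=7)
        # the unpenalized deconvolution is ill-posed and converges slowly;
        # a capped iteration budget is enough to expose the contrast
        penalized = cal.estimate_response(noisy, max_nfev=80)
        unpenalized = cal.estimate_response(noisy, smoothness_weight=0.0,
                                            max_nfev=80)

        def hf_energy(r):
            return np.sum(np.diff(r / max(r.max(), 1e-12)) ** 2)

        total_pen = sum(hf_energy(penalized.r_star.r[n]) for n in range(4))
        total_unpen = sum(hf_energy(unpenalized.r_star.r[n]) for n in range(4))
        assert total_pen < total_unpen


class TestFitNoiseModel:
    def test_recovery_within_ten_percent(self):
        # exposure-balanced white stack generated directly from the noise
        # law (the variance-of-variance at a few hundred repeats is ~10%
        # per level, so a well-conditioned intercept needs more repeats)
        from msiox.camera import NoiseModel, sample_noise
        truth = NoiseModel(a=np.full(N_BANDS, 3e-4),
                           b=np.full(N_BANDS, 1.0 / 1e-3), I_max=1.0)
        rng = np.random.default_rng(3)
        levels = [0.05, 0.15, 0.3, 0.5, 0.7, 0.9]
        n_repeats = 4000
        stack = np.empty((len(levels), n_repeats, N_BANDS))
        for i, level in enumerate(levels):
            base = np.full(N_BANDS, level)
            for t in range(n_repeats):
                stack[i, t] = base * (1.0 + sample_noise(truth, base, rng))
        fit = cal.fit_noise_model(stack)
        np.testing.assert_allclose(fit.a, truth.a, rtol=0.10)
        np.testing.assert_allclose(1.0 / fit.b, 1.0 / truth.b, rtol=0.10)

    def test_forward_stack_recovery_of_brightness_slope(self, models_small):
        # through the full white forward pass: bright bands recover the
        # intensity slope; dim bands are noisier, so compare in the median
        truth = default_noise_model()
        stack = synth.generate_white_stack(
            models_small, levels=[0.15, 0.3, 0.5, 0.7, 0.9],
            n_repeats=2000, seed=3)
        fit = cal.fit_noise_model(stack)
        med_b = np.median(np.abs(1 / fit.b - 1 / truth.b) / (1 / truth.b))
        assert med_b < 0.10

    def test_zero_noise_stack(self):
        stack = np.tile(np.linspace(0.2, 0.8, N_BANDS), (3, 40, 1))
        stack *= np.array([0.5, 1.0, 1.5])[:, None, None]
        fit = cal.fit_noise_model(stack)
        np.testing.assert_allclose(fit.a, 0.0, atol=1e-20)
        np.testing.assert_allclose(1.0 / fit.b, 0.0, atol=1e-20)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            cal.fit_noise_model(np.ones((1, 50, N_BANDS)))

    def test_variance_extrapolates_to_intercept(self):
        noise = cal.NoiseModel(a=np.full(N_BANDS, 3e-4),
                               b=np.full(N_BANDS, 1e4))
        np.testing.assert_allclose(noise.variance(0.0), 3e-4)


class TestFitLampVariation:
    def test_stable_lamp_gives_zero_drift(self):
        L = Spectrum(np.linspace(1.0, 2.0, 301))
        Lres, dt, dth = cal.fit_lamp_variation(
            [(0, L.copy()), (60, L.copy())], {0: L.copy(), 22: L.copy()})
        np.testing.assert_allclose(dt.values, 0.0)
        np.testing.assert_allclose(dth.values, 0.0)

    def test_angle_ratio_definition(self):
        L0 = Spectrum(np.linspace(1.0, 2.0, 301))
        L22 = Spectrum(1.02 * L0.values)
        _, _, dth = cal.fit_lamp_variation([(0, L0), (60, L0)],
                                           {0: L0, 22: L22})
        np.testing.assert_allclose(dth.values, 0.02, rtol=1e-12)

    def test_intermediate_scaling_factor_recovered(self):
        rng = np.random.default_rng(0)
        L = Spectrum(1.0 + rng.random(301))
        dt_max = Spectrum(0.05 * np.sin(np.linspace(0, 3, 301)))
        observed = Spectrum(L.values * (1 + 0.4 * dt_max.values))
        q = cal.fit_lamp_q(observed, L, dt_max)
        assert q == pytest.approx(0.4, abs=1e-10)

    def test_missing_endpoints_rejected(self):
        L = Spectrum(np.ones(301))
        with pytest.raises(ValueError):
            cal.fit_lamp_variation([(0, L)], {0: L, 22: L})
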