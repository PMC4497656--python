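"""Closed-form checks of the derived statistics."""

import numpy as np
import pytest

from diffhomeo import metrics


class TestResponseR2:
    def test_exact_linear_response(self):
        x = np.linspace(-5, 5, 50)
        assert metrics.response_r2(x, 2 * x) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=5000)
        y = rng.normal(size=5000)
        assert metrics.response_r2(x, y) < 0.01

    def test_rectified_response_r2(self):
        # y = max(x, 0) on symmetric Gaussian x: R^2 = corr^2 =
        # (1/2)^2 / ((1/2 - 1/(2*pi))) = 0.25/(0.3408) ~ 0.7337
        rng = np.random.default_rng(1)
        x = rng.normal(size=200000)
        y = np.maximum(x, 0.0)
        expected = 0.25 / (0.5 - 1.0 / (2 * np.pi))
        assert metrics.response_r2(x, y) == pytest.approx(expected, abs=0.01)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=1000)
        y = x + 0.5 * rng.normal(size=1000)
        r2 = metrics.response_r2(x, y)
        assert metrics.response_r2(3 * x - 7, -2 * y + 1) == pytest.approx(r2, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            metrics.response_r2(np.ones(10), np.arange(10.0))


class TestPersistence:
    def _series(self, mu1, mu2, sd, n=40, seed=0):
        rng = np.random.default_rng(seed)
        t = len(mu1)
        g1 = np.asarray(mu1)[:, None] + sd * rng.normal(size=(t, n))
        g2 = np.asarray(mu2)[:, None] + sd * rng.normal(size=(t, n))
        return g1, g2

    def test_identical_groups_cross_immediately(self):
        mu = np.full(200, 5.0)
        g1, g2 = self._series(mu, mu, 1.0)
        assert metrics.persistence_time(g1, g2, smooth_s=1.0) < 20.0

    def test_constant_separation_censored(self):
        t = 200
        g1, g2 = self._series(np.full(t, 8.0), np.full(t, 4.0), 1.0)
        assert metrics.persistence_time(g1, g2, smooth_s=1.0) == np.inf

    def test_linear_decay_crossing_recovered(self):
        # mu1 - mu2 crosses zero at t = 100 s; noiseless groups
        t = np.arange(300.0)
        mu1 = 5.0 + 2.0 * (1 - t / 100.0)
        mu2 = np.full(300, 5.0)
        g1 = np.tile(mu1[:, None], (1, 10)) + np.linspace(0, 0.1, 10)
        g2 = np.tile(mu2[:, None], (1, 10)) + np.linspace(0, 0.1, 10)
        est = metrics.persistence_time(g1, g2, smooth_s=1.0)
        assert est == pytest.approx(100.0, abs=1.5)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            metrics.persistence_time(np.zeros((10, 0)), np.zeros((10, 3)))


class TestTrackingRMS:
    def test_perfect_tracking_zero(self):
        x = np.sin(np.linspace(0, 10, 100))
        assert metrics.tracking_rms(x, x.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_is_two(self):
        x = np.sin(np.linspace(0, 10, 100))
        assert metrics.tracking_rms(x, -x) == pytest.approx(2.0, rel=1e-12)

    def test_uncorrelated_is_sqrt_two(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100000)
        y = rng.normal(size=100000)
        assert metrics.tracking_rms(x, y) == pytest.approx(np.sqrt(2), abs=0.02)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            metrics.tracking_rms(np.zeros(5), np.zeros(6))


class TestDecoder:
    def test_single_active_neuron(self):
        rates = np.array([0.0, 3.0, 0.0])
        pref = np.array([10.0, 200.0, 300.0])
        assert metrics.population_vector_decode(rates, pref) == pytest.approx(200.0)

    def test_uniform_rates_zero_vector_rejected(self):
        pref = np.arange(0, 360, 45.0)
        with pytest.raises(ValueError):
            metrics.population_vector_decode(np.ones(8), pref)

    def test_noiseless_tuning_decodes_exactly(self):
        from diffhomeo.inputs import OrientationStimulus, orientation_rates
        pref = np.linspace(0, 360, 720, endpoint=False)
        stim = OrientationStimulus(preferred=pref, stimulus_angle=90.0)
        resp = orientation_rates(stim).rates - 20.0  # tuned component
        assert metrics.population_vector_decode(resp, pref) == pytest.approx(90.0, abs=1e-6)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(4)
        pref = rng.uniform(0, 360, 100)
        rates = rng.uniform(0.5, 2.0, 100)
        base = metrics.population_vector_decode(rates, pref)
        rotated = metrics.population_vector_decode(rates, (pref + 40.0) % 360)
        assert metrics.circular_error_deg(rotated, base + 40.0) == pytest.approx(0.0, abs=1e-9)

    def test_circular_error_range(self):
        err = metrics.circular_error_deg([350.0, 10.0, 181.0], [10.0, 350.0, 0.0])
        assert np.allclose(err, [-20.0, 20.0, -179.0])


class TestSpikeStatistics:
    def test_periodic_train_cv_zero(self):
        t = np.arange(0, 10, 0.1)
        st = metrics.spike_statistics(t, np.zeros(len(t), dtype=int), 1, 10.0)
        assert st.cv[0] == pytest.approx(0.0, abs=1e-12)

    def test_poisson_train_cv_near_one_flat_autocorr(self):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(0, 100, 2000))  # 20 Hz Poisson
        st = metrics.spike_statistics(t, np.zeros(len(t), dtype=int), 1, 100.0)
        assert st.cv[0] == pytest.approx(1.0, abs=0.1)
        # autocorrelogram flat at rate*rate*bin coincidences per second
        expected = 20.0 * 20.0 * 0.0025
        assert np.mean(st.autocorr[1:]) == pytest.approx(expected, rel=0.2)

    def test_neurons_with_single_spike_excluded_from_cv(self):
        t = np.array([1.0, 2.0, 3.0, 5.0])
        i = np.array([0, 0, 0, 1])
        st = metrics.spike_statistics(t, i, 2, 10.0)
        assert len(st.cv) == 1
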