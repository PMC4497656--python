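"""Input-generator distributions, clipping, and determinism."""

import numpy as np
import pytest

from diffhomeo import inputs


class TestStaticRates:
    def test_moments_match_requested_gaussian(self):
        d = inputs.draw_static_rates(20000, 10.0, 10.0, seed=1)
        # pre-clip draws are N(10, 10^2); 4 standard errors of the mean
        assert abs(d.raw_rates.mean() - 10.0) < 4 * 10.0 / np.sqrt(20000)
        assert abs(d.raw_rates.std() - 10.0) < 0.3
        assert np.all(d.rates >= 0)

    def test_zero_sd_is_constant(self):
        d = inputs.draw_static_rates(4, 5.0, 0.0, seed=0)
        assert np.allclose(d.rates, 5.0)

    def test_rectified_gaussian_mean_matches_closed_form(self):
        # for N(0, 1) clipped at 0 the mean is 1/sqrt(2*pi)
        d = inputs.draw_static_rates(100000, 0.0, 1.0, seed=3)
        assert abs(d.rates.mean() - 1.0 / np.sqrt(2 * np.pi)) < 0.01

    def test_seed_reproducibility(self):
        a = inputs.draw_static_rates(100, 10.0, 10.0, seed=9)
        b = inputs.draw_static_rates(100, 10.0, 10.0, seed=9)
        assert np.array_equal(a.rates, b.rates)

    @pytest.mark.parametrize("n", [0, -5])
    def test_nonpositive_n_rejected(self, n):
        with pytest.raises(ValueError):
            inputs.draw_static_rates(n, 10.0, 10.0)

    def test_columnar_serialization(self):
        d = inputs.draw_static_rates(50, 10.0, 10.0, seed=2)
        df = d.to_frame()
        assert list(df.columns) == ["neuron_id", "rate_hz", "raw_rate_hz", "group"]
        assert len(df) == 50
        assert np.array_equal(df["rate_hz"].to_numpy(), d.rates)


class TestGroups:
    def test_partition_sizes_and_disjointness(self):
        labels = inputs.assign_groups(2500, [250, 250], seed=1)
        assert (labels == 1).sum() == 250
        assert (labels == 2).sum() == 250
        assert (labels == 0).sum() == 2000

    def test_empty_group_list(self):
        labels = inputs.assign_groups(10, [], seed=1)
        assert np.all(labels == 0)

    def test_different_seeds_give_different_partitions(self):
        a = inputs.assign_groups(100, [50, 50], seed=1)
        b = inputs.assign_groups(100, [50, 50], seed=2)
        assert not np.array_equal(a, b)
        assert (a == 1).sum() == (b == 1).sum() == 50

    def test_oversubscription_rejected(self):
        with pytest.raises(ValueError):
            inputs.assign_groups(100, [60, 60])

    def test_eligibility_restriction(self):
        eligible = np.arange(50)
        labels = inputs.assign_groups(100, [20], seed=0, eligible=eligible)
        assert np.all(np.nonzero(labels)[0] < 50)


class TestTimeVaryingPattern:
    def test_sample_sd_matches(self):
        pat = inputs.time_varying_pattern(10, 1000.0, sd=25.0, seed=4)
        assert abs(pat.group_rates.std() - 25.0) < 1.0

    def test_zero_sd_all_zero(self):
        pat = inputs.time_varying_pattern(3, 10.0, sd=0.0, seed=4)
        assert np.all(pat.group_rates == 0)

    def test_steps_uncorrelated(self):
        pat = inputs.time_varying_pattern(1, 10000.0, sd=25.0, seed=5)
        x = pat.group_rates[:, 0]
        lag1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(lag1) < 0.05

    def test_pattern_drive_clips_and_offsets(self):
        base = np.array([10.0, 10.0, 10.0])
        labels = np.array([0, 1, 2])
        pat = inputs.TimeVaryingPattern(
            group_rates=np.array([[5.0, -30.0]]), dt_pattern=1.0)
        rates = inputs.pattern_drive(base, labels, pat)
        assert rates.shape == (1, 3)
        assert rates[0, 0] == 10.0        # background untouched
        assert rates[0, 1] == 15.0        # +5 offset
        assert rates[0, 2] == 0.0         # 10 - 30 clipped at 0


class TestOrientation:
    def test_peak_rate_at_preferred(self):
        stim = inputs.OrientationStimulus(
            preferred=np.array([90.0]), stimulus_angle=90.0)
        assert inputs.orientation_rates(stim).rates[0] == pytest.approx(22.5)

    def test_zero_amplitude_uniform(self):
        stim = inputs.OrientationStimulus(
            preferred=np.linspace(0, 360, 50), stimulus_angle=10.0, amplitude=0.0)
        assert np.allclose(inputs.orientation_rates(stim).rates, 20.0)

    def test_gaussian_falloff_at_one_width(self):
        stim = inputs.OrientationStimulus(
            preferred=np.array([120.0]), stimulus_angle=30.0, width=90.0)
        expected = 20.0 + 2.5 * np.exp(-0.5)
        assert inputs.orientation_rates(stim).rates[0] == pytest.approx(expected)

    def test_circular_distance_wraps(self):
        assert inputs.circular_distance_deg(350.0, 10.0) == pytest.approx(-20.0)
        assert inputs.circular_distance_deg(10.0, 350.0) == pytest.approx(20.0)


class TestPoissonArrivals:
    def test_counts_match_poisson_statistics(self):
        ev = inputs.poisson_arrivals([10.0], dt=1e-3, duration=100.0, seed=6)
        n = ev.sum()
        assert abs(n - 1000) < 2 * np.sqrt(1000)

    def test_zero_rate_no_events(self):
        ev = inputs.poisson_arrivals([0.0, 0.0], dt=1e-3, duration=10.0, seed=6)
        assert ev.sum() == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            inputs.poisson_arrivals([-1.0], dt=1e-3, duration=1.0)
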