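"""Ca2+/nNOS dynamics and the NO diffusion-decay field."""

import numpy as np
import pytest

from diffhomeo import chemistry
from diffhomeo.params import ChemParams


@pytest.fixture
def params():
    return ChemParams(ds=10.0)  # 100x100 test grid


class TestCalcium:
    def test_single_spike_decays_with_tau_ca(self, params):
        ca = np.zeros(1)
        ca = chemistry.update_calcium(ca, np.array([1]), 0.0, params)
        for _ in range(100):  # 100 x 0.1 ms = 10 ms = tau_Ca
            ca = chemistry.update_calcium(ca, np.array([0]), 0.1, params)
        assert ca[0] == pytest.approx(np.exp(-1), rel=1e-6)

    def test_no_spikes_stays_zero(self, params):
        ca = chemistry.update_calcium(np.zeros(3), np.zeros(3), 0.1, params)
        assert np.all(ca == 0)

    def test_periodic_spiking_reaches_linear_filter_mean(self, params):
        # steady mean of the linear filter is rate * tau_Ca * ca_spike
        rate_hz, dt = 50.0, 0.1
        period = int(1000.0 / rate_hz / dt)
        ca = np.zeros(1)
        trace = []
        for k in range(40000):
            spike = np.array([1 if k % period == 0 else 0])
            ca = chemistry.update_calcium(ca, spike, dt, params)
            trace.append(ca[0])
        mean = np.mean(trace[20000:])
        assert mean == pytest.approx(rate_hz * (params.tau_ca / 1000.0), rel=0.02)


class TestNnos:
    def test_hill_midpoint(self, params):
        assert chemistry.hill(1.0, params.hill_n, params.hill_k) == pytest.approx(0.5)

    def test_relaxation_time_constant(self, params):
        # step Ca: nNOS relaxes toward Hill(Ca) with tau_nNOS = 100 ms
        nnos = np.zeros(1)
        ca = np.ones(1)
        for _ in range(1000):  # 100 ms at dt = 0.1
            nnos = chemistry.update_nnos(nnos, ca, 0.1, params)
        assert nnos[0] == pytest.approx(0.5 * (1 - np.exp(-1)), rel=0.01)

    def test_decays_to_zero_without_calcium(self, params):
        nnos = np.full(2, 0.7)
        for _ in range(5000):
            nnos = chemistry.update_nnos(nnos, np.zeros(2), 0.1, params)
        assert np.all(nnos < 0.01)

    def test_activation_bounded_and_monotone(self, params):
        ca = np.array([0.1, 0.5, 1.0, 3.0, 10.0])
        h = chemistry.hill(ca, params.hill_n, params.hill_k)
        assert np.all(np.diff(h) > 0)
        assert h[-1] < 1.0


class TestDiffusion:
    def test_mass_conserved_without_decay(self):
        p = ChemParams(ds=10.0, lambda_decay=0.0)
        rng = np.random.default_rng(0)
        field = rng.random((p.n_side, p.n_side))
        total = field.sum()
        for _ in range(1000):
            field = chemistry.step_diffusion(field, p)
        assert field.sum() == pytest.approx(total, rel=1e-10)

    def test_uniform_field_decays_exponentially(self):
        p = ChemParams(ds=10.0, lambda_decay=0.1)
        field = np.full((p.n_side, p.n_side), 3.0)
        for _ in range(1000):  # 1 s
            field = chemistry.step_diffusion(field, p)
        # per-step first-order decay compounds to (1 - lambda*dt)^n
        expected = 3.0 * (1 - 1e-4) ** 1000
        assert np.allclose(field, expected, rtol=1e-12)
        assert field[0, 0] == pytest.approx(3.0 * np.exp(-0.1), rel=1e-3)

    def test_impulse_matches_heat_kernel(self):
        p = ChemParams(ds=10.0, lambda_decay=0.0)
        m = p.n_side
        field = np.zeros((m, m))
        field[m // 2, m // 2] = 1.0
        t_ms = 2000.0  # long enough that the lattice (kurtosis) correction ~ 1/t is < 1%
        for _ in range(int(t_ms / p.dt_diff)):
            field = chemistry.step_diffusion(field, p)
        D_ms = p.D / 1000.0
        x = (np.arange(m) - m // 2) * p.ds
        xx, yy = np.meshgrid(x, x, indexing="ij")
        kernel = (
            np.exp(-(xx**2 + yy**2) / (4 * D_ms * t_ms))
            / (4 * np.pi * D_ms * t_ms) * p.ds**2
        )
        assert np.max(np.abs(field - kernel)) / kernel.max() < 0.01

    def test_stability_bound_enforced(self):
        with pytest.raises(ValueError):
            ChemParams(ds=1.0)  # D*dt/ds^2 = 1 > 0.25

    def test_sample_no_reads_cells(self):
        field = np.arange(16.0).reshape(4, 4)
        cells = np.array([0, 5, 5, 15])
        vals = chemistry.sample_no(field, cells)
        assert np.array_equal(vals, [0.0, 5.0, 5.0, 15.0])


class TestNondiffusive:
    def test_fixed_point_is_source_over_decay(self, params):
        # constant nNOS = a: steady NO = a / lambda
        a, lam_ms = 0.3, params.lambda_decay / 1000.0
        no = np.zeros(1)
        for _ in range(200000):  # 200 s at 1 ms
            no = chemistry.update_no_nondiffusive(no, np.full(1, a), 1.0, params)
        assert no[0] == pytest.approx(a / lam_ms, rel=1e-3)

    def test_pure_decay(self, params):
        no = np.full(1, 5.0)
        for _ in range(10000):  # 10 s
            no = chemistry.update_no_nondiffusive(no, np.zeros(1), 1.0, params)
        assert no[0] == pytest.approx(5.0 * np.exp(-1.0), rel=1e-2)
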