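import numpy as np
import pytest
from scipy.linalg import expm, solve_lyapunov

from netdcm.connectivity import EffectiveConnectivity
from netdcm.forward import (
    CrossSpectralDensity,
    FrequencyGrid,
    connection_kernel,
    csd_to_cross_covariance,
    estimate_csd,
    fc_from_csd,
    functional_connectivity,
    hemodynamic_transfer,
    predicted_csd,
)
from netdcm.params import DEFAULT_HEMO, DEFAULT_NEURAL_FLUCT, FluctuationParams
from netdcm.regions import NETWORK_ORDER, RegionSet
from netdcm.synthetic import SubjectTimeSeries, hemodynamic_kernel, simulate_bold


def random_stable(n, seed, margin=0.3):
    rng = np.random.default_rng(seed)
    M = rng.normal(0, 0.2, (n, n))
    M -= np.eye(n) * (np.max(np.linalg.eigvals(M).real) + margin)
    rs = RegionSet(tuple(f"r{i}" for i in range(n)), ("X",) * n)
    return EffectiveConnectivity(M, rs)


def spectral_integral(csd):
    """Two-sided integral of a CSD over frequency (trapezoid + DC closure)."""
    f = csd.grid.frequencies
    G = np.real(csd.values)
    body = np.trapezoid(G, f, axis=0)
    return 2.0 * (body + G[0] * f[0])


class TestFrequencyGrid:
    def test_default_spans_fundamental_to_quarter_hz(self):
        g = FrequencyGrid.default(T=170, dt=2.0)
        assert g.frequencies[0] == pytest.approx(1 / 340)
        assert g.frequencies[-1] == pytest.approx(0.25)
        assert g.n_bins == 64

    def test_nonmonotone_rejected(self):
        with pytest.raises(ValueError):
            FrequencyGrid(np.array([0.1, 0.05]))


class TestHemodynamicTransfer:
    def test_dc_limit_equals_kernel_integral(self):
        grid = FrequencyGrid(np.array([1e-4, 0.01, 0.25]))
        K = hemodynamic_transfer(DEFAULT_HEMO, grid)
        integral = hemodynamic_kernel(DEFAULT_HEMO, 0.01, duration=64.0).sum() * 0.01
        assert abs(K[0]) == pytest.approx(integral, rel=0.05)

    def test_matches_fft_of_time_domain_kernel(self):
        # oracle: DFT of the sampled kernel on a fine grid
        dt, dur = 0.002, 64.0
        k = hemodynamic_kernel(DEFAULT_HEMO, dt, duration=dur)
        freqs = np.fft.rfftfreq(k.size, dt)
        K_fft = np.fft.rfft(k) * dt
        sel = (freqs > 0.005) & (freqs <= 0.25)
        grid = FrequencyGrid(freqs[sel])
        K = hemodynamic_transfer(DEFAULT_HEMO, grid)
        rel = np.abs(K - K_fft[sel]) / np.abs(K_fft[sel])
        assert rel.max() < 1e-4

    def test_low_pass(self):
        grid = FrequencyGrid(np.array([0.01, 0.25]))
        K = hemodynamic_transfer(DEFAULT_HEMO, grid)
        assert abs(K[1]) < abs(K[0])


class TestPredictedCsd:
    def test_scalar_lorentzian_closed_form(self):
        rs = RegionSet(("a",), ("X",))
        a = 0.4
        ec = EffectiveConnectivity(np.array([[-a]]), rs)
        grid = FrequencyGrid(np.linspace(0.01, 0.25, 64))
        csd = predicted_csd(ec, FluctuationParams(0.7, 0.0), None, grid)
        w = grid.omega
        assert np.allclose(csd.values[:, 0, 0].real, 0.7 / (a**2 + w**2), rtol=1e-12)
        assert np.allclose(csd.values[:, 0, 0].imag, 0.0)

    def test_diagonal_coupling_no_cross_terms(self):
        rs = RegionSet(("a", "b", "c"), ("X",) * 3)
        ec = EffectiveConnectivity(-0.5 * np.eye(3), rs)
        grid = FrequencyGrid(np.linspace(0.01, 0.25, 64))
        csd = predicted_csd(ec, DEFAULT_NEURAL_FLUCT, DEFAULT_HEMO, grid)
        off = ~np.eye(3, dtype=bool)
        assert np.abs(csd.values[:, off]).max() == 0

    @pytest.mark.parametrize("n,seed", [(3, 0), (5, 1), (10, 2)])
    def test_spectral_integral_matches_lyapunov(self, n, seed):
        # oracle: stationary covariance from the Lyapunov equation
        ec = random_stable(n, seed)
        alpha = 0.05
        grid = FrequencyGrid(np.linspace(1e-4, 40.0, 20000))
        csd = predicted_csd(ec, FluctuationParams(alpha, 0.0), None, grid)
        S_int = spectral_integral(csd)
        S_lyap = solve_lyapunov(ec.matrix, -alpha * np.eye(n))
        assert np.linalg.norm(S_int - S_lyap) / np.linalg.norm(S_lyap) < 0.01

    def test_slices_hermitian_psd(self):
        ec = random_stable(4, 3)
        grid = FrequencyGrid.default()
        csd = predicted_csd(ec, DEFAULT_NEURAL_FLUCT, DEFAULT_HEMO, grid)
        for G in csd.values:
            assert np.allclose(G, G.conj().T)
            assert np.linalg.eigvalsh(G).min() > -1e-8


class TestCrossCovariance:
    def test_ou_exponential_decay(self):
        # oracle: OU autocovariance C(tau) = C(0) exp(-a|tau|)
        rs = RegionSet(("a",), ("X",))
        a = 0.4
        ec = EffectiveConnectivity(np.array([[-a]]), rs)
        grid = FrequencyGrid(np.linspace(5e-4, 60.0, 60000))
        csd = predicted_csd(ec, FluctuationParams(1.0, 0.0), None, grid)
        cov = csd_to_cross_covariance(csd, [0.0, 1.0, 2.0])
        c = cov.values[:, 0, 0]
        assert c[1] / c[0] == pytest.approx(np.exp(-a), rel=0.01)
        assert c[2] / c[0] == pytest.approx(np.exp(-2 * a), rel=0.02)
        assert c[0] == pytest.approx(1.0 / (2 * a), rel=0.01)

    def test_time_reversal_identity(self):
        ec = random_stable(3, 5)
        grid = FrequencyGrid(np.linspace(1e-3, 10.0, 4096))
        csd = predicted_csd(ec, FluctuationParams(1.0, 0.0), None, grid)
        cov = csd_to_cross_covariance(csd, [-2.0, 0.0, 2.0])
        assert np.allclose(cov.at_lag(2.0), cov.at_lag(-2.0).T, atol=1e-12)

    def test_lag_beyond_resolution_rejected(self):
        ec = random_stable(2, 1)
        grid = FrequencyGrid(np.linspace(0.01, 0.25, 64))
        csd = predicted_csd(ec, FluctuationParams(1.0, 0.0), None, grid)
        with pytest.raises(ValueError, match="alias"):
            csd_to_cross_covariance(csd, [10000.0])

    def test_coarse_grid_rejected(self):
        ec = random_stable(2, 1)
        grid = FrequencyGrid(np.linspace(0.01, 0.25, 10))
        csd = predicted_csd(ec, FluctuationParams(1.0, 0.0), None, grid)
        with pytest.raises(ValueError, match="64"):
            csd_to_cross_covariance(csd, [0.0])


class TestFunctionalConnectivity:
    def test_decoupled_gives_identity(self):
        rs = RegionSet(("a", "b"), ("X", "X"))
        ec = EffectiveConnectivity(-0.5 * np.eye(2), rs)
        grid = FrequencyGrid(np.linspace(1e-3, 20.0, 8192))
        fc = fc_from_csd(predicted_csd(ec, FluctuationParams(1.0, 0.0), None, grid))
        assert np.allclose(fc.values, np.eye(2), atol=1e-10)

    def test_template_block_signs(self, regions15, template15):
        grid = FrequencyGrid.default()
        fc = fc_from_csd(
            predicted_csd(template15, DEFAULT_NEURAL_FLUCT, DEFAULT_HEMO, grid)
        )
        idx = {n: regions15.indices(n) for n in NETWORK_ORDER}
        for net in NETWORK_ORDER:
            sub = fc.values[np.ix_(idx[net], idx[net])]
            mask = ~np.eye(len(idx[net]), dtype=bool)
            assert sub[mask].mean() > 0
        for other in ("SN", "DAN"):
            assert fc.values[np.ix_(idx["cDN"], idx[other])].mean() < 0

    def test_one_way_coupling_yields_symmetric_nonzero_correlation(self):
        # the degenerate cause->effect mapping: a one-way connection still
        # produces symmetric functional connectivity
        rs = RegionSet(("a", "b"), ("X", "X"))
        A = np.array([[-0.5, 0.0], [0.4, -0.5]])  # a drives b, not vice versa
        ec = EffectiveConnectivity(A, rs)
        grid = FrequencyGrid(np.linspace(1e-3, 20.0, 8192))
        fc = fc_from_csd(predicted_csd(ec, FluctuationParams(1.0, 0.0), None, grid))
        assert fc.values[0, 1] == pytest.approx(fc.values[1, 0])
        assert fc.values[0, 1] > 0.1

    def test_agrees_with_long_simulation(self):
        # oracle: empirical correlation of a long fine-grid simulation driven
        # by white fluctuations (finite records of 1/f noise converge slowly)
        rs = RegionSet(("a", "b", "c"), ("X",) * 3)
        A = np.array([[-0.5, 0.25, 0.0], [0.1, -0.5, -0.2], [0.0, 0.3, -0.5]])
        ec = EffectiveConnectivity(A, rs)
        fl = FluctuationParams(0.01, 0.0)
        ts = simulate_bold(
            ec, fluct=fl, T=20000, dt=0.2, seed=4, dt_sim=0.1,
            obs_noise=FluctuationParams(0.0, 0.0),
        )
        emp = np.corrcoef(ts.data, rowvar=False)
        grid = FrequencyGrid(np.linspace(2.5e-4, 2.5, 8192))
        fc = fc_from_csd(predicted_csd(ec, fl, DEFAULT_HEMO, grid))
        assert np.abs(fc.values - emp).max() < 0.05


class TestConnectionKernel:
    def test_diagonal_coupling_cross_kernel_zero(self):
        rs = RegionSet(("a", "b"), ("X", "X"))
        ec = EffectiveConnectivity(-0.5 * np.eye(2), rs)
        k = connection_kernel(ec, DEFAULT_HEMO, "a", "b", np.linspace(0, 30, 61))
        assert np.abs(k).max() == 0

    def test_scalar_closed_form(self):
        # oracle: direct convolution of the hemodynamic kernel with exp(-a t)
        rs = RegionSet(("a",), ("X",))
        a = 0.5
        ec = EffectiveConnectivity(np.array([[-a]]), rs)
        tspan = np.linspace(0, 20, 41)
        k = connection_kernel(ec, DEFAULT_HEMO, "a", "a", tspan, dt_fine=0.01)
        dt = 0.01
        h = hemodynamic_kernel(DEFAULT_HEMO, dt, duration=32.0)
        t = np.arange(int(30 / dt)) * dt
        ref_full = np.convolve(np.exp(-a * t), h)[: t.size] * dt
        ref = np.interp(tspan, t, ref_full)
        assert np.abs(k - ref).max() < 5e-3 * np.abs(ref).max()

    def test_decays_for_stable_coupling(self, template15):
        tspan = np.linspace(0, 90, 181)
        k = connection_kernel(template15, DEFAULT_HEMO, "PCC", "dACC", tspan)
        peak = np.abs(k).max()
        assert np.abs(k[tspan > 60]).max() < 1e-3 * peak


class TestEstimateCsd:
    def test_white_noise_flat_spectrum(self):
        rng = np.random.default_rng(0)
        ts = SubjectTimeSeries(rng.standard_normal((4096, 2)), 2.0, ("a", "b"))
        grid = FrequencyGrid.default(T=4096, dt=2.0)
        csd = estimate_csd(ts, grid, order=8)
        diag = csd.values[:, 0, 0].real
        assert diag.max() / diag.min() < 3

    def test_ar1_spectrum_closed_form(self):
        # oracle: analytic AR(1) spectrum dt*s2/|1 - phi e^{-2 pi i f dt}|^2
        rng = np.random.default_rng(1)
        phi, s2, dt, T = 0.6, 1.0, 2.0, 4096
        x = np.zeros(T)
        for t in range(1, T):
            x[t] = phi * x[t - 1] + rng.normal(0, np.sqrt(s2))
        ts = SubjectTimeSeries(x[:, None] - x.mean(), dt, ("a",))
        grid = FrequencyGrid.default(T=T, dt=dt)
        csd = estimate_csd(ts, grid, order=8)
        f = grid.frequencies
        analytic = dt * s2 / np.abs(1 - phi * np.exp(-2j * np.pi * f * dt)) ** 2
        rel = np.abs(csd.values[:, 0, 0].real - analytic) / analytic
        assert np.median(rel) < 0.10

    def test_generator_estimator_consistency(self, truth3):
        # long simulation: MAR estimate approximates the model CSD
        # order high enough to resolve the low-frequency spectral peak
        ts = simulate_bold(truth3, T=16384, dt=2.0, seed=3)
        grid = FrequencyGrid.default(T=170, dt=2.0, n_bins=64)
        est = estimate_csd(ts, grid, order=48)
        from netdcm.params import DEFAULT_OBS_NOISE

        pred = predicted_csd(
            truth3, DEFAULT_NEURAL_FLUCT, DEFAULT_HEMO, grid, obs_noise=DEFAULT_OBS_NOISE
        )
        rel = np.linalg.norm(est.values - pred.values) / np.linalg.norm(pred.values)
        assert rel < 0.3

    def test_too_short_series_rejected(self):
        ts = SubjectTimeSeries(np.random.default_rng(0).standard_normal((24, 2)), 2.0, ("a", "b"))
        with pytest.raises(ValueError, match="order"):
            estimate_csd(ts, FrequencyGrid.default(T=24, dt=2.0), order=8)
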