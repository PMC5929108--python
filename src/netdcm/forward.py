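"""Generative spectral model: coupling matrix -> cross spectra -> correlations.

This module maps causes to effects.  A stable coupling matrix A, a power-law
spectrum of endogenous fluctuations and a hemodynamic transfer function
jointly determine the cross-spectral density (CSD) of the observed BOLD
signal,

    G_y(w) = H(w) G_v(w) H(w)* + G_e(w),    H(w) = K(w) (i w I - A)^-1,

with w = 2*pi*f, G_v(w) = alpha_v * w**-beta_v * I the endogenous spectrum,
G_e the observation-noise spectrum and K(w) the per-region hemodynamic
transfer.  Inverse Fourier transformation gives cross-covariance functions,
and their zero-lag normalization the functional-connectivity (correlation)
matrix.  The same module estimates a CSD from data through a multivariate
autoregressive model, which is the data feature the inversion fits.

All spectra are two-sided densities over f in Hz: integrating a CSD over
(-Nyquist, Nyquist) with measure df yields the stationary covariance (for
beta = 0 and K = 1 this equals the solution of the Lyapunov equation
A S + S A' + alpha I = 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .connectivity import EffectiveConnectivity
from .params import FluctuationParams, HemodynamicParams, DEFAULT_HEMO
from .synthetic import SubjectTimeSeries, _balloon_system, hemodynamic_kernel


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing positive frequencies in Hz."""

    frequencies: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", f)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequencies must be a non-empty 1-D array")
        if f[0] <= 0 or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing and positive")

    @property
    def omega(self) -> np.ndarray:
        return 2.0 * np.pi * self.frequencies

    @property
    def n_bins(self) -> int:
        return self.frequencies.size

    @classmethod
    def default(cls, T: int = 170, dt: float = 2.0, n_bins: int = 64) -> "FrequencyGrid":
        """Linear grid from the fundamental 1/(T dt) up to 0.25 Hz."""
        f_min = 1.0 / (T * dt)
        f_max = min(0.25, 1.0 / (2.0 * dt))
        return cls(np.linspace(f_min, f_max, n_bins))


@dataclass(frozen=True)
class CrossSpectralDensity:
    """Complex Hermitian n x n matrix per frequency bin."""

    values: np.ndarray  # (F, n, n) complex
    grid: FrequencyGrid
    labels: Tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=complex)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if v.shape != (self.grid.n_bins, n, n):
            raise ValueError(
                f"values shape {v.shape} does not match "
                f"({self.grid.n_bins}, {n}, {n})"
            )
        herm_err = np.max(np.abs(v - np.conj(np.transpose(v, (0, 2, 1)))))
        if herm_err > 1e-6 * max(1.0, np.max(np.abs(v))):
            raise ValueError(f"CSD slices are not Hermitian (max deviation {herm_err:.3g})")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class CrossCovariance:
    """Real n x n matrix per lag; lags form a symmetric grid in seconds."""

    values: np.ndarray  # (L, n, n)
    lags: np.ndarray  # (L,)
    labels: Tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        lags = np.asarray(self.lags, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if v.shape != (lags.size, n, n):
            raise ValueError("values must be (n_lags, n, n)")

    def at_lag(self, lag: float) -> np.ndarray:
        idx = np.flatnonzero(np.isclose(self.lags, lag))
        if idx.size == 0:
            raise KeyError(f"lag {lag} not present")
        return self.values[idx[0]]


@dataclass(frozen=True)
class FCMatrix:
    """Functional connectivity: symmetric correlation matrix with unit diagonal."""

    values: np.ndarray
    labels: Tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("FC matrix must be square and match labels")
        if np.max(np.abs(v - v.T)) > 1e-8:
            raise ValueError("FC matrix must be symmetric")
        if np.max(np.abs(np.diag(v) - 1.0)) > 1e-8:
            raise ValueError("FC matrix must have unit diagonal")
        if np.max(np.abs(v)) > 1.0 + 1e-8:
            raise ValueError("correlations must lie in [-1, 1]")


def hemodynamic_transfer(
    hemo: HemodynamicParams, grid: FrequencyGrid
) -> np.ndarray:
    """Frequency response K(w) of the linearized hemodynamic kernel (complex, per bin)."""
    Ah, B, C = _balloon_system(hemo)
    iw = 1j * grid.omega
    eye = np.eye(4)
    M = iw[:, None, None] * eye - Ah
    sol = np.linalg.solve(M, np.broadcast_to(B, (grid.n_bins, 4))[..., None])
    return np.einsum("j,fj->f", C, sol[..., 0])


def _transfer_matrix(
    A: np.ndarray, K: np.ndarray, omega: np.ndarray
) -> np.ndarray:
    """H(w) = diag(K_region(w)) (i w I - A)^-1, shape (F, n, n).

    K may be (F,) for identical regions or (F, n) per region.
    """
    n = A.shape[0]
    eye = np.eye(n)
    M = 1j * omega[:, None, None] * eye - A
    X = np.linalg.inv(M)
    if K.ndim == 1:
        K = K[:, None]
    return K[:, :, None] * X


def _power_law(omega: np.ndarray, amplitude: float, exponent: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return amplitude * omega ** (-exponent)


def predicted_csd(
    A: EffectiveConnectivity,
    fluct: FluctuationParams,
    hemo: Optional[HemodynamicParams],
    grid: FrequencyGrid,
    obs_noise: Optional[FluctuationParams] = None,
) -> CrossSpectralDensity:
    """Model CSD of the observed signal given coupling, spectra and hemodynamics.

    ``hemo=None`` uses a unit observation kernel (K = 1), which exposes the
    neuronal CSD directly; then for white fluctuations the spectral integral
    equals the Lyapunov stationary covariance.
    """
    A.assert_stable()
    omega = grid.omega
    K = hemodynamic_transfer(hemo, grid) if hemo is not None else np.ones_like(omega, dtype=complex)
    gv = _power_law(omega, fluct.amplitude, fluct.exponent)
    ge = (
        _power_law(omega, obs_noise.amplitude, obs_noise.exponent)
        if obs_noise is not None
        else np.zeros_like(omega)
    )
    G = _csd_values(A.matrix, K, gv, ge, omega)
    worst = np.linalg.cond(1j * omega[0] * np.eye(A.n) - A.matrix)
    if worst > 1e12:
        warnings.warn(
            f"(i w I - A) badly conditioned at lowest frequency (cond {worst:.3g})"
        )
    return CrossSpectralDensity(G, grid, A.regions.labels)


def _csd_values(
    A: np.ndarray,
    K: np.ndarray,
    gv: np.ndarray,
    ge: np.ndarray,
    omega: np.ndarray,
) -> np.ndarray:
    """Core CSD computation on raw arrays (used by the model inversion too)."""
    H = _transfer_matrix(A, K, omega)
    G = np.einsum("fik,f,fjk->fij", H, gv, np.conj(H))
    n = A.shape[0]
    G = G + ge[:, None, None] * np.eye(n)
    # enforce exact Hermitian symmetry against rounding
    return 0.5 * (G + np.conj(np.transpose(G, (0, 2, 1))))


def csd_to_cross_covariance(
    csd: CrossSpectralDensity, lags: Sequence[float]
) -> CrossCovariance:
    """Inverse Fourier transform of the two-sided (Hermitian-extended) CSD.

    Requires a dense, uniform frequency grid; lags beyond 1/(2 df) alias and
    are rejected.
    """
    f = csd.grid.frequencies
    if f.size < 64:
        raise ValueError("frequency grid too coarse (need >= 64 bins)")
    df = np.diff(f)
    if np.max(np.abs(df - df[0])) > 1e-9 * df[0]:
        raise ValueError("cross-covariance requires a uniform frequency grid")
    df = float(df[0])
    lags = np.asarray(lags, dtype=float)
    max_lag = 1.0 / (2.0 * df)
    if np.any(np.abs(lags) > max_lag):
        raise ValueError(
            f"requested lag exceeds 1/(2 df) = {max_lag:.3g} s (aliasing)"
        )
    phase = np.exp(2j * np.pi * np.outer(lags, f))  # (L, F)
    # two-sided integral: G(-f) = conj(G(f)), so C(tau) = 2 Re sum G(f) e^{2pi i f tau} df
    C = 2.0 * np.real(np.einsum("lf,fij->lij", phase, csd.values)) * df
    return CrossCovariance(C, lags, csd.labels)


def functional_connectivity(cov: CrossCovariance) -> FCMatrix:
    """Correlation matrix: the normalized cross-covariance at zero lag."""
    C0 = cov.at_lag(0.0)
    var = np.diag(C0)
    bad = np.flatnonzero(var <= 0)
    if bad.size:
        names = [cov.labels[i] for i in bad]
        raise ValueError(f"zero or negative variance at lag 0 for regions: {names}")
    d = 1.0 / np.sqrt(var)
    R = C0 * np.outer(d, d)
    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)
    R = np.clip(R, -1.0, 1.0)
    return FCMatrix(R, cov.labels)


def fc_from_csd(csd: CrossSpectralDensity) -> FCMatrix:
    """Convenience: FC implied by a CSD (zero-lag normalized spectral integral)."""
    cov = csd_to_cross_covariance(csd, [0.0])
    return functional_connectivity(cov)


def connection_kernel(
    A: EffectiveConnectivity,
    hemo: HemodynamicParams,
    source: str,
    target: str,
    tspan: Sequence[float],
    dt_fine: float = 0.05,
) -> np.ndarray:
    """First-order BOLD response of ``target`` to an endogenous impulse at ``source``.

    The neuronal response is expm(A t) restricted to the (target, source)
    entry, convolved with the hemodynamic kernel and sampled on ``tspan``.
    """
    A.assert_stable()
    from scipy.linalg import expm

    tspan = np.asarray(tspan, dtype=float)
    if np.any(tspan < 0):
        raise ValueError("tspan must be nonnegative")
    i = A.regions.index(target)
    j = A.regions.index(source)
    t_max = float(tspan.max()) if tspan.size else 0.0
    n_fine = int(np.ceil(t_max / dt_fine)) + 1
    E = expm(A.matrix * dt_fine)
    # neuronal impulse response x(t) = [expm(A t)]_{i, j}
    col = np.zeros(A.n)
    col[j] = 1.0
    xt = np.empty(n_fine)
    state = col
    for k in range(n_fine):
        xt[k] = state[i]
        state = E @ state
    kern = hemodynamic_kernel(hemo, dt_fine, duration=min(32.0, max(dt_fine, t_max) + dt_fine))
    from scipy.signal import fftconvolve

    resp = fftconvolve(xt, kern)[:n_fine] * dt_fine
    t_fine = np.arange(n_fine) * dt_fine
    return np.interp(tspan, t_fine, resp)


def estimate_csd(
    ts: SubjectTimeSeries,
    grid: FrequencyGrid,
    order: int = 8,
    ridge: Optional[float] = None,
) -> CrossSpectralDensity:
    """CSD of a sampled series via a least-squares multivariate AR model.

    A vector AR(order) model is fit to the mean-centered data; the CSD is
    evaluated from the AR transfer function on ``grid`` as
    ``dt * H_ar(f) Sigma_u H_ar(f)*``, which is Hermitian positive
    semidefinite by construction.  Ill-conditioned normal equations fall back
    to a small ridge penalty with a warning.
    """
    y = ts.data - ts.data.mean(axis=0, keepdims=True)
    T, n = y.shape
    if T <= 4 * order:
        raise ValueError(f"need T > 4*order samples (T={T}, order={order})")
    if grid.frequencies[-1] > 1.0 / (2.0 * ts.dt) + 1e-12:
        raise ValueError("grid exceeds the Nyquist frequency of the data")
    # lagged design: rows t = order..T-1, regressors [y[t-1], ..., y[t-order]]
    X = np.concatenate([y[order - k - 1 : T - k - 1] for k in range(order)], axis=1)
    Y = y[order:]
    XtX = X.T @ X
    cond = np.linalg.cond(XtX)
    if ridge is None and cond > 1e10:
        ridge = 1e-6 * np.trace(XtX) / XtX.shape[0]
        warnings.warn(
            f"AR normal equations ill-conditioned (cond {cond:.3g}); "
            f"using ridge penalty {ridge:.3g}"
        )
    if ridge:
        coef = np.linalg.solve(XtX + ridge * np.eye(XtX.shape[0]), X.T @ Y)
    else:
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    dof = max(Y.shape[0] - X.shape[1], 1)
    sigma_u = resid.T @ resid / dof
    # AR coefficient blocks: y[t] = sum_k A_k y[t-k] + u[t]
    A_blocks = [coef[k * n : (k + 1) * n].T for k in range(order)]
    eye = np.eye(n)
    F = grid.n_bins
    G = np.empty((F, n, n), dtype=complex)
    for fi, f in enumerate(grid.frequencies):
        Af = eye.astype(complex).copy()
        for k, Ak in enumerate(A_blocks, start=1):
            Af -= Ak * np.exp(-2j * np.pi * f * k * ts.dt)
        Hf = np.linalg.inv(Af)
        G[fi] = ts.dt * Hf @ sigma_u @ Hf.conj().T
    G = 0.5 * (G + np.conj(np.transpose(G, (0, 2, 1))))
    return CrossSpectralDensity(G, grid, ts.labels)


def empirical_fc(ts: SubjectTimeSeries) -> FCMatrix:
    """Pearson correlation of the sampled time series."""
    R = np.corrcoef(ts.data, rowvar=False)
    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)
    return FCMatrix(np.clip(R, -1, 1), ts.labels)
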