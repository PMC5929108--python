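"""Synthetic resting-state BOLD cohorts from known effective connectivity.

The generator emulates the structure of a multi-region resting-state study:
linear stochastic neuronal dynamics ``dx/dt = A x + v`` driven by power-law
endogenous fluctuations v, observed through a linearized hemodynamic
convolution kernel, sampled at the repetition time and corrupted by additive
observation noise.  Ground-truth coupling is recorded for every subject so
the whole inference chain can be validated without any external data.

The default template couples three networks (cDN, SN, DAN) with the signed
pattern characteristic of anticorrelated resting-state systems: the SN and
DAN inhibit the cDN, the cDN weakly excites the SN and DAN, and the SN and
DAN excite each other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict, fields as dc_fields
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .connectivity import EffectiveConnectivity, StabilityError, stable
from .params import (
    DEFAULT_HEMO,
    DEFAULT_NEURAL_FLUCT,
    DEFAULT_OBS_NOISE,
    FluctuationParams,
    HemodynamicParams,
)
from .regions import NETWORK_ORDER, RegionSet, load_region_fixture

RngLike = Union[int, np.random.Generator, None]

#: Between-network mean couplings (Hz), keyed (source, target).  The signed
#: pattern: SN/DAN -> cDN inhibitory, cDN -> SN/DAN weakly excitatory,
#: SN <-> DAN excitatory.
DEFAULT_BETWEEN_MEANS: Dict[Tuple[str, str], float] = {
    ("SN", "DAN"): 0.03,
    ("SN", "cDN"): -0.13,
    ("DAN", "SN"): 0.02,
    ("DAN", "cDN"): -0.10,
    ("cDN", "SN"): 0.02,
    ("cDN", "DAN"): 0.02,
}

#: Default within-network off-diagonal coupling (Hz).  Chosen so every
#: network block (up to 6 regions) stays dissipative under the canonical
#: -0.5 Hz self-inhibition: the largest block eigenvalue is
#: self + (n_block - 1) * within, which must remain negative.
DEFAULT_WITHIN = 0.0625

DEFAULT_SELF = -0.5


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SubjectTimeSeries:
    """A T x n sampled BOLD matrix with its sampling interval (seconds)."""

    data: np.ndarray
    dt: float
    labels: Tuple[str, ...]

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "labels", tuple(self.labels))
        if d.ndim != 2:
            raise ValueError("data must be a T x n matrix")
        if d.shape[1] != len(self.labels):
            raise ValueError("number of columns must match number of labels")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if d.shape[0] < 2 * d.shape[1]:
            raise ValueError(
                f"need at least 2n samples (T={d.shape[0]}, n={d.shape[1]})"
            )
        if not np.all(np.isfinite(d)):
            raise ValueError("time series contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


def make_template_A(
    partition: RegionSet,
    between_means: Optional[Dict[Tuple[str, str], float]] = None,
    within_strength: float = DEFAULT_WITHIN,
    self_strength: float = DEFAULT_SELF,
) -> EffectiveConnectivity:
    """Build the block-structured group coupling template.

    ``between_means`` maps (source_network, target_network) to the mean
    coupling (Hz) of every connection from a source-network region to a
    target-network region.  Within-network off-diagonals are uniform at
    ``within_strength``; the diagonal is ``self_strength`` (< 0).  The result
    must be dynamically stable, otherwise a :class:`StabilityError` is raised.
    """
    if not self_strength < 0:
        raise ValueError("self_strength must be negative (self-inhibition)")
    nets = partition.network_names
    if between_means is None:
        between_means = dict(DEFAULT_BETWEEN_MEANS) if set(nets) >= set(NETWORK_ORDER) else {}
    n = partition.n
    A = np.zeros((n, n))
    idx = {net: partition.indices(net) for net in nets}
    for net in nets:
        block = idx[net]
        for i in block:
            for j in block:
                A[i, j] = self_strength if i == j else within_strength
    for (src, tgt), mean in between_means.items():
        if src not in idx or tgt not in idx:
            raise KeyError(f"between_means names unknown network: {(src, tgt)}")
        if src == tgt:
            raise ValueError("between_means must couple distinct networks")
        A[np.ix_(idx[tgt], idx[src])] = mean
    ec = EffectiveConnectivity(A, partition)
    return ec.assert_stable()


def sample_subject_A(
    template: EffectiveConnectivity,
    sd: float,
    seed: RngLike = None,
    max_retries: int = 50,
) -> EffectiveConnectivity:
    """Add Gaussian between-subject variation to the off-diagonal couplings.

    Off-diagonals get independent N(0, sd^2) perturbations; self-connections
    are kept at the template value.  Draws are rejected (up to
    ``max_retries``) until the perturbed matrix is stable.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return template
    rng = _rng(seed)
    n = template.n
    off = ~np.eye(n, dtype=bool)
    for _ in range(max_retries):
        A = template.matrix.copy()
        A[off] += rng.normal(0.0, sd, size=int(off.sum()))
        if stable(A):
            return EffectiveConnectivity(A, template.regions)
    raise StabilityError(
        f"no stable subject matrix found in {max_retries} draws at sd={sd}; "
        f"try a smaller between-subject sd"
    )


def generate_fluctuations(
    n: int,
    t_sim: int,
    dt_sim: float,
    params: FluctuationParams,
    seed: RngLike = None,
) -> np.ndarray:
    """Sample power-law noise by spectral synthesis (columns independent).

    White Gaussian noise is shaped in the frequency domain by
    ``sqrt(amplitude * omega**-exponent)`` with omega = 2*pi*f (f in Hz given
    the grid spacing ``dt_sim``), the zero-frequency bin is set to 0 (no DC
    drift) and the result inverse-transformed.  The expected per-sample
    periodogram ``|FFT|^2 / T`` follows ``amplitude * omega**-exponent``; for
    ``exponent = 0`` the sample variance is approximately ``amplitude``.
    """
    if params.amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if params.amplitude == 0:
        return np.zeros((t_sim, n))
    rng = _rng(seed)
    freqs = np.fft.rfftfreq(t_sim, d=dt_sim)
    omega = 2.0 * np.pi * freqs
    shape = np.zeros_like(omega)
    with np.errstate(divide="ignore"):
        shape[1:] = np.sqrt(params.amplitude * omega[1:] ** (-params.exponent))
    # E|F_k|^2 = T * S_k per-sample convention; Hermitian-symmetric synthesis
    n_bins = freqs.size
    out = np.empty((t_sim, n))
    scale = np.sqrt(t_sim) * shape
    for col in range(n):
        coeffs = np.zeros(n_bins, dtype=complex)
        interior = slice(1, n_bins - 1 if t_sim % 2 == 0 else n_bins)
        z = rng.standard_normal((n_bins, 2))
        coeffs[interior] = scale[interior] * (z[interior, 0] + 1j * z[interior, 1]) / np.sqrt(2.0)
        if t_sim % 2 == 0:
            coeffs[-1] = scale[-1] * z[-1, 0]  # Nyquist bin is real
        out[:, col] = np.fft.irfft(coeffs, n=t_sim)
    return out


def hemodynamic_kernel(
    hemo: HemodynamicParams, dt: float, duration: float = 32.0
) -> np.ndarray:
    """Impulse response of the linearized balloon model on a grid of spacing dt.

    First-order expansion of the balloon equations around rest: vasodilatory
    signal s and inflow f, venous volume v and deoxyhemoglobin q, read out
    through the standard BOLD observation equation.  Returned kernel k(t)
    satisfies BOLD(t) = (k * neural)(t) (convolution with measure dt).
    """
    Ah, B, C = _balloon_system(hemo)
    from scipy.linalg import expm

    steps = int(np.ceil(duration / dt))
    E = expm(Ah * dt)
    state = B.copy()
    k = np.empty(steps)
    for i in range(steps):
        k[i] = C @ state
        state = E @ state
    return k


def _balloon_system(hemo: HemodynamicParams):
    """Linearized balloon dynamics as (A, B, C): dz/dt = A z + B u, y = C z."""
    kappa, gamma = hemo.signal_decay, hemo.feedback
    tau, alpha, e0 = hemo.transit, hemo.stiffness, hemo.extraction
    # states z = (s, f, v, q) as deviations from rest
    cf = 1.0 + (1.0 - e0) * np.log(1.0 - e0) / e0  # d/df of f*E(f)/E0 at rest
    Ah = np.array(
        [
            [-kappa, -gamma, 0.0, 0.0],
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 1.0 / tau, -1.0 / (alpha * tau), 0.0],
            [0.0, cf / tau, -(1.0 / alpha - 1.0) / tau, -1.0 / tau],
        ]
    )
    B = np.array([1.0, 0.0, 0.0, 0.0])
    k1, k2, k3 = 7.0 * e0, 2.0, 2.0 * e0 - 0.2
    C = np.array([0.0, 0.0, k2 - k3, -(k1 + k2)])
    return Ah, B, C


def simulate_bold(
    A: EffectiveConnectivity,
    fluct: FluctuationParams = DEFAULT_NEURAL_FLUCT,
    hemo: HemodynamicParams = DEFAULT_HEMO,
    T: int = 170,
    dt: float = 2.0,
    obs_noise: FluctuationParams = DEFAULT_OBS_NOISE,
    seed: RngLike = None,
    dt_sim: float = 0.1,
    burn_in: float = 64.0,
) -> SubjectTimeSeries:
    """Integrate the neuronal model and observe it through the hemodynamics.

    Euler integration of dx/dt = A x + v on the fine grid ``dt_sim``,
    convolution of each region with the linearized hemodynamic kernel,
    downsampling to the repetition time ``dt``, additive observation noise at
    the sampled rate, burn-in discarded, per-region mean removed.
    """
    A.assert_stable()
    if dt_sim > 0.5:
        raise ValueError("dt_sim must be <= 0.5 s to resolve the sampled band")
    ratio = dt / dt_sim
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("dt must be an integer multiple of dt_sim")
    ratio = int(round(ratio))
    rng = _rng(seed)
    n = A.n
    n_fine = int(np.ceil(burn_in / dt_sim)) + T * ratio

    # endogenous forcing: physical density fluct.amplitude * omega**-beta
    v = generate_fluctuations(
        n, n_fine, dt_sim,
        FluctuationParams(fluct.amplitude / dt_sim, fluct.exponent), rng,
    )
    x = np.zeros((n_fine, n))
    M = A.matrix
    xi = np.zeros(n)
    for k in range(n_fine - 1):
        xi = xi + dt_sim * (M @ xi + v[k])
        if not np.all(np.abs(xi) < 1e9):
            raise FloatingPointError(
                "neuronal integration overflowed; use a smaller dt_sim"
            )
        x[k + 1] = xi

    kern = hemodynamic_kernel(hemo, dt_sim)
    from scipy.signal import fftconvolve

    bold_fine = fftconvolve(x, kern[:, None], axes=0)[:n_fine] * dt_sim

    start = n_fine - T * ratio
    y = bold_fine[start::ratio][:T]

    if obs_noise.amplitude > 0:
        e = generate_fluctuations(
            n, T, dt, FluctuationParams(obs_noise.amplitude / dt, obs_noise.exponent), rng
        )
        y = y + e
    y = y - y.mean(axis=0, keepdims=True)
    return SubjectTimeSeries(data=y, dt=dt, labels=A.regions.labels)


@dataclass(frozen=True)
class CohortConfig:
    """Generation conditions for a synthetic cohort.

    Defaults mirror the study design the generator emulates: 15 regions in 3
    networks, 170 retained volumes at a 2 s repetition time, N subjects drawn
    from a group template with Gaussian between-subject variation on the
    off-diagonal couplings.
    """

    n_subjects: int = 20
    subject_sd: float = 0.05
    seed: int = 0
    T: int = 170
    dt: float = 2.0
    within_strength: float = DEFAULT_WITHIN
    self_strength: float = DEFAULT_SELF
    between_means: Optional[Dict[Tuple[str, str], float]] = None
    fluct_amplitude: float = DEFAULT_NEURAL_FLUCT.amplitude
    fluct_exponent: float = DEFAULT_NEURAL_FLUCT.exponent
    obs_amplitude: float = DEFAULT_OBS_NOISE.amplitude
    obs_exponent: float = DEFAULT_OBS_NOISE.exponent
    dt_sim: float = 0.1
    burn_in: float = 64.0

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown cohort config keys: {unknown}")
        d = dict(d)
        if "between_means" in d and d["between_means"] is not None:
            bm = d["between_means"]
            if isinstance(bm, dict) and bm and isinstance(next(iter(bm)), str):
                bm = {tuple(k.split("->")): v for k, v in bm.items()}
            d["between_means"] = {tuple(k): float(v) for k, v in bm.items()}
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["between_means"] is not None:
            d["between_means"] = {f"{s}->{t}": v for (s, t), v in d["between_means"].items()}
        return d


@dataclass(frozen=True)
class Cohort:
    subjects: Tuple[SubjectTimeSeries, ...]
    truths: Tuple[EffectiveConnectivity, ...]
    template: EffectiveConnectivity
    config: CohortConfig

    def __post_init__(self):
        if len(self.subjects) != len(self.truths):
            raise ValueError("one ground-truth matrix per subject required")

    @property
    def regions(self) -> RegionSet:
        return self.template.regions

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def generate_cohort(
    config: CohortConfig, regions: Optional[RegionSet] = None
) -> Cohort:
    """Generate a reproducible cohort; per-subject seed = master seed + index."""
    regions = regions if regions is not None else load_region_fixture()
    template = make_template_A(
        regions,
        between_means=config.between_means,
        within_strength=config.within_strength,
        self_strength=config.self_strength,
    )
    fluct = FluctuationParams(config.fluct_amplitude, config.fluct_exponent)
    obs = FluctuationParams(config.obs_amplitude, config.obs_exponent)
    subjects: List[SubjectTimeSeries] = []
    truths: List[EffectiveConnectivity] = []
    for i in range(config.n_subjects):
        rng = np.random.default_rng(config.seed + i)
        truth = sample_subject_A(template, config.subject_sd, rng)
        ts = simulate_bold(
            truth,
            fluct=fluct,
            hemo=DEFAULT_HEMO,
            T=config.T,
            dt=config.dt,
            obs_noise=obs,
            seed=rng,
            dt_sim=config.dt_sim,
            burn_in=config.burn_in,
        )
        subjects.append(ts)
        truths.append(truth)
    return Cohort(tuple(subjects), tuple(truths), template, config)
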