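"""Network-level statistics: Bayesian contrasts, between-network averages,
hierarchy strength, and two-mode clustering of connectivity matrices.

Given a Gaussian posterior N(M, Sigma) over coupling parameters, any linear
functional c of the parameters has expectation mu = c'M and variance
sigma^2 = c'Sigma c — a Bayesian contrast.  Averaging contrasts over the
connections between two networks summarizes the 15x15 coupling matrix as a
3x3 network-level matrix with full uncertainty propagation; the hierarchy
strength of a network is the sum of its unsigned between-network efferent
averages minus the sum of its unsigned afferent averages, ranking networks
by how much they influence the others relative to being influenced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import norm
from sklearn.metrics import adjusted_rand_score

from .connectivity import EffectiveConnectivity
from .forward import FCMatrix
from .inversion import ParameterSpace, Posterior
from .regions import NETWORK_ORDER, RegionSet


@dataclass(frozen=True)
class Contrast:
    """A linear functional of a Gaussian posterior."""

    weights: np.ndarray
    mu: float
    sigma2: float
    p_nonzero: float
    sided: str

    @property
    def sd(self) -> float:
        return float(np.sqrt(max(self.sigma2, 0.0)))


def contrast(post: Posterior, c: np.ndarray, sided: str = "one") -> Contrast:
    """mu = c'M, sigma^2 = c'Sigma c, with a Gaussian tail probability.

    ``sided="one"``: posterior probability that the contrast exceeds zero.
    ``sided="two"``: posterior probability that it differs from zero (i.e.,
    the probability mass on the side of zero indicated by the mean).
    """
    c = np.asarray(c, dtype=float)
    if c.shape != (post.P,):
        raise ValueError(f"contrast length {c.shape} != number of parameters {post.P}")
    mu = float(c @ post.mean)
    sigma2 = float(c @ post.cov @ c)
    sigma2 = max(sigma2, 0.0)
    sd = np.sqrt(sigma2)
    if sd == 0:
        p = 0.5 if mu == 0 else 1.0
    elif sided == "one":
        p = float(norm.sf(0.0, loc=mu, scale=sd))
    elif sided == "two":
        p = float(2.0 * norm.cdf(abs(mu) / sd) - 1.0)
    else:
        raise ValueError("sided must be 'one' or 'two'")
    return Contrast(c, mu, sigma2, p, sided)


@dataclass(frozen=True)
class NetworkAverages:
    """3x3 (or k x k) matrix of average connection strengths between networks.

    ``mu[i, j]`` is the average coupling from network j (source) to network i
    (target); diagonal cells average the within-network off-diagonal
    couplings.  Each cell is a Bayesian contrast with equal weights over its
    connection set, so ``sigma2`` and ``p_nonzero`` carry the conditional
    uncertainty of the average.
    """

    networks: Tuple[str, ...]
    mu: np.ndarray
    sigma2: np.ndarray
    p_nonzero: np.ndarray

    def cell(self, source: str, target: str) -> Tuple[float, float, float]:
        i = self.networks.index(target)
        j = self.networks.index(source)
        return float(self.mu[i, j]), float(self.sigma2[i, j]), float(self.p_nonzero[i, j])

    @classmethod
    def from_cells(
        cls, cells: Dict[Tuple[str, str], float],
        networks: Sequence[str] = NETWORK_ORDER,
    ) -> "NetworkAverages":
        """Build from known (source, target) -> mean values (zero uncertainty)."""
        networks = tuple(networks)
        k = len(networks)
        mu = np.zeros((k, k))
        for (src, tgt), v in cells.items():
            mu[networks.index(tgt), networks.index(src)] = v
        return cls(networks, mu, np.zeros((k, k)), np.full((k, k), np.nan))


def between_network_average(
    post: Posterior,
    partition: RegionSet,
    sided: str = "two",
) -> NetworkAverages:
    """Network-level averages of the posterior over couplings.

    Each cell is the equal-weight contrast over all connections from the
    source network to the target network (within-network off-diagonals on
    the diagonal), so both strengths and their conditional covariances enter.
    The posterior may be over the full parameter space or any subset that
    contains every coupling parameter ``A[target<-source]``.
    """
    pos = {name: k for k, name in enumerate(post.names)}
    nets = partition.network_names
    k = len(nets)
    labels = partition.labels
    mu = np.zeros((k, k))
    s2 = np.zeros((k, k))
    pp = np.zeros((k, k))
    for ti, tgt_net in enumerate(nets):
        for sj, src_net in enumerate(nets):
            tgt_idx = partition.indices(tgt_net)
            src_idx = partition.indices(src_net)
            pairs = [
                (labels[i], labels[j])
                for i in tgt_idx
                for j in src_idx
                if i != j
            ]
            if not pairs:
                raise ValueError(
                    f"no connections from {src_net} to {tgt_net} to average"
                )
            c = np.zeros(post.P)
            wt = 1.0 / len(pairs)
            for tgt_lab, src_lab in pairs:
                name = f"A[{tgt_lab}<-{src_lab}]"
                if name not in pos:
                    raise KeyError(f"posterior lacks coupling parameter {name}")
                c[pos[name]] = wt
            ct = contrast(post, c, sided=sided)
            mu[ti, sj] = ct.mu
            s2[ti, sj] = ct.sigma2
            pp[ti, sj] = ct.p_nonzero
    return NetworkAverages(tuple(nets), mu, s2, pp)


@dataclass(frozen=True)
class HierarchyScore:
    """Efferent-minus-afferent score of one network, with its formula trace."""

    network: str
    score: float
    efferent: Dict[str, float]  # target network -> unsigned between-network average
    afferent: Dict[str, float]  # source network -> unsigned between-network average
    mode: str


def hierarchy_strength(
    avgs: NetworkAverages, network: str, mode: str = "sum"
) -> HierarchyScore:
    """Hierarchy strength: unsigned efferent minus unsigned afferent averages.

    ``mode="sum"`` (default) sums the between-network cells,
    ``mode="mean"`` averages them (the two differ by the number of other
    networks).  A positive score marks a network that influences the others
    more strongly than it is influenced — higher in the hierarchy.
    """
    if network not in avgs.networks:
        raise KeyError(f"unknown network {network!r}")
    if mode not in ("sum", "mean"):
        raise ValueError("mode must be 'sum' or 'mean'")
    others = [n for n in avgs.networks if n != network]
    eff = {o: abs(avgs.cell(network, o)[0]) for o in others}
    aff = {o: abs(avgs.cell(o, network)[0]) for o in others}
    agg = (lambda d: float(np.sum(list(d.values())))) if mode == "sum" else (
        lambda d: float(np.mean(list(d.values())))
    )
    return HierarchyScore(network, agg(eff) - agg(aff), eff, aff, mode)


def hierarchy_scores(avgs: NetworkAverages, mode: str = "sum") -> Dict[str, float]:
    return {net: hierarchy_strength(avgs, net, mode).score for net in avgs.networks}


@dataclass(frozen=True)
class ClusterResult:
    labels: Tuple[str, ...]
    assignments: np.ndarray  # cluster id per region (1..k)
    linkage: np.ndarray  # scipy linkage matrix
    k: int

    def partition(self) -> Dict[str, int]:
        return {lab: int(c) for lab, c in zip(self.labels, self.assignments)}


def _region_profiles(values: np.ndarray) -> np.ndarray:
    """Per-region profile: afferent row and efferent column, self excluded."""
    n = values.shape[0]
    profiles = np.empty((n, 2 * (n - 1)))
    for i in range(n):
        mask = np.arange(n) != i
        profiles[i] = np.concatenate([values[i, mask], values[mask, i]])
    return profiles


def cluster_regions(
    matrix, k: int = 2, distance: str = "correlation", method: str = "average"
) -> ClusterResult:
    """Agglomerative clustering of regions by their connectivity profiles.

    Works on either a directed coupling matrix or a correlation matrix; each
    region is represented by its concatenated afferent and efferent profile
    (self entry excluded), compared by correlation distance with average
    linkage by default.  Deterministic given inputs.
    """
    if isinstance(matrix, EffectiveConnectivity):
        values, labels = matrix.matrix, matrix.regions.labels
    elif isinstance(matrix, FCMatrix):
        values, labels = matrix.values, matrix.labels
    else:
        values = np.asarray(matrix, dtype=float)
        labels = tuple(f"r{i}" for i in range(values.shape[0]))
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("need a square connectivity matrix")
    if k < 2:
        raise ValueError("k must be >= 2")
    profiles = _region_profiles(values)
    if distance == "correlation":
        sd = profiles.std(axis=1)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            names = [labels[i] for i in flat]
            raise ValueError(
                f"constant connectivity profile (zero variance) for regions: {names}"
            )
    D = pdist(profiles, metric=distance)
    Z = linkage(D, method=method)
    assign = fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(tuple(labels), assign, Z, k)


def coupling_matrix_from_posterior(
    post: Posterior, regions: RegionSet
) -> EffectiveConnectivity:
    """Decode a posterior's mean into the coupling matrix it parameterizes.

    Off-diagonals are the ``A[t<-s]`` parameters; the diagonal is
    ``-0.5 * exp(self[r])``.  Works for any posterior whose names include all
    coupling parameters (full first-level or group-level subsets).
    """
    pos = {name: k for k, name in enumerate(post.names)}
    n = regions.n
    A = np.zeros((n, n))
    for i, tgt in enumerate(regions.labels):
        for j, src in enumerate(regions.labels):
            if i == j:
                name = f"self[{tgt}]"
                A[i, i] = -0.5 * np.exp(post.mean[pos[name]]) if name in pos else -0.5
            else:
                A[i, j] = post.mean[pos[f"A[{tgt}<-{src}]"]]
    return EffectiveConnectivity(A, regions)


def compare_partitions(a: Sequence, b: Sequence) -> float:
    """Adjusted Rand index between two region partitions (1.0 iff identical)."""
    if len(a) != len(b):
        raise ValueError("partitions must label the same regions")
    return float(adjusted_rand_score(list(a), list(b)))
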