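"""Second-level machinery: Bayesian model reduction, greedy search, model
averaging and parametric empirical Bayes.

Bayesian model reduction (BMR) gives the posterior and evidence of any model
nested in a full model — obtained by changing the prior, typically pinning a
parameter to zero with near-zero variance — in closed form from the full
model's prior and posterior.  That makes an enormous model space searchable:
a greedy search prunes couplings whose removal does not reduce the evidence,
the best models are averaged weighted by evidence (BMA), and parametric
empirical Bayes (PEB) pools full subject posteriors (means *and*
covariances) under a between-subject general linear model with random
effects, so group estimates honour each subject's uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

from .inversion import ParameterSpace, Posterior, PriorSpec, _logdet_psd, _repair_psd

#: variance used to pin a pruned parameter (effectively a delta at zero)
PINNED_VARIANCE = 1e-8


@dataclass(frozen=True)
class GaussianPrior:
    """A bare diagonal Gaussian prior (for posteriors over parameter subsets)."""

    mean: np.ndarray
    variance: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, float))
        object.__setattr__(self, "variance", np.asarray(self.variance, float))

    @property
    def free(self) -> np.ndarray:
        return self.variance > 0


def coupling_prunable(names: Sequence[str]) -> np.ndarray:
    """Indices of off-diagonal coupling parameters among ``names``."""
    return np.array([k for k, nm in enumerate(names) if nm.startswith("A[")], dtype=int)


# ---------------------------------------------------------------------------
# Bayesian model reduction
# ---------------------------------------------------------------------------

def bmr_reduce(
    post: Posterior,
    full_prior_mean: np.ndarray,
    full_prior_cov: np.ndarray,
    reduced_prior_mean: np.ndarray,
    reduced_prior_cov: np.ndarray,
) -> Tuple[Posterior, float]:
    """Closed-form posterior and log-evidence change under a reduced prior.

    With precisions P (posterior), P0 (full prior), Pr (reduced prior):

        Pq = P + Pr - P0,
        mq = Pq^-1 (P m + Pr mr - P0 m0),
        dF = 1/2 [ logdet P + logdet Pr - logdet P0 - logdet Pq ]
           - 1/2 [ m'P m + mr'Pr mr - m0'P0 m0 - mq'Pq mq ].

    Exact — no iteration.  Raises if the reduced precision is not positive
    definite (an invalid reduction).
    """
    m = post.mean
    m0 = np.asarray(full_prior_mean, float)
    mr = np.asarray(reduced_prior_mean, float)
    S = np.asarray(post.cov, float)
    S0 = np.atleast_2d(np.asarray(full_prior_cov, float))
    Sr = np.atleast_2d(np.asarray(reduced_prior_cov, float))
    if S0.ndim == 2 and S0.shape[0] != S0.shape[1]:
        raise ValueError("full prior covariance must be square")
    P = np.linalg.inv(_jitter(S))
    P0 = np.linalg.inv(_jitter(S0))
    Pr = np.linalg.inv(_jitter(Sr))
    Pq = P + Pr - P0
    try:
        ld_q = _chol_logdet(Pq)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "reduced posterior precision is not positive definite: "
            "the requested prior reduction is invalid for this posterior"
        )
    Sq = np.linalg.inv(Pq)
    mq = Sq @ (P @ m + Pr @ mr - P0 @ m0)
    dF = 0.5 * (_chol_logdet(P) + _chol_logdet(Pr) - _chol_logdet(P0) - ld_q)
    dF -= 0.5 * (m @ P @ m + mr @ Pr @ mr - m0 @ P0 @ m0 - mq @ Pq @ mq)
    reduced = Posterior(
        post.names, mq, _repair_psd(Sq), post.F + dF,
        {**post.settings, "reduced": True},
    )
    return reduced, float(dF)


def _jitter(S: np.ndarray) -> np.ndarray:
    return S + 0.0  # covariances here are PD by construction; hook for robustness


def _chol_logdet(M: np.ndarray) -> float:
    L = np.linalg.cholesky(M)
    return 2.0 * float(np.sum(np.log(np.diag(L))))


# ---------------------------------------------------------------------------
# Greedy search over pruned couplings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelScore:
    """A scored reduced model: pruning mask, evidence change, reduced posterior."""

    mask: Tuple[bool, ...]  # True = parameter retained
    delta_f: float  # log evidence relative to the full model
    _ctx: "_SearchContext" = field(repr=False, compare=False)

    @property
    def pruned(self) -> Tuple[int, ...]:
        return tuple(i for i, on in enumerate(self.mask) if not on)

    def reduced_posterior(self) -> Posterior:
        return self._ctx.reduced_posterior(self.pruned)


class _SearchContext:
    """Shared state for fast single/multi-parameter BMR during the search.

    Pruning parameter i replaces its prior variance v0_i by the pinned value
    and its prior mean by 0; with diagonal priors and zero prior means on
    prunable parameters this is a low-rank precision update, so evidence and
    posterior of any pruned set follow from small sub-blocks of the full
    posterior covariance.
    """

    def __init__(self, post: Posterior, prior: PriorSpec, prunable: np.ndarray):
        free = np.flatnonzero(prior.free)
        self.names = post.names
        self.post = post
        self.prior = prior
        self.free = free
        self.m = post.mean[free]
        self.S = post.cov[np.ix_(free, free)]
        self.v0 = prior.variance[free]
        self.m0 = prior.mean[free]
        # delta precision when pinning: 1/pinned - 1/v0 (> 0 for valid nesting)
        self.delta = 1.0 / PINNED_VARIANCE - 1.0 / self.v0
        self.b = np.linalg.solve(_nudge(self.S), self.m)  # P m
        self.prunable = prunable
        if prunable.size and not np.allclose(prior.mean[prunable], 0.0):
            raise ValueError("prunable parameters must have zero prior mean")
        loc = {int(g): k for k, g in enumerate(free)}
        self.free_pos = loc

    def delta_f(self, pruned_free: Sequence[int]) -> float:
        """Log-evidence change (vs full model) for pruning the given free-space set."""
        T = np.asarray(sorted(pruned_free), dtype=int)
        if T.size == 0:
            return 0.0
        D = self.delta[T]
        S_TT = self.S[np.ix_(T, T)]
        mT = self.m[T]
        Idt = np.eye(T.size)
        M1 = Idt + D[:, None] * S_TT  # I + D S_TT
        sign, ld1 = np.linalg.slogdet(M1)
        if sign <= 0:
            raise np.linalg.LinAlgError("invalid reduction (non-PD reduced precision)")
        w = np.linalg.solve(np.diag(1.0 / D) + S_TT, mT)
        logdet_terms = float(np.sum(np.log1p(D * self.v0[T]))) - float(ld1)
        quad = float(w @ mT)
        return 0.5 * logdet_terms - 0.5 * quad

    def reduced_posterior(self, pruned_free: Sequence[int]) -> Posterior:
        T = np.asarray(sorted(pruned_free), dtype=int)
        dF = self.delta_f(T)
        m_new = self.m.copy()
        S_new = self.S.copy()
        if T.size:
            D = self.delta[T]
            SU = self.S[:, T]
            core = np.linalg.inv(np.diag(1.0 / D) + self.S[np.ix_(T, T)])
            m_new = self.m - SU @ (core @ self.m[T])
            S_new = self.S - SU @ core @ SU.T
        P = len(self.names)
        M = self.post.mean.copy()
        Sg = np.zeros((P, P))
        M[self.free] = m_new
        Sg[np.ix_(self.free, self.free)] = _repair_psd(S_new)
        return Posterior(self.names, M, Sg, self.post.F + dF, {**self.post.settings})


def _nudge(S: np.ndarray) -> np.ndarray:
    # guards solve() against exactly singular posterior covariances
    eps = 1e-12 * max(float(np.trace(S)) / max(S.shape[0], 1), 1e-300)
    return S + eps * np.eye(S.shape[0])


def prunable_indices(space: ParameterSpace) -> np.ndarray:
    """Off-diagonal coupling parameters — the only ones the search may prune."""
    return space.a_indices


def greedy_search(
    post: Posterior,
    prior: PriorSpec,
    prunable: Optional[Sequence[int]] = None,
    max_sweeps: int = 512,
) -> List[ModelScore]:
    """Greedy Bayesian-model-reduction search over pruned couplings.

    Each sweep scores the removal of every remaining prunable parameter; all
    removals that do not decrease the model evidence are applied jointly
    (falling back to the best single removal if the joint model is worse).
    The search stops when no removal keeps the evidence from decreasing.
    Returns every model evaluated, sorted by evidence (best first); the full
    model has ``delta_f = 0`` exactly.
    """
    if prunable is None:
        space = getattr(prior, "space", None)
        prunable = prunable_indices(space) if space is not None else coupling_prunable(post.names)
    prunable = np.asarray(prunable, dtype=int)
    free = np.flatnonzero(prior.free)
    free_set = {int(g) for g in free}
    prunable = np.array([p for p in prunable if p in free_set], dtype=int)
    ctx = _SearchContext(post, prior, prunable)
    P = len(post.names)

    pos = ctx.free_pos
    evaluated: Dict[Tuple[int, ...], float] = {(): 0.0}
    current: Tuple[int, ...] = ()  # pruned set, in free-subspace indices
    current_df = 0.0
    for _ in range(max_sweeps):
        candidates = [pos[int(p)] for p in prunable if pos[int(p)] not in current]
        if not candidates:
            break
        gains = []
        for c in candidates:
            trial = tuple(sorted(current + (c,)))
            df = evaluated.get(trial)
            if df is None:
                df = ctx.delta_f(trial)
                evaluated[trial] = df
            gains.append((df - current_df, c, trial))
        keep = [(g, c, t) for g, c, t in gains if g >= -1e-9]
        if not keep:
            break
        if len(keep) > 1:
            joint = tuple(sorted(set(current) | {c for _, c, _ in keep}))
            df_joint = evaluated.get(joint)
            if df_joint is None:
                df_joint = ctx.delta_f(joint)
                evaluated[joint] = df_joint
            if df_joint - current_df >= -1e-9:
                current, current_df = joint, df_joint
                continue
        best = max(keep, key=lambda x: (x[0], -x[1]))
        current, current_df = best[2], evaluated[best[2]]

    def to_mask(pruned: Tuple[int, ...]) -> Tuple[bool, ...]:
        mask = [True] * P
        for c in pruned:
            mask[int(ctx.free[c])] = False
        return tuple(mask)

    scores = [
        ModelScore(to_mask(pruned), df, ctx) for pruned, df in evaluated.items()
    ]
    # evidence first; on ties prefer the more parsimonious (more pruned) model
    scores.sort(key=lambda s: (-s.delta_f, -len(s.pruned), s.pruned))
    return scores


# ---------------------------------------------------------------------------
# Bayesian model averaging
# ---------------------------------------------------------------------------

def bma(scores: Sequence[ModelScore], top_k: int = 256) -> Posterior:
    """Evidence-weighted moment-matched average of the best ``top_k`` models.

    Weights are softmax over delta-F; the averaged Gaussian matches the first
    two moments of the mixture.
    """
    if not scores:
        raise ValueError("no models to average")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    ranked = sorted(scores, key=lambda s: -s.delta_f)[: min(top_k, len(scores))]
    dfs = np.array([s.delta_f for s in ranked])
    w = np.exp(dfs - dfs.max())
    w = w / w.sum()
    posts = [s.reduced_posterior() for s in ranked]
    P = posts[0].P
    mbar = np.zeros(P)
    second = np.zeros((P, P))
    for wk, pk in zip(w, posts):
        mbar += wk * pk.mean
        second += wk * (pk.cov + np.outer(pk.mean, pk.mean))
    Sbar = second - np.outer(mbar, mbar)
    F = float(posts[0].F)
    return Posterior(
        posts[0].names, mbar, _repair_psd(Sbar), F,
        {**posts[0].settings, "bma_weights": w.tolist(), "bma_models": len(ranked)},
    )


# ---------------------------------------------------------------------------
# Parametric empirical Bayes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PEBResult:
    """Group posterior over design-effects beta (K covariates x P parameters)."""

    names: Tuple[str, ...]  # parameter names
    effect_names: Tuple[str, ...]  # design-matrix column names
    beta_mean: np.ndarray  # (K*P,) ordered effect-major: [effect0 params, effect1 params, ...]
    beta_cov: np.ndarray  # (K*P, K*P)
    log_precision: float  # between-subject log precision lambda
    F: float
    prior_mean: np.ndarray  # (K*P,) prior used for beta
    prior_var: np.ndarray

    def group_posterior(self) -> Posterior:
        """Posterior over the group-mean effect (first design column)."""
        P = len(self.names)
        idx = np.arange(P)
        return Posterior(
            self.names,
            self.beta_mean[idx],
            self.beta_cov[np.ix_(idx, idx)],
            self.F,
            {"level": "group", "log_precision": self.log_precision},
        )

    def group_prior(self) -> Tuple[np.ndarray, np.ndarray]:
        P = len(self.names)
        return self.prior_mean[:P].copy(), self.prior_var[:P].copy()


def peb_fit(
    subject_posteriors: Sequence[Posterior],
    X: Optional[np.ndarray] = None,
    effect_names: Optional[Sequence[str]] = None,
    prior_mean: Optional[np.ndarray] = None,
    prior_var: Optional[np.ndarray] = None,
    between_var_scale: float = 1.0 / 16.0,
    lambda_prior: Tuple[float, float] = (0.0, 4.0),
) -> PEBResult:
    """Hierarchical Gaussian model over subject parameters.

    Subject posteriors N(m_i, S_i) act as likelihoods for subject effects
    theta_i = (x_i kron I) beta + eps_i with eps_i ~ N(0, exp(-lambda) Q),
    Q = ``between_var_scale`` * diag(prior variance).  beta and lambda are
    estimated by maximizing the (Laplace) model evidence; the group posterior
    uses both the expected subject parameters and their uncertainty.

    ``X`` is the between-subject design (first column must be ones, the group
    mean; covariates should be mean-centered).  ``prior_mean``/``prior_var``
    default to zero mean and the first subject's recorded first-level scheme
    is not required: pass the first-level prior if available.
    """
    if not subject_posteriors:
        raise ValueError("need at least one subject posterior")
    N = len(subject_posteriors)
    P = subject_posteriors[0].P
    names = subject_posteriors[0].names
    for p in subject_posteriors:
        if p.names != names:
            raise ValueError("subject posteriors have inconsistent parameter names")
    if X is None:
        X = np.ones((N, 1))
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != N:
        raise ValueError(f"design matrix has {X.shape[0]} rows for {N} subjects")
    if not np.allclose(X[:, 0], 1.0):
        raise ValueError("first design column must be the group mean (ones)")
    K = X.shape[1]
    if np.linalg.matrix_rank(X) < K:
        # identify collinear columns via QR pivoting
        _, R = np.linalg.qr(X)
        bad = [int(i) for i in np.flatnonzero(np.abs(np.diag(R)) < 1e-10)]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    if effect_names is None:
        effect_names = ["mean"] + [f"cov{i}" for i in range(1, K)]
    effect_names = tuple(effect_names)

    if prior_var is None:
        prior_var = np.full(P, 1.0 / 64.0)
    prior_var = np.asarray(prior_var, float)
    if prior_mean is None:
        prior_mean = np.zeros(P)
    prior_mean = np.asarray(prior_mean, float)
    # beta prior: group-mean column inherits the first-level prior; covariate
    # effects are zero-centered with the same scale
    b0 = np.concatenate([prior_mean] + [np.zeros(P)] * (K - 1))
    v0 = np.concatenate([prior_var] * K)
    v0 = np.where(v0 > 0, v0, PINNED_VARIANCE)

    ms = [p.mean for p in subject_posteriors]
    Ss = [p.cov for p in subject_posteriors]
    Q = between_var_scale * np.where(prior_var > 0, prior_var, PINNED_VARIANCE)

    lam0, lam_var = lambda_prior

    def _fit_given_lambda(lam: float):
        Vb = np.exp(-lam) * Q
        Prec_i = []
        logdets = []
        for S in Ss:
            Ci = S + np.diag(Vb)
            Prec_i.append(np.linalg.inv(Ci))
            logdets.append(_logdet_psd(Ci))
        # posterior over beta
        Pi_b = np.diag(1.0 / v0).astype(float)
        rhs = Pi_b @ b0
        for i in range(N):
            xi = X[i]
            blk = np.kron(np.outer(xi, xi), Prec_i[i])
            Pi_b = Pi_b + blk
            rhs = rhs + np.kron(xi, Prec_i[i] @ ms[i])
        Sb = np.linalg.inv(Pi_b)
        mb = Sb @ rhs
        # Laplace evidence with beta integrated out
        quad = float(b0 @ (b0 / v0)) - float(mb @ Pi_b @ mb)
        for i in range(N):
            quad += float(ms[i] @ Prec_i[i] @ ms[i])
        F = -0.5 * sum(logdets) - 0.5 * N * P * np.log(2 * np.pi)
        F += -0.5 * float(np.sum(np.log(v0))) - 0.5 * _logdet_psd(Pi_b)
        F += -0.5 * quad
        F += -0.5 * (lam - lam0) ** 2 / lam_var - 0.5 * np.log(2 * np.pi * lam_var)
        return F, mb, Sb

    res = minimize_scalar(
        lambda l: -_fit_given_lambda(l)[0], bounds=(-8.0, 12.0), method="bounded",
        options={"xatol": 1e-3},
    )
    lam = float(res.x)
    F, mb, Sb = _fit_given_lambda(lam)
    return PEBResult(
        names=names,
        effect_names=effect_names,
        beta_mean=mb,
        beta_cov=_repair_psd(Sb),
        log_precision=lam,
        F=float(F),
        prior_mean=b0,
        prior_var=v0,
    )


def subject_conditional(
    peb: PEBResult, subject_posterior: Posterior, x_row: np.ndarray,
    between_var_scale: float = 1.0 / 16.0,
) -> Posterior:
    """Empirical-Bayes shrinkage: a subject's posterior under the group model.

    Combines the subject's first-level posterior with the group prediction
    (x_i kron I) beta-hat as a prior with the estimated between-subject
    variance; the result lies between the first-level mean and the group
    prediction coordinatewise in the diagonal-covariance approximation.
    """
    P = len(peb.names)
    x = np.asarray(x_row, float)
    pred = (np.kron(x, np.eye(P)) @ peb.beta_mean)
    prior_var = np.exp(-peb.log_precision) * between_var_scale * peb.prior_var[:P]
    S = subject_posterior.cov
    m = subject_posterior.mean
    Pi = np.linalg.inv(_nudge(S))
    Pi_g = np.diag(1.0 / prior_var)
    Sc = np.linalg.inv(Pi + Pi_g)
    mc = Sc @ (Pi @ m + Pi_g @ pred)
    return Posterior(peb.names, mc, _repair_psd(Sc), subject_posterior.F, {"level": "conditional"})


# ---------------------------------------------------------------------------
# Retention probabilities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RetentionMask:
    names: Tuple[str, ...]
    probability: np.ndarray  # posterior probability of the model WITH the parameter
    retained: np.ndarray  # bool
    threshold: float


def retention_mask(
    bma_post: Posterior,
    prior: PriorSpec,
    prunable: Optional[Sequence[int]] = None,
    threshold: float = 0.95,
) -> RetentionMask:
    """Per-parameter with-vs-without posterior probability via BMR.

    For each prunable parameter the evidence of the model without it is
    computed by pinning it; p(with) = 1 / (1 + exp(dF_without)).  Parameters
    with p > ``threshold`` are retained.  Non-prunable parameters are always
    retained with probability 1.
    """
    if prunable is None:
        space = getattr(prior, "space", None)
        prunable = prunable_indices(space) if space is not None else coupling_prunable(bma_post.names)
    prunable = np.asarray(prunable, dtype=int)
    free = np.flatnonzero(prior.free)
    free_set = {int(g) for g in free}
    ctx = _SearchContext(bma_post, prior, prunable)
    P = bma_post.P
    prob = np.ones(P)
    for p in prunable:
        if int(p) not in free_set:
            prob[p] = 0.0
            continue
        df_without = ctx.delta_f([ctx.free_pos[int(p)]])
        prob[p] = 1.0 / (1.0 + np.exp(np.clip(df_without, -500, 500)))
    return RetentionMask(
        names=bma_post.names,
        probability=prob,
        retained=prob > threshold,
        threshold=threshold,
    )
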