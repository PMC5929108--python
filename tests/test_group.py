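import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netdcm.group import (
    GaussianPrior,
    PINNED_VARIANCE,
    bma,
    bmr_reduce,
    greedy_search,
    peb_fit,
    retention_mask,
    subject_conditional,
)
from netdcm.inversion import Posterior

NAMES4 = ("A[b<-a]", "A[a<-b]", "A[c<-a]", "A[a<-c]")


def conjugate_problem(P, seed, n_shrink=None):
    """Linear-Gaussian regression with closed-form posterior and evidence.

    Independent oracle for BMR: the reduced model's posterior and evidence
    are computed by direct conjugate inversion under the reduced prior.
    """
    rng = np.random.default_rng(seed)
    Nd = 4 * P
    X = rng.normal(size=(Nd, P))
    sigma2 = 0.5
    y = X @ rng.normal(size=P) + rng.normal(0, np.sqrt(sigma2), Nd)
    m0 = rng.normal(0, 0.5, P)
    v0 = rng.uniform(0.5, 2.0, P)

    def invert(mean, var):
        Pi = X.T @ X / sigma2 + np.diag(1.0 / var)
        S = np.linalg.inv(Pi)
        m = S @ (X.T @ y / sigma2 + mean / var)
        C = np.diag(sigma2 * np.ones(Nd)) + X @ np.diag(var) @ X.T
        sign, ld = np.linalg.slogdet(C)
        resid = y - X @ mean
        logz = -0.5 * (Nd * np.log(2 * np.pi) + ld + resid @ np.linalg.solve(C, resid))
        return m, S, logz

    n_shrink = n_shrink if n_shrink is not None else max(1, P // 2)
    shrink = rng.choice(P, size=n_shrink, replace=False)
    mr = m0.copy()
    vr = v0.copy()
    mr[shrink] = 0.0
    vr[shrink] = rng.uniform(1e-6, 1e-3, n_shrink)
    return dict(m0=m0, v0=v0, mr=mr, vr=vr, invert=invert)


class TestBmrReduce:
    def test_identity_reduction_is_noop(self):
        prob = conjugate_problem(4, 0)
        m, S, _ = prob["invert"](prob["m0"], prob["v0"])
        post = Posterior(NAMES4, m, S, 0.0)
        red, dF = bmr_reduce(post, prob["m0"], np.diag(prob["v0"]), prob["m0"], np.diag(prob["v0"]))
        assert dF == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(red.mean, m, atol=1e-10)
        assert np.allclose(red.cov, S, atol=1e-10)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_direct_conjugate_inversion(self, seed):
        prob = conjugate_problem(4, seed)
        m, S, logz_full = prob["invert"](prob["m0"], prob["v0"])
        mr_direct, Sr_direct, logz_red = prob["invert"](prob["mr"], prob["vr"])
        post = Posterior(NAMES4, m, S, 0.0)
        red, dF = bmr_reduce(post, prob["m0"], np.diag(prob["v0"]), prob["mr"], np.diag(prob["vr"]))
        assert dF == pytest.approx(logz_red - logz_full, abs=1e-8)
        assert np.abs(red.mean - mr_direct).max() < 1e-8
        assert np.abs(red.cov - Sr_direct).max() < 1e-8

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(P=st.integers(2, 8), seed=st.integers(0, 10_000))
    def test_exactness_property(self, P, seed):
        prob = conjugate_problem(P, seed)
        m, S, logz_full = prob["invert"](prob["m0"], prob["v0"])
        _, _, logz_red = prob["invert"](prob["mr"], prob["vr"])
        post = Posterior(tuple(f"p{i}" for i in range(P)), m, S, 0.0)
        _, dF = bmr_reduce(post, prob["m0"], np.diag(prob["v0"]), prob["mr"], np.diag(prob["vr"]))
        assert dF == pytest.approx(logz_red - logz_full, abs=1e-7)

    def test_pinning_strong_parameter_penalized(self):
        # |M|/sd > 4: removing the parameter must lower the evidence
        m = np.array([0.5, 0.0])
        S = np.diag([0.005, 0.01])
        post = Posterior(("a", "b"), m, S, 0.0)
        m0 = np.zeros(2)
        V0 = np.diag([1 / 64, 1 / 64])
        mr = np.zeros(2)
        Vr = np.diag([PINNED_VARIANCE, 1 / 64])
        _, dF = bmr_reduce(post, m0, V0, mr, Vr)
        assert dF < 0


def make_group_posterior(mean, var_diag, names=NAMES4):
    return Posterior(tuple(names), np.asarray(mean, float), np.diag(var_diag), 0.0)


class TestGreedySearch:
    def test_uninformative_posterior_prunes_everything(self):
        prior = GaussianPrior(np.zeros(4), np.full(4, 1 / 64))
        post = make_group_posterior(np.zeros(4), np.full(4, 1 / 64))
        scores = greedy_search(post, prior)
        best = scores[0]
        assert best.delta_f >= 0
        assert len(best.pruned) == 4

    def test_full_model_has_zero_delta_f(self):
        prior = GaussianPrior(np.zeros(4), np.full(4, 1 / 64))
        post = make_group_posterior([0.2, 0.0, -0.15, 0.0], [0.001, 1 / 64, 0.001, 1 / 64])
        scores = greedy_search(post, prior)
        full = [s for s in scores if not s.pruned]
        assert len(full) == 1 and full[0].delta_f == 0.0

    def test_strong_parameters_survive_weak_pruned(self):
        prior = GaussianPrior(np.zeros(4), np.full(4, 1 / 64))
        post = make_group_posterior([0.2, 0.0, -0.15, 0.0], [0.001, 1 / 64, 0.001, 1 / 64])
        scores = greedy_search(post, prior)
        best = scores[0]
        assert set(best.pruned) == {1, 3}

    def test_final_model_not_worse_than_full(self):
        prior = GaussianPrior(np.zeros(4), np.full(4, 1 / 64))
        post = make_group_posterior([0.2, 0.01, -0.15, -0.02], [0.001, 0.01, 0.001, 0.01])
        scores = greedy_search(post, prior)
        assert scores[0].delta_f >= 0

    def test_reduced_posterior_matches_generic_bmr(self):
        # the fast search-path reduction equals the generic BMR formula
        prior = GaussianPrior(np.zeros(4), np.full(4, 1 / 64))
        rng = np.random.default_rng(0)
        L = rng.normal(0, 0.03, (4, 4))
        S = L @ L.T + 0.001 * np.eye(4)
        post = Posterior(NAMES4, np.array([0.2, 0.0, -0.1, 0.05]), S, 0.0)
        scores = greedy_search(post, prior)
        target = next(s for s in scores if s.pruned == (1,))
        red = target.reduced_posterior()
        mr = np.zeros(4)
        Vr = np.diag([1 / 64, PINNED_VARIANCE, 1 / 64, 1 / 64])
        ref, dF = bmr_reduce(post, np.zeros(4), np.diag(np.full(4, 1 / 64)), mr, Vr)
        assert target.delta_f == pytest.approx(dF, abs=1e-6)
        assert np.abs(red.mean - ref.mean).max() < 1e-6

    def test_sparse_truth_precision_recall(self, truth3):
        # end of the first-level chain: search on a strong-SNR posterior
        from conftest import invert_benchmark

        A = truth3.matrix
        post, sp, _, priors = invert_benchmark(truth3, T=4096, seed=13)
        conn = sp.a_indices
        sub = post.subset(conn)
        g_prior = GaussianPrior(priors.mean[conn], priors.variance[conn])
        scores = greedy_search(sub, g_prior)
        best = scores[0]
        retained = {sub.names[i] for i in range(6) if best.mask[i]}
        true_nonzero = {
            f"A[{truth3.regions.labels[i]}<-{truth3.regions.labels[j]}]"
            for i in range(3)
            for j in range(3)
            if i != j and abs(A[i, j]) >= 0.1
        }
        tp = len(retained & true_nonzero)
        precision = tp / max(len(retained), 1)
        recall = tp / len(true_nonzero)
        assert precision >= 0.8
        assert recall >= 0.8


class _StubScore:
    def __init__(self, delta_f, post):
        self.delta_f = delta_f
        self._post = post

    def reduced_posterior(self):
        return self._post


class TestBma:
    def test_single_model_unchanged(self):
        post = make_group_posterior([0.1, 0.2, 0.0, -0.1], np.full(4, 0.01))
        avg = bma([_StubScore(0.0, post)], top_k=256)
        assert np.allclose(avg.mean, post.mean)
        assert np.allclose(avg.cov, post.cov)

    def test_symmetric_pair_averages_to_zero_with_inflated_cov(self):
        m = np.array([0.3, -0.2, 0.1, 0.0])
        S = np.diag(np.full(4, 0.01))
        a = _StubScore(1.0, Posterior(NAMES4, m, S, 0.0))
        b = _StubScore(1.0, Posterior(NAMES4, -m, S, 0.0))
        avg = bma([a, b])
        assert np.allclose(avg.mean, 0, atol=1e-12)
        assert np.allclose(avg.cov, S + np.outer(m, m), atol=1e-12)

    def test_weights_match_brute_force_softmax(self):
        post = make_group_posterior(np.zeros(4), np.full(4, 0.01))
        dfs = [0.0, -1.3, -2.6, -7.1]
        avg = bma([_StubScore(d, post) for d in dfs], top_k=4)
        w = np.array(avg.settings["bma_weights"])
        brute = np.exp(dfs) / np.sum(np.exp(dfs))
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.abs(w - brute).max() < 1e-12

    def test_top_1_equals_best_model(self):
        prior = GaussianPrior(np.zeros(4), np.full(4, 1 / 64))
        post = make_group_posterior([0.2, 0.0, -0.15, 0.0], [0.001, 1 / 64, 0.001, 1 / 64])
        scores = greedy_search(post, prior)
        avg = bma(scores, top_k=1)
        best = scores[0].reduced_posterior()
        assert np.allclose(avg.mean, best.mean, atol=1e-12)
        assert np.allclose(avg.cov, best.cov, atol=1e-10)


class TestPeb:
    def test_single_subject_flat_prior_identity(self):
        rng = np.random.default_rng(0)
        m = rng.normal(0, 0.1, 4)
        S = np.diag(np.full(4, 0.01))
        post = Posterior(NAMES4, m, S, 0.0)
        res = peb_fit([post], prior_var=np.full(4, 1e6), between_var_scale=1e-8)
        assert np.abs(res.group_posterior().mean - m).max() < 1e-6

    def test_group_template_recovery(self, regions15, template15):
        # subject posteriors built directly around sampled truths
        from netdcm.inversion import ParameterSpace
        from netdcm.synthetic import sample_subject_A

        sp = ParameterSpace(regions15)
        conn = sp.a_and_self_indices
        names = tuple(sp.names[i] for i in conn)
        rng = np.random.default_rng(3)
        posts = []
        for i in range(20):
            truth = sample_subject_A(template15, 0.05, seed=100 + i)
            theta = sp.encode_template(truth.matrix)[conn]
            m = theta + rng.normal(0, 0.05, theta.size)
            posts.append(Posterior(names, m, np.diag(np.full(theta.size, 0.05**2)), 0.0))
        res = peb_fit(posts, prior_var=np.full(len(conn), 1 / 64))
        g = res.group_posterior()
        tmpl_theta = sp.encode_template(template15.matrix)[conn]
        off = np.array([nm.startswith("A[") for nm in names])
        corr = np.corrcoef(tmpl_theta[off], g.mean[off])[0, 1]
        assert corr >= 0.9
        from netdcm.stats import between_network_average

        avgs = between_network_average(g, regions15)
        from netdcm.synthetic import DEFAULT_BETWEEN_MEANS

        for (src, tgt), want in DEFAULT_BETWEEN_MEANS.items():
            got, _, _ = avgs.cell(src, tgt)
            assert np.sign(got) == np.sign(want)

    def test_null_covariate_is_harmless(self):
        rng = np.random.default_rng(1)
        N, P = 12, 4
        posts = [
            Posterior(NAMES4, rng.normal(0, 0.1, P), np.diag(np.full(P, 0.01)), 0.0)
            for _ in range(N)
        ]
        base = peb_fit(posts)
        cov = rng.standard_normal(N)
        X = np.column_stack([np.ones(N), cov - cov.mean()])
        with_cov = peb_fit(posts, X, effect_names=["mean", "null"])
        prior_sd = np.sqrt(1 / 64)
        shift = np.abs(with_cov.group_posterior().mean - base.group_posterior().mean)
        assert np.all(shift < 0.3 * prior_sd)

    def test_rank_deficient_design_rejected(self):
        posts = [
            Posterior(NAMES4, np.zeros(4), np.diag(np.full(4, 0.01)), 0.0)
            for _ in range(4)
        ]
        X = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(ValueError, match="collinear"):
            peb_fit(posts, X)

    def test_first_column_must_be_ones(self):
        posts = [Posterior(NAMES4, np.zeros(4), np.diag(np.full(4, 0.01)), 0.0)] * 2
        with pytest.raises(ValueError, match="ones"):
            peb_fit(posts, np.array([[2.0], [2.0]]))

    def test_shrinkage_between_subject_and_group(self):
        rng = np.random.default_rng(2)
        N, P = 10, 4
        posts = [
            Posterior(NAMES4, rng.normal(0.2, 0.05, P), np.diag(np.full(P, 0.02)), 0.0)
            for _ in range(N)
        ]
        res = peb_fit(posts)
        g = res.group_posterior().mean
        for p in posts:
            cond = subject_conditional(res, p, np.array([1.0]))
            lo = np.minimum(p.mean, g) - 1e-9
            hi = np.maximum(p.mean, g) + 1e-9
            assert np.all(cond.mean >= lo) and np.all(cond.mean <= hi)


class TestRetention:
    def test_uninformative_parameter_near_half(self):
        prior = GaussianPrior(np.zeros(4), np.full(4, 1 / 64))
        post = make_group_posterior(np.zeros(4), np.full(4, 1 / 64))
        res = retention_mask(post, prior)
        assert np.allclose(res.probability, 0.5, atol=1e-6)
        assert not res.retained.any()

    def test_strong_parameter_retained(self):
        prior = GaussianPrior(np.zeros(4), np.full(4, 0.1))
        mean = np.array([6 * np.sqrt(0.001), 0, 0, 0])
        post = make_group_posterior(mean, np.full(4, 0.001))
        res = retention_mask(post, prior)
        assert res.retained[0]

    def test_reordering_invariance(self):
        prior = GaussianPrior(np.zeros(4), np.full(4, 0.05))
        mean = np.array([0.3, 0.0, -0.2, 0.05])
        var = np.array([0.002, 0.05, 0.003, 0.01])
        post = make_group_posterior(mean, var)
        res = retention_mask(post, prior)
        perm = [2, 0, 3, 1]
        post_p = Posterior(
            tuple(NAMES4[i] for i in perm), mean[perm], np.diag(var[perm]), 0.0
        )
        res_p = retention_mask(post_p, prior)
        assert np.allclose(res_p.probability, res.probability[perm], atol=1e-10)
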