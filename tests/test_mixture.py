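"""EM fitting of MVB mixtures, BIC selection, and state assignment."""

import math
from itertools import permutations

import numpy as np
import pytest

from gammasync.errors import StarvedComponentError
from gammasync.mixture import (
    StateSequence,
    assign_states,
    bic,
    e_step,
    kmeans_beta_init,
    m_step,
    run_em,
    select_p,
    state_means,
)
from gammasync.mvb import MVBParams, mvb_loglik, mvb_mle, mvb_sample
from gammasync.simulate import gen_mixture_dataset


def match_components(fitted: list[MVBParams], truth: list[MVBParams]):
    """Best label permutation by total absolute theta error."""
    best = None
    for perm in permutations(range(len(truth))):
        err = sum(
            np.abs(fitted[perm[k]].theta - truth[k].theta).sum()
            for k in range(len(truth))
        )
        if best is None or err < best[0]:
            best = (err, perm)
    return best[1]


@pytest.fixture(scope="module")
def two_state_data():
    pis = np.array([0.3, 0.7])
    thetas = [
        MVBParams(theta=np.array([8.0, 2.0, 3.0])),
        MVBParams(theta=np.array([2.0, 9.0, 3.0])),
    ]
    U, labels = gen_mixture_dataset(pis, thetas, 3000, seed=7)
    return pis, thetas, U, labels


class TestESTep:
    def test_identical_components_share_responsibility(self):
        theta = MVBParams(theta=np.array([3.0, 2.0, 4.0]))
        U = mvb_sample(theta, 40, seed=0)
        r = e_step(U, np.array([0.5, 0.5]), [theta, theta])
        assert np.allclose(r, 0.5, atol=1e-14)

    def test_prior_dominance_with_identical_components(self):
        theta = MVBParams(theta=np.array([3.0, 2.0, 4.0]))
        U = mvb_sample(theta, 40, seed=1)
        r = e_step(U, np.array([1 - 1e-12, 1e-12]), [theta, theta])
        assert np.all(r[0] > 1 - 1e-9)

    def test_columns_sum_to_one(self):
        thetas = [
            MVBParams(theta=np.array([8.0, 2.0, 3.0])),
            MVBParams(theta=np.array([2.0, 9.0, 3.0])),
        ]
        U, _ = gen_mixture_dataset(np.array([0.4, 0.6]), thetas, 200, seed=2)
        r = e_step(U, np.array([0.4, 0.6]), thetas)
        assert np.allclose(r.sum(axis=0), 1.0, atol=1e-12)


class TestMStep:
    def test_hard_assignment_reduces_to_per_cluster_mle(self, two_state_data):
        _, _, U, labels = two_state_data
        U, labels = U[:400], labels[:400]
        resp = np.vstack([(labels == 1).astype(float), (labels == 2).astype(float)])
        pis, thetas = m_step(U, resp)
        assert pis == pytest.approx(
            [(labels == 1).mean(), (labels == 2).mean()], abs=1e-12
        )
        for k, lab in enumerate((1, 2)):
            direct = mvb_mle(U[labels == lab])
            assert np.allclose(thetas[k].theta, direct.theta, rtol=1e-4)

    def test_uniform_responsibilities_give_equal_components(self, two_state_data):
        _, _, U, _ = two_state_data
        U = U[:300]
        resp = np.full((3, 300), 1.0 / 3.0)
        _, thetas = m_step(U, resp)
        for k in (1, 2):
            assert np.allclose(thetas[0].theta, thetas[k].theta, rtol=1e-6)

    def test_soft_responsibilities_at_truth_recover_parameters(self, two_state_data):
        pis, thetas, U, _ = two_state_data
        resp = e_step(U, pis, thetas)
        _, fitted = m_step(U, resp)
        for k in range(2):
            rel = np.abs(fitted[k].theta - thetas[k].theta) / thetas[k].theta
            assert np.all(rel < 0.15)

    def test_starved_component_raises(self, two_state_data):
        _, _, U, _ = two_state_data
        U = U[:100]
        resp = np.vstack([np.full(100, 0.99), np.full(100, 0.01)])
        with pytest.raises(StarvedComponentError):
            m_step(U, resp)


class TestBIC:
    def test_direct_arithmetic(self):
        assert bic(0.0, 1, 4, 100) == pytest.approx(5 * math.log(100), abs=1e-12)
        assert bic(-500.0, 4, 4, 746) == pytest.approx(
            1000 + 23 * math.log(746), abs=1e-10
        )

    def test_penalty_increment_per_extra_state(self):
        J, n = 3, 500
        assert bic(-100.0, 4, J, n) - bic(-100.0, 3, J, n) == pytest.approx(
            (J + 2) * math.log(n), abs=1e-10
        )


class TestRunEM:
    def test_single_component_reduces_to_mle(self):
        theta = MVBParams(theta=np.array([3.0, 5.0, 2.0]))
        U = mvb_sample(theta, 800, seed=4)
        fit = run_em(U, 1, seed=0)
        assert fit.pis == pytest.approx([1.0], abs=1e-12)
        assert fit.loglik == pytest.approx(mvb_loglik(U, mvb_mle(U)), rel=1e-6)

    def test_two_component_recovery(self, two_state_data):
        pis, thetas, U, _ = two_state_data
        fit = run_em(U, 2, seed=0)
        perm = match_components(fit.thetas, thetas)
        assert np.all(np.abs(fit.pis[list(perm)] - pis) < 0.05)
        for k in range(2):
            rel = np.abs(fit.thetas[perm[k]].theta - thetas[k].theta) / thetas[k].theta
            assert np.all(rel < 0.20)

    def test_loglik_trace_nondecreasing(self, two_state_data):
        _, _, U, _ = two_state_data
        fit = run_em(U, 2, seed=0)
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs >= -1e-8 * np.abs(fit.loglik_trace[:-1]))
        assert fit.loglik >= fit.loglik_trace[0]

    def test_label_permutation_equivalence(self, two_state_data):
        _, _, U, _ = two_state_data
        pis0, thetas0 = kmeans_beta_init(U, 2, seed=0)
        f1 = run_em(U, 2, init=(pis0, thetas0), seed=0)
        f2 = run_em(U, 2, init=(pis0[::-1].copy(), thetas0[::-1]), seed=0)
        assert f1.loglik == pytest.approx(f2.loglik, rel=1e-8)
        perm = match_components(f2.thetas, f1.thetas)
        assert list(perm) == [1, 0]
        for k in range(2):
            assert np.allclose(f2.thetas[perm[k]].theta, f1.thetas[k].theta, rtol=1e-3)


class TestInitialization:
    def test_separable_clouds_recovered(self):
        rng = np.random.default_rng(0)
        a = 0.1 + 0.01 * rng.standard_normal((100, 2))
        b = 0.9 + 0.01 * rng.standard_normal((100, 2))
        U = np.clip(np.vstack([a, b]), 0.001, 0.999)
        pis, thetas = kmeans_beta_init(U, 2, seed=0)
        assert pis == pytest.approx([0.5, 0.5], abs=1e-12)
        means = sorted(t.theta[0] / (t.theta[0] + t.theta[2]) for t in thetas)
        assert means[0] == pytest.approx(0.1, abs=0.05)
        assert means[1] == pytest.approx(0.9, abs=0.05)

    def test_single_cluster_matches_global_fit(self, two_state_data):
        _, _, U, _ = two_state_data
        U = U[:500]
        pis, thetas = kmeans_beta_init(U, 1, seed=0)
        assert pis == pytest.approx([1.0], abs=1e-12)
        assert np.allclose(thetas[0].theta, mvb_mle(U).theta, rtol=1e-4)

    def test_init_quality_matches_best_random_start(self, two_state_data):
        _, _, U, _ = two_state_data
        f_km = run_em(U, 2, seed=0)
        rng = np.random.default_rng(99)
        best = -np.inf
        for i in range(10):
            init = (
                np.array([0.5, 0.5]),
                [MVBParams(theta=rng.uniform(0.5, 10.0, size=3)) for _ in range(2)],
            )
            best = max(best, run_em(U, 2, init=init, seed=100 + i).loglik)
        assert f_km.loglik >= best - 1e-3


class TestSelectP:
    def test_single_component_data_selects_one(self):
        U = mvb_sample(MVBParams(theta=np.array([3.0, 4.0, 2.0])), 1500, seed=5)
        best, bics = select_p(U, range(1, 5), seed=0)
        assert best.p == 1

    def test_u_shaped_bic_returns_argmin(self, two_state_data):
        _, _, U, _ = two_state_data
        best, bics = select_p(U, range(1, 4), seed=0)
        assert best.p == min(bics, key=bics.get)
        assert best.p == 2


class TestStates:
    def test_argmax_and_tie_rule(self):
        class FakeFit:
            resp = np.array([[0.1, 0.5], [0.7, 0.5], [0.1, 0.0], [0.1, 0.0]])

        seq = assign_states(FakeFit())
        assert list(seq.states) == [2, 1]

    def test_hard_responsibilities_pass_through(self, two_state_data):
        _, _, U, labels = two_state_data
        fit = run_em(U, 2, seed=0)
        hard = np.zeros_like(fit.resp)
        hard[fit.resp.argmax(axis=0), np.arange(fit.resp.shape[1])] = 1.0
        fit.resp = hard
        assert np.array_equal(assign_states(fit).states, hard.argmax(axis=0) + 1)

    def test_state_means_hand_computed(self):
        U = np.array([[0.2, 0.8], [0.4, 0.6], [0.6, 0.4], [0.8, 0.2]])
        seq = StateSequence(states=np.array([1, 1, 2, 2]))
        means, sds = state_means(U, seq)
        assert means[0] == pytest.approx([0.3, 0.7], abs=1e-12)
        assert means[1] == pytest.approx([0.7, 0.3], abs=1e-12)
        sd = np.sqrt(((0.2 - 0.3) ** 2 + (0.4 - 0.3) ** 2) / 1)
        assert sds[0] == pytest.approx([sd, sd], abs=1e-12)

    def test_duplicated_rows_leave_moments_unchanged(self):
        rng = np.random.default_rng(6)
        U = np.clip(rng.uniform(0.1, 0.9, size=(20, 3)), 0.001, 0.999)
        seq1 = StateSequence(states=np.tile([1, 2], 10))
        m1, s1 = state_means(U, seq1)
        seq2 = StateSequence(states=np.tile([1, 2], 20))
        m2, s2 = state_means(np.vstack([U, U]), seq2)
        assert np.allclose(m1, m2)
        # ddof=1 shifts slightly under duplication; moments agree closely
        assert np.allclose(s1, s2, rtol=0.05)

    def test_all_rows_one_state_gives_global_moments(self):
        rng = np.random.default_rng(7)
        U = np.clip(rng.uniform(0.1, 0.9, size=(30, 2)), 0.001, 0.999)
        means, sds = state_means(U, StateSequence(states=np.ones(30, dtype=int)))
        assert means[0] == pytest.approx(U.mean(axis=0), abs=1e-12)
        assert sds[0] == pytest.approx(U.std(axis=0, ddof=1), abs=1e-12)

    def test_recovered_state_means_cross_coupling_threshold_correctly(self):
        """A state coupled on channels {1,2} crosses 0.6 exactly there."""
        thA = MVBParams(theta=np.array([10.0, 10.0, 2.0, 2.0, 3.0]))
        thB = MVBParams(theta=np.array([2.0, 2.0, 2.0, 2.0, 3.0]))
        U, _ = gen_mixture_dataset(np.array([0.5, 0.5]), [thA, thB], 2000, seed=11)
        fit = run_em(U, 2, seed=0)
        means, _ = state_means(U, assign_states(fit))
        coupled = means[means[:, 0].argmax()]
        uncoupled = means[means[:, 0].argmin()]
        assert np.array_equal(coupled > 0.6, [True, True, False, False])
        assert np.all(uncoupled < 0.6)
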