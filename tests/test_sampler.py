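import math

import numpy as np
import pytest

import trailmc as tm
from trailmc.grids import GridDistribution
from trailmc.sampler import (
    ChainConfig, MemoryModel, WalkerState, acceptance_ratio, cleaning_schedule,
    propose, run_chain, step, transition_matrix, visit_distribution,
)


@pytest.fixture
def p3x3():
    rng = np.random.default_rng(5)
    return GridDistribution(rng.dirichlet(np.ones(9)).reshape(3, 3))


def reference_transition_matrix(pv: np.ndarray, weights: np.ndarray, trail: bool):
    """Independent enumeration of single-step transition probabilities."""
    n_rows, n_cols = pv.shape
    n = pv.size
    T = np.zeros((n, n))
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    nr, nc = (r + dr) % n_rows, (c + dc) % n_cols
                    j = nr * n_cols + nc
                    pc, pp = pv[r, c], pv[nr, nc]
                    if pc > 0 and pp > 0:
                        if trail:
                            ratio = (pp ** 2 * weights[r, c]) / (pc ** 2 * weights[nr, nc])
                        else:
                            ratio = pp / pc
                    elif pc == 0 and pp == 0:
                        ratio = 1.0
                    elif pc == 0:
                        ratio = math.inf
                    else:
                        ratio = 0.0
                    a = min(1.0, ratio)
                    T[i, j] += a / 9.0
                    T[i, i] += (1.0 - a) / 9.0
    return T


class TestPropose:
    def test_periodic_wrap_from_corner(self):
        rng = np.random.default_rng(0)
        seen = {(propose(WalkerState(0, 0), rng, 5, 5).row,
                 propose(WalkerState(0, 0), rng, 5, 5).col) for _ in range(500)}
        # all 9 Moore cells around (0,0) on a 5x5 torus, including (4,4)
        assert seen == {(r % 5, c % 5) for r in (-1, 0, 1) for c in (-1, 0, 1)}

    def test_all_nine_moves_equiprobable(self):
        rng = np.random.default_rng(1)
        counts = {}
        n = 90_000
        for _ in range(n):
            s = propose(WalkerState(2, 2), rng, 5, 5)
            counts[(s.row, s.col)] = counts.get((s.row, s.col), 0) + 1
        freqs = np.array(list(counts.values())) / n
        assert len(counts) == 9
        assert np.all(np.abs(freqs - 1 / 9) < 0.005)


class TestAcceptanceRatio:
    def test_squared_objective_doubles_to_four(self):
        # a cell of mass 0.2 is 4x as attractive as one of mass 0.1
        p = GridDistribution(np.array([[0.2, 0.1], [0.3, 0.4]]))
        m = MemoryModel((2, 2), alpha=1.0)
        ratio = acceptance_ratio(p, m, WalkerState(0, 1), WalkerState(0, 0), "trail")
        assert ratio == 4.0

    def test_self_move_ratio_is_one(self, p3x3):
        m = MemoryModel((3, 3), alpha=2.0,
                        deposits=np.random.default_rng(0).gamma(1, 1, (3, 3)))
        s = WalkerState(1, 1)
        assert acceptance_ratio(p3x3, m, s, s, "trail") == 1.0
        assert acceptance_ratio(p3x3, m, s, s, "plain_mh") == 1.0

    def test_memory_weighted_ratio_hand_value(self):
        # P(prop)=0.1, P(curr)=0.2, M(prop)=1, M(curr)=2 -> 0.5*(0.1/1)/(0.2/2)
        p = GridDistribution(np.array([[0.1, 0.2], [0.3, 0.4]]))
        m = MemoryModel((2, 2), alpha=1.0,
                        deposits=np.array([[0.0, 1.0], [0.0, 0.0]]))
        ratio = acceptance_ratio(p, m, WalkerState(0, 1), WalkerState(0, 0), "trail")
        assert ratio == pytest.approx(0.5, abs=1e-15)

    def test_invariant_under_power_of_two_memory_rescale(self, p3x3):
        rng = np.random.default_rng(3)
        dep = rng.gamma(1.0, 2.0, (3, 3))
        m = MemoryModel((3, 3), alpha=1.0, deposits=dep)
        m8 = MemoryModel((3, 3), alpha=8.0, deposits=8.0 * dep)
        for r in range(3):
            for c in range(3):
                a = acceptance_ratio(p3x3, m, WalkerState(1, 1), WalkerState(r, c))
                b = acceptance_ratio(p3x3, m8, WalkerState(1, 1), WalkerState(r, c))
                assert a == b  # exact: the global scale cancels

    def test_zero_support_rules(self):
        p = GridDistribution(np.array([[0.0, 0.0], [0.0, 1.0]]))
        m = MemoryModel((2, 2), alpha=1.0)
        # null -> null: free diffusion
        assert acceptance_ratio(p, m, WalkerState(0, 0), WalkerState(0, 1)) == 1.0
        # null -> positive: always escape
        assert acceptance_ratio(p, m, WalkerState(0, 0), WalkerState(1, 1)) == math.inf
        # positive -> null: never accept
        assert acceptance_ratio(p, m, WalkerState(1, 1), WalkerState(0, 0)) == 0.0


class TestTransitionOracle:
    @pytest.mark.parametrize("variant,trail", [("plain_mh", False), ("trail", True)])
    def test_matches_enumeration_oracle(self, p3x3, variant, trail):
        rng = np.random.default_rng(7)
        m = MemoryModel((3, 3), alpha=1.0, deposits=rng.gamma(1.0, 2.0, (3, 3)))
        impl = transition_matrix(p3x3, m, variant)
        ref = reference_transition_matrix(p3x3.values, m.weights, trail)
        assert np.abs(impl - ref).max() < 1e-12
        assert np.allclose(impl.sum(axis=1), 1.0, atol=1e-12)

    def test_infinite_decay_recovers_mh_on_p_squared(self, p3x3):
        # with the memory collapsed to the prior, trail == plain M-H on P^2
        prior = MemoryModel((3, 3), alpha=1.0)
        p2 = GridDistribution(p3x3.values ** 2 / (p3x3.values ** 2).sum())
        assert np.abs(transition_matrix(p3x3, prior, "trail")
                      - transition_matrix(p2, prior, "plain_mh")).max() < 1e-12

    def test_frozen_memory_stationary_distribution_is_p_squared(self):
        # 1x3 target (0.5, 0.3, 0.2): stationary of frozen-M trail chain
        # must be P^2 renormalized = (0.658, 0.237, 0.105)
        p = GridDistribution(np.array([[0.5, 0.3, 0.2]]))
        T = transition_matrix(p, MemoryModel((1, 3), alpha=1.0), "trail")
        w, v = np.linalg.eig(T.T)
        pi = np.real(v[:, np.argmax(np.real(w))])
        pi /= pi.sum()
        assert np.allclose(pi, [0.658, 0.237, 0.105], atol=5e-4)
        # empirical frequencies of the frozen chain agree
        cfg = ChainConfig(variant="trail", n_steps=200_000, seed=3, freeze_memory=True)
        emp = run_chain(p, cfg).visit_counts().ravel() / 200_000
        assert np.abs(emp - pi).max() < 0.01


class TestStep:
    def test_single_deposit_lands_on_post_decision_cell(self):
        p = GridDistribution.uniform(2, 2)
        m = MemoryModel((2, 2), alpha=1.0)
        rng = np.random.default_rng(0)
        new = step(p, m, WalkerState(0, 0), rng)
        assert m.total == pytest.approx(5.0)
        assert m.weight(new.row, new.col) == pytest.approx(2.0)
        assert np.sort(m.weights.ravel()).tolist() == pytest.approx([1, 1, 1, 2])

    def test_decisions_identical_under_memory_rescale(self, p3x3):
        # x8-scaled memory (exact in floats): same seed, same path
        rng_a = np.random.default_rng(11)
        rng_b = np.random.default_rng(11)
        dep = np.random.default_rng(4).gamma(1.0, 1.0, (3, 3))
        m_a = MemoryModel((3, 3), alpha=1.0, deposits=dep.copy())
        m_b = MemoryModel((3, 3), alpha=8.0, deposits=8.0 * dep)
        s_a = s_b = WalkerState(0, 0)
        for _ in range(200):
            s_a = step(p3x3, m_a, s_a, rng_a, freeze_memory=True)
            s_b = step(p3x3, m_b, s_b, rng_b, freeze_memory=True)
            assert (s_a.row, s_a.col) == (s_b.row, s_b.col)


class TestRunChain:
    def test_zero_steps_leaves_prior(self, p3x3):
        trace = run_chain(p3x3, ChainConfig(n_steps=0, seed=1))
        assert len(trace) == 0
        assert trace.ce_curve == []
        assert trace.final_memory.deposits.sum() == 0.0

    def test_replay_is_bit_identical(self, p3x3):
        cfg = ChainConfig(n_steps=5000, seed=9, ce_snapshot_interval=1000)
        a = run_chain(p3x3, cfg)
        b = run_chain(p3x3, cfg)
        assert np.array_equal(a.states, b.states)
        assert a.ce_curve == b.ce_curve
        assert np.array_equal(a.final_memory.deposits, b.final_memory.deposits)

    def test_cleaning_resets_deposits_to_prior(self, p3x3):
        trace = run_chain(p3x3, ChainConfig(n_steps=100, seed=1, cleaning_times=(100,)))
        assert trace.final_memory.deposits.sum() == 0.0

    def test_cleaning_time_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ChainConfig(n_steps=100, cleaning_times=(101,))

    def test_deposit_count_matches_steps(self, p3x3):
        n = 3000
        trace = run_chain(p3x3, ChainConfig(n_steps=n, seed=2))
        # with lambda=0 and no resets: total = alpha*n_cells + n deposits
        assert trace.final_memory.total == pytest.approx(9 + n)
        assert np.array_equal(trace.final_memory.deposits, trace.visit_counts())

    def test_decay_shrinks_old_deposits(self, p3x3):
        lam = 0.01
        trace = run_chain(p3x3, ChainConfig(n_steps=2000, seed=2, decay_lambda=lam))
        excess = trace.final_memory.deposits.sum()
        # geometric series bound: sum_{k=0..n-1} e^{-lam k} < 1/(1-e^-lam)
        assert excess < 1.0 / (1.0 - math.exp(-lam)) + 1e-9
        assert excess > 1.0  # most recent deposits barely decayed

    def test_cleaning_schedule_five_resets(self):
        assert cleaning_schedule(60_000, 5) == (10_000, 20_000, 30_000, 40_000, 50_000)

    def test_fixed_start_state_respected(self):
        p = GridDistribution.uniform(5, 5)
        trace = run_chain(p, ChainConfig(n_steps=1, seed=0, start=WalkerState(2, 2)))
        # after one step the walker is inside the Moore neighbourhood of the start
        assert abs(int(trace.states[0, 0]) - 2) <= 1
        assert abs(int(trace.states[0, 1]) - 2) <= 1


class TestVisitDistribution:
    def test_no_visits_with_smoothing_is_uniform(self, p3x3):
        trace = run_chain(p3x3, ChainConfig(n_steps=0, seed=0))
        d = visit_distribution(trace, smoothing_alpha=1.0)
        assert np.allclose(d.values, 1 / 9)

    def test_no_visits_without_smoothing_errors(self, p3x3):
        trace = run_chain(p3x3, ChainConfig(n_steps=0, seed=0))
        with pytest.raises(ValueError):
            visit_distribution(trace, smoothing_alpha=0.0)

    def test_smoothed_counts_hand_value(self):
        p = GridDistribution(np.array([[0.6, 0.2, 0.2]]))
        trace = run_chain(p, ChainConfig(n_steps=4, seed=0))
        counts = trace.visit_counts()
        d = visit_distribution(trace, smoothing_alpha=1.0)
        assert np.allclose(d.values, (counts + 1) / (counts + 1).sum())


class TestConvergence:
    def test_plain_mh_visit_distribution_converges_to_target(self):
        # CE of the smoothed sample vs P approaches H(P) on a 10x10 target
        target = tm.sparse_gamma_target(tm.SparseTargetConfig(10, 10, 0.5, seed=7))
        h = tm.entropy(target)
        cfg = ChainConfig(variant="plain_mh", n_steps=200_000, seed=0,
                          ce_snapshot_interval=200_000)
        ce = run_chain(target, cfg).ce_curve[-1][1]
        assert ce - h < 0.05

    def test_trail_memory_converges_toward_target(self):
        # the externalized memory M itself approaches P: CE(P, M) gap
        # shrinks by far more than half over the run
        target = tm.sparse_gamma_target(tm.SparseTargetConfig(10, 10, 0.5, seed=7))
        h = tm.entropy(target)
        ce0 = tm.cross_entropy(target, GridDistribution.uniform(10, 10))
        cfg = ChainConfig(variant="trail", n_steps=200_000, seed=0,
                          ce_snapshot_interval=200_000, ce_estimator="memory")
        cef = run_chain(target, cfg).ce_curve[-1][1]
        assert (ce0 - cef) / (ce0 - h) >= 0.5
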