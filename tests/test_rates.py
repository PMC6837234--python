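import dendropy
import numpy as np
import pytest
from scipy.linalg import expm

import kinrates as kr
from kinrates.rates import (
    ChainSchedule,
    ExponentialPrior,
    UniformPrior,
    build_q,
    empirical_frequencies,
    gelman_rubin,
    global_rate,
    mcmc_rate,
    mcmc_rate_joint,
    pruning_loglik,
    scale_rate,
    stepping_stone,
    stepping_stone_betas,
    summarize,
    transition_matrix,
    validate_q,
)
from kinrates.types import MultistateCharacter, ValidationError


def _char(meaning, states):
    return MultistateCharacter(meaning, states)


def _random_pi(rng, k):
    v = rng.dirichlet(np.ones(k) * 2)
    v = np.maximum(v, 1e-3)
    return v / v.sum()


class TestSchedule:
    def test_invariants_enforced(self):
        with pytest.raises(ValidationError):
            ChainSchedule(100, 100, 1)
        with pytest.raises(ValidationError):
            ChainSchedule(100, 10, 7)  # 90 not divisible by 7
        with pytest.raises(ValidationError):
            ChainSchedule(100, 10, 0)

    def test_draw_count(self):
        assert ChainSchedule(110_000, 10_000, 100).n_draws == 1_000


class TestEmpiricalFrequencies:
    def test_half_half(self):
        pi = empirical_frequencies(_char("x", {"A": 0, "B": 0, "C": 1, "D": 1}))
        np.testing.assert_allclose(pi, [0.5, 0.5])

    def test_constant(self):
        pi = empirical_frequencies(_char("x", {"A": 0, "B": 0, "C": 0}))
        np.testing.assert_allclose(pi, [1.0])

    def test_grandfather_terms_three_classes(self):
        pi = empirical_frequencies(
            _char("FF", {"English": 0, "Swedish": 1, "Polish": 2})
        )
        np.testing.assert_allclose(pi, [1 / 3, 1 / 3, 1 / 3])

    def test_all_missing_rejected(self):
        with pytest.raises(ValidationError):
            empirical_frequencies(_char("x", {"A": None}))


class TestQMatrix:
    def test_two_state_half(self):
        q = build_q(np.array([0.5, 0.5]), 1.0)
        np.testing.assert_allclose(q, [[-0.5, 0.5], [0.5, -0.5]])

    @pytest.mark.parametrize("seed", range(5))
    def test_rows_sum_zero_and_stationarity(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        pi = _random_pi(rng, k)
        mu = float(rng.uniform(0.1, 5))
        q = build_q(pi, mu)
        validate_q(q)
        np.testing.assert_allclose(q.sum(axis=1), 0.0, atol=1e-12)
        # pi is stationary: pi Q = 0
        np.testing.assert_allclose(pi @ q, np.zeros(k), atol=1e-12)

    def test_k1_degenerate(self):
        q = build_q(np.array([1.0]), 2.0)
        assert q.shape == (1, 1) and q[0, 0] == 0.0


class TestGlobalRate:
    def test_two_state_hand_value(self):
        pi = np.array([0.5, 0.5])
        assert global_rate(build_q(pi, 1.0), pi) == pytest.approx(0.5)

    @pytest.mark.parametrize("k", [2, 3, 5, 10])
    def test_uniform_closed_form(self, k):
        pi = np.full(k, 1 / k)
        mu = 2.5
        assert global_rate(build_q(pi, mu), pi) == pytest.approx(mu * (1 - 1 / k))

    def test_degenerate_frequencies_give_zero_flux(self):
        # all mass on one state: no observable replacement
        pi = np.array([1.0, 0.0])
        q = np.array([[0.0, 0.0], [3.0, -3.0]])
        assert global_rate(q, pi) == 0.0

    def test_scale_rate_exact(self):
        assert scale_rate(1e-4) == pytest.approx(1.0)
        assert scale_rate(0.0) == 0.0
        assert scale_rate(3.7) / 1e4 == pytest.approx(3.7)  # exact inverse


class TestTransitionMatrix:
    def test_t0_identity(self):
        pi = np.array([0.2, 0.3, 0.5])
        np.testing.assert_allclose(transition_matrix(pi, 1.0, 0.0), np.eye(3))

    def test_infinite_time_rows_equal_pi(self):
        pi = np.array([0.2, 0.3, 0.5])
        p = transition_matrix(pi, 1.0, 1e9)
        for row in p:
            np.testing.assert_allclose(row, pi, atol=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            transition_matrix(np.array([0.5, 0.5]), 1.0, -1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_matrix_exponential(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        pi = _random_pi(rng, k)
        mu = float(rng.uniform(0.05, 3))
        t = float(rng.uniform(0, 5))
        p = transition_matrix(pi, mu, t)
        np.testing.assert_allclose(p, expm(build_q(pi, mu) * t), atol=1e-10)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_chapman_kolmogorov(self, seed):
        rng = np.random.default_rng(100 + seed)
        pi = _random_pi(rng, 3)
        mu, s, t = rng.uniform(0.1, 2, 3)
        lhs = transition_matrix(pi, mu, s) @ transition_matrix(pi, mu, t)
        rhs = transition_matrix(pi, mu, s + t)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)


class TestPruningLoglik:
    def test_single_leaf_gives_log_pi(self):
        tree = dendropy.Tree.get(data="(A:100);", schema="newick")
        pi = np.array([0.3, 0.7])
        ll = pruning_loglik(tree, _char("x", {"A": 1}), pi, 0.01)
        assert ll == pytest.approx(np.log(0.7))

    def test_two_leaf_closed_form(self):
        tree = dendropy.Tree.get(data="(A:2,B:3);", schema="newick")
        pi = np.array([0.4, 0.6])
        mu = 0.3
        p = lambda i, j, t: pi[j] + ((i == j) - pi[j]) * np.exp(-mu * t)
        expected = sum(pi[i] * p(i, 0, 2.0) * p(i, 0, 3.0) for i in range(2))
        ll = pruning_loglik(tree, _char("x", {"A": 0, "B": 0}), pi, mu)
        assert ll == pytest.approx(np.log(expected), rel=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_oracle(self, seed, loglik_oracle):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 6))
        k = int(rng.integers(2, 5))
        tree = kr.simulate_tree(n, float(rng.uniform(0.5, 5)), seed=seed)
        pi = _random_pi(rng, k)
        mu = float(rng.uniform(0.05, 2))
        taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
        states = {
            t: (None if rng.random() < 0.15 else int(rng.integers(k))) for t in taxa
        }
        if all(s is None for s in states.values()):
            states[taxa[0]] = 0
        # densify observed states (character invariant); pi stays length k
        relabel = {}
        for t in taxa:
            if states[t] is not None and states[t] not in relabel:
                relabel[states[t]] = len(relabel)
        states = {t: (None if s is None else relabel[s]) for t, s in states.items()}
        char = _char("x", states)
        ours = pruning_loglik(tree, char, pi, mu)
        oracle = loglik_oracle(tree, char, pi, mu)
        assert ours == pytest.approx(oracle, rel=1e-10)

    def test_invariant_to_state_relabelling(self):
        rng = np.random.default_rng(5)
        tree = kr.simulate_tree(6, 3.0, seed=5)
        taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
        states = {t: int(rng.integers(3)) for t in taxa}
        pi = _random_pi(rng, 3)
        perm = np.array([2, 0, 1])
        states_p = {t: int(perm[s]) for t, s in states.items()}
        pi_p = np.empty(3)
        pi_p[perm] = pi
        a = pruning_loglik(tree, _char("x", states), pi, 0.4)
        b = pruning_loglik(tree, _char("x", states_p), pi_p, 0.4)
        assert a == pytest.approx(b, rel=1e-12)


class TestMcmc:
    def test_prior_only_reproduces_prior_moments(self, tree47):
        """With the likelihood switched off the chain must sample the prior:
        mean and variance of mu match exponential(1) within 3 sigma MC error."""
        char, _ = kr.simulate_character(tree47, 1.0, seed=0, meaning="x")
        schedule = ChainSchedule(1_010_000, 10_000, 100)  # 10,000 draws
        post = mcmc_rate(char, tree47, schedule=schedule, seed=1, power=0.0)
        n = len(post.mu)
        # crude ESS guard: thinned every 100, treat draws as weakly dependent
        se_mean = 1.0 / np.sqrt(n / 5)
        assert abs(post.mu.mean() - 1.0) < 3 * se_mean
        assert abs(post.mu.var() - 1.0) < 10 * se_mean

    def test_constant_character_rates_zero(self, tree47):
        char = _char("x", {l.taxon.label: 0 for l in tree47.leaf_node_iter()})
        post = mcmc_rate(char, tree47, schedule=kr.TEST_SCHEDULE, seed=2)
        assert np.all(post.rates >= 0)
        assert np.all(post.rates == 0)  # k=1: no observable flux

    def test_seeded_determinism(self, tree47):
        char, _ = kr.simulate_character(tree47, 2.0, seed=3, meaning="x")
        a = mcmc_rate(char, tree47, schedule=kr.TEST_SCHEDULE, seed=9)
        b = mcmc_rate(char, tree47, schedule=kr.TEST_SCHEDULE, seed=9)
        np.testing.assert_array_equal(a.rates, b.rates)
        np.testing.assert_array_equal(a.tree_index, b.tree_index)

    def test_tree_sample_modes_run(self, tree47):
        char, _ = kr.simulate_character(tree47, 2.0, seed=4, meaning="x")
        sample = kr.jitter_tree_sample(tree47, 5, 0.1, seed=4)
        small = ChainSchedule(20_000, 5_000, 50)
        for scheme in ("random", "sequential"):
            post = mcmc_rate(char, sample, schedule=small, seed=5, tree_scheme=scheme)
            assert len(post.rates) == small.n_draws
            assert post.tree_index.max() < 5

    def test_joint_replicates_recover_truth(self, tree47):
        """50 replicate characters at true R=2 analysed jointly under the
        equal-frequency model: posterior mean within 15% of truth."""
        rng = np.random.default_rng(30)
        chars = [
            kr.simulate_character(
                tree47, 2.0, seed=int(rng.integers(2**31)), meaning="x"
            )[0]
            for _ in range(50)
        ]
        post = mcmc_rate_joint(
            chars, tree47, schedule=ChainSchedule(30_000, 5_000, 25),
            seed=31, pi_mode="uniform",
        )
        assert abs(post.mean - 2.0) / 2.0 < 0.15


class TestSteppingStone:
    def test_beta_ladder(self):
        betas = stepping_stone_betas(100)
        assert betas[0] == 0.0 and betas[-1] == 1.0
        assert np.all(np.diff(betas) > 0)
        # Beta(0.3, 1) quantiles: (k/K)^(1/0.3)
        assert betas[50] == pytest.approx(0.5 ** (1 / 0.3))

    def test_flat_likelihood_gives_zero(self, tree47):
        # k=1 character: likelihood identically 1, so log ml must be 0
        char = _char("x", {l.taxon.label: 0 for l in tree47.leaf_node_iter()})
        res = stepping_stone(char, tree47, n_stones=20, iters_per_stone=200, seed=6)
        assert res.log_ml == pytest.approx(0.0, abs=1e-12)

    def test_matches_quadrature_oracle(self):
        """1-D rate problem on a fixed tree: stepping-stone agrees with
        adaptive quadrature of the marginal likelihood within 0.1 log units."""
        from scipy.integrate import quad
        from kinrates.rates import YEARS_PER_UNIT

        tree = kr.simulate_tree(10, 8700, seed=1)
        char, _ = kr.simulate_character(tree, 2.0, seed=2, meaning="B")
        pi = empirical_frequencies(char)

        def integrand(mu10k):
            return np.exp(
                pruning_loglik(tree, char, pi, mu10k / YEARS_PER_UNIT) - mu10k
            )

        val, err = quad(integrand, 0, 80, limit=300)
        assert err < 1e-8
        res = stepping_stone(char, tree, seed=7)
        assert abs(res.log_ml - np.log(val)) < 0.1

    def test_two_seeds_agree(self):
        tree = kr.simulate_tree(10, 8700, seed=1)
        char, _ = kr.simulate_character(tree, 2.0, seed=2, meaning="B")
        a = stepping_stone(char, tree, seed=10)
        b = stepping_stone(char, tree, seed=11)
        assert abs(a.log_ml - b.log_ml) < 0.15


class TestGelmanRubin:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = [rng.normal(size=10_000) for _ in range(3)]
        rep = gelman_rubin(chains)
        assert 0.999 <= rep.psrf <= 1.05  # sampling noise can dip a hair below 1
        assert rep.passed

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 5_000)
        b = rng.normal(10, 1, 5_000)
        rep = gelman_rubin([a, b])
        assert rep.psrf > 1.1 * 3
        assert not rep.passed
        # analytic: split halves have means 0,0,10,10 -> between-half variance
        # n*100/3, within ~ 1, so PSRF ~ sqrt(1 + 100/3)
        assert rep.psrf == pytest.approx(np.sqrt(1 + 100 / 3), rel=0.1)

    def test_single_chain_rejected(self):
        with pytest.raises(ValidationError):
            gelman_rubin([np.zeros(10)])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            gelman_rubin([np.zeros(10), np.zeros(11)])

    def test_agrees_with_arviz_direction(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            import arviz as az
        rng = np.random.default_rng(2)
        good = np.stack([rng.normal(size=4_000) for _ in range(3)])
        bad = np.stack([rng.normal(5 * i, 1, 4_000) for i in range(3)])
        assert gelman_rubin(list(good)).passed == (float(az.rhat(good)) < 1.1)
        assert gelman_rubin(list(bad)).passed == (float(az.rhat(bad)) < 1.1)


class TestSummarize:
    def _post(self, draws, meaning="x", seed=0):
        sched = ChainSchedule(len(draws) * 10 + 1000, 1000, 10)
        return kr.RatePosterior(
            meaning=meaning,
            rates=np.asarray(draws, dtype=float),
            mu=np.asarray(draws, dtype=float),
            tree_index=np.zeros(len(draws), dtype=int),
            loglik=np.zeros(len(draws)),
            seed=seed,
            schedule=sched,
            acceptance=0.3,
            step=0.5,
            pi=np.array([0.5, 0.5]),
        )

    def test_symmetric_posterior_mean_equals_median(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(5, 1, 9_000).clip(min=0)
        s = summarize([self._post(draws)])
        assert s.mean == pytest.approx(np.median(draws), abs=0.05)

    def test_constant_draws_zero_width_interval(self):
        s = summarize([self._post(np.full(1000, 2.0))])
        assert s.ci_low == s.ci_high == 2.0

    def test_chain_order_invariance(self):
        rng = np.random.default_rng(4)
        a = self._post(rng.gamma(2, 1, 2_000))
        b = self._post(rng.gamma(2, 1, 2_000))
        s1 = summarize([a, b])
        s2 = summarize([b, a])
        assert (s1.mean, s1.ci_low, s1.ci_high) == (s2.mean, s2.ci_low, s2.ci_high)

    def test_nonconverged_chains_warn(self):
        a = self._post(np.full(1000, 1.0))
        b = self._post(np.full(1000, 5.0))
        with pytest.warns(UserWarning, match="PSRF"):
            summarize([a, b])
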