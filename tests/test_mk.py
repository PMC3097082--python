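import numpy as np
import pytest

from phylodiscord import (
    CharacterMatrix,
    ValidationError,
    build_rate_matrix,
    fit_model,
    likelihood_ratio_test,
    log_likelihood,
    marginal_asr,
    parse_newick,
    resolve_polytomies,
    sim_mk_characters,
    sim_tree,
    transition_probs,
)
from phylodiscord.mk import n_params
from oracles import brute_force_likelihood, brute_force_marginals


def random_model(rng, k=None, kind=None):
    k = k or int(rng.integers(2, 4))
    kind = kind or rng.choice(["ER", "SYM", "ARD"])
    rates = 10.0 ** rng.uniform(-1, 0.7, size=n_params(kind, k))
    return build_rate_matrix(kind, k, rates)


class TestRateMatrix:
    def test_er_two_state(self):
        m = build_rate_matrix("ER", 2, [0.7])
        assert np.allclose(m.generator, [[-0.7, 0.7], [0.7, -0.7]])

    def test_param_counts_k4(self):
        assert n_params("ER", 4) == 1
        assert n_params("SYM", 4) == 6
        assert n_params("ARD", 4) == 12

    def test_sym_generator_symmetric_rows_zero(self):
        m = build_rate_matrix("SYM", 3, [0.1, 0.2, 0.3])
        Q = m.generator
        assert np.allclose(Q, Q.T)
        assert np.allclose(Q.sum(axis=1), 0.0)
        assert Q[0, 1] == 0.1 and Q[0, 2] == 0.2 and Q[1, 2] == 0.3

    def test_ard_row_major_fill(self):
        m = build_rate_matrix("ARD", 3, [1, 2, 3, 4, 5, 6])
        Q = m.generator
        assert Q[0, 1] == 1 and Q[0, 2] == 2 and Q[1, 0] == 3
        assert Q[1, 2] == 4 and Q[2, 0] == 5 and Q[2, 1] == 6

    def test_wrong_param_count_states_expected(self):
        with pytest.raises(ValidationError, match="6"):
            build_rate_matrix("SYM", 4, [1.0])


class TestTransitionProbs:
    def test_zero_time_identity(self):
        m = build_rate_matrix("ARD", 3, [0.1, 0.4, 0.2, 0.9, 0.3, 0.5])
        assert np.allclose(transition_probs(m, 0.0), np.eye(3), atol=1e-12)

    def test_two_state_er_closed_form(self):
        r, t = 0.37, 1.3
        P = transition_probs(build_rate_matrix("ER", 2, [r]), t)
        expect = 0.5 + 0.5 * np.exp(-2 * r * t)
        assert P[0, 0] == pytest.approx(expect, abs=1e-12)
        assert P[0, 1] == pytest.approx(1 - expect, abs=1e-12)

    def test_long_branch_reaches_uniform(self):
        m = build_rate_matrix("SYM", 4, [0.2, 0.5, 0.3, 0.8, 0.4, 0.6])
        P = transition_probs(m, 1e4)
        assert np.allclose(P, 0.25, atol=1e-9)

    def test_rows_stochastic(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            m = random_model(rng)
            P = transition_probs(m, float(rng.exponential(0.5)))
            assert np.all(P >= 0)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)


class TestLikelihood:
    def test_zero_length_tree_is_prior_mass(self):
        t = parse_newick("(A:0,B:0);")
        chars = CharacterMatrix({"A": ["0"], "B": ["0"]}, ["0", "1"])
        m = build_rate_matrix("ER", 2, [1.0])
        assert log_likelihood(t, chars, m) == pytest.approx(np.log(0.5), abs=1e-12)

    def test_matches_enumeration_oracle_four_leaf(self, four_leaf_tree):
        chars = CharacterMatrix(
            {"A": ["0"], "B": ["1"], "C": ["0"], "D": ["1"]}, ["0", "1"]
        )
        m = build_rate_matrix("ARD", 2, [0.8, 0.3])
        got = log_likelihood(four_leaf_tree, chars, m)
        want = brute_force_likelihood(
            four_leaf_tree, chars, m.generator, np.array([0.5, 0.5])
        )
        assert got == pytest.approx(want, abs=1e-10)

    def test_all_missing_leaf_changes_nothing(self, four_leaf_tree):
        chars = CharacterMatrix(
            {"A": ["0"], "B": ["1"], "C": ["0"], "D": ["1"]}, ["0", "1"]
        )
        m = build_rate_matrix("ER", 2, [0.6])
        base = log_likelihood(four_leaf_tree, chars, m)
        bigger = parse_newick(
            "(((A:0.1,B:0.2)1.0:0.05,X:0.4):0.0,(C:0.3,D:0.15)1.0:0.07);"
        )
        chars_x = CharacterMatrix(
            {"A": ["0"], "B": ["1"], "C": ["0"], "D": ["1"], "X": ["?"]},
            ["0", "1"],
        )
        assert log_likelihood(bigger, chars_x, m) == pytest.approx(base, abs=1e-10)

    def test_polytomy_resolution_preserves_likelihood(self):
        poly = parse_newick("((A:0.2,B:0.1,C:0.3):0.1,(D:0.2,E:0.1):0.15);")
        chars = CharacterMatrix(
            {t: [s] for t, s in zip("ABCDE", "01100")}, ["0", "1"]
        )
        m = build_rate_matrix("SYM", 2, [0.9])
        direct = log_likelihood(poly, chars, m)
        resolved = log_likelihood(resolve_polytomies(poly), chars, m)
        assert direct == pytest.approx(resolved, abs=1e-10)

    def test_missing_leaf_data_rejected(self, four_leaf_tree):
        chars = CharacterMatrix({"A": ["0"], "B": ["1"]}, ["0", "1"])
        with pytest.raises(ValidationError, match="C"):
            log_likelihood(four_leaf_tree, chars, build_rate_matrix("ER", 2, [1]))


class TestFit:
    def test_nesting_of_maximized_likelihoods(self):
        tree = sim_tree(8, 3, mean_length=0.3)
        chars = sim_mk_characters(tree, build_rate_matrix("ER", 3, [0.8]), 60, 9)
        fits = {k: fit_model(tree, chars, k, n_starts=2) for k in ("ER", "SYM", "ARD")}
        assert (
            fits["ER"].log_likelihood
            <= fits["SYM"].log_likelihood + 1e-6
            <= fits["ARD"].log_likelihood + 2e-6
        )

    def test_er_rate_recovery_within_20_percent(self):
        tree = sim_tree(24, 1, mean_length=0.4)
        true = 0.5
        chars = sim_mk_characters(tree, build_rate_matrix("ER", 2, [true]), 500, 4)
        fit = fit_model(tree, chars, "ER")
        assert fit.converged
        assert abs(fit.model.params[0] - true) / true < 0.20

    def test_constant_character_drives_rate_to_lower_bound(self):
        tree = sim_tree(6, 2)
        chars = CharacterMatrix(
            {name: ["0"] for name in tree.leaves}, ["0", "1"]
        )
        fit = fit_model(tree, chars, "ER", n_starts=2)
        assert fit.model.params[0] == pytest.approx(1e-8, rel=10)


class TestLRT:
    def test_equal_likelihoods_give_p_one(self):
        from phylodiscord import ModelFit

        er = ModelFit(build_rate_matrix("ER", 3, [0.5]), -10.0, True, 1)
        sym = ModelFit(
            build_rate_matrix("SYM", 3, [0.5, 0.5, 0.5]), -10.0, True, 1
        )
        lrt = likelihood_ratio_test(er, sym)
        assert lrt.statistic == 0.0 and lrt.p == 1.0 and lrt.df == 2

    def test_df_zero_pair_rejected(self):
        from phylodiscord import ModelFit

        er = ModelFit(build_rate_matrix("ER", 2, [0.5]), -10.0, True, 1)
        sym = ModelFit(build_rate_matrix("SYM", 2, [0.5]), -10.0, True, 1)
        with pytest.raises(ValidationError, match="k=2"):
            likelihood_ratio_test(er, sym)

    def test_df_er_vs_ard_k2(self):
        from phylodiscord import ModelFit

        er = ModelFit(build_rate_matrix("ER", 2, [0.5]), -12.0, True, 1)
        ard = ModelFit(build_rate_matrix("ARD", 2, [0.5, 0.9]), -11.0, True, 1)
        lrt = likelihood_ratio_test(er, ard)
        assert lrt.df == 1
        assert lrt.statistic == pytest.approx(2.0)

    def test_df_er_vs_sym_k4(self):
        k = 4
        assert n_params("SYM", k) - n_params("ER", k) == 5

    def test_non_nested_pair_rejected(self):
        tree = sim_tree(5, 1, mean_length=0.3)
        chars = sim_mk_characters(tree, build_rate_matrix("ER", 2, [0.5]), 10, 0)
        er = fit_model(tree, chars, "ER", n_starts=1)
        with pytest.raises(ValidationError):
            likelihood_ratio_test(er, er)


class TestMarginalASR:
    def test_symmetric_cherry_is_fifty_fifty(self):
        t = parse_newick("(A:0.3,B:0.3);")
        chars = CharacterMatrix({"A": ["0"], "B": ["1"]}, ["0", "1"])
        asr = marginal_asr(t, chars, build_rate_matrix("ER", 2, [0.8]))
        (vec,) = asr.node_likelihoods.values()
        assert np.allclose(vec, [0.5, 0.5], atol=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle(self, seed, four_leaf_tree):
        rng = np.random.default_rng(seed)
        m = random_model(rng, k=2)
        states = rng.choice(["0", "1", "?"], size=4, p=[0.45, 0.45, 0.1])
        chars = CharacterMatrix(
            {t: [s] for t, s in zip("ABCD", states)}, ["0", "1"]
        )
        asr = marginal_asr(four_leaf_tree, chars, m)
        want = brute_force_marginals(
            four_leaf_tree, chars, m.generator, np.array([0.5, 0.5])
        )
        for clade, vec in asr.node_likelihoods.items():
            assert np.allclose(vec, want[clade], atol=1e-10)
        want_ll = brute_force_likelihood(
            four_leaf_tree, chars, m.generator, np.array([0.5, 0.5])
        )
        assert asr.log_likelihood == pytest.approx(want_ll, abs=1e-10)

    def test_vectors_sum_to_one_and_unanimous_tips_dominate(self):
        tree = sim_tree(12, 8, mean_length=0.2)
        chars = CharacterMatrix(
            {name: ["G"] for name in tree.leaves}, ["G", "C", "L"]
        )
        m = build_rate_matrix("ER", 3, [0.4])
        asr = marginal_asr(tree, chars, m)
        for vec in asr.node_likelihoods.values():
            assert vec.sum() == pytest.approx(1.0, abs=1e-9)
            assert vec[0].argmax() == 0  # the observed state G wins everywhere

    def test_taxon_input_order_invariance(self):
        tree = parse_newick("((A:0.1,B:0.2)1.0:0.1,(C:0.2,D:0.1)1.0:0.2);")
        states = {"A": ["0"], "B": ["1"], "C": ["1"], "D": ["0"]}
        m = build_rate_matrix("ER", 2, [0.5])
        a = marginal_asr(tree, CharacterMatrix(states, ["0", "1"]), m)
        reordered = dict(reversed(list(states.items())))
        b = marginal_asr(tree, CharacterMatrix(reordered, ["0", "1"]), m)
        for clade in a.node_likelihoods:
            assert np.allclose(a.node_likelihoods[clade], b.node_likelihoods[clade])
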