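import math

import numpy as np
import pytest

from _oracle import enumeration_loglik
from conftest import random_binary_tree
from phylorates.char_matrix import CharacterMatrix, compress_patterns
from phylorates.likelihood import (NEG_INF, LikelihoodConfig, pattern_loglik,
                                   total_loglik, transition_probs,
                                   unobservable_loglik)
from phylorates.rate_models import (assemble_q, calibrate_q, discrete_gamma,
                                    make_model_spec, uniform_prior)
from phylorates.tree_io import parse_newick, reroot_at_edge


def er_config(a=2, mu=1.0, **kw):
    spec = make_model_spec("ER", a)
    return LikelihoodConfig(model=spec, rel_rates=np.ones(1), mu={1: mu},
                            root_prior=uniform_prior(a), **kw)


def calibrated(name, a, rel=None, pi=None, reversible=False):
    spec = make_model_spec(name, a)
    rel = np.ones(spec.free_params) if rel is None else np.asarray(rel)
    pi = uniform_prior(a) if pi is None else pi
    return calibrate_q(assemble_q(spec, rel, pi, reversible), pi)


class TestTransitionProbs:
    def test_zero_time_is_identity(self):
        q = calibrated("SYM", 3, [1.0, 2.0, 0.5])
        np.testing.assert_allclose(transition_probs(q, 0.0), np.eye(3),
                                   atol=1e-14)

    def test_two_state_closed_form(self):
        q = calibrated("ER", 2)
        for nu in (0.01, math.log(2) / 2, 0.7, 3.0):
            expect = (1 - math.exp(-2 * nu)) / 2
            assert transition_probs(q, nu)[0, 1] == pytest.approx(
                expect, abs=1e-10)

    def test_long_branch_reaches_uniform(self):
        q = calibrated("ER", 4)
        p = transition_probs(q, 1e6)
        np.testing.assert_allclose(p, 0.25, atol=1e-8)

    def test_rows_sum_to_one(self, rng):
        q = calibrated("ARD", 3, rng.uniform(0.3, 2.0, 6))
        p = transition_probs(q, 0.9)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-10)
        assert (p >= 0).all() and (p <= 1).all()

    def test_negative_nu_rejected(self):
        q = calibrated("ER", 2)
        with pytest.raises(ValueError):
            transition_probs(q, -0.1)
        with pytest.raises(ValueError):
            transition_probs(q, float("nan"))


class TestPatternLoglik:
    def test_zero_length_identical_pattern(self):
        tree = parse_newick("(A:0,B:0);")
        ll = pattern_loglik(tree, {"A": 0, "B": 0}, er_config())
        assert ll == pytest.approx(math.log(0.5), abs=1e-12)

    def test_zero_length_impossible_pattern(self):
        tree = parse_newick("(A:0,B:0);")
        assert pattern_loglik(tree, {"A": 0, "B": 1}, er_config()) == NEG_INF

    def test_missing_leaf_rejected(self):
        tree = parse_newick("(A:0.1,B:0.1);")
        with pytest.raises(ValueError, match="missing leaves"):
            pattern_loglik(tree, {"A": 0}, er_config())

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_leaves = int(rng.integers(2, 6))
        a = int(rng.integers(2, 4))
        tree = random_binary_tree(rng, n_leaves)
        name = ["ER", "SYM", "ARD", "BDER"][seed % 4]
        spec = make_model_spec(name, a)
        rel = rng.uniform(0.3, 2.5, spec.free_params)
        pi = rng.dirichlet(np.ones(a))
        mu = float(rng.uniform(0.2, 2.0))
        config = LikelihoodConfig(model=spec, rel_rates=rel, mu={1: mu},
                                  root_prior=pi)
        states = {name_: int(rng.integers(a)) for name_ in tree.leaf_names}
        got = pattern_loglik(tree, states, config)
        expect = enumeration_loglik(tree, states, config.build_q(), pi,
                                    {1: mu})
        assert got == pytest.approx(expect, abs=1e-9)


class TestUnobservable:
    def test_zero_length_star(self):
        tree = parse_newick("(A:0,B:0,C:0);")
        assert unobservable_loglik(tree, er_config()) == pytest.approx(
            math.log(0.5), abs=1e-12)

    def test_mu_zero_reduces_to_prior(self, tree4):
        spec = make_model_spec("ER", 2)
        pi = np.array([0.7, 0.3])
        config = LikelihoodConfig(model=spec, rel_rates=np.ones(1),
                                  mu={1: 0.0}, root_prior=pi)
        assert unobservable_loglik(tree4, config) == pytest.approx(
            math.log(0.7), abs=1e-12)

    def test_matches_enumeration(self, rng):
        tree = parse_newick("((A:0.4,B:0.3):0.2,C:0.5);")
        config = er_config(mu=1.3)
        expect = enumeration_loglik(tree, {"A": 0, "B": 0, "C": 0},
                                    config.build_q(), config.root_prior,
                                    {1: 1.3})
        assert unobservable_loglik(tree, config) == pytest.approx(
            expect, abs=1e-12)


class TestTotalLoglik:
    def make_patterns(self, grid, a=2):
        taxa = [chr(ord("A") + i) for i in range(grid.shape[0])]
        return compress_patterns(CharacterMatrix(taxa, np.asarray(grid), a))

    def test_equals_weighted_pattern_sum(self, tree4, rng):
        grid = rng.integers(0, 2, (4, 30))
        ps = self.make_patterns(grid)
        config = er_config(mu=0.8)
        total = total_loglik(tree4, ps, config)
        by_site = sum(
            pattern_loglik(tree4, dict(zip(["A", "B", "C", "D"], grid[:, s])),
                           config) for s in range(30))
        assert total == pytest.approx(by_site, abs=1e-9)

    def test_correction_raises_loglik(self, tree4, rng):
        grid = rng.integers(0, 2, (4, 25))
        grid[0, (grid == 0).all(axis=0)] = 1  # drop all-zero columns
        ps = self.make_patterns(grid)
        plain = total_loglik(tree4, ps, er_config(mu=0.8))
        corrected = total_loglik(tree4, ps,
                                 er_config(mu=0.8, zerocorrection=True))
        assert corrected > plain

    def test_corrected_probabilities_sum_to_one(self):
        tree = parse_newick("((A:0.3,B:0.5):0.2,C:0.4);")
        config = er_config(mu=1.1, zerocorrection=True)
        total = 0.0
        for code in range(1, 8):  # all observable patterns
            states = [(code >> k) & 1 for k in range(3)]
            grid = np.array(states)[:, None]
            ps = self.make_patterns(grid)
            total += math.exp(total_loglik(tree, ps, config))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_gamma_k1_equals_plain(self, tree4, rng):
        grid = rng.integers(0, 2, (4, 20))
        ps = self.make_patterns(grid)
        plain = total_loglik(tree4, ps, er_config(mu=0.9))
        g1 = total_loglik(tree4, ps,
                          er_config(mu=0.9, gamma=discrete_gamma(0.6, 1)))
        assert g1 == pytest.approx(plain, abs=1e-12)

    def test_gamma_large_alpha_converges_to_plain(self, tree4, rng):
        grid = rng.integers(0, 2, (4, 20))
        ps = self.make_patterns(grid)
        plain = total_loglik(tree4, ps, er_config(mu=0.9))
        g = total_loglik(tree4, ps,
                         er_config(mu=0.9, gamma=discrete_gamma(1e6, 4)))
        assert g == pytest.approx(plain, abs=1e-4)

    def test_branch_category_consistency(self, rng):
        from phylorates.tree_io import parse_rate_newick
        plain = parse_newick("((A:0.3,B:0.4):0.2,(C:0.25,D:0.35):0.15);")
        labelled = parse_rate_newick(
            "((A$1:0.3,B$2:0.4)$1:0.2,(C$2:0.25,D$1:0.35)$2:0.15);")
        grid = rng.integers(0, 2, (4, 15))
        ps = self.make_patterns(grid)
        spec = make_model_spec("ER", 2)
        one = LikelihoodConfig(model=spec, rel_rates=np.ones(1), mu={1: 0.7},
                               root_prior=uniform_prior(2))
        two = LikelihoodConfig(model=spec, rel_rates=np.ones(1),
                               mu={1: 0.7, 2: 0.7},
                               root_prior=uniform_prior(2))
        assert total_loglik(plain, ps, one) == pytest.approx(
            total_loglik(labelled, ps, two), abs=1e-10)

    def test_missing_mu_category_rejected(self):
        from phylorates.tree_io import parse_rate_newick
        tree = parse_rate_newick("((A$1:0.3,B$2:0.4)$1:0.2,C$2:0.5);")
        grid = np.array([[0], [1], [0]])
        ps = self.make_patterns(grid)
        with pytest.raises(ValueError, match="categories"):
            total_loglik(tree, ps, er_config(mu=1.0))

    def test_impossible_pattern_gives_neg_inf(self):
        tree = parse_newick("(A:0,B:0);")
        ps = self.make_patterns(np.array([[0], [1]]))
        assert total_loglik(tree, ps, er_config()) == NEG_INF


class TestPulleyPrinciple:
    def grid(self, rng, n):
        return rng.integers(0, 2, (5, n))

    def reference_and_reroots(self, tree, ps, config, tol):
        base = total_loglik(tree, ps, config)
        for node in list(tree.postorder()):
            if node is tree.root or node.length == 0:
                continue
            rerooted = reroot_at_edge(tree, node, node.length / 2)
            assert total_loglik(rerooted, ps, config) == pytest.approx(
                base, abs=tol)

    def test_er_uniform_invariant(self, tree5, rng):
        ps = TestTotalLoglik().make_patterns(self.grid(rng, 12))
        self.reference_and_reroots(tree5, ps, er_config(mu=0.9), 1e-8)

    def test_reversible_skewed_prior_invariant(self, tree5, rng):
        grid = rng.integers(0, 3, (5, 10))
        ps = TestTotalLoglik().make_patterns(grid, a=3)
        spec = make_model_spec("SYM", 3)
        config = LikelihoodConfig(
            model=spec, rel_rates=np.array([1.0, 1.7, 0.6]), mu={1: 0.8},
            root_prior=np.array([0.5, 0.2, 0.3]), reversible=True)
        self.reference_and_reroots(tree5, ps, config, 1e-8)

    def test_ard_can_break_invariance(self, tree5, rng):
        grid = self.grid(rng, 10)
        ps = TestTotalLoglik().make_patterns(grid)
        spec = make_model_spec("ARD", 2)
        config = LikelihoodConfig(
            model=spec, rel_rates=np.array([1.0, 3.0]), mu={1: 0.8},
            root_prior=np.array([0.9, 0.1]))
        base = total_loglik(tree5, ps, config)
        node = tree5.find("E")
        moved = total_loglik(reroot_at_edge(tree5, node, node.length / 2),
                             ps, config)
        assert abs(base - moved) > 1e-6  # irreversible: root placement matters
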