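import numpy as np
import pytest

from slopehte.trees import (DecisionTree, Node, SplitData, TreePrior,
                            birth_proposal, build_cutpoint_grid, death_proposal,
                            eligible_splits, leaf_assign, log_tree_prior,
                            predict_surface)


def split_tree(var, cut, cut_idx=0):
    root = Node(var=var, cut_idx=cut_idx, cut=cut,
                left=Node(depth=1), right=Node(depth=1))
    return DecisionTree(root)


class TestCutpointGrid:
    def test_binary_column_single_midpoint(self):
        X = np.column_stack([np.array([0, 1, 0, 1, 1]), np.arange(5.0)])
        grids, names = build_cutpoint_grid(X, [0])
        np.testing.assert_allclose(grids[0], [0.5])

    def test_continuous_deciles(self, rng):
        X = rng.uniform(-2, 2, size=(500, 1))
        grids, _ = build_cutpoint_grid(X, [0], n_cuts=9)
        assert len(grids[0]) == 9
        assert np.all(np.diff(grids[0]) > 0)

    def test_constant_column_excluded_with_warning(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.warns(UserWarning):
            grids, _ = build_cutpoint_grid(X, [0, 1])
        assert len(grids[0]) == 0 and len(grids[1]) > 0


class TestTreePrior:
    def prior(self, **kw):
        kw.setdefault("grids", [np.array([0.5]), np.array([0.5])])
        return TreePrior(**kw)

    def test_root_only_structural_term(self):
        # 1 - c0 * (1+0)^-d0 = 0.05
        lp = log_tree_prior(DecisionTree(), self.prior())
        assert np.isclose(lp, np.log(0.05))

    def test_split_cost_grows_with_depth(self):
        # structural log-prior change of splitting a leaf at depth d,
        # log p(d) + 2 log(1 - p(d+1)) - log(1 - p(d)), decreases in d
        prior = self.prior()

        def gain(d):
            return (np.log(prior.p_split(d)) + 2 * np.log1p(-prior.p_split(d + 1))
                    - np.log1p(-prior.p_split(d)))

        gains = [gain(d) for d in range(4)]
        assert np.all(np.diff(gains) < 0)

    def test_d0_zero_is_depth_independent(self):
        prior = self.prior(c0=0.6, d0=0.0)
        assert prior.p_split(0) == prior.p_split(5) == 0.6


class TestLeafAssign:
    def test_root_tree_single_leaf(self, rng):
        X = rng.normal(size=(20, 3))
        assert np.all(leaf_assign(DecisionTree(), X) == 0)

    def test_egfr_threshold_routing(self):
        # split 'eGFR <= 34.32'; higher-eGFR subjects go right
        tree = split_tree(0, 34.32)
        assert leaf_assign(tree, np.array([44.23])) == 1
        assert leaf_assign(tree, np.array([23.97])) == 0
        assert leaf_assign(tree, np.array([34.32])) == 0  # ties go left

    def test_partition_counts_sum_to_n(self, rng):
        tree = split_tree(0, 0.0)
        tree.root.right = Node(var=1, cut_idx=0, cut=0.5, depth=1,
                               left=Node(depth=2), right=Node(depth=2))
        X = rng.normal(size=(200, 2))
        lab = tree.assign(X)
        assert np.bincount(lab, minlength=3).sum() == 200

    def test_missing_value_rejected(self):
        tree = split_tree(0, 0.0)
        with pytest.raises(ValueError):
            tree.assign(np.array([[np.nan]]))


class TestPredictSurface:
    def test_constant_effect_root_tree(self, rng):
        x = rng.normal(size=(7, 2))
        out = predict_surface(DecisionTree(), np.array([0.1]), x, x, "tau0")
        np.testing.assert_allclose(out, 0.1)

    def test_two_group_effect_from_slopes(self):
        # treatment slope -3 / -1 vs control -4 / -1.5 across GFR 75
        tree = split_tree(0, 75.0)
        control = np.array([-4.0, -1.5])
        treated = np.array([-3.0, -1.0])
        tau = treated - control
        gfr = np.array([[60.0], [90.0]])
        np.testing.assert_allclose(predict_surface(tree, tau, gfr, gfr, "tau0"),
                                   [1.0, 0.5])

    def test_equal_leaf_coefficients_reduce_to_linear(self, rng):
        tree = split_tree(0, 0.0)
        coef = np.array([[1.0, 2.0], [1.0, 2.0]])
        x = rng.normal(size=(30, 2))
        np.testing.assert_allclose(predict_surface(tree, coef, x, x, "alpha0"),
                                   x @ coef[0])

    def test_piecewise_constant_takes_at_most_J_values(self, rng):
        tree = split_tree(0, 0.0)
        out = predict_surface(tree, np.array([0.3, -0.2]),
                              rng.normal(size=(300, 1)), rng.normal(size=(300, 1)),
                              "tau0")
        assert len(np.unique(out)) <= 2


class TestProposals:
    def prior(self, min_leaf=1):
        return TreePrior(grids=[np.array([0.5]), np.array([0.5])], min_leaf=min_leaf)

    def test_birth_from_root_gives_two_leaves(self, rng):
        out = birth_proposal(DecisionTree(), self.prior(), rng)
        assert out is not None
        new, _, info = out
        assert new.n_leaves == 2 and info["move"] == "birth"

    def test_birth_respects_min_leaf_and_arms(self, rng):
        SX = np.array([[0.0], [0.0], [1.0], [1.0], [1.0], [1.0]])
        trt = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        sdata = SplitData(SX=SX, trt=trt, min_leaf=3)
        prior = TreePrior(grids=[np.array([0.5])], min_leaf=3)
        members = [np.arange(6)]
        # left child would hold 2 < 3 subjects: no eligible split
        assert birth_proposal(DecisionTree(), prior, rng, split_data=sdata,
                              membership=members) is None

    def test_single_arm_child_ineligible(self, rng):
        SX = np.array([[0.0], [0.0], [1.0], [1.0]])
        trt = np.array([1.0, 1.0, 1.0, 0.0])  # left child all treated
        sdata = SplitData(SX=SX, trt=trt, min_leaf=1)
        prior = TreePrior(grids=[np.array([0.5])], min_leaf=1)
        elig = eligible_splits(np.arange(4), prior, sdata)
        assert elig == {}

    def test_death_restores_root(self, rng):
        tree = split_tree(0, 0.5)
        out = death_proposal(tree, self.prior(), rng)
        assert out is not None
        new, _, info = out
        assert new.n_leaves == 1 and info["move"] == "death"

    def test_birth_then_death_is_involution(self, rng):
        tree = DecisionTree()
        new, _, _ = birth_proposal(tree, self.prior(), rng)
        back, _, _ = death_proposal(new, self.prior(), rng)
        assert back.canonical_key() == tree.canonical_key()

    def test_death_unavailable_at_root(self, rng):
        assert death_proposal(DecisionTree(), self.prior(), rng) is None

    def test_hastings_ratio_antisymmetry(self, rng):
        # q-ratio of a birth equals minus the q-ratio of the matching death
        prior = self.prior()
        new, logq_b, info = birth_proposal(DecisionTree(), prior, rng)
        back, logq_d, _ = death_proposal(new, prior, rng)
        assert np.isclose(logq_b, -logq_d)


class TestSerialization:
    def test_round_trip(self):
        tree = split_tree(1, 0.5)
        tree.root.left = Node(var=0, cut_idx=2, cut=-0.3, depth=1,
                              left=Node(depth=2), right=Node(depth=2))
        back = DecisionTree.from_dict(tree.to_dict())
        assert back.canonical_key() == tree.canonical_key()

    def test_named_variables_in_dict(self):
        d = split_tree(0, 34.32).to_dict(["eGFR"])
        assert d["var"] == "eGFR" and d["cut"] == 34.32


class TestPriorChain:
    """Birth/death chain without data must target the tree prior exactly."""

    def test_enumerable_space_frequencies(self):
        from scipy.stats import chisquare

        from slopehte.sampler import prior_tree_chain
        prior = TreePrior(grids=[np.array([0.5]), np.array([0.5])],
                          c0=0.95, d0=2.0, max_depth=2)
        rng = np.random.default_rng(7)
        draws = prior_tree_chain(prior, 4000, rng, thin=10)

        def enumerate_trees():
            # depth <= 2 over two binary variables
            leaves2 = Node(depth=2)

            def child(kind, depth):
                if kind == "leaf":
                    return Node(depth=depth)
                return Node(var=kind, cut_idx=0, cut=0.5, depth=depth,
                            left=Node(depth=depth + 1), right=Node(depth=depth + 1))
            trees = [DecisionTree()]
            for v in (0, 1):
                for lk in ("leaf", 0, 1):
                    for rk in ("leaf", 0, 1):
                        root = Node(var=v, cut_idx=0, cut=0.5,
                                    left=child(lk, 1), right=child(rk, 1))
                        trees.append(DecisionTree(root))
            return trees

        trees = enumerate_trees()
        logp = np.array([log_tree_prior(t, prior) for t in trees])
        probs = np.exp(logp - logp.max())
        probs /= probs.sum()
        keys = [t.canonical_key() for t in trees]
        counts = {k: 0 for k in keys}
        for d in draws:
            counts[d.canonical_key()] += 1
        # aggregate: root, each single-split, all deeper trees
        observed = [counts[keys[0]]]
        expected = [probs[0]]
        singles = [i for i, t in enumerate(trees)
                   if t.n_leaves == 2]
        for i in singles:
            observed.append(counts[keys[i]])
            expected.append(probs[i])
        rest_obs = len(draws) - sum(observed)
        observed.append(rest_obs)
        expected.append(1.0 - sum(expected))
        res = chisquare(observed, np.array(expected) * len(draws))
        assert res.pvalue > 0.001, (observed, np.array(expected) * len(draws))
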