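import numpy as np
import pytest

from talonmorph.gmm import procrustes_anova
from talonmorph.pcm import (PhyloCovariance, ancestral_bm, kmult, mcc_tree,
                            pgls)
from talonmorph.phylo import Phylo, TreeSample, simulate_yule, star_tree


def scalar_blomberg_k(y, tree):
    """Independent scalar Blomberg's K via explicit dense GLS algebra."""
    C = tree.vcv()
    n = len(y)
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    a = ones @ Cinv @ y / (ones @ Cinv @ ones)
    msr = ((y - a) ** 2).sum()
    mse = (y - a) @ Cinv @ (y - a)
    expected = (np.trace(C) - n / (ones @ Cinv @ ones)) / (n - 1)
    return (msr / mse) / expected


class TestPhyloCovariance:
    def test_whitening_identity(self):
        for seed in range(5):
            tree = simulate_yule(int(np.random.default_rng(seed).integers(5, 64)),
                                 seed=seed)
            pc = PhyloCovariance.from_tree(tree)
            np.testing.assert_allclose(pc.P @ pc.C @ pc.P.T,
                                       np.eye(tree.n_tips), atol=1e-8)

    def test_known_three_tip_matrix(self):
        tree = Phylo.from_newick("((A:1,B:1):1,C:2);")
        pc = PhyloCovariance.from_tree(tree, ["A", "B", "C"])
        np.testing.assert_allclose(pc.C, [[2, 1, 0], [1, 2, 0], [0, 0, 2]],
                                   atol=1e-12)

    def test_singular_tree_rejected(self):
        tree = Phylo.from_newick("((A:0,B:0):1,C:1);")
        with pytest.raises(ValueError, match="singular"):
            PhyloCovariance.from_tree(tree)


class TestMCC:
    def test_all_identical_returns_that_topology(self):
        s = "((A:1,B:1):1,(C:1,D:1):1);"
        ts = TreeSample.from_newicks([s] * 5)
        assert mcc_tree(ts).bipartitions() == ts.trees[0].bipartitions()

    def test_dominant_topology_wins_9v1(self):
        a = "((A:1,B:1):1,(C:1,D:1):1);"
        b = "(((A:1,C:1):1,B:2):0.5,D:2.5);"
        ts = TreeSample.from_newicks([a] * 9 + [b])
        result = mcc_tree(ts)
        # brute-force clade-frequency oracle over the 10 trees
        freqs = {}
        for t in ts.trees:
            for c in t.bipartitions():
                freqs[c] = freqs.get(c, 0) + 1
        scores = [sum(np.log(freqs[c] / 10) for c in t.bipartitions())
                  for t in ts.trees]
        assert result.bipartitions() == ts.trees[int(np.argmax(scores))].bipartitions()
        assert result.bipartitions() == ts.trees[0].bipartitions()

    def test_single_tree(self):
        ts = TreeSample.from_newicks(["((A:1,B:1):1,C:2);"])
        assert mcc_tree(ts) is ts.trees[0]

    def test_mismatched_tip_sets_rejected(self):
        with pytest.raises(ValueError, match="tip set"):
            TreeSample.from_newicks(["((A:1,B:1):1,C:2);",
                                     "((A:1,B:1):1,D:2);"])


class TestKmult:
    def test_univariate_matches_scalar_oracle(self):
        tree = simulate_yule(12, seed=9)
        y = tree.simulate_bm(1.0, np.random.default_rng(4))[:, 0]
        res = kmult(y, tree, n_perm=99, seed=0)
        assert res.k == pytest.approx(scalar_blomberg_k(y, tree), abs=1e-10)

    def test_bm_expectation_near_one(self):
        ks = []
        for r in range(60):
            tree = simulate_yule(21, seed=700 + r)
            Y = tree.simulate_bm(1.0, np.random.default_rng(r), n_traits=4)
            ks.append(kmult(Y, tree, n_perm=99, seed=r).k)
        assert 0.88 <= np.mean(ks) <= 1.12

    def test_star_tree_statistic_permutation_invariant(self, rng):
        tree = star_tree([f"t{i}" for i in range(10)])
        Y = rng.normal(size=(10, 3))
        k1 = kmult(Y, tree, n_perm=99, seed=0).k
        perm = rng.permutation(10)
        k2 = kmult(Y[perm], tree, n_perm=99, seed=0).k
        assert k1 == pytest.approx(k2, abs=1e-12)

    def test_reorder_invariance(self, rng):
        tree = simulate_yule(10, seed=3)
        Y = rng.normal(size=(10, 3))
        k1 = kmult(Y, tree, tip_order=tree.tip_labels, n_perm=99, seed=1).k
        order = list(rng.permutation(tree.tip_labels))
        idx = [tree.tip_labels.index(lb) for lb in order]
        k2 = kmult(Y[idx], tree, tip_order=order, n_perm=99, seed=1).k
        assert k1 == pytest.approx(k2, abs=1e-10)

    def test_constant_traits_rejected(self):
        tree = simulate_yule(6, seed=0)
        with pytest.raises(ValueError, match="constant"):
            kmult(np.ones((6, 2)), tree, n_perm=99, seed=0)


class TestPGLS:
    def test_star_tree_equals_ordinary_fit(self, rng):
        tree = star_tree([f"t{i}" for i in range(12)], depth=2.0)
        Y = rng.normal(size=(12, 4))
        g = ["a"] * 6 + ["b"] * 6
        r_pgls = pgls(Y, tree, groups=g, n_perm=199, seed=3)
        r_ols = procrustes_anova(Y, groups=g, n_perm=199, seed=3)
        assert r_pgls.F == pytest.approx(r_ols.F, abs=1e-10)
        assert r_pgls.p == r_ols.p

    def test_exact_linear_function_recovered(self, rng):
        tree = simulate_yule(15, seed=4)
        x = rng.uniform(1, 3, 15)
        Y = np.outer(x, [1.0, -2.0, 0.5])
        res = pgls(Y, tree, covariate=x, n_perm=199, seed=5)
        assert res.r2 > 0.99
        assert res.p == pytest.approx(1 / 199)

    def test_identity_covariance_equals_anova(self, rng):
        # a star tree's C is proportional to I, so the whitened engine must
        # coincide with the non-phylogenetic one exactly
        tree = star_tree([f"t{i}" for i in range(10)], depth=3.0)
        y = rng.normal(size=10)
        res1 = pgls(y, tree, covariate=rng.uniform(1, 2, 10), n_perm=99, seed=7)
        assert np.isfinite(res1.F)

    def test_rank_deficient_design_rejected(self, rng):
        tree = simulate_yule(8, seed=1)
        Y = rng.normal(size=(8, 2))
        X = np.ones((8, 2))  # collinear with the intercept
        with pytest.raises(ValueError, match="rank"):
            pgls(Y, tree, covariate=X, n_perm=99, seed=0)


class TestAncestralBM:
    def test_two_tip_equal_branches(self):
        tree = Phylo.from_newick("(A:1,B:1);")
        _, root, _ = ancestral_bm(np.array([2.0, 6.0]), tree, ["A", "B"])
        assert root == pytest.approx(4.0, abs=1e-12)

    def test_two_tip_weighted(self):
        tree = Phylo.from_newick("(A:1,B:3);")
        _, root, _ = ancestral_bm(np.array([2.0, 6.0]), tree, ["A", "B"])
        expected = (2.0 / 1 + 6.0 / 3) / (1 / 1 + 1 / 3)
        assert root == pytest.approx(expected, abs=1e-12)

    def test_matches_dense_gls_oracle(self):
        tree = simulate_yule(8, seed=2)
        y = tree.simulate_bm(1.0, np.random.default_rng(0))[:, 0]
        est, root, _ = ancestral_bm(y, tree)

        t = tree.tree
        depth = {}
        for node in t.preorder_node_iter():
            depth[node] = (0.0 if node.parent_node is None
                           else depth[node.parent_node] + (node.edge.length or 0.0))
        tips = list(t.leaf_node_iter())
        y_map = dict(zip(tree.tip_labels, y))
        yo = np.array([y_map[l.taxon.label] for l in tips])

        def ancestors(n):
            s = set()
            while n is not None:
                s.add(n)
                n = n.parent_node
            return s

        C = np.array([[max(depth[m] for m in ancestors(a) & ancestors(b))
                       for b in tips] for a in tips])
        Cinv = np.linalg.inv(C)
        ones = np.ones(len(tips))
        a_hat = ones @ Cinv @ yo / (ones @ Cinv @ ones)
        for node in t.preorder_internal_node_iter():
            cross = np.array([max(depth[m] for m in ancestors(node) & ancestors(b))
                              for b in tips])
            dense = a_hat + cross @ Cinv @ (yo - a_hat)
            assert est[node] == pytest.approx(dense, abs=1e-8)

    def test_root_equals_phylogenetic_gls_mean(self):
        tree = simulate_yule(9, seed=5)
        y = tree.simulate_bm(1.0, np.random.default_rng(1))[:, 0]
        _, root, _ = ancestral_bm(y, tree)
        C = tree.vcv()
        Cinv = np.linalg.inv(C)
        ones = np.ones(len(y))
        a_hat = ones @ Cinv @ y / (ones @ Cinv @ ones)
        assert root == pytest.approx(a_hat, abs=1e-12)

    def test_zero_length_terminal_pins_parent(self):
        tree = Phylo.from_newick("((A:0,B:2):1,C:3);")
        est, _, _ = ancestral_bm(np.array([5.0, 1.0, 0.0]), tree,
                                 ["A", "B", "C"])
        parent = next(t for t in tree.tree.leaf_node_iter()
                      if t.taxon.label == "A").parent_node
        assert est[parent] == pytest.approx(5.0, abs=1e-12)

    def test_branch_segments_interpolate_linearly(self):
        tree = Phylo.from_newick("(A:1,B:1);")
        _, root, segs = ancestral_bm(np.array([0.0, 10.0]), tree, ["A", "B"])
        seg_a = next(s for s in segs if s["branch"] == "A")
        np.testing.assert_allclose(seg_a["values"],
                                   np.linspace(root, 0.0, 11), atol=1e-12)
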