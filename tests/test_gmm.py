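import numpy as np
import pytest
from scipy import stats

from talonmorph.gmm import (allometric_regression, centroid_size, gpa,
                            pairwise_group_tests, pca, procrustes_anova)



def random_similarity(rng):
    """A random proper rotation + positive scale + translation."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q, rng.uniform(0.5, 2.0), rng.normal(size=3)


class TestCentroidSize:
    def test_analytic_square(self):
        pts = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0.]])
        assert centroid_size(pts) == pytest.approx(np.sqrt(8), rel=1e-12)

    def test_homogeneity(self, rng):
        pts = rng.normal(size=(10, 3))
        assert centroid_size(3.7 * pts) == pytest.approx(
            3.7 * centroid_size(pts), rel=1e-12)

    def test_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            centroid_size(np.ones((73, 3)))


class TestGPA:
    def test_similarity_copies_align_exactly(self, rng):
        base = rng.normal(size=(10, 3))
        q, s, t = random_similarity(rng)
        shapes = np.stack([base, base @ q * s + t])
        a = gpa(shapes)
        assert np.linalg.norm(a.coords[0] - a.coords[1]) < 1e-9

    def test_unit_centroid_size_and_consensus(self, rng):
        a = gpa(rng.normal(size=(8, 20, 3)))
        cs = np.sqrt((a.coords ** 2).sum(axis=(1, 2)))
        np.testing.assert_allclose(cs, 1.0, atol=1e-9)
        assert np.sqrt((a.consensus ** 2).sum()) == pytest.approx(1.0, abs=1e-9)
        mean = a.coords.mean(axis=0)
        np.testing.assert_allclose(a.consensus,
                                   mean / np.sqrt((mean ** 2).sum()), atol=1e-9)

    def test_idempotent(self, rng):
        a = gpa(rng.normal(size=(8, 20, 3)))
        b = gpa(a.coords.copy())
        # already aligned: re-running changes nothing beyond tolerance
        assert np.abs(np.linalg.norm(b.coords, axis=(1, 2)) - 1).max() < 1e-9
        d_a = np.linalg.norm(a.coords[:, None] - a.coords[None], axis=(2, 3))
        d_b = np.linalg.norm(b.coords[:, None] - b.coords[None], axis=(2, 3))
        np.testing.assert_allclose(d_a, d_b, atol=1e-9)

    def test_invariance_to_input_similarity_transforms(self, rng):
        base = rng.normal(size=(12, 30, 3))
        pert = np.stack([b @ random_similarity(rng)[0] *
                         rng.uniform(0.5, 2) + rng.normal(size=3) for b in base])
        d1 = gpa(base.copy())
        d2 = gpa(pert)
        dd1 = np.linalg.norm(d1.coords[:, None] - d1.coords[None], axis=(2, 3))
        dd2 = np.linalg.norm(d2.coords[:, None] - d2.coords[None], axis=(2, 3))
        assert np.abs(dd1 - dd2).max() < 1e-8

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            gpa(np.zeros((3, 5, 3)))


class TestPCA:
    def test_identical_specimens_zero_variance(self):
        x = np.tile(np.arange(15.0), (4, 1))
        res = pca(x + 0.0)
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_two_distinct_shapes_single_axis(self, rng):
        a, b = rng.normal(size=(2, 15))
        x = np.stack([a, b, a, b])
        res = pca(x)
        assert res.pct_variance[0] == pytest.approx(100.0, abs=1e-6)

    def test_reconstruction_completeness(self, rng):
        x = rng.normal(size=(10, 21))
        res = pca(x)
        rec = res.scores @ res.components + res.mean
        np.testing.assert_allclose(rec, x, atol=1e-9)

    def test_scores_covariance_diagonal(self, rng):
        res = pca(rng.normal(size=(15, 40)))
        cov = res.scores.T @ res.scores / 14
        np.testing.assert_allclose(cov, np.diag(res.eigenvalues), atol=1e-9)

    def test_matches_sklearn(self, rng):
        from sklearn.decomposition import PCA as SkPCA

        x = rng.normal(size=(12, 30))
        res = pca(x)
        sk = SkPCA(n_components=11).fit(x)   # n - 1 non-null components
        np.testing.assert_allclose(res.eigenvalues[:11],
                                   sk.explained_variance_, atol=1e-9)
        np.testing.assert_allclose(np.abs(res.scores[:, :11]),
                                   np.abs(sk.transform(x)), atol=1e-8)


class TestProcrustesAnova:
    def test_matches_classical_anova_f(self):
        y = np.array([3.1, 2.9, 3.4, 5.0, 5.2, 4.8, 1.0, 1.4, 1.2])
        g = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = procrustes_anova(y, groups=g, n_perm=99, seed=1)
        f_classical, _ = stats.f_oneway(y[:3], y[3:6], y[6:])
        assert res.F == pytest.approx(f_classical, abs=1e-10)
        assert res.df == (2, 6)

    def test_minimal_p_with_observed_included(self, rng):
        y = np.r_[rng.normal(0, 1e-6, 10), 100 + rng.normal(0, 1e-6, 10)]
        res = procrustes_anova(y, groups=["a"] * 10 + ["b"] * 10,
                               n_perm=200, seed=2)
        assert res.p == pytest.approx(1 / 200)

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            procrustes_anova(np.ones(10), groups=["a"] * 5 + ["b"] * 5,
                             n_perm=99, seed=0)

    def test_single_member_level_rejected(self):
        with pytest.raises(ValueError, match="single member"):
            procrustes_anova(np.arange(5.0), groups=["a"] * 4 + ["b"],
                             n_perm=99, seed=0)

    def test_r2_bounds_and_p_resolution(self, rng):
        y = rng.normal(size=(12, 4))
        res = procrustes_anova(y, groups=["a"] * 6 + ["b"] * 6, n_perm=99, seed=3)
        assert 0.0 <= res.r2 <= 1.0
        assert res.p >= 1 / 99


class TestPairwise:
    def test_shifted_group_detected(self, rng):
        shared = rng.normal(0, 1, 8)
        y = np.r_[shared, shared, rng.normal(50, 1, 8)]
        g = ["a"] * 8 + ["b"] * 8 + ["c"] * 8
        levels, pm = pairwise_group_tests(y, g, n_perm=199, seed=4)
        ia, ib, ic = levels.index("a"), levels.index("b"), levels.index("c")
        assert pm[min(ia, ic), max(ia, ic)] <= 0.01
        assert pm[min(ib, ic), max(ib, ic)] <= 0.01
        # identical groups: zero between-mean distance, maximal p
        assert pm[min(ia, ib), max(ia, ib)] > 0.5

    def test_two_group_consistency_with_anova(self, rng):
        y = np.r_[rng.normal(0, 1, 10), rng.normal(8, 1, 10)]
        g = ["a"] * 10 + ["b"] * 10
        _, pm = pairwise_group_tests(y, g, n_perm=199, seed=5)
        res = procrustes_anova(y, groups=g, n_perm=199, seed=5)
        assert (pm[0, 1] <= 0.05) == (res.p <= 0.05)

    def test_p_resolution(self, rng):
        y = np.r_[np.zeros(6), np.full(6, 99.0)] + rng.normal(0, 1e-9, 12)
        _, pm = pairwise_group_tests(y, ["a"] * 6 + ["b"] * 6,
                                     n_perm=99, seed=6)
        assert pm[0, 1] >= 1 / 99


class TestAllometricRegression:
    def test_exact_linear_dependence(self, rng):
        cs = rng.uniform(10, 50, 20)
        shapes = np.outer(cs, rng.normal(size=6)) + 3.0
        res = allometric_regression(shapes, cs, n_perm=199, seed=7)
        assert res.r2 > 0.99
        assert res.p == pytest.approx(1 / 199)

    def test_exclude_group_drops_rows(self, rng):
        y = rng.normal(size=(21, 4))
        cs = rng.uniform(1, 2, 21)
        groups = ["SM"] * 10 + ["ML"] * 7 + ["NP"] * 4
        full = allometric_regression(y, cs, n_perm=99, seed=8)
        sub = allometric_regression(y, cs, groups=groups, exclude_group="NP",
                                    n_perm=99, seed=8)
        assert full.df == (1, 19)    # n = 21
        assert sub.df == (1, 15)     # n = 17 after dropping the 4 NP rows

    def test_log_size_option(self, rng):
        cs = rng.uniform(10, 50, 16)
        y = np.outer(np.log(cs), rng.normal(size=3))
        res = allometric_regression(y, cs, log_size=True, n_perm=99, seed=9)
        assert res.r2 > 0.99

    def test_nonpositive_sizes_rejected(self, rng):
        with pytest.raises(ValueError, match="positive"):
            allometric_regression(rng.normal(size=(8, 2)),
                                  np.r_[np.ones(7), -1.0], n_perm=99, seed=0)
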