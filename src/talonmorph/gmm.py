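"""Geometric-morphometric core.

Generalized Procrustes analysis (translation, unit-centroid-size scaling,
optimal proper rotation, iterated to a consensus), principal component
analysis of the aligned coordinates, and a shared permutational
linear-model engine (residual randomization, RRPP) behind the Procrustes
ANOVA, pairwise group tests and multivariate allometric regression.

The permutation convention throughout: the observed statistic is counted
among the permutations, so the minimal attainable p-value is
1 / (n_perm + 1) and ties count as >= observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import LandmarkSet, stack

# ------------------------------------------------------------------- types


@dataclass
class AlignedShapes:
    """Procrustes-aligned specimens x points x 3 coordinates.

    Each configuration is centered at the origin with unit centroid size;
    ``consensus`` is the coordinate-wise mean configuration.
    """

    coords: np.ndarray            # (n, p, 3)
    centroid_sizes: np.ndarray    # (n,) original CS in mm
    consensus: np.ndarray         # (p, 3) mean shape, rescaled to unit CS
    specimen_ids: list[str]

    @property
    def n_specimens(self) -> int:
        return len(self.coords)

    def flat(self) -> np.ndarray:
        """(n, 3p) flattened coordinates."""
        return self.coords.reshape(self.n_specimens, -1)


@dataclass
class StatResult:
    """One permutational linear-model test."""

    F: float
    r2: float
    p: float
    df: tuple[int, int]
    n_perm: int
    seed: int

    def as_dict(self) -> dict:
        return {"F": self.F, "r2": self.r2, "p": self.p,
                "df_effect": self.df[0], "df_residual": self.df[1],
                "n_perm": self.n_perm, "seed": self.seed}


@dataclass
class PCAResult:
    scores: np.ndarray        # (n, n_components)
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    components: np.ndarray    # (n_components, 3p) orthonormal rows
    mean: np.ndarray          # (3p,)


# ------------------------------------------------------------------ basics

def centroid_size(lm: LandmarkSet | np.ndarray) -> float:
    """CS = sqrt(sum of squared distances of landmarks from their centroid)."""
    x = lm.points if isinstance(lm, LandmarkSet) else np.asarray(lm, float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    d = x - x.mean(axis=0)
    cs = float(np.sqrt((d ** 2).sum()))
    if cs == 0.0:
        raise ValueError("degenerate configuration: all points coincide")
    return cs


def _optimal_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R (det = +1) minimizing ||x R - target||."""
    u, _, vt = np.linalg.svd(x.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:  # resolve reflection to a proper rotation
        u[:, -1] *= -1
        r = u @ vt
    return r


def gpa(specimens: list[LandmarkSet] | np.ndarray,
        tol: float = 1e-10, max_iter: int = 1000) -> AlignedShapes:
    """Generalized Procrustes Analysis.

    Configurations are centered, scaled to unit centroid size, rotated to
    the running consensus by orthogonal Procrustes (proper rotations only),
    and the consensus re-estimated until the change in summed Procrustes
    distance is below ``tol``.
    """
    if isinstance(specimens, np.ndarray):
        coords = np.asarray(specimens, float).copy()
        ids = [f"spec_{i}" for i in range(len(coords))]
    else:
        coords = stack(specimens)
        ids = [s.specimen_id for s in specimens]
    if len(coords) < 2:
        raise ValueError("need at least 2 specimens")

    coords -= coords.mean(axis=1, keepdims=True)
    cs = np.sqrt((coords ** 2).sum(axis=(1, 2)))
    if (cs == 0).any():
        raise ValueError("degenerate configuration: zero centroid size")
    coords /= cs[:, None, None]

    consensus = coords[0]
    prev = np.inf
    for _ in range(max_iter):
        for i in range(len(coords)):
            coords[i] = coords[i] @ _optimal_rotation(coords[i], consensus)
        consensus = coords.mean(axis=0)
        consensus /= np.sqrt((consensus ** 2).sum())
        total = ((coords - consensus) ** 2).sum()
        if abs(prev - total) < tol:
            break
        prev = total
    else:
        raise RuntimeError(f"GPA did not converge in {max_iter} iterations "
                           f"(last change {abs(prev - total):.3g})")
    return AlignedShapes(coords, cs, consensus, ids)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two aligned configurations."""
    return float(np.linalg.norm(a - b))


# --------------------------------------------------------------------- PCA

def pca(shapes: AlignedShapes | np.ndarray) -> PCAResult:
    """PCA of the flattened aligned coordinates (specimen covariance)."""
    y = shapes.flat() if isinstance(shapes, AlignedShapes) else np.asarray(shapes, float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 specimens")
    mean = y.mean(axis=0)
    yc = y - mean
    u, s, vt = np.linalg.svd(yc, full_matrices=False)
    eig = s ** 2 / (n - 1)
    keep = min(n - 1, yc.shape[1])
    eig = eig[:keep]
    scores = (u[:, :keep] * s[:keep])
    total = eig.sum()
    pct = eig / total * 100.0 if total > 0 else np.zeros_like(eig)
    return PCAResult(scores, eig, pct, vt[:keep], mean)


# ------------------------------------------------------------- RRPP engine

def _as_response(y) -> np.ndarray:
    if isinstance(y, AlignedShapes):
        return y.flat()
    y = np.asarray(y, float)
    return y[:, None] if y.ndim == 1 else y


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto col(x) via pinv, and rank(x)."""
    q, r = np.linalg.qr(x)
    rank = int((np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())).sum())
    h = x @ np.linalg.pinv(x)
    return h, rank


def rrpp_f_test(y: np.ndarray, x_effect: np.ndarray, n_perm: int, seed: int,
                cov_transform: np.ndarray | None = None,
                x_nuisance: np.ndarray | None = None) -> StatResult:
    """Permutational F-test of ``x_effect`` on multivariate ``y``.

    The model is y ~ [1, x_nuisance, x_effect]; sums of squares come from
    linear-model projections on the (optionally covariance-transformed)
    response, and the null distribution from residual randomization under
    the reduced model (RRPP). ``cov_transform`` is a whitening matrix P
    (e.g. the inverse square root of a phylogenetic covariance) applied to
    response and design alike.
    """
    y = _as_response(y)
    n = len(y)
    if np.allclose(y, y[0]):
        raise ValueError("constant response")
    x_effect = np.asarray(x_effect, float)
    if x_effect.ndim == 1:
        x_effect = x_effect[:, None]
    ones = np.ones((n, 1))
    x_red = ones if x_nuisance is None else np.hstack([ones, x_nuisance])
    x_full = np.hstack([x_red, x_effect])

    if cov_transform is not None:
        y = cov_transform @ y
        x_red = cov_transform @ x_red
        x_full = cov_transform @ x_full

    h_red, rank_red = _hat(x_red)
    h_full, rank_full = _hat(x_full)
    df_eff = rank_full - rank_red
    df_res = n - rank_full
    if df_eff < 1:
        raise ValueError("effect design is rank deficient")
    if df_res < 1:
        raise ValueError("no residual degrees of freedom")

    fitted_red = h_red @ y
    resid_red = y - fitted_red
    diff = h_full - h_red
    i_min_full = np.eye(n) - h_full

    def f_stat(resid: np.ndarray) -> tuple[float, float, float]:
        # SS under re-composed response fitted_red + resid; quadratic forms
        # are clamped at zero against cancellation on (near-)perfect fits
        yy = fitted_red + resid
        ss_eff = max(float(np.einsum("ij,ij->", yy, diff @ yy)), 0.0)
        ss_res = max(float(np.einsum("ij,ij->", yy, i_min_full @ yy)), 0.0)
        if ss_res == 0.0:
            return ss_eff, ss_res, np.inf if ss_eff > 0 else 0.0
        return ss_eff, ss_res, (ss_eff / df_eff) / (ss_res / df_res)

    ss_eff, ss_res, f_obs = f_stat(resid_red)
    rng = np.random.default_rng(seed)
    count = 1  # observed included
    tie_tol = 1e-12 * max(1.0, abs(f_obs)) if np.isfinite(f_obs) else 0.0
    for _ in range(n_perm - 1):
        perm = rng.permutation(n)
        _, _, f = f_stat(resid_red[perm])
        if f >= f_obs - tie_tol:
            count += 1
    p = count / n_perm
    r2 = ss_eff / (ss_eff + ss_res) if (ss_eff + ss_res) > 0 else 0.0
    return StatResult(F=f_obs, r2=r2, p=p, df=(df_eff, df_res),
                      n_perm=n_perm, seed=seed)


def group_design(groups) -> np.ndarray:
    """Treatment-coded dummy matrix (first level dropped; intercept added
    by the engine). Levels in order of first appearance."""
    groups = list(groups)
    levels = list(dict.fromkeys(groups))
    if len(levels) < 2:
        raise ValueError("factor needs at least 2 levels")
    counts = {lv: groups.count(lv) for lv in levels}
    small = [lv for lv, c in counts.items() if c < 2]
    if small:
        raise ValueError(f"levels with a single member: {small}")
    return np.column_stack([[1.0 if g == lv else 0.0 for g in groups]
                            for lv in levels[1:]])


def procrustes_anova(response, groups=None, covariate=None, *,
                     n_perm: int = 999, seed: int = 0,
                     cov_transform: np.ndarray | None = None) -> StatResult:
    """Procrustes ANOVA / multivariate regression with RRPP inference.

    ``response`` is an :class:`AlignedShapes` or a per-specimen scalar /
    matrix; give either ``groups`` (a factor) or ``covariate`` (numeric).
    ``cov_transform`` realizes phylogenetic generalized least squares.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if (groups is None) == (covariate is None):
        raise ValueError("give exactly one of groups/covariate")
    if groups is not None:
        x = group_design(groups)
    else:
        x = np.asarray(covariate, float)
        x = x[:, None] if x.ndim == 1 else x
    return rrpp_f_test(_as_response(response), x, n_perm, seed, cov_transform)


def pairwise_group_tests(response, groups, *, n_perm: int = 999,
                         seed: int = 0) -> tuple[list[str], np.ndarray]:
    """Permutation tests of between-group mean distances, pair by pair.

    The statistic is the Euclidean (Procrustes, for shapes) distance
    between group mean configurations, or |mean difference| for scalars;
    group labels are permuted within each pair's subset. Returns the level
    order and an upper-triangular p matrix (pairwise p above the diagonal,
    zeros elsewhere).
    """
    y = _as_response(response)
    groups = np.asarray(list(groups))
    levels = list(dict.fromkeys(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    k = len(levels)
    pmat = np.zeros((k, k))
    rng = np.random.default_rng(seed)
    for a in range(k):
        for b in range(a + 1, k):
            sel = (groups == levels[a]) | (groups == levels[b])
            ysub = y[sel]
            gsub = (groups[sel] == levels[b]).astype(int)
            obs = np.linalg.norm(ysub[gsub == 0].mean(0) - ysub[gsub == 1].mean(0))
            count = 1
            for _ in range(n_perm - 1):
                gp = rng.permutation(gsub)
                d = np.linalg.norm(ysub[gp == 0].mean(0) - ysub[gp == 1].mean(0))
                if d >= obs - 1e-12:
                    count += 1
            pmat[a, b] = count / n_perm
    return levels, pmat


def allometric_regression(response, sizes, *, groups=None,
                          exclude_group: str | None = None,
                          log_size: bool = False,
                          n_perm: int = 999, seed: int = 0,
                          cov_transform: np.ndarray | None = None) -> StatResult:
    """Multivariate regression of shape (or mean stress) on centroid size.

    ``exclude_group`` drops that diet category (requires ``groups``) before
    fitting — e.g. removing the non-predatory species. ``log_size`` switches
    the covariate to log(CS).
    """
    y = _as_response(response)
    sizes = np.asarray(sizes, float)
    if (sizes <= 0).any():
        raise ValueError("sizes must be positive")
    keep = np.ones(len(y), bool)
    if exclude_group is not None:
        if groups is None:
            raise ValueError("exclude_group requires groups")
        keep = np.asarray([g != exclude_group for g in groups])
        if cov_transform is not None:
            raise ValueError("pre-computed cov_transform cannot be subset; "
                             "transform after exclusion instead")
    if keep.sum() < 4:
        raise ValueError("need at least 4 specimens after exclusion")
    x = np.log(sizes[keep]) if log_size else sizes[keep]
    return rrpp_f_test(y[keep], x[:, None], n_perm, seed, cov_transform)
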