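"""Phylogenetic comparative statistics.

Maximum clade credibility tree selection, the multivariate phylogenetic
signal statistic K_mult (the multivariate extension of Blomberg's K, equal
to 1 in expectation under Brownian motion), phylogenetic generalized least
squares via the inverse-square-root covariance transform, and maximum
likelihood Brownian-motion ancestral state estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gmm import StatResult, group_design, rrpp_f_test
from .phylo import Phylo, TreeSample


@dataclass
class PhyloCovariance:
    """Brownian-motion covariance C of a tree's tips, with its symmetric
    inverse square root P (so P C P^T = I)."""

    tip_order: list[str]
    C: np.ndarray
    P: np.ndarray

    @classmethod
    def from_tree(cls, tree: Phylo, order: list[str] | None = None,
                  eig_floor: float = 1e-12) -> "PhyloCovariance":
        order = list(order or tree.tip_labels)
        C = tree.vcv(order)
        lam, V = np.linalg.eigh(C)
        if lam.min() < eig_floor:
            raise ValueError(
                f"phylogenetic covariance is singular (min eigenvalue "
                f"{lam.min():.3g}); zero-length terminal branches?")
        P = V @ np.diag(lam ** -0.5) @ V.T
        return cls(order, C, P)


@dataclass
class KmultResult:
    k: float
    p: float
    n_perm: int
    seed: int


def mcc_tree(trees: TreeSample) -> Phylo:
    """Maximum clade credibility tree of a sample.

    Each tree is scored by the sum over its internal clades of the log of
    that clade's frequency in the sample; the highest-scoring sample tree
    wins (first index on ties).
    """
    clade_sets = [t.bipartitions() for t in trees.trees]
    freq: dict[frozenset, int] = {}
    for cs in clade_sets:
        for c in cs:
            freq[c] = freq.get(c, 0) + 1
    n = len(trees)
    best_i, best_score = 0, -np.inf
    for i, cs in enumerate(clade_sets):
        score = sum(np.log(freq[c] / n) for c in cs)
        if score > best_score:
            best_i, best_score = i, score
    return trees.trees[best_i]


def _gls_mean(C_inv_ones: np.ndarray, Y: np.ndarray) -> np.ndarray:
    # a_hat = (1' C^-1 1)^-1 1' C^-1 Y
    return C_inv_ones @ Y / C_inv_ones.sum()


def kmult(Y: np.ndarray, tree: Phylo, tip_order: list[str] | None = None,
          n_perm: int = 999, seed: int = 0) -> KmultResult:
    """Multivariate phylogenetic signal K_mult.

    ``Y`` is specimens x traits in ``tip_order`` (default: tree tip
    order). K is the ratio of observed to Brownian-expected
    (non-phylogenetic / phylogenetic) sum-of-squares ratios; the p-value
    permutes rows of Y against the tree (observed included).
    """
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = len(Y)
    if n < 4:
        raise ValueError("need at least 4 tips")
    if np.allclose(Y, Y[0]):
        raise ValueError("constant traits")
    pc = PhyloCovariance.from_tree(tree, tip_order)
    C_inv = np.linalg.inv(pc.C)
    ones = np.ones(n)
    C_inv_ones = ones @ C_inv
    denom_exp = (np.trace(pc.C) - n / C_inv_ones.sum()) / (n - 1)

    def k_stat(y: np.ndarray) -> float:
        a = _gls_mean(C_inv_ones, y)
        dev = y - a
        num = np.einsum("ij,ij->", dev, dev)
        U = pc.P @ dev
        den = np.einsum("ij,ij->", U, U)
        return (num / den) / denom_exp

    k_obs = k_stat(Y)
    rng = np.random.default_rng(seed)
    count = 1
    for _ in range(n_perm - 1):
        if k_stat(Y[rng.permutation(n)]) >= k_obs - 1e-12 * abs(k_obs):
            count += 1
    return KmultResult(float(k_obs), count / n_perm, n_perm, seed)


def pgls(Y: np.ndarray, tree: Phylo, groups=None, covariate=None,
         tip_order: list[str] | None = None,
         n_perm: int = 999, seed: int = 0) -> StatResult:
    """Phylogenetic generalized least squares with RRPP inference.

    Rows of ``Y`` follow ``tip_order``; give either ``groups`` (a factor)
    or ``covariate`` (e.g. centroid size). Both response and design are
    whitened by P = C^(-1/2) before the shared permutational engine runs,
    which realizes the phylogenetic error covariance.
    """
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if (groups is None) == (covariate is None):
        raise ValueError("give exactly one of groups/covariate")
    if groups is not None:
        x = group_design(groups)
    else:
        x = np.asarray(covariate, float)
        x = x[:, None] if x.ndim == 1 else x
    pc = PhyloCovariance.from_tree(tree, tip_order)
    return rrpp_f_test(Y, x, n_perm, seed, cov_transform=pc.P)


def _combine(pairs: list[tuple[float, float]]) -> tuple[float, float]:
    """Precision-weighted combination of (estimate, effective length)
    messages; a zero-length message pins the result exactly."""
    for v, ln in pairs:
        if ln == 0.0:
            return v, 0.0
    w = [1.0 / ln for _, ln in pairs]
    wt = sum(w)
    return sum(wi * v for wi, (v, _) in zip(w, pairs)) / wt, 1.0 / wt


def ancestral_bm(trait: np.ndarray, tree: Phylo,
                 tip_order: list[str] | None = None,
                 n_segments: int = 10):
    """Maximum-likelihood Brownian-motion ancestral states.

    Two-pass pruning (belief propagation on the tree Gaussian): an upward
    pass computes each node's conditional subtree estimate and effective
    branch length; a downward pass sends the rest-of-tree message through
    each branch; the marginal ML state is the precision-weighted blend of
    the two. Equals the dense GLS solution from the node-augmented
    Brownian covariance.

    Returns ``(estimates, root_estimate, segments)`` where ``estimates``
    maps each dendropy node to its state, and ``segments`` linearly
    interpolate the states along every branch (continuous-trait mapping).
    Zero-length terminal branches collapse the parent estimate to the tip
    value (logged by the pinning rule of the combiner).
    """
    order = list(tip_order or tree.tip_labels)
    trait = np.asarray(trait, float)
    vals = dict(zip(order, trait))
    t = tree.tree

    up: dict[int, tuple[float, float]] = {}       # node -> (estimate, length)
    for node in t.postorder_node_iter():
        if node.is_leaf():
            up[id(node)] = (vals[node.taxon.label], 0.0)
        else:
            msgs = [(up[id(ch)][0], up[id(ch)][1] + (ch.edge.length or 0.0))
                    for ch in node.child_nodes()]
            up[id(node)] = _combine(msgs)

    down: dict[int, tuple[float, float]] = {}     # message arriving at node
    est: dict = {}
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            est[node] = up[id(node)][0]
            continue
        parent = node.parent_node
        msgs = [(up[id(ch)][0], up[id(ch)][1] + (ch.edge.length or 0.0))
                for ch in parent.child_nodes() if ch is not node]
        if parent.parent_node is not None:
            msgs.append(down[id(parent)])
        dv, dl = _combine(msgs)
        down[id(node)] = (dv, dl + (node.edge.length or 0.0))
        if node.is_leaf():
            est[node] = vals[node.taxon.label]
        else:
            est[node] = _combine([up[id(node)], down[id(node)]])[0]

    segments = []
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            continue
        v0, v1 = est[node.parent_node], est[node]
        fr = np.linspace(0, 1, n_segments + 1)
        name = node.taxon.label if node.is_leaf() else ""
        segments.append({"branch": name, "length": node.edge.length or 0.0,
                         "values": v0 + fr * (v1 - v0)})
    return est, float(est[t.seed_node]), segments
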