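"""Rooted phylogenies with branch lengths, tree samples and Brownian-motion
utilities.

Wraps :mod:`dendropy` for parsing and topology; the Brownian-motion
covariance `C` (shared root-to-MRCA path lengths), Yule simulation and
trait simulation are implemented here on top of it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import dendropy
import numpy as np


def _schema_for(path) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    return "nexus" if ext in {".nex", ".nexus", ".trees"} else "newick"


@dataclass
class Phylo:
    """A single rooted tree with nonnegative branch lengths and unique tips."""

    tree: dendropy.Tree
    tip_labels: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.tree.is_rooted = True
        labels = []
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise ValueError("tree has unlabeled tips")
            labels.append(leaf.taxon.label)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")
        self.tip_labels = labels

    # ------------------------------------------------------------- parsing
    @classmethod
    def from_newick(cls, s: str) -> "Phylo":
        t = dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True,
                              suppress_internal_node_taxa=True)
        return cls(t)

    @classmethod
    def from_file(cls, path, schema: str | None = None) -> "Phylo":
        t = dendropy.Tree.get(path=str(path), schema=schema or _schema_for(path),
                              preserve_underscores=True)
        return cls(t)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True,
                                   unquoted_underscores=True).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ----------------------------------------------------------- structure
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def clone(self) -> "Phylo":
        return Phylo(self.tree.clone(depth=1))

    def subset(self, labels: list[str]) -> "Phylo":
        """Pruned copy retaining only the given tips."""
        t = self.tree.clone(depth=1)
        t.retain_taxa_with_labels(labels)
        return Phylo(t)

    def resolve_polytomies(self) -> "Phylo":
        """Return a binary copy (zero-length branches inserted if needed)."""
        t = self.tree.clone(depth=1)
        t.resolve_polytomies()
        for e in t.preorder_edge_iter():
            if e.length is None and e.head_node.parent_node is not None:
                e.length = 0.0
        return Phylo(t)

    def root_to_tip_depth(self, label: str) -> float:
        node = next(l for l in self.tree.leaf_node_iter()
                    if l.taxon.label == label)
        d = 0.0
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        return d

    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial clades as frozensets of tip labels."""
        out = set()
        n = self.n_tips
        for node in self.tree.preorder_internal_node_iter():
            tips = frozenset(l.taxon.label for l in node.leaf_iter())
            if 1 < len(tips) < n:
                out.add(tips)
        return out

    # ------------------------------------------------- Brownian covariance
    def vcv(self, order: list[str] | None = None) -> np.ndarray:
        """Brownian-motion covariance: C[i, j] = shared path length from the
        root to the MRCA of tips i and j."""
        order = order or self.tip_labels
        idx = {lb: i for i, lb in enumerate(order)}
        n = len(order)
        C = np.zeros((n, n))

        def visit(node, depth):
            blen = node.edge.length or 0.0 if node.parent_node is not None else 0.0
            depth = depth + blen
            if node.is_leaf():
                return [idx[node.taxon.label]]
            groups = [visit(ch, depth) for ch in node.child_nodes()]
            tips = [t for g in groups for t in g]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        for j in groups[b]:
                            C[i, j] = C[j, i] = depth
            return tips

        tips = visit(self.tree.seed_node, 0.0)
        for lb in order:
            C[idx[lb], idx[lb]] = self.root_to_tip_depth(lb)
        return C

    # --------------------------------------------------- trait simulation
    def simulate_bm(self, rate: float, rng: np.random.Generator,
                    root_value: float = 0.0, n_traits: int = 1) -> np.ndarray:
        """Brownian-motion tip values: Gaussian increments with variance
        ``rate * branch_length`` accumulated from the root. Returns
        (n_tips, n_traits) in ``tip_labels`` order."""
        values: dict[int, np.ndarray] = {}
        out = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                v = np.full(n_traits, float(root_value))
            else:
                t = node.edge.length or 0.0
                v = values[id(node.parent_node)] + \
                    rng.normal(0.0, np.sqrt(max(rate, 0.0) * t), size=n_traits)
            values[id(node)] = v
            if node.is_leaf():
                out[node.taxon.label] = v
        return np.stack([out[lb] for lb in self.tip_labels])


@dataclass
class TreeSample:
    """An ordered collection of trees over one shared tip set."""

    trees: list[Phylo]

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("empty tree sample")
        tips0 = set(self.trees[0].tip_labels)
        for i, t in enumerate(self.trees):
            if set(t.tip_labels) != tips0:
                raise ValueError(f"tree {i} has a different tip set")

    def __len__(self) -> int:
        return len(self.trees)

    @classmethod
    def from_file(cls, path, schema: str | None = None) -> "TreeSample":
        tl = dendropy.TreeList.get(path=str(path), preserve_underscores=True,
                                   schema=schema or _schema_for(path))
        return cls([Phylo(t) for t in tl])

    @classmethod
    def from_newicks(cls, newicks: list[str]) -> "TreeSample":
        return cls([Phylo.from_newick(s) for s in newicks])


def simulate_yule(n_tips: int, birth_rate: float = 1.0,
                  seed: int | np.random.Generator = 0,
                  labels: list[str] | None = None) -> Phylo:
    """Pure-birth (Yule) tree: lineages split at exponential waiting times
    until ``n_tips`` are extant; pendant edges extend to the final event.

    Tip labels default to t1..tn and are attached in a seed-determined
    random order, so group labels assigned by name are exchangeable with
    respect to topology.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_tips)]
    if len(labels) != n_tips:
        raise ValueError("labels length must equal n_tips")

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    active = [tree.seed_node]
    now = 0.0
    birth_times = {id(tree.seed_node): 0.0}
    while len(active) < n_tips:
        now += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(int(rng.integers(len(active))))
        node.edge.length = now - birth_times[id(node)]
        for _ in range(2):
            ch = node.new_child()
            birth_times[id(ch)] = now
            active.append(ch)
    now += rng.exponential(1.0 / (birth_rate * len(active)))
    order = rng.permutation(n_tips)
    for node, k in zip(active, order):
        node.edge.length = now - birth_times[id(node)]
        node.taxon = taxa.get_taxon(labels[k])
    tree.seed_node.edge.length = None
    return Phylo(tree)


def star_tree(labels: list[str], depth: float = 1.0) -> Phylo:
    """Star phylogeny: all tips attached to the root at equal depth."""
    s = "(" + ",".join(f"{lb}:{depth}" for lb in labels) + ");"
    return Phylo.from_newick(s)
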