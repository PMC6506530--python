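"""Phylogenetic comparative statistics on simulated traits.

K_mult measures multivariate phylogenetic signal against the Brownian
expectation (K = 1 under pure BM); PGLS fits a linear model with the
Brownian error covariance; Brownian ancestral states are estimated by
two-pass pruning; the MCC tree summarizes a tree sample.
"""

import numpy as np

from talonmorph import (TreeSample, ancestral_bm, kmult, mcc_tree, pgls,
                        simulate_yule)

tree = simulate_yule(21, seed=5)
rng = np.random.default_rng(0)

bm_traits = tree.simulate_bm(1.0, rng, n_traits=6)
res_bm = kmult(bm_traits, tree, n_perm=999, seed=1)
iid_traits = rng.normal(size=(21, 6))
res_iid = kmult(iid_traits, tree, n_perm=999, seed=1)
print(f"K_mult, Brownian traits: {res_bm.k:.3f} (p={res_bm.p:.3f})")
print(f"K_mult, iid traits:      {res_iid.k:.3f} (p={res_iid.p:.3f})")
# Brownian traits give K near 1 and a small p; iid traits give K well
# below 1 and no significance.

groups = ["a"] * 11 + ["b"] * 10
shifted = bm_traits + 3.0 * np.array([g == "b" for g in groups])[:, None]
res = pgls(shifted, tree, groups=groups, n_perm=999, seed=2)
print(f"PGLS trait ~ group: F={res.F:.2f}, p={res.p:.3f}")

trait = tree.simulate_bm(1.0, rng)[:, 0]
_, root, segments = ancestral_bm(trait, tree)
print(f"ancestral root state: {root:.3f} "
      f"(tip range {trait.min():.3f}..{trait.max():.3f}); "
      f"{len(segments)} interpolated branches")

sample = TreeSample.from_newicks(
    ["((A:1,B:1):1,(C:1,D:1):1);"] * 9 + ["(((A:1,C:1):1,B:2):0.5,D:2.5);"])
print("MCC tree of a 9-vs-1 sample:", mcc_tree(sample).to_newick())
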