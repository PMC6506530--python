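"""Geometric morphometrics of a synthetic radiation.

GPA aligns the 73-landmark configurations to unit centroid size, PCA
ordinates the aligned shapes, and permutational Procrustes ANOVA tests
the diet effect with residual randomization (RRPP).
"""

from talonmorph import (RadiationSpec, gpa, make_talon, pairwise_group_tests,
                        pca, procrustes_anova, simulate_radiation)

params, table, tree = simulate_radiation(RadiationSpec(seed=7))
landmarks = []
for sp in table["species"]:
    _, _, lm = make_talon(params[sp], (16, 12, 2))
    lm.specimen_id = sp
    landmarks.append(lm)

aligned = gpa(landmarks)
ord_ = pca(aligned)
print("per-PC variance (%):", [f"{v:.1f}" for v in ord_.pct_variance[:4]])

groups = list(table["diet"])
res = procrustes_anova(aligned, groups=groups, n_perm=999, seed=1)
print(f"shape ~ diet: F={res.F:.3f}, r2={res.r2:.3f}, p={res.p:.3f} "
      f"(df {res.df[0]},{res.df[1]}; {res.n_perm} permutations)")
levels, pmat = pairwise_group_tests(aligned, groups, n_perm=999, seed=2)
print("pairwise p (above diagonal), order", levels)
print(pmat.round(3))
# A large r2 with p at the permutation resolution means diet category
# explains most of the between-species shape variation.
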