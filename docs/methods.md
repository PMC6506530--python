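# Methods

## The model system

The package studies one question end to end: across a raptor radiation,
is the shape and the mechanical performance of the hallux talon (the bony
ungual of the rear toe) structured by relative prey size, by overall body
size, or by shared ancestry? Because real specimen scans are not bundled,
the study runs on a synthetic radiation whose generating truth is known;
every analysis module is nevertheless written for real landmark/mesh/tree
data and accepts the standard formats (TPS, CSV, PLY/STL/OFF, TetGen
.node/.ele, Newick/NEXUS).

## Parametric talon geometry

A talon is a solid swept along a circular-arc centerline in the sagittal
plane. Parameters (all lengths in mm, defaults in brackets):

* `arc_angle` [100°] — angle subtended by the centerline arc; the
  curvature proxy. Valid range (10°, 180°).
* `length` [20] — centerline arc length.
* `taper_exponent` [0.8] — section radius ∝ (1 − t)^p along the arc
  fraction t; smaller p is blunter.
* `base_height` [6], `base_width` [4.5] — proximal elliptical section
  diameters (dorso-ventral, medio-lateral). The articulation "robustness".
* `tubercle_amplitude` [1.2], `tubercle_position` [0.22] — height and arc
  position of a ventral Gaussian bump standing in for the flexor tubercle.
* `facet_depth` [0.6] — depth of the two cotyla depressions pushed into
  the proximal end face.
* `porosity` [0] — optional internal coaxial void fraction (≤ 0.3); a
  deliberately crude stand-in for trabecular structure.

The centerline is a constant-curvature arc rather than a logarithmic
spiral: it has one fewer parameter and the common claw-curvature measures
are arc-based. Foramina are landmark positions only, not holes, keeping
the surface watertight. The self-intersection guard rejects geometries
whose ventral surface would cross the arc center
(`base_height/2 + tubercle_amplitude ≥ 0.95 R`).

Meshing is structured and deterministic: cross-section rings at `n_axial`
stations × `n_circumferential` sectors × `n_radial` layers; each
hexahedral/wedge cell is fanned into tetrahedra around its centroid, with
quad faces split by a global smallest-index diagonal rule so the mesh is
conforming by construction. The default demo resolution (32, 16, 4) gives
≈ 22k tets; resolution is a free knob down to (8, 8, 2).

Ground-truth landmarks (8 fixed S1–S8, 65 semilandmarks on curves C1–C8:
10+10+9+8+7+7+7+7) are defined at parametric surface positions — tip,
mid-arc, tubercle apex, foramina, dorsal/ventral/lateral curves, facet rim
— and snapped to the nearest structured surface vertex, so they lie on the
mesh exactly at any resolution; along-curve equidistance is therefore
approximate at the one-grid-cell level.

## The simulated radiation

`simulate_radiation` evolves each shape parameter by Brownian motion
(variance = rate × branch length) on a tree rescaled to unit mean depth,
adds the tip's diet-category mean shift, multiplies the linear dimensions
by an isometric size factor, and clips to hard bounds (clipping logged;
> 20 % of species clipped raises a warning).

Conditions, chosen once to emulate the real sample:

* **Species and tree.** The 21 study species with their diet classes
  (10 SM / 7 ML / 4 NP) and a fixed ultrametric reference topology in
  which diet is phylogenetically clustered (hawk/eagle clade mostly ML,
  falcons + owls + kites SM, vultures/corvid/cockatoo NP). A Yule
  simulation is available instead (`tree=None`). Clustered diet matters:
  with diet assigned randomly on the tree, group shifts act as
  anti-phylogenetic noise and the phylogenetic signal of shape collapses,
  which is not what a real, taxonomically structured sample looks like.
* **Diet shifts** (SM baseline): ML +25° curvature, +1.0 mm tubercle,
  +0.6/+1.3 mm section diameters, +0.3 mm facet depth; NP the mirror
  image plus a −0.10 taper shift (blunter tip). ML geometry is
  stress-lowering — a one-factor-at-a-time FE sensitivity analysis shows
  section width and curvature dominate the landmark-sampled von Mises
  mean, so robust, curved, large-tubercled ML talons come out least
  stressed and slender NP talons most stressed, while the shift magnitudes
  (≈ 2–4 within-group SDs) give diet effects of roughly the strength the
  study design presumes (r² ≈ 0.5–0.8 at n = 21).
* **Residual Brownian rates** per unit tree depth: curvature sd ≈ 7°,
  length sd ≈ 1 mm, section sds ≈ 0.2–0.25 mm, tubercle sd ≈ 0.15 mm.
* **Size.** An iid per-species log-normal isometric factor (sd 0.4,
  ≈ 5-fold range) scales length, section diameters, tubercle and facet
  depth together. Size is deliberately independent of both diet and the
  phylogeny: each real diet class spans tiny to huge species, and the
  non-phylogenetic allometry regressions assume exchangeable sizes — a
  Brownian size trait on the shared tree is spuriously correlated with
  any other Brownian trait and would manufacture allometry that the
  construction is supposed to exclude. Body masses in the species table
  are fixed descriptive values and enter no analysis.

What passing tests on these data do **not** show: that the geometry spans
real talon shape space (no keratin sheath, no true trabecular
architecture, constant-curvature centerline), that real digitization
noise is represented (landmarks are noise-free), or that the effect sizes
match any particular empirical system quantitatively.

## Finite elements

Isotropic linear elasticity, small strain, 4-node constant-strain
tetrahedra; cortical bone E = 21,100 MPa, ν = 0.32 (steel, 200,000 MPa,
for the optional stiffened patches). The global system is reduced by
eliminating restrained translational DOFs and solved by sparse LU
(conjugate gradients with Jacobi preconditioning as an option, relative
residual 1e-10, error with residual history on non-convergence). Element
stresses are σ = D B u per element; von Mises from the Voigt tensor.

The comparative protocol: scale to the reference external surface area
with k = √(SA_ref/SA_model) on linear dimensions (the only dimensionally
consistent reading of an area-matching scale factor; the literal
√SA/SA_ref variant is kept behind `literal_formula=True` for
archaeology). Restraints: all translations at the tip node set and at the
two cotyla apex nodes — on rotation-free solid DOFs a translational pin
inherently leaves material rotation about the pin free, which realizes
"fixed in translation, free in rotation" as closely as solid elements
allow. Loads: total grip force (default 9.77 N) ÷ number of digits
(default 4) = 2.4425 N per digit, split equally between the medial and
lateral tubercle patches, along −z, distributed uniformly over each
patch's nodes. A beam-cage-like `stiff_patch` option couples patch nodes
through a steel truss network to spread the load; loads are never applied
to restrained nodes (applying both, as a commercial-solver protocol can,
is contradictory for solids).

Verification: uniaxial patch test exact to round-off (constant-strain
elements reproduce constant stress); slender cantilever converges
monotonically from below to PL³/(3EI) (3.2 % error at ≈ 104k tets);
reactions balance applied loads to 1e-8; doubling E halves displacements
and leaves stresses unchanged; the scale-free protocol maps a ×3 model
onto the identical stress field.

## Stress profiles

At 26 selected landmarks (default: the 8 fixed + 18 evenly indexed curve
points over the inner/outer/ventral curvature and the medial edge — the
identity of the selection is a config input, not a claim), each value is
the mean von Mises stress of the k = 4 elements with nearest centroids.
The default selection pool excludes curve points within 18 % of the
configuration extent of the talon tip: the tip is restrained in the
loading protocol, element stresses beside a restraint are singular (they
grow without bound under refinement) and differ between geometries for
reasons unrelated to the biology, so sampling there would make the group
comparison mesh-dependent. Element lookups are deterministic
(index-order tie-breaks; an incident-to-nearest-node mode
is available). A landmark farther than 10 % of the mesh diameter from any
centroid is treated as a frame mismatch and rejected. A specimen's
summary is the arithmetic mean over the 26.

## Statistics

One permutational engine serves every linear-model test: sums of squares
from projections onto nested design matrices, F = (SS_eff/df_eff)/
(SS_res/df_res), r² = SS_eff/(SS_eff+SS_res), inference by residual
randomization under the reduced model (RRPP) with the observed statistic
counted among the permutations — minimal p = 1/(n_perm+1), ties counted
conservatively, n_perm defaults to 999. Group designs are treatment-coded
dummies; single-member levels are rejected. With a scalar response and no
covariance the F equals the classical one-way ANOVA F exactly. Pairwise
group tests permute labels within each pair and use the Euclidean
(Procrustes) distance between group means.

GPA: center, scale to unit centroid size, rotate to the running consensus
by orthogonal Procrustes restricted to proper rotations, iterate to a
1e-10 change in total Procrustes distance (cap 1000 iterations —
noise-like configurations need a few hundred; convergence failure
raises). The stored consensus is the mean shape rescaled to unit CS. The
allometric battery regresses shape (or mean stress) on CS, optionally on
log CS, optionally excluding the NP group (the covariate follows the raw-CS
convention by default).

Semilandmark transfer: a 3D thin-plate spline (U(r) = r) anchored on the
8 fixed-landmark correspondences warps the template, then each
semilandmark is projected to the nearest point of the target surface
(exact point-triangle distance on KD-tree candidates). Optional sliding
minimizes thin-plate bending energy along local curve tangents with
re-projection for up to 5 cycles; sliding is off by default since the
transfer protocol alone defines correspondence.

PCM: the Brownian covariance C holds shared root-to-MRCA path lengths;
its inverse square root P comes from the symmetric eigendecomposition
(eigenvalue floor 1e-12, singular C raises), so P C Pᵀ = I and the
transform is stable under permutation. K_mult is the ratio of
non-phylogenetic to phylogenetically whitened sums of squares about the
GLS mean, normalized by its Brownian expectation; for one trait it equals
Blomberg's K exactly. PGLS whitens response and design by P and hands off
to the same RRPP engine, so a star phylogeny reproduces the ordinary fit
to machine precision. Ancestral states use two-pass pruning (precision-
weighted message passing), which equals the dense GLS solution; branch
values are linearly interpolated for continuous-trait maps. The MCC tree
maximizes the sum of log clade frequencies over the sample, ties broken
by first index.

## Pipeline scales

The default demo study is 21 species at (32, 16, 4) resolution
(≈ 22k tets/specimen) with 499 permutations — about a minute on one CPU.
Replicated calibration and pattern-recovery experiments run at
(12, 8, 2) with 199 permutations so that 50 full-study replicates finish
in a few minutes; mesh resolution changes absolute stress values but not
the group ordering or the inference structure. Reports are reproducible
bit-identically from (config, seed); all seeds are explicit arguments and
no global RNG state is used.

## Known limitations

* Constant-strain tetrahedra are stiff in bending; absolute deflections
  converge from below and coarse meshes understate stress gradients. The
  comparative conclusions rest on identical protocols across specimens,
  not on absolute accuracy.
* The landmark-snapping scheme ties ground-truth landmark positions to
  the mesh resolution; comparing configurations generated at different
  resolutions mixes discretization into shape.
* The pairwise permutation test and the RRPP ANOVA assume exchangeable
  specimens; with phylogenetically structured data only the PGLS/K_mult
  battery accounts for relatedness.
* Porosity is a coaxial void, not trabecular architecture; external
  surface area only is used for scaling.
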