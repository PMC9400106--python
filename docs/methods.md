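# Methods

This note records the models, conventions and numerical choices behind
`taamkit`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and where the genuinely open design choices were
made.

## The pseudoatom model

Each atom type carries a Hansen–Coppens multipolar pseudoatom:

ρ(**r**) = ρ_core(r) + P_val κ³ ρ_val(κr) + Σ_{l≤4} κ′³ R_l(κ′r) Σ_m P_lm d_lm(θ, φ)

* `P_val` (electrons) is the spherical valence population; `κ` and `κ′`
  (dimensionless, ≈1) contract or expand the spherical and deformation
  valence shells.
* `d_lm` are real spherical harmonics in the *density* normalization:
  `d_00 = 1/4π` and `∫|d_lm| dΩ = 2` for `l > 0`, so `P_lm = 1` shifts one
  electron between the function's positive and negative lobes. The angular
  parts use `scipy.special.lpmv`, i.e. the Condon–Shortley phase is kept
  for odd m. With this sign choice, bond-directed deformation lobes
  reproduce the dominant-multipole signs familiar from transferable
  pseudoatom banks: a tetrahedral sp³ type shows a **negative P32** in a
  frame whose Z bisects two bonds (ZabXc), and a trigonal planar sp² type a
  **positive P33** in a frame whose X bisects two bonds (XabYa). The
  normalization prefactors are computed at import time from the exact
  `∫|P_l^m|` integrals (adaptive quadrature with analytic break points),
  not from a hard-coded table.
* Radial functions are normalized single-ζ Slater forms
  `R(r) ∝ r^n e^{-ζr}`. The per-element exponents shipped in
  `hansen_coppens.default_radial_model` are an internally consistent
  package choice (twice single-ζ orbital exponents, converted to Å⁻¹);
  every statistical operation in the package acts on the parameters
  themselves, and the density evaluator exists chiefly as the geometric
  oracle that validates parameter rotation. Points closer than 1e-4 Å to
  the nucleus are clamped to that radius.

## Rotating populations between local coordinate systems

A local coordinate system (LCS) is built from two axis specifications
(toward a neighbor, toward the average of two or three neighbors, toward
the nearest non-collinear distant neighbor, or any-orthogonal), the third
axis following from the right-hand rule. Eight groups classify atom types
by first-neighbor count and arrangement (1x, 1p, 2x, 2p, 3p, 3n, 4n, 6n);
the enumeration yields 1, 1, 2, 6, 12, 16, 40 and 1 systems respectively,
with rotation numbers banded per family (1–12 ZaXb, 21–32 XabYa, 41–52
ZabXc, 61–64 ZabcXa, 71–72 ZabYa).

Rotation matrices for the real harmonics are obtained by numerically exact
quadrature projection in the orthonormal basis (Gauss–Legendre × uniform
azimuth, sized to integrate all degree ≤ 2·l_max products exactly; an even
θ-node count keeps grid points off the equator so symmetry operations
cannot map them onto the poles, where `√(1−z²)` would amplify rounding).
Populations transform as `p′ = C⁻¹ D C p`, where `C` is the diagonal
density↔orthonormal rescaling. Two consequences worth noting:

* `κ`, `P_val`, `κ′` never change under a frame change.
* Because the density-normalized harmonics are **not** orthonormal (their
  constants differ with |m| by a few percent), the raw Euclidean norm of a
  `P_lm` block is *not* exactly conserved; the conserved quantity is the L2
  function norm `‖C p‖` per degree, exposed as `harmonics.plm_l_norms` and
  verified to 1e-9 in the tests. The density-grid oracle (rotate
  parameters vs. rotate the evaluation grid) agrees to better than
  1e-6 e Å⁻³.

Improper operations are excluded from `rotate_plm`; mirror symmetry is
handled analytically in the symmetry module via the parity factor (−1)^l.

## Site symmetry

Allowed `(l, m)` sets per point group (1, m, mm2, 3m, −6m2, −43m,
cylindrical) are *derived*, not tabulated: the group is closed from its
generators, each element's action on the d-basis is assembled, and an index
is allowed iff the group-averaged projector does not annihilate it. The
orientation conventions match the frames that reveal each symmetry (mirror
of `m` = local XZ plane; 3-fold of `3m` along Z with an XZ mirror; −6m2
adds the horizontal mirror; −43m is conjugated into the ZabXc realization).
Symmetry detection returns the largest-order candidate whose disallowed
indices all stay below a tolerance (default 0.005 e, just above the
0.002 e storage floor). Note that with these conventions mm2 is *not* a
subgroup of −6m2 (its YZ mirror is not one of the three σ_v), so allowed-set
containment holds only along generator-subset chains.

## Topology trees

Trees divide types by element → number of first neighbors → first-neighbor
elements → number of second neighbors → second-neighbor elements → type
names (extended), stopping before the second-neighbor levels (general) or
additionally dropping first-neighbor elements and names (concise).
Planarity and ring membership are node annotations, never dividing
criteria; types that cannot have second neighbors carry the value "none".
Density-cluster overlays categorize each type from its per-frame labels:
`main` (all rotations in the per-dataset largest cluster), `distinct`
(some rotations detach), `unique` (only singleton clusters), `outlier`
(all rotations noise), `complex` (anything else).

## Density clustering

Features are 18-dimensional: κ, P_val, κ′ and the fifteen dipole–octupole
populations. Hexadecapoles are supported by the model but intentionally
excluded from clustering features. Transforms: subtraction (κ−1, κ′−1,
P_val minus the formal valence-electron count) and column-wise L2
normalization, composable, with an optional uniform scale factor applied
last (cosmetic only — it cancels in relative distances).

Eps selection uses the sorted k-nearest-neighbor distance curve
(k = MinPts, exact-duplicate rows removed first so indistinguishable
rotations cannot flatten the curve to zero) and the chord rule: the knee is
the curve point of maximum perpendicular distance to the straight line from
first to last point. DBSCAN itself is scikit-learn's, with labels
renumbered deterministically by order of first member row; a brute-force
O(n²) implementation serves as an independent oracle in the tests.

The multi-level protocol clusters all rows once (MinPts = 2 by default),
then re-clusters any cluster whose *original-scale* Plm sample standard
deviations exceed 0.05 e — κ, P_val and κ′ sds never trigger subdivision,
since they do not depend on the frame. Eps for each sub-run comes from a
replayable schedule keyed by cluster path, or from a fresh knee estimate.
Outliers (−1) terminate a label path and are never subdivided; recursion is
capped at four levels. Labels accumulate into underscore-joined paths
("10_0_16_3"). The sd criterion is evaluated in electrons on the original
parameter scale regardless of the distance-space transform, because the
0.05 e threshold is a physical one.

## The synthetic bank generator

The generator is the package's test substrate: it emulates the statistical
structure of a real multipolar databank with known ground truth. Each
planted cluster specifies an element, group, hybridization, point group,
reference frame family and mean parameters; member atoms get idealized
neighbor geometries (linear, bent at 104.5°, trigonal planar, pyramidal,
tetrahedral, octahedral) with Gaussian angular jitter (default 2° sd), and
deformation patterns are *bond directed*: the degree-limited expansion of
lobes along bonds and lone pairs (lone pairs weighted 1.3), which inherits
the point symmetry of the direction set exactly. Member populations are
stored in the global frame, so any frame recomputation must genuinely
rotate them back.

Default study conditions (chosen once, with the reasoning below):

* `P_val` drawn around the formal valence-electron count, κ/κ′ around 1.
* Member-to-member Plm noise 0.02 e — below the 0.05 e inconsistency
  threshold, so default banks are consistent; a "hard" preset at 0.08 e
  exercises the flag. The flag lives on the bank entry, computed in the
  type's own reference frame; rotated rows in deliberately misaligned
  frames may legitimately inflate above the threshold, as real rotated
  banks do.
* Type-to-type scatter within a planted cluster (0.002 e per Plm, 0.005 e
  on P_val, 0.003 on κ/κ′) is kept an order of magnitude below the
  between-cluster pattern separations (0.1–0.35 e dominant populations, in
  the field-typical range), so that planted clusters are recoverable at
  this reduced problem size: the knee-estimated Eps tracks the intra-blob
  distance scale, and recoverability requires that scale to sit well below
  the separations.
* 16 member atoms per type, so member-noise offsets (0.02/√16 per
  dimension) stay inside the intra-blob floor.
* The default spec plants 11 clusters over H/C/N/O/S across groups 1x, 1p,
  2x, 2p, 3p, 3n and 4n — polar vs nonpolar hydrogen, sp³/sp²/sp¹ carbon,
  pyramidal nitrogen, water-like and terminal oxygen, a sulfur analogue
  with larger populations — plus two deliberately *unique* types. The
  unique types serve two purposes: they exercise the "unique" overlay
  category, and they anchor the upper end of the k-distance curve so the
  chord knee lands above the type-offset rise (real banks likewise contain
  types unlike any other).

Ground truth for recovery scoring labels each (type, frame) row with the
planted cluster id *and* the frame's system family: rotations of one type
in different families genuinely carry different population vectors, while
within a family all rotations coincide because the planted patterns carry
the maximal site symmetry of their group.

**What the generator does not emulate:** real quantum-chemical parameter
distributions (bond-directed lobes are a geometric caricature — e.g. real
sp³ nitrogen deviates toward sp²-like patterns), correlations between κ
and P_val, population-weighted sds, heavier elements, and the long tail of
rare chemical environments. Passing the recovery tests therefore shows the
*pipeline* is correct on data with known structure, not that a real bank
would cluster this cleanly.

## Scaled-down problem sizes

The default synthetic bank has ~54 types and ~530 rotated entries — the
same group structure as a 651-type bank that blows up to 11 064 rotated
entries, at a size where the whole pipeline (generation, rotation in all
frames, multi-level clustering) runs in well under a minute. The
frame-enumeration census itself is exact combinatorics and is checked
against the published per-group counts at full scale. Statistics reported
for a real bank (cluster counts, outliers, inconsistency fractions) are
only reproducible with the real bank as input; the pipeline accepts one in
the documented text dialect together with a replayable Eps schedule.

## Known limitations

* Frames engaging all four neighbors of a 4n type simultaneously are not
  implemented (no such system family is defined here).
* `rotate_plm` rejects improper operations by design; mirrors act only
  inside the symmetry module.
* Rotating a bank without member atoms (`rotate` without `--members`) uses
  idealized group geometries and propagates sds through squared rotation
  blocks under an independence assumption — a fallback, not a substitute
  for member-level recomputation.
* The knee rule is one fixed, documented variant; other Eps heuristics
  exist and give different values on the same data.
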