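# Methods

This note documents the models, algorithms and numerical choices behind
`tractshift`, what the synthetic generator does and does not emulate, and
the limits of what the test suite shows.

## Problem setting

Two species' cortices are represented as spheres (the standard inflated
registration domain) carrying per-vertex scalar maps. Cross-species change
in a tract's cortical terminations is decomposed into (i) *relocation* —
homologous areas moved because the cortical sheet expanded unevenly — and
(ii) *extension* — the tract innervates territory beyond what relocation
predicts. Relocation is modelled by a surface-to-surface registration
driven by myelin-like maps (high in primary sensory/motor cortex, low in
association cortex, and similar enough across species to compare like with
like); whatever the registered prediction fails to cover is attributed to
extension.

## Spherical registration

A `Registration` stores, for every source-sphere vertex, a position on the
target sphere ("warped sphere" convention). `apply_registration` resamples
a source map at target vertices through the warped source mesh, i.e. the
inverse correspondence; `compose` interpolates one warp field at another's
warped positions, which makes chained species pairs (A→B, B→C ⇒ A→C)
cheap and keeps every stage in the same representation.

**Objective.** Similarity is the mean of windowed Pearson correlations
between the z-scored source feature and the target feature sampled at the
current warp. Windows are geodesic discs with fixed membership on the
*source* sphere (centers on a level-2 icosphere, radius
`max(similarity_window/2, 1.6 × center spacing)`), so a candidate move
changes only the sampled values of the vertices it touches and the full
objective can be re-evaluated exactly — every accepted move strictly
increases the global objective, giving a non-decreasing objective history
by construction. Windows are weighted by their source-feature variance:
featureless windows would otherwise reward aligning noise. The distortion
penalty is the mean squared log2 areal ratio over faces plus mean squared
log edge strain, weighted by `regularization_weight` (λ, default 0.02).
λ is deliberately small because genuine cross-species expansion *is* a
large distortion; its role is to suppress noise-chasing, not to keep the
warp rigid.

**Optimization.** A rotation pre-stage first hill-climbs over global
rotations (±8°, 4°, 2°, 1°, 0.5° about the coordinate axes) — a bulk
rotation is isometric, invisible to the distortion penalty, and poorly
handled by local moves. Then, for control grids of increasing resolution
(icosphere levels 1..`levels`, default 2), each control point is visited in
index order and nine candidates are scored: no move, or a capped tangent
step in 8 directions, applied to nearby vertices with a Gaussian falloff
(σ = 0.6 × control spacing) and re-projected to the sphere. Steps are
capped at 0.45 × control spacing and swept at fractions (1, ½, ¼, ⅛) of
that cap per level. Candidates that would make any touched face's scalar
triple product non-positive (a fold) are rejected outright, so the result
is fold-free without post-hoc fixing; ties break toward "no move" and then
the lowest direction index, making the search deterministic —
identical inputs give bit-identical warps.

The control grids are kept much coarser than the data mesh on purpose.
With one control point per data vertex the similarity term can overfit:
in experiments the objective kept rising while the warp drifted away from
the ground truth by aligning the smooth noise fields of the two maps. Two
control levels (42 + 162 points for a 642-vertex source) plus the variance
weighting and the small λ remove most of that failure mode. Residual
recovery error is dominated by regions where the feature field has little
structure — exactly the regime in which any feature-driven registration is
underdetermined.

**Two stages.** Stage one (`roi_initialize`) matches three binary landmark
ROIs: a least-squares (Kabsch) rotation of the ROI centroid directions is
compared against the identity under the same objective — whichever scores
better seeds the refinement — and the refinement runs the optimizer on the
lightly smoothed ROI indicators (smoothing at a common angular scale of 8°
so differently-sized spheres yield comparable fields), all channels at
once. Stage two aligns the whole myelin maps starting from stage one's
warp. If stage two cannot improve on its initialization it returns the
initialization unchanged with a logged warning rather than failing.

**QA maps.** `distortion_map` reports per-vertex log2 of warped/original
incident spherical (solid-angle) area. Because solid-angle triangle areas
tessellate the sphere exactly, the area-weighted mean of `2^value` equals
the squared radius ratio to rounding error — the conservation law the tests
assert at 1e-6. `local_similarity_map` is the plain windowed Pearson
correlation between a transported map and the target map.

## Tractogram → tract map

A tractogram is a voxelwise streamline-visitation volume with a `waytotal`
count; it is normalized by dividing by waytotal. Surface projection
multiplies a sparse vertex × voxel connectivity matrix by the normalized
tractogram. Before projection, each matrix entry is divided by the
Euclidean vertex-to-voxel distance (re-balancing deep vs superficial
voxels); distances under half a voxel edge are clamped there, since a
vertex inside a voxel would otherwise dominate. "Euclidean" is a choice:
streamline path length would be an alternative, but the matrix carries no
path information. Per-subject matrices are averaged before use.

Raw projected maps are smoothed on the (mid-thickness) surface with a
truncated geodesic Gaussian (exact arc distances on spheres, Dijkstra edge
distances on anatomical meshes; truncation at 3σ with per-vertex weight
renormalization, invalid vertices excluded from numerator and denominator),
then mapped to [0, 1] by the monotone compression
`y = log(1 + x/ε̂) / log(1 + max(x)/ε̂)` with `ε̂ = max(x) × 1e-3`.
The transform maps 0 → 0 and the maximum → exactly 1, compresses the heavy
right tail typical of tractography intensities and preserves rank order;
it is recorded in map metadata so an alternative transform could be swapped
in. Medial-wall/insula-style exclusion masks simply invalidate vertices,
which removes them from all downstream thresholds and statistics.

## Comparison statistics

The binarization threshold is the k-th largest valid value of the
*reference* map with `k = round(coverage_fraction × n_valid)` (default
coverage 0.40; robustness sweep at 0.20/0.30/0.50); the same absolute
threshold binarizes the predicted map. Ties at the threshold are all
included, so realized coverage can exceed the target by the tie count
(logged). Per-pair statistics are Dice `2|H∩P|/(|H|+|P|)` and the extension
ratio `|H|/|H∩P|` (≥ 1 by construction; +∞ with a warning if the sets are
disjoint). Statistics are always computed on per-pair records (every
reference subject × every other-species subject), never on averaged maps;
group maps are used only for display-style outputs. The weighted
correlation map multiplies the windowed correlation by the rescaled product
of the two intensities (post-multiplication; in-window weighting and no
weighting are available as options), so it is high only where both tracts
terminate *and* their spatial patterns agree. Connectivity fingerprints
are the per-subject vectors of tract-map intensities at a chosen vertex
across a fixed, ordered tract set.

## Permutation inference

Extension ratios form a balanced species × tract design with the reference
subject as a repeated-measures block. The engine fits fixed effects
(subject intercepts as nuisance, effect-coded species, tract and
interaction) and computes F statistics from projection-matrix quadratic
forms. Null distributions use Freedman–Lane permutation: the reduced model
(all terms but the tested one) is fitted, its residuals are permuted
*within subject blocks*, re-added to the reduced fit, and F is recomputed;
p = (1 + #{F* ≥ F}) / (1 + n_perm), so the smallest attainable p is
1/(n_perm + 1). Family-wise error over the three contrasts uses
Westfall–Young min-p on the same permutation stream, and corrected p is
clamped to be ≥ uncorrected. A Manly scheme (permuting raw data within
blocks) is selectable. This fixed-effects-with-blocks construction is an
approximation of a mixed model — exchangeability is assumed within
subject, not modelled; the calibration simulation in the acceptance suite
(200 null tables, 499 permutations) checks that per-contrast type-I error
stays within [0.02, 0.09] at nominal 0.05. Sign-flipping is not used
(ratios are bounded below by 1 and not sign-symmetric).

## Synthetic data: what it emulates, what it does not

The generator defines the study conditions: a reference cohort of 20
subjects and two other-species cohorts of 5; spheres of differing
resolution and radius (reference: level-4 icosphere, 100 mm; others:
level 3 at 50 and 80 mm); tract-map smoothing kernels of 4/3/2 mm.

*Canonical fields live in reference space.* The myelin field is a sum of
angular-Gaussian landmarks — three sharp ROI-defining bumps (motor-strip-,
MT+- and occipital-pole-like) plus a fixed field of broad and fine texture
bumps standing in for the myelin structure of association cortex. Each
other species sees the canonical field through its ground-truth warp
(its map at vertex v is the field evaluated at W(v)), which keeps multiple
species mutually consistent and makes W the exact registration target.
Without the texture component the registration problem is underdetermined
away from the landmarks; real myelin maps are informative nearly
everywhere, so the texture is realism, not a convenience.

*Deformations* superpose radial expansion fields: inside a hotspot of
extent Θ, a point at angle θ from the center moves outward by
`m·sin(πθ/Θ)`; each field is a diffeomorphism when the peak displacement
m < Θ/π (validated at construction), and the superposition is explicitly
checked for folds. Default hotspots cover most of the sphere with peak
displacements of 10–16°, so the identity baseline has a well-defined
nonzero median error. Total area is conserved exactly (sphere-to-sphere
bijection).

*Tract scenarios.* The termination patch is a cap in reference space with
a Gaussian falloff (a smoothed indicator); the source species' map is the
same field seen through its warp. Under *relocation* the target map is
exactly the transported source map; under *extension* the reference map
additionally contains a disjoint patch (disjointness of the cap cores is
validated). A per-species `extension_presence` lets one species' tract
reach part of the extension territory, which is what creates a genuine
species × tract interaction. Subject cohorts add smooth multiplicative
(sd 0.10) and additive (sd 0.05, 10° correlation scale) noise, clipped to
[0, 1]. Synthetic tractography draws streamline endpoints around the
patch (both patches, 70/30, for extension tracts), rasterizes straight
core-to-endpoint segments into voxel counts, and builds a vertex-voxel
matrix with Gaussian capture of voxels within two voxel edges of each
vertex.

Not emulated: cortical folding and gyral bias, realistic dMRI noise and
tractography artifacts, hemispheric asymmetries (hemispheres are
independent seeded replicates), partial-volume effects. Passing tests
therefore show the *inference chain* is correct under its assumptions —
that a fold-free feature registration recovers smooth deformations well
enough to separate relocation from extension — not that any particular
real-data result would replicate.

## Problem sizes and runtimes

Analyses in tests and examples use level-3/4 icospheres (642/2562
vertices), chosen so the complete suite (including a 20-seed scenario
discrimination study, 5-seed two-stage recovery runs and a 200-replicate
permutation calibration) completes in minutes on one CPU. Registration of
a level-3 source to a level-4 target takes a few seconds per stage. The
scenario-discrimination study registers with the whole-map feature stage
from the identity (its species differ by expansion only); the two-stage
path is exercised by the recovery suite.

## Numerical conventions

- Vertex indexing is 0-based everywhere, including on-disk text formats.
- NaN in a map ⇔ invalid vertex; invalidity propagates through resampling
  (any contributing invalid corner) and excludes vertices from statistics.
- Spherical point location: candidate faces from the nearest vertices'
  incidence lists, barycentric coordinates by scalar-triple-product
  Cramer's rule, acceptance at −1e−9; numerically homeless points snap to
  the nearest vertex with a logged warning.
- Geodesic Gaussian smoothing truncates at 3σ and renormalizes weights.
- Sphere faces are outward-oriented (positive scalar triple product); any
  non-positive orientation counts as a fold.
- GIFTI stores float32 (the format's conforming type); the OBJ/CSV text
  fallbacks carry full float64 precision. JSON artifacts are written with
  sorted keys, and the pipeline manifest records the SHA-256 of every
  output, so identical (config, seed) reruns are byte-identical.

## Known limitations

- Registration quality is feature-limited: in regions where the myelin
  field is flat the warp stays near its initialization, and mean recovery
  error with realistic map noise is roughly half the identity baseline
  (about a third without noise). Claims about fine-grained homology in
  featureless cortex are outside what the method can support.
- The extension ratio saturates at +∞ when the prediction misses the
  reference tract entirely; records carry the sentinel, and the permutation
  engine expects finite ratios (guaranteed in the synthetic scenarios).
- The permutation engine's block scheme is a documented approximation of a
  mixed model, adequate for the balanced designs produced here.
- The 40° correlation window is treated as an angular radius; on spheres
  of different physical radius the metric window differs accordingly.
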