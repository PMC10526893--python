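# Methods

This note documents the models, conventions and numerical choices behind
`nodalmap`, what the synthetic phantom does and does not emulate, and the
problem sizes used in the validation suite.

## Coordinate contract

All geometry lives on `ImageGrid`s: world coordinates are millimetres in
the image header's frame, the origin is the *center* of voxel (0,0,0), and
every volume is reoriented to RAS+ (+x right, +y anterior, +z superior) on
load.  A fixed internal orientation is essential here because half of the
20 nodal levels are bilateral: a silent left/right flip would corrupt the
involvement distribution while leaving every magnitude unchanged.  Label
maps are piecewise constant, so point lookups use the nearest voxel center
with indices rounded half away from zero; interpolating a label map is
meaningless.  Companion volumes (GTV mask vs level volume) must share a
grid exactly — mismatches are hard errors, never silent resampling,
because assignment distances are physical millimetres on these grids.

## Node isolation

Clinically contoured nodal GTVs often merge abutting metastases.  Nodes
are separated by erosion with an ellipsoidal structuring element whose
radius is specified in mm and converted to voxels per axis (so a 2 mm
radius reaches one voxel in-plane but zero voxels across 3 mm slices),
connected-component labelling (26-connectivity by default), and geodesic
reconstruction of each eroded core inside the original mask, implemented
as a marker-based watershed on the negated interior distance transform.
Consequences that the tests rely on:

* the final components exactly partition the original foreground — the
  erosion separates nodes but never shrinks the analyzed mask;
* components that vanish entirely under erosion (small nodes) are retained
  unsplit, and an erosion that removes all foreground falls back to the
  raw components with a logged warning;
* node centers are unweighted centroids of the *reconstructed* components
  in world mm.  Computing centers on the eroded cores instead would bias
  them for boundary-asymmetric nodes; whether the original clinical
  pipeline used eroded or reconstructed components is not stated anywhere,
  so the unbiased choice is made and documented here.

The default erosion radius of 2 mm splits necks of clinically sized
touching nodes (the splitting threshold for two 6 mm-radius spheres sits
near tangency) without destroying small nodes; the structuring element
always retains its center voxel.

## Level assignment

A node center inside a level's label voxels is assigned to that level with
distance 0.  Otherwise the node is assigned to the level with the nearest
foreground *voxel center* in Euclidean mm — "nearest surface" is undefined
on a voxel grid, while voxel-center distance is unambiguous, consistent
across resolutions and identical in spirit to the containment lookup.
Distances are computed exactly with one KD-tree per level; a deliberately
independent brute-force scan over every foreground voxel is kept in the
package and the two are cross-checked on ≥ 1000 random instances in the
acceptance suite.  There is no maximum distance: every node receives a
level, and the fraction assigned from outside the segmentations is
reported per cohort.  Distances within 1e-9 mm of the minimum count as
tied; ties are resolved by the canonical level ordering (1a, 1b_L, 1b_R,
2_L, 2_R, …), which deterministically favours the left member of a
mirrored pair for a node exactly on the midline.  Ties are logged.

## Multireader majority voting

Each reader either confirms a node's automated level or corrects it to a
named level (self-corrections and duplicate votes are rejected).  Per
node, every reader contributes one effective label; a label wins only with
a strict majority, and without one the automated label is kept.  The
fallback matters in exactly two situations — an even split, or three
readers proposing three different labels — and keeping the automated call
is the conservative choice consistent with review framed as
confirm-or-correct.  Under this rule a cohort in which no node is
corrected by two readers always yields a consensus equal to the automated
distribution, which is precisely the structure of the embedded reference
cohort (one reader with five corrections, one with none, one with one, on
distinct nodes).

## Template mapping

A patient→template transform is an invertible 3×3 affine plus translation
(mm), optionally composed with a dense displacement field on a
template-space grid: y = Ax + b, then y' = y + v(y) with v sampled
trilinearly (nearest-edge values outside the field's grid, with a
warning).  Transforms interchange as a 4×4 text affine plus a NIfTI vector
field (4th dimension = 3, values in mm), which keeps the package
interoperable with common registration toolchains without binding to any
one format.  Computing transforms is a pluggable backend: `identity`,
`synthetic` (replays a phantom's stored ground-truth transforms), or an
external engine following the documented recipe (rigid → affine →
B-spline-SyN with cross-correlation, cost-function masking over tumor and
nodal GTV voxels).  Intensity-based registration and average-template
construction are long-running external computations and are deliberately
out of scope; the package defines patient→template as the forward
direction and requires inputs in that convention.

## Kernel density estimation

The cohort density is a sum of equal-weight Gaussian kernels at the mapped
node centers, bandwidth in mm of template world coordinates (default
4 mm), distance measured with a p-norm (default p = 2, for which the
kernel is separable and evaluated as an outer product of 1D factors).
Evaluation is exact at the voxel centers of an isotropic grid (default
2 mm) covering the template extent; each kernel is truncated at 6
bandwidths (~1e-9 of its mass).  Two normalization steps are applied:

* **per-kernel discrete normalization** — each kernel's lattice values are
  divided by their sum, so every point contributes identical mass even
  when the bandwidth is far below the grid spacing.  Without this, a
  sub-voxel-bandwidth kernel centred near a voxel center would outweigh
  one centred near a cell corner after global normalization, and the
  small-bandwidth limit would not recover the empirical histogram.  For
  bandwidths at or above the grid spacing the correction is negligible
  (the discrete sum approximates the continuous integral to high order);
* **global renormalization** so the voxel sum times the voxel volume is
  exactly 1 (checked to 1e-6), absorbing truncation and boundary clipping.

Per-level involvement is predicted by partitioning *every* evaluation
voxel into exactly one level with the same rule used for nodes (inside,
else nearest level by per-level Euclidean distance transforms, canonical
tie-break) and summing density mass per cell.  Reusing the node rule makes
node-wise and density-wise attribution mutually consistent, makes the
residual (mass outside all cells) identically zero, and means the
small-bandwidth limit of the predicted proportions is the empirical
assignment histogram.  How density mass outside the level contours was
attributed in the original clinical analysis is not stated; the exhaustive
partition is this package's choice.

## Chi-squared comparison

The default comparison is a Pearson goodness-of-fit of the observed
per-level counts against expected counts nᐧp̂ from the predicted
proportions: cells with expected mass below 1e-12 and zero observations
are dropped, df = retained cells − 1, upper-tail p from the χ² density, no
continuity correction.  An observed count where the prediction puts no
mass yields an infinite statistic (p = 0) rather than an error.  A
two-sample homogeneity variant (2×k contingency table) is available via
`method="homogeneity"`; the goodness-of-fit orientation is the default
because the scientific question is whether the mapping-based prediction
explains the observed distribution.  Calibration is verified by
simulation: 500 multinomial null replicates at n = 449 under the phantom's
default probabilities (smallest expected count ≈ 4.5, within the usual
validity range for the Pearson approximation) must give an α = 0.05
rejection rate within 3 standard errors of 5%.

## The phantom

The phantom generates the *geometry* the pipeline consumes, not anatomy or
CT intensities.  Its defaults define the validation conditions:

* grid 96×96×64 voxels at 2×2×3 mm — desk-scale while preserving the
  anisotropic 3 mm slice thickness of head-and-neck planning CTs;
* 20 pairwise-disjoint ellipsoidal compartments, exactly mirror symmetric
  about the midsagittal voxel plane, elongated along y (≈28 ml for the
  lateral compartments) so several non-touching nodes fit in one level;
* per-level probabilities emulating a definitive-chemoradiation cohort:
  level 2 ≈ 58% bilaterally, level 3 ≈ 22%, smaller mass on 1b, 5, 4a and
  8, none elsewhere; node counts per patient uniform 1–6; node radii
  uniform 4–10 mm (spanning the 2 mm erosion radius so splitting logic is
  exercised);
* per-patient deformations: a random translation (±2 mm) composed with a
  Gaussian-smoothed random displacement field (amplitude 4 mm, smoothness
  12 mm), checked for invertibility via its Jacobian.  The patient volume
  is the pull-back of the template through the stored patient→template
  transform, so generated geometry and ground-truth transform are exactly
  consistent by construction.

Nodes are placed by complete search: candidate centers are voxels whose
interior distance exceeds the node radius and whose distance to already
placed nodes exceeds the sum of radii plus one voxel diagonal (keeping
planted nodes 26-disconnected, so component analysis must recover exactly
one record per node).  Crowded compartments are handled by annealing the
radius draw toward its minimum and, if needed, restarting a patient's
placements with fresh radii and positions.  Levels are drawn *before*
placement from the untouched random stream, so the pooled level
distribution remains exactly multinomial in the specified probabilities
regardless of restarts; node radii, in contrast, are mildly conditioned on
feasibility in crowded compartments.

What the phantom does not emulate — and therefore what passing tests do
not show about clinical data: realistic anatomy and level shapes, CT
intensities and contouring noise, segmentation errors in the level
autosegmentation, registration error (phantom transforms are exact by
construction), and non-spherical or confluent nodal masses beyond what the
erosion tests construct explicitly.

## Validation problem sizes

The acceptance suite and `scripts/acceptance.py` use: the embedded
449-node reference tables for the review statistics; ≥ 1000 random
instances for the assignment oracle cross-check; a deformed 500-node
cohort mapped with true transforms for density parameter recovery, where
each level's predicted proportion must fall within 3 binomial standard
errors of its generating probability plus a 2/n discretization allowance
(the same bound as the small-bandwidth limit; a pure 3·SE bound would
demand exactly zero predicted mass in zero-probability levels, which no
kernel method attains); 500 null replicates for χ² calibration; and a
30-patient undeformed cohort for end-to-end determinism and 100%
ground-truth recovery.

## Known limitations

DICOM-RT ingestion rasterizes contours by the voxel-center-in-polygon rule
(no hole support) and is an optional adapter, not a validated clinical
converter.  The distance convention (voxel centers, not surface meshes)
can differ from mesh-based distances by up to half a voxel diagonal near
level boundaries.  Level compartments absent from a patient's label volume
simply never win an assignment.  The chi-squared test treats nodes as
independent draws; within-patient correlation of nodal involvement is not
modelled.
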