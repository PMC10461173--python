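# Methods

## Match graphs

A scan pair's correspondences are an undirected bipartite graph over the two
scans' lesion index sets, augmented with one sentinel node per side (NEW on
the scan-1 side, DISAPPEARED on the scan-2 side). Sentinels are reserved
tokens, never the integer 0 — the zero convention exists only in the
two-column workbook CSV dialect, where a 0 entry means "no counterpart on
that scan". Edges are stored canonically as (scan-1 element, scan-2 element)
and graph equality is set equality. Invariants enforced: no (NEW,
DISAPPEARED) edge; every real lesion has at least one edge; a lesion is
either matched to real lesions or carries exactly its sentinel edge, never
both. Many-to-one, one-to-many and many-to-many edges are allowed, because
lesions split and merge between scans. Whether a lesion could legitimately
be "partially new" (matched *and* flagged new) is a modelling question with
no clear clinical answer; we adopt the exclusive-or rule and
`validate_graph` reports violations as data rather than raising, so reader
workbooks that break it can still be inspected.

## The matcher

Pipeline order: registration → resample scan-2 labels onto the scan-1 grid
(nearest neighbor) → connected-component indexing if the input is binary →
volume filter → dilation → within-scan clustering → cluster assignment →
expansion to lesion edges. All overlap computation happens on the scan-1
grid in physical units; cross-volume operations never compare voxel indices
directly.

**Parameters.**

| parameter | default | meaning |
|---|---|---|
| `dilation_mm` | 25 | radius (mm) of the Euclidean ball each lesion mask is dilated by; absorbs residual registration error. Note the *matching tolerance* is roughly twice this plus the lesion radii, because both scans' lesions are dilated before intersection. |
| `min_volume_cm3` | 0.1 | strict lower bound: lesions with volume ≤ threshold are excluded on both scans before dilation, matching the smallest size readers can reliably match. Applied to the matcher's inputs, not just the evaluation; configurable to 0. |
| `connectivity` | 26 | 3D neighborhood for component indexing of binary input (6, 18 or 26). |
| `registration.mode` | auto | `auto` (translation init + B-spline FFD), `field` (user-supplied displacement field), `identity`. |
| `registration.grid_spacing_mm` | 50 | B-spline control-point spacing; bounds the deformation scale the FFD can represent. |
| `registration.metric` | mattes | similarity metric: Mattes mutual information (robust across contrast change), `meansquares` or `correlation` for same-protocol pairs. |
| `registration.seed` | 12345 | seed for metric sampling, making registration bit-reproducible. |

**Volume filter.** "Above the threshold" is a strict inequality: a
100-voxel lesion at 1 mm isotropic spacing (exactly 0.1 cm³) is removed,
101 voxels are retained. Filtering precedes dilation and clustering;
filtering after clustering would change cluster topology unpredictably.

**Dilation.** A voxel belongs to the dilated mask iff its center lies
within `dilation_mm` (Euclidean, millimetres) of some lesion-voxel center.
Implemented with an exact Euclidean distance transform using the voxel
spacing as sampling, so anisotropic grids are handled correctly; computed
on a padded bounding box per lesion for speed.

**Clustering and assignment.** Clusters are connected components of the
within-scan graph linking lesions whose dilated masks share a voxel;
cluster masks are unions of member dilated masks. The cluster-to-cluster
intersection-volume matrix feeds a maximizing linear sum assignment
(Munkres). Zero-overlap cells are *forbidden*, not merely worthless — a
match with no intersection volume would contradict the objective — so rows
and columns that cannot be covered profitably stay unmatched. Ties between
equal-total assignments are broken toward the lexicographically smallest
(row, column) pair set by greedy re-solving, which keeps the output
deterministic under permutations with tied weights. Matched cluster pairs
expand to lesion edges: every member pair with positive dilated
intersection becomes an edge; a member with no positive overlap to the
counterpart cluster becomes new/disappeared, as do all lesions of unmatched
clusters. The clustering-then-expansion semantics is our concretization of
a step whose published description is brief; it is deterministic and
handles splits and merges symmetrically.

**Determinism.** Every stage is a pure function of inputs and
configuration; the only potentially stochastic component (metric sampling
in the FFD) is explicitly seeded. Two runs on identical inputs produce
identical graphs, which the test suite and the acceptance script verify.

## Registration

The translation stage aligns the physical centroids of the provided
organ/bone masks (closed-form, deterministic). The published approach
optimizes a mask alignment without stating the objective; centroid
alignment is our testable default. When no masks are given but CT images
are, a surrogate bone mask is computed by thresholding at 200 HU and
keeping components of at least 10 cm³. The deformable stage is a
multi-resolution B-spline FFD (L-BFGS-B optimizer, 3 levels, 50 iterations
per level, 20 % seeded metric sampling by default). Registration direction:
scan 2 (moving) is warped into scan 1 (fixed) space.

Transform objects store the ITK *resampling* map — fixed-space physical
points into moving space — which is what resamplers and the
`DisplacementFieldTransform` consume; displacement-field files are sampled
on the fixed grid in that same convention (mm). Pure translations
additionally report the forward vector that carries the moving object onto
the fixed one. Label resampling is nearest neighbor and therefore never
invents label values.

## The phantom generator

The generator emulates what the matcher assumes about longitudinal oncology
scans: 1–200 roughly ellipsoidal lesions on a regular grid, a smooth
inter-scan deformation, and per-lesion events (disappear, new, split,
merge) with a ground-truth graph. Defaults: 110×110×80 voxels at 3 mm
(a torso-scale field of view), 20 lesions with volumes log-uniform in
0.05–5 cm³ — spanning the 0.1 cm³ threshold so filtering is exercised —
event probabilities 0.1/0.1/0.05/0.05 (disappear/new/split/merge), and a
12 mm-amplitude, 150 mm-wavelength sinusoidal displacement field.
Volumes above ~5 cm³ are supported by supplying a larger grid; the desk-
scale default keeps a full generate-and-match cycle at a few seconds.

Key design choices:

- **Separation.** Lesion centers are at least 2 × 25 mm + 2 × r_max + 4 mm
  apart (overridable), so distinct lesions never share a dilated cluster by
  construction; merge partners are exempt and placed ~18 mm apart. This
  encodes the scattered-metastases regime the matcher targets; densely
  packed organs (e.g. miliary liver disease) are deliberately not emulated,
  so passing tests bound performance only in the separated regime.
- **Deformation** is a sum of low-frequency sinusoids with a closed-form
  value at any point, so true landmark positions and the exact displacement
  field are available analytically; the stated amplitude is a bound on the
  displacement magnitude. Real respiratory/postural deformation is not
  band-limited; the phantom tests the geometry of the method, not
  registration robustness on clinical texture.
- **Rasterization** paints, for each lesion, exactly round(V / voxel
  volume) voxels of least ellipsoidal distance, keeping rasterized volumes
  within half a voxel of the drawn volume at any resolution.
- **Anatomy** in the CT-like images is a field of smooth Gaussian blobs
  displaced as material points, plus lesion hyperintensity and seeded
  noise — enough texture to drive the FFD, with none of CT's tissue
  statistics.
- Split fragments are placed 8 mm from the parent center (inside its
  dilated footprint) unless the adversarial flag moves them outside, for
  failure-mode studies.

`truth_recovery_score` generates a phantom, runs the matcher, restricts the
truth graph to the lesions the matcher analysed (those above the volume
threshold as measured on the analysis grid) and returns the agreement
metrics. The restriction re-sentinels lesions whose only partners were
dropped, mirroring how an evaluation limited to above-threshold lesions is
defined.

## Metrics

Precision, recall, F1 and the number of differences are computed over full
edge sets, sentinels included — the canonical reader disagreement
("disappeared + new" versus "same lesion") is exactly three differing
edges and is only expressible if sentinel edges count. F1 is computed from
set cardinalities, 2|∩| / (2|∩| + |A\B| + |B\A|), and cross-checked in
tests against the harmonic-mean route to 1e-12. Empty edge sets make
precision/recall undefined; they are reported as 1.0 with an explicit flag
rather than silently. Graphs must share node sets to be compared; per-pair
metrics can be aggregated (median, min, max) with the batch comparison
command, matching how cohort summaries are usually tabulated.

## Problem sizes and numerical notes

The default test and acceptance conditions use 20-lesion phantoms on the
default grid (≈1M voxels), where a full generate–match–score cycle takes a
few seconds, and a 40×56×56 grid at 4 mm for FFD recovery tests (~10 s per
registration with 20 % sampling and 30 iterations/level). The dilation
boundary uses ≤ with a 1e-9 mm guard against floating-point rounding of
exact radii. Volumes are computed as voxel count × spacing product / 1000
in that order, so the 0.1 cm³ boundary case is exact in floating point.
Assignment tie-breaks only engage on exactly tied totals (common with
integer-valued test matrices, measure-zero for real overlap volumes).

## Known limitations

- Pairwise scans only; chaining more than two timepoints is the caller's
  responsibility.
- The organ/bone contouring used upstream in clinical deployments is out of
  scope; the 200 HU surrogate is crude and only used when no masks are
  given.
- The matcher's accuracy on clinical data is bounded by registration
  quality; the phantom's band-limited deformation is kinder than reality.
- Anatomy-specific dilation radii (smaller in bone, larger in soft tissue)
  are not implemented; one global radius applies.
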