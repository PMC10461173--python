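"""The automated registration-based lesion matcher.

Given two label volumes of the same patient at two timepoints, the matcher
proceeds in four conceptual steps:

1. *Registration* — scan 2 is aligned onto scan 1 (translation-only mask
   initialization followed by a B-spline free-form deformation, or a supplied
   displacement field), and its label map is resampled onto the scan-1 grid
   with nearest-neighbor interpolation.
2. *Dilation* — each lesion mask is dilated by a fixed physical radius
   (default 25 mm) to absorb residual registration error.
3. *Clustering* — within each scan, lesions whose dilated masks touch are
   grouped into clusters, so that lesions that split or merge between scans
   are compared as a unit.
4. *Assignment* — clusters of scan 1 are matched one-to-one to clusters of
   scan 2 by the Munkres (Hungarian) algorithm, maximizing the total
   intersection volume of the dilated cluster masks; cluster matches are then
   expanded to lesion-level edges.

Lesions below a volume threshold (default 0.1 cm³) are excluded before
dilation on both scans, mirroring the smallest lesion size readers can
reliably match.  Every step is deterministic, so repeated runs on identical
inputs produce identical match graphs.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import LabelVolume, LesionRecord, MatchGraph, build_graph
from .registration import (
    RegistrationConfig,
    SpatialTransform,
    apply_transform_labels,
    bone_mask_from_ct,
    deformable_register,
    translation_align,
)

__all__ = [
    "MatchConfig",
    "LesionSet",
    "ClusterSet",
    "label_components",
    "extract_lesions",
    "filter_by_volume",
    "dilate_lesions",
    "cluster_within_scan",
    "intersection_matrix",
    "solve_assignment",
    "expand_to_lesion_edges",
    "match_pipeline",
]

_CONNECTIVITY_ORDER = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class MatchConfig:
    """Tunable parameters of the matcher.

    ``dilation_mm`` is the physical dilation radius absorbing registration
    uncertainty; ``min_volume_cm3`` the strict lower volume bound for a lesion
    to participate; ``connectivity`` the 3D voxel neighborhood used when
    indexing connected components of binary input.
    """

    dilation_mm: float = 25.0
    min_volume_cm3: float = 0.1
    connectivity: int = 26
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)

    def __post_init__(self):
        if self.dilation_mm < 0:
            raise ValueError("dilation_mm must be >= 0")
        if self.min_volume_cm3 < 0:
            raise ValueError("min_volume_cm3 must be >= 0")
        if self.connectivity not in _CONNECTIVITY_ORDER:
            raise ValueError("connectivity must be one of 6, 18, 26")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LesionSet:
    """All lesions of one scan, on a common grid."""

    lesions: dict[int, LesionRecord]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    @property
    def indices(self) -> list[int]:
        return sorted(self.lesions)

    def __len__(self) -> int:
        return len(self.lesions)


@dataclass
class ClusterSet:
    """Partition of one scan's lesions into dilated-overlap clusters.

    ``clusters[k]`` is the sorted tuple of member lesion indices;
    ``cluster_masks[k]`` the union of their dilated masks.  Clusters are
    ordered by smallest member index.
    """

    clusters: list[tuple[int, ...]]
    cluster_masks: list[np.ndarray]
    spacing: tuple[float, float, float]


def label_components(binary_mask: LabelVolume, connectivity: int = 26) -> LabelVolume:
    """Index connected components of a binary mask with unique integers.

    Labels are assigned in raster-scan order of each component's first
    encountered voxel, so the indexing is deterministic.
    """
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_ORDER[connectivity])
    labeled, _ = ndimage.label(binary_mask.voxels > 0, structure=structure)
    return replace(binary_mask, voxels=labeled.astype(np.int32))


def extract_lesions(labels: LabelVolume) -> LesionSet:
    """Split a label volume into per-lesion records with physical volumes."""
    vox_mm3 = labels.voxel_volume_mm3
    lesions: dict[int, LesionRecord] = {}
    for idx in labels.labels():
        mask = labels.voxels == idx
        count = int(mask.sum())
        lesions[idx] = LesionRecord(
            index=idx,
            voxel_count=count,
            volume_cm3=count * vox_mm3 / 1000.0,
            mask=mask,
        )
    return LesionSet(lesions, labels.spacing, labels.voxels.shape)


def filter_by_volume(lesions: LesionSet, min_volume_cm3: float) -> LesionSet:
    """Keep lesions strictly above the volume threshold; indices unchanged."""
    kept = {
        i: rec for i, rec in lesions.lesions.items() if rec.volume_cm3 > min_volume_cm3
    }
    return LesionSet(kept, lesions.spacing, lesions.shape)


def _ball_dilate(mask: np.ndarray, spacing_zyx: Sequence[float], radius_mm: float,
                 ) -> np.ndarray:
    """Dilate by a physical ball: voxel centers within radius_mm of the mask."""
    if radius_mm == 0 or not mask.any():
        return mask.copy()
    pad = [int(np.ceil(radius_mm / s)) for s in spacing_zyx]
    nz = np.argwhere(mask)
    lo = np.maximum(nz.min(axis=0) - pad, 0)
    hi = np.minimum(nz.max(axis=0) + pad + 1, mask.shape)
    crop = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    dist = ndimage.distance_transform_edt(~crop, sampling=spacing_zyx)
    out = np.zeros_like(mask)
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = dist <= radius_mm + 1e-9
    return out


def dilate_lesions(lesions: LesionSet, radius_mm: float) -> LesionSet:
    """Populate each lesion's dilated mask (Euclidean ball in physical mm).

    Anisotropic spacing is respected: the criterion is on voxel-center
    distances in millimetres, not voxel counts.
    """
    spacing_zyx = lesions.spacing[::-1]
    out: dict[int, LesionRecord] = {}
    for i, rec in lesions.lesions.items():
        out[i] = LesionRecord(
            index=rec.index,
            voxel_count=rec.voxel_count,
            volume_cm3=rec.volume_cm3,
            mask=rec.mask,
            dilated_mask=_ball_dilate(rec.mask, spacing_zyx, radius_mm),
        )
    return LesionSet(out, lesions.spacing, lesions.shape)


def _bbox(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    nz = np.argwhere(mask)
    return nz.min(axis=0), nz.max(axis=0) + 1


def _masks_overlap_count(a: np.ndarray, b: np.ndarray) -> int:
    """Voxel count of a AND b, with a bounding-box prefilter."""
    if not a.any() or not b.any():
        return 0
    alo, ahi = _bbox(a)
    blo, bhi = _bbox(b)
    lo = np.maximum(alo, blo)
    hi = np.minimum(ahi, bhi)
    if np.any(lo >= hi):
        return 0
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    return int(np.logical_and(a[sl], b[sl]).sum())


def cluster_within_scan(lesions: LesionSet) -> ClusterSet:
    """Group lesions whose dilated masks share at least one voxel.

    Clusters are the connected components of the dilated-overlap graph,
    ordered deterministically by smallest member index.
    """
    idxs = lesions.indices
    n = len(idxs)
    for i in idxs:
        if lesions.lesions[i].dilated_mask is None:
            raise ValueError(f"lesion {i}: dilated mask not populated")
    rows, cols = [], []
    for a in range(n):
        for b in range(a + 1, n):
            if _masks_overlap_count(
                lesions.lesions[idxs[a]].dilated_mask,
                lesions.lesions[idxs[b]].dilated_mask,
            ):
                rows += [a, b]
                cols += [b, a]
    if n:
        adj = csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        )
        n_comp, comp = connected_components(adj, directed=False)
    else:
        n_comp, comp = 0, np.array([], dtype=int)
    groups: dict[int, list[int]] = {}
    for pos, c in enumerate(comp):
        groups.setdefault(int(c), []).append(idxs[pos])
    ordered = sorted((tuple(sorted(g)) for g in groups.values()), key=lambda t: t[0])
    masks = []
    for members in ordered:
        m = np.zeros(lesions.shape, dtype=bool)
        for i in members:
            m |= lesions.lesions[i].dilated_mask
        masks.append(m)
    return ClusterSet(list(ordered), masks, lesions.spacing)


def intersection_matrix(c1: ClusterSet, c2: ClusterSet) -> np.ndarray:
    """Pairwise intersection volumes (cm³) of dilated cluster masks.

    Both cluster sets must live on the same (scan-1) grid.
    """
    if c1.cluster_masks and c2.cluster_masks:
        if c1.cluster_masks[0].shape != c2.cluster_masks[0].shape:
            raise ValueError("cluster sets are on different grids")
        if not np.allclose(c1.spacing, c2.spacing):
            raise ValueError("cluster sets have different spacings")
    vox_cm3 = float(np.prod(c1.spacing)) / 1000.0
    out = np.zeros((len(c1.clusters), len(c2.clusters)))
    for i, m1 in enumerate(c1.cluster_masks):
        for j, m2 in enumerate(c2.cluster_masks):
            out[i, j] = _masks_overlap_count(m1, m2) * vox_cm3
    return out


def _optimal_total(matrix: np.ndarray) -> float:
    """Maximum total value of a partial one-to-one assignment (zeros worthless)."""
    if matrix.size == 0:
        return 0.0
    r, c = linear_sum_assignment(matrix, maximize=True)
    return float(matrix[r, c].sum())


def solve_assignment(overlaps: np.ndarray) -> set[tuple[int, int]]:
    """Optimal one-to-one cluster assignment maximizing total overlap.

    Cells with zero overlap are forbidden: the Munkres solution never pairs
    spatially disjoint clusters, and rows/columns it cannot profitably cover
    stay unmatched.  Ties between equal-total assignments are broken by
    preferring the lexicographically smallest (row, column) pair set.
    Returns 0-based (row, column) pairs.
    """
    m = np.asarray(overlaps, dtype=float)
    if m.ndim != 2:
        raise ValueError("overlap matrix must be 2D")
    if m.size and m.min() < 0:
        raise ValueError("overlap matrix must be non-negative")
    if m.size == 0:
        return set()
    best = _optimal_total(m)
    tol = 1e-9 * max(1.0, abs(best))
    chosen: list[tuple[int, int]] = []
    free_rows = list(range(m.shape[0]))
    free_cols = list(range(m.shape[1]))
    base = 0.0
    for i in range(m.shape[0]):
        if i not in free_rows:
            continue
        for j in list(free_cols):
            if m[i, j] <= 0:
                continue
            rows = [r for r in free_rows if r != i]
            cols = [c for c in free_cols if c != j]
            rest = _optimal_total(m[np.ix_(rows, cols)])
            if base + m[i, j] + rest >= best - tol:
                chosen.append((i, j))
                base += m[i, j]
                free_rows.remove(i)
                free_cols.remove(j)
                break
    return set(chosen)


def expand_to_lesion_edges(
    pairs: set[tuple[int, int]],
    lesions1: LesionSet,
    lesions2: LesionSet,
    c1: ClusterSet,
    c2: ClusterSet,
) -> MatchGraph:
    """Expand cluster-level assignments into the lesion-level match graph.

    Within each matched cluster pair, every member lesion pair with positive
    dilated-mask intersection becomes an edge; members with no positive
    overlap to the counterpart cluster fall back to the highest-overlap
    counterpart or, failing that, become new/disappeared.  Lesions of
    unmatched clusters are new/disappeared.
    """
    matches: set[tuple[int, int]] = set()
    for ci, cj in sorted(pairs):
        members1 = c1.clusters[ci]
        members2 = c2.clusters[cj]
        overlap = {}
        for a in members1:
            for b in members2:
                overlap[a, b] = _masks_overlap_count(
                    lesions1.lesions[a].dilated_mask,
                    lesions2.lesions[b].dilated_mask,
                )
                if overlap[a, b] > 0:
                    matches.add((a, b))
        for a in members1:
            if not any((a, b) in matches for b in members2):
                best_b = max(members2, key=lambda b: (overlap[a, b], -b))
                if overlap[a, best_b] > 0:
                    matches.add((a, best_b))
        for b in members2:
            if not any((a, b) in matches for a in members1):
                best_a = max(members1, key=lambda a: (overlap[a, b], -a))
                if overlap[best_a, b] > 0:
                    matches.add((best_a, b))
    return build_graph(lesions1.indices, lesions2.indices, matches)


def _resolve_transform(
    config: MatchConfig,
    scan1_labels: LabelVolume,
    images: tuple[sitk.Image, sitk.Image] | None,
    masks: tuple[LabelVolume, LabelVolume] | None,
    displacement_field: sitk.Image | None,
) -> SpatialTransform:
    mode = config.registration.mode
    if mode == "identity":
        return SpatialTransform.identity()
    if mode == "field":
        if displacement_field is None:
            raise ValueError("registration mode 'field' requires a displacement field")
        return SpatialTransform.from_displacement_field(displacement_field)
    # mode == "auto": translation on masks (or bone surrogate), then FFD on images
    if mode != "auto":
        raise ValueError(f"unknown registration mode {mode!r}")
    if masks is None and images is not None:
        masks = (bone_mask_from_ct(images[0]), bone_mask_from_ct(images[1]))
    init = SpatialTransform.identity()
    if masks is not None and masks[0].voxels.any() and masks[1].voxels.any():
        init = translation_align(masks[0], masks[1])
    if images is not None:
        return deformable_register(images[0], images[1], init, config.registration)
    return init


def match_pipeline(
    scan1_labels: LabelVolume,
    scan2_labels: LabelVolume,
    images: tuple[sitk.Image, sitk.Image] | None = None,
    masks: tuple[LabelVolume, LabelVolume] | None = None,
    displacement_field: sitk.Image | None = None,
    config: MatchConfig | None = None,
) -> tuple[MatchGraph, dict]:
    """Run the full matcher on a scan pair; returns (graph, provenance).

    ``images`` are optional co-registered anatomical (CT) images driving the
    deformable stage; ``masks`` optional organ/bone masks for the translation
    stage; ``displacement_field`` a precomputed field used when the
    registration mode is ``field``.  Binary (unindexed) label inputs are
    indexed by connected-component analysis.  The provenance dict records the
    configuration, the transform, and per-stage lesion/cluster counts.
    """
    config = config or MatchConfig()
    t0 = time.perf_counter()
    transform = _resolve_transform(
        config, scan1_labels, images, masks, displacement_field
    )
    warped2 = apply_transform_labels(scan2_labels, transform, scan1_labels)

    vol1 = scan1_labels
    if vol1.voxels.max(initial=0) == 1:
        vol1 = label_components(vol1, config.connectivity)
    if warped2.voxels.max(initial=0) == 1:
        warped2 = label_components(warped2, config.connectivity)

    set1 = extract_lesions(vol1)
    set2 = extract_lesions(warped2)
    n_initial = (len(set1), len(set2))
    set1 = filter_by_volume(set1, config.min_volume_cm3)
    set2 = filter_by_volume(set2, config.min_volume_cm3)
    n_filtered = (len(set1), len(set2))
    set1 = dilate_lesions(set1, config.dilation_mm)
    set2 = dilate_lesions(set2, config.dilation_mm)
    c1 = cluster_within_scan(set1)
    c2 = cluster_within_scan(set2)
    overlaps = intersection_matrix(c1, c2)
    pairs = solve_assignment(overlaps)
    graph = expand_to_lesion_edges(pairs, set1, set2, c1, c2)
    provenance = {
        "config": config.to_dict(),
        "transform": {
            "kind": transform.kind,
            "translation_mm": transform.translation_mm,
        },
        "counts": {
            "lesions_initial": n_initial,
            "lesions_after_volume_filter": n_filtered,
            "clusters": (len(c1.clusters), len(c2.clusters)),
            "cluster_pairs_assigned": len(pairs),
            "edges": len(graph.edges),
        },
        "duration_s": time.perf_counter() - t0,
    }
    return graph, provenance
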