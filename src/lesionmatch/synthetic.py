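"""Seeded phantom generator: longitudinal scan pairs with known truth.

The generator emulates the structure the matcher assumes about real
longitudinal oncology scans: a handful to a couple of hundred roughly
ellipsoidal lesions scattered through the body, a smooth inter-scan
deformation of bounded amplitude (patient repositioning and anatomical
change), and per-lesion events between timepoints — disappearance, new
appearance, splitting into fragments, merging of neighbours.  Every phantom
comes with the exact ground-truth match graph and the exact displacement
field, so the matcher, the registration stage, and the metrics can each be
tested against an analytic answer.

Lesions are placed with a minimum pairwise centre separation derived from
the dilation radius the matcher is designed around, so that distinct lesions
do not fall into one dilated cluster; merge partners are deliberately exempt
and placed close together.  The deformation is a sum of low-frequency
sinusoids, so the true position of any material point is available in closed
form.  All randomness flows from one integer seed; identical seeds give
bit-identical volumes and graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import SimpleITK as sitk

from .core import LabelVolume, MatchGraph, build_graph, restrict_graph
from .matching import MatchConfig, extract_lesions, filter_by_volume, match_pipeline
from .metrics import compare_graphs
from .core import MetricsReport

__all__ = ["PhantomSpec", "PhantomPair", "GenerationError",
           "generate_phantom_pair", "truth_recovery_score"]


class GenerationError(RuntimeError):
    """Phantom could not be generated (e.g. infeasible lesion packing)."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic longitudinal scan pair.

    ``grid_shape`` is in array order (z, y, x); ``spacing_mm`` in (x, y, z).
    ``volume_range_cm3`` bounds the (log-uniformly drawn) lesion volumes and
    by default spans the 0.1 cm³ analysis threshold so volume filtering is
    exercised.  ``deformation_amplitude_mm`` bounds the displacement
    magnitude; ``deformation_wavelength_mm`` sets its spatial scale.
    ``dilation_clearance_mm`` is the dilation radius the phantom is laid out
    for: lesion centres are separated by at least twice this plus two maximal
    radii, unless ``min_separation_mm`` overrides the derived value.
    ``adversarial_split`` places split fragments outside the parent's dilated
    footprint, for failure-mode studies.
    """

    grid_shape: tuple[int, int, int] = (80, 110, 110)
    spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_lesions: int = 20
    volume_range_cm3: tuple[float, float] = (0.05, 5.0)
    p_disappear: float = 0.1
    p_new: float = 0.1
    p_split: float = 0.05
    p_merge: float = 0.05
    deformation_amplitude_mm: float = 12.0
    deformation_wavelength_mm: float = 150.0
    seed: int = 0
    dilation_clearance_mm: float = 25.0
    min_separation_mm: float | None = None
    adversarial_split: bool = False

    def __post_init__(self):
        for name in ("p_disappear", "p_new", "p_split", "p_merge"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.p_split + self.p_disappear > 1.0:
            raise ValueError("p_split + p_disappear must be <= 1")
        if self.deformation_wavelength_mm <= 0:
            raise ValueError("deformation_wavelength_mm must be > 0")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        lo, hi = self.volume_range_cm3
        if not 0 < lo <= hi:
            raise ValueError("volume_range_cm3 must satisfy 0 < min <= max")

    @property
    def max_radius_mm(self) -> float:
        return (3.0 * self.volume_range_cm3[1] * 1000.0 / (4.0 * np.pi)) ** (1 / 3)

    @property
    def separation_mm(self) -> float:
        if self.min_separation_mm is not None:
            return self.min_separation_mm
        return 2.0 * self.dilation_clearance_mm + 2.0 * self.max_radius_mm + 4.0


@dataclass
class PhantomPair:
    """One synthetic scan pair with its exact ground truth."""

    ct1: sitk.Image
    labels1: LabelVolume
    ct2: sitk.Image
    labels2: LabelVolume
    truth: MatchGraph
    displacement_field: sitk.Image
    events: dict


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _coord_axes(shape_zyx, spacing_xyz):
    sz, sy, sx = shape_zyx
    hx, hy, hz = spacing_xyz
    return (
        np.arange(sz) * hz,  # z coordinates, mm
        np.arange(sy) * hy,
        np.arange(sx) * hx,
    )


def _sinusoid_field(spec: PhantomSpec, phases: np.ndarray):
    """Closed-form smooth displacement u(x) with |u| <= amplitude."""
    amp = spec.deformation_amplitude_mm / np.sqrt(3.0)
    k = 2.0 * np.pi / spec.deformation_wavelength_mm

    def u(points_xyz: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points_xyz)
        ux = amp * np.sin(k * p[:, 1] + phases[0])
        uy = amp * np.sin(k * p[:, 2] + phases[1])
        uz = amp * np.sin(k * p[:, 0] + phases[2])
        return np.stack([ux, uy, uz], axis=1)

    return u


def _rasterize_lesion(arr, zc, yc, xc, center_xyz, semi_axes_xyz, target_voxels, label):
    """Paint the ``target_voxels`` voxels of least ellipsoidal distance.

    Choosing exactly round(V / voxel volume) voxels keeps rasterized volumes
    within half a voxel of the drawn volume at any grid resolution.
    """
    cx, cy, cz = center_xyz
    ax, ay, az = semi_axes_xyz
    # generous crop: the k chosen voxels lie within the ellipsoid's bbox + 2 voxels
    zi = np.searchsorted(zc, [cz - az - 2 * (zc[1] - zc[0]), cz + az + 2 * (zc[1] - zc[0])])
    yi = np.searchsorted(yc, [cy - ay - 2 * (yc[1] - yc[0]), cy + ay + 2 * (yc[1] - yc[0])])
    xi = np.searchsorted(xc, [cx - ax - 2 * (xc[1] - xc[0]), cx + ax + 2 * (xc[1] - xc[0])])
    zi, yi, xi = np.clip(zi, 0, len(zc)), np.clip(yi, 0, len(yc)), np.clip(xi, 0, len(xc))
    Z, Y, X = np.meshgrid(zc[zi[0]:zi[1]], yc[yi[0]:yi[1]], xc[xi[0]:xi[1]],
                          indexing="ij")
    if Z.size == 0:
        raise GenerationError("lesion crop is empty (lesion outside grid)")
    d = ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2
    k = min(target_voxels, d.size)
    flat = np.argsort(d, axis=None, kind="stable")[:k]
    iz, iy, ix = np.unravel_index(flat, d.shape)
    arr[iz + zi[0], iy + yi[0], ix + xi[0]] = label


def _add_gaussian_blob(ct, zc, yc, xc, center_xyz, sigma_mm, amplitude):
    cx, cy, cz = center_xyz
    r = 3.0 * sigma_mm
    zi = np.searchsorted(zc, [cz - r, cz + r])
    yi = np.searchsorted(yc, [cy - r, cy + r])
    xi = np.searchsorted(xc, [cx - r, cx + r])
    Z, Y, X = np.meshgrid(zc[zi[0]:zi[1]], yc[yi[0]:yi[1]], xc[xi[0]:xi[1]],
                          indexing="ij")
    if Z.size == 0:
        return
    g = amplitude * np.exp(
        -((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2) / (2.0 * sigma_mm**2)
    )
    ct[zi[0]:zi[1], yi[0]:yi[1], xi[0]:xi[1]] += g


def _sample_sites(rng, n, lo_xyz, hi_xyz, min_sep, max_attempts):
    """Sequential rejection sampling of well-separated sites."""
    sites: list[np.ndarray] = []
    attempts = 0
    while len(sites) < n:
        if attempts >= max_attempts:
            return None
        attempts += 1
        p = rng.uniform(lo_xyz, hi_xyz)
        if all(np.linalg.norm(p - q) >= min_sep for q in sites):
            sites.append(p)
    return sites


def _semi_axes(rng, volume_cm3):
    """Axis-aligned ellipsoid semi-axes (mm) with mild random anisotropy."""
    r = (3.0 * volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1 / 3)
    f = rng.uniform(0.8, 1.25, size=3)
    f /= f.prod() ** (1 / 3)
    return r * f


def _make_image(arr, spec: PhantomSpec, vector=False) -> sitk.Image:
    img = sitk.GetImageFromArray(arr, isVector=vector)
    img.SetSpacing(spec.spacing_mm)
    img.SetOrigin((0.0, 0.0, 0.0))
    return img


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_phantom_pair(spec: PhantomSpec) -> PhantomPair:
    """Generate one longitudinal phantom pair with ground truth.

    Raises :class:`GenerationError` when the requested number of lesions
    cannot be packed into the grid at the required separation after bounded
    retries.
    """
    rng = np.random.default_rng(spec.seed)
    zc, yc, xc = _coord_axes(spec.grid_shape, spec.spacing_mm)
    phys_hi = np.array([xc[-1], yc[-1], zc[-1]])
    vox_cm3 = float(np.prod(spec.spacing_mm)) / 1000.0

    # -- event plan --------------------------------------------------------
    n = spec.n_lesions
    n_merge_pairs = int(rng.binomial(n // 2, spec.p_merge)) if n >= 2 else 0
    n_single = n - 2 * n_merge_pairs
    u_events = rng.random(n_single)
    single_events = np.where(
        u_events < spec.p_disappear,
        "disappear",
        np.where(u_events < spec.p_disappear + spec.p_split, "split", "carry"),
    )
    n_new = int(rng.binomial(n, spec.p_new)) if n else 0

    # -- placement ---------------------------------------------------------
    margin = spec.max_radius_mm + spec.deformation_amplitude_mm + 2 * max(
        spec.spacing_mm
    )
    lo = np.full(3, margin)
    hi = phys_hi - margin
    if np.any(hi <= lo):
        raise GenerationError("grid too small for lesion radius + deformation margin")
    n_sites = n_single + n_merge_pairs + n_new
    sites = None
    for _ in range(20):
        sites = _sample_sites(
            rng, n_sites, lo, hi, spec.separation_mm, max_attempts=500 * max(n_sites, 1)
        )
        if sites is not None:
            break
    if sites is None:
        raise GenerationError(
            f"could not place {n_sites} lesions with separation "
            f"{spec.separation_mm:.0f} mm in a "
            f"{tuple(round(float(v)) for v in phys_hi)} mm grid"
        )

    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
    u = _sinusoid_field(spec, phases)

    def warp(p):
        return np.asarray(p, float) + u(np.asarray(p, float))[0]

    labels1 = np.zeros(spec.grid_shape, dtype=np.int32)
    labels2 = np.zeros(spec.grid_shape, dtype=np.int32)

    # scan-1 lesions: singles first, then merge-pair members
    scan1 = []  # (index, center, semi_axes, volume)
    idx = 0
    for s in range(n_single):
        idx += 1
        v = float(np.exp(rng.uniform(*np.log(spec.volume_range_cm3))))
        scan1.append(
            dict(index=idx, center=sites[s], axes=_semi_axes(rng, v), volume=v,
                 event=str(single_events[s]))
        )
    merge_groups = []
    for m in range(n_merge_pairs):
        site = sites[n_single + m]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        gap = 18.0
        pair = []
        for sign in (+1.0, -1.0):
            idx += 1
            v = float(np.exp(rng.uniform(*np.log(spec.volume_range_cm3))))
            pair.append(
                dict(index=idx, center=site + sign * (gap / 2.0) * direction,
                     axes=_semi_axes(rng, v), volume=v, event="merge")
            )
        merge_groups.append(pair)
        scan1.extend(pair)

    for rec in scan1:
        k = max(1, int(round(rec["volume"] / vox_cm3)))
        _rasterize_lesion(labels1, zc, yc, xc, rec["center"], rec["axes"], k,
                          rec["index"])

    # -- scan 2 ------------------------------------------------------------
    matches = []
    jdx = 0
    events = {"disappear": 0, "new": n_new, "split": 0, "merge": n_merge_pairs}
    split_offset = 8.0 if not spec.adversarial_split else (
        spec.dilation_clearance_mm + 15.0
    )
    for rec in scan1:
        if rec["event"] == "carry":
            jdx += 1
            k = max(1, int(round(rec["volume"] / vox_cm3)))
            _rasterize_lesion(labels2, zc, yc, xc, warp(rec["center"]), rec["axes"],
                              k, jdx)
            matches.append((rec["index"], jdx))
        elif rec["event"] == "disappear":
            events["disappear"] += 1
        elif rec["event"] == "split":
            events["split"] += 1
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            c2 = warp(rec["center"])
            for sign in (+1.0, -1.0):
                jdx += 1
                vf = rec["volume"] / 2.0
                kf = max(1, int(round(vf / vox_cm3)))
                _rasterize_lesion(
                    labels2, zc, yc, xc, c2 + sign * split_offset * direction,
                    rec["axes"] * 0.5 ** (1 / 3), kf, jdx,
                )
                matches.append((rec["index"], jdx))
    for pair in merge_groups:
        jdx += 1
        mid = 0.5 * (pair[0]["center"] + pair[1]["center"])
        axis = pair[0]["center"] - pair[1]["center"]
        half_gap = 0.5 * np.linalg.norm(axis)
        r = max(
            (3.0 * p["volume"] * 1000.0 / (4.0 * np.pi)) ** (1 / 3) for p in pair
        )
        vm = pair[0]["volume"] + pair[1]["volume"]
        km = max(1, int(round(vm / vox_cm3)))
        # elongated ellipsoid bridging both parent positions
        long_ax = half_gap + r
        dom = int(np.argmax(np.abs(axis)))
        axes = np.full(3, r)
        axes[dom] = long_ax
        _rasterize_lesion(labels2, zc, yc, xc, warp(mid), axes, km, jdx)
        matches.append((pair[0]["index"], jdx))
        matches.append((pair[1]["index"], jdx))
    for m in range(n_new):
        jdx += 1
        site = sites[n_single + n_merge_pairs + m]
        v = float(np.exp(rng.uniform(*np.log(spec.volume_range_cm3))))
        k = max(1, int(round(v / vox_cm3)))
        _rasterize_lesion(labels2, zc, yc, xc, warp(site), _semi_axes(rng, v), k, jdx)

    truth = build_graph(
        [r["index"] for r in scan1], list(range(1, jdx + 1)), matches
    )

    # -- anatomical (CT-like) images ---------------------------------------
    ct1 = np.zeros(spec.grid_shape, dtype=np.float32)
    ct2 = np.zeros(spec.grid_shape, dtype=np.float32)
    n_blobs = max(10, 3 * max(n, 1))
    blob_c = rng.uniform(lo - margin / 2, hi + margin / 2, size=(n_blobs, 3))
    blob_s = rng.uniform(12.0, 28.0, size=n_blobs)
    blob_a = rng.uniform(40.0, 120.0, size=n_blobs)
    for c, s, a in zip(blob_c, blob_s, blob_a):
        _add_gaussian_blob(ct1, zc, yc, xc, c, s, a)
        _add_gaussian_blob(ct2, zc, yc, xc, warp(c), s, a)
    ct1 += 80.0 * (labels1 > 0)
    ct2 += 80.0 * (labels2 > 0)
    ct1 += rng.normal(0.0, 2.0, size=spec.grid_shape).astype(np.float32)
    ct2 += rng.normal(0.0, 2.0, size=spec.grid_shape).astype(np.float32)

    # -- exact displacement field on the scan-1 grid -----------------------
    Z, Y, X = np.meshgrid(zc, yc, xc, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    disp = u(pts).reshape(spec.grid_shape + (3,))

    return PhantomPair(
        ct1=_make_image(ct1, spec),
        labels1=LabelVolume(labels1, spec.spacing_mm),
        ct2=_make_image(ct2, spec),
        labels2=LabelVolume(labels2, spec.spacing_mm),
        truth=truth,
        displacement_field=_make_image(disp.astype(np.float64), spec, vector=True),
        events=events,
    )


def truth_recovery_score(
    spec: PhantomSpec, config: MatchConfig | None = None
) -> MetricsReport:
    """Generate a phantom, run the matcher, score it against the truth.

    The truth graph is restricted to the lesions the matcher analysed (those
    above the volume threshold on the analysis grid) before comparison, since
    matching evaluation is limited to lesions above the threshold.
    """
    config = config or MatchConfig()
    pair = generate_phantom_pair(spec)
    graph, _ = match_pipeline(
        pair.labels1,
        pair.labels2,
        images=(pair.ct1, pair.ct2),
        displacement_field=pair.displacement_field,
        config=config,
    )
    truth = restrict_graph(pair.truth, graph.n1, graph.n2)
    return compare_graphs(graph, truth)
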