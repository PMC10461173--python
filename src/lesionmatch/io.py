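"""Readers and writers: NIfTI label volumes, reader match tables, graph JSON.

Match tables follow the reader-workbook dialect: a two-column CSV where each
row pairs a scan-1 lesion index with a scan-2 lesion index, and a 0 entry
means "no counterpart on that scan" (disappeared / new).  A row of two zeros
is invalid.  Lesions present on a scan but never mentioned in the table are
auto-completed with their sentinel edge, with a warning, because readers only
fill the rows they decided on.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .core import (
    DISAPPEARED,
    NEW,
    GraphValidationError,
    LabelVolume,
    MatchGraph,
    build_graph,
    sorted_edges,
    validate_graph,
)

__all__ = [
    "read_label_volume",
    "write_label_volume",
    "read_image",
    "label_volume_to_sitk",
    "sitk_to_label_volume",
    "read_match_table",
    "write_match_table",
    "read_graph_json",
    "write_graph_json",
    "read_displacement_field",
    "write_displacement_field",
]


class FormatError(ValueError):
    """Input file violates the expected format."""


# ---------------------------------------------------------------------------
# Label volumes (NIfTI via SimpleITK)
# ---------------------------------------------------------------------------

def label_volume_to_sitk(vol: LabelVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(vol.voxels.astype(np.int32, copy=False))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    img.SetDirection(vol.direction)
    return img


def sitk_to_label_volume(img: sitk.Image) -> LabelVolume:
    arr = sitk.GetArrayFromImage(img)
    return LabelVolume(
        voxels=arr.astype(np.int32, copy=False),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
        direction=tuple(img.GetDirection()),
    )


def read_label_volume(path: str | Path, tol: float = 1e-6) -> LabelVolume:
    """Read an integer label map, accepting float encodings of integers.

    Raises :class:`FormatError` when voxel values deviate from integers by
    more than ``tol``.
    """
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got {arr.ndim}D")
    rounded = np.rint(arr)
    if np.abs(arr - rounded).max(initial=0.0) > tol:
        bad = float(arr.flat[np.abs(arr - rounded).argmax()])
        raise FormatError(f"{path}: non-integer voxel value {bad!r}")
    return LabelVolume(
        voxels=rounded.astype(np.int32),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
        direction=tuple(img.GetDirection()),
    )


def write_label_volume(vol: LabelVolume, path: str | Path) -> None:
    sitk.WriteImage(label_volume_to_sitk(vol), str(path))


def read_image(path: str | Path) -> sitk.Image:
    """Read a scalar anatomical image (e.g. CT) as float32."""
    return sitk.Cast(sitk.ReadImage(str(path)), sitk.sitkFloat32)


# ---------------------------------------------------------------------------
# Displacement fields
# ---------------------------------------------------------------------------

def read_displacement_field(path: str | Path) -> sitk.Image:
    """Read a 3-component vector NIfTI displacement field (mm).

    The field is sampled on the fixed (scan-1) grid and maps fixed-space
    physical points into moving (scan-2) space — the resampling convention
    consumed by ``sitk.DisplacementFieldTransform``.
    """
    img = sitk.ReadImage(str(path))
    if img.GetNumberOfComponentsPerPixel() != 3:
        raise FormatError(
            f"{path}: displacement field must have 3 components per voxel, "
            f"got {img.GetNumberOfComponentsPerPixel()}"
        )
    return sitk.Cast(img, sitk.sitkVectorFloat64)


def write_displacement_field(field: sitk.Image, path: str | Path) -> None:
    sitk.WriteImage(sitk.Cast(field, sitk.sitkVectorFloat64), str(path))


# ---------------------------------------------------------------------------
# Match tables (reader-workbook CSV dialect)
# ---------------------------------------------------------------------------

def _load_table_rows(path: str | Path) -> list[tuple[int, int]]:
    raw = pd.read_csv(path, header=None, dtype=str, skip_blank_lines=True)
    if raw.shape[1] != 2:
        raise FormatError(f"{path}: expected 2 columns, got {raw.shape[1]}")
    # Header auto-detection: first row non-numeric -> header.
    start = 0
    first = raw.iloc[0]
    try:
        int(first[0]), int(first[1])
    except (ValueError, TypeError):
        start = 1
    rows: list[tuple[int, int]] = []
    for k in range(start, len(raw)):
        a_s, b_s = raw.iloc[k]
        try:
            a, b = int(a_s), int(b_s)
        except (ValueError, TypeError):
            raise FormatError(f"{path}: row {k + 1}: non-integer entry ({a_s}, {b_s})")
        if a < 0 or b < 0:
            raise FormatError(f"{path}: row {k + 1}: negative index ({a}, {b})")
        if a == 0 and b == 0:
            raise FormatError(f"{path}: row {k + 1}: both entries zero")
        rows.append((a, b))
    return rows


def read_match_table(
    path: str | Path, n1: Iterable[int], n2: Iterable[int]
) -> MatchGraph:
    """Parse a two-column reader match table into a match graph.

    ``(a, b)`` with both positive is a match edge, ``(a, 0)`` marks lesion
    ``a`` as disappeared, ``(0, b)`` marks ``b`` as new.  Lesions of
    ``n1``/``n2`` never mentioned get their sentinel edge (warned).  Duplicate
    identical rows are collapsed with a warning.
    """
    n1 = frozenset(int(i) for i in n1)
    n2 = frozenset(int(i) for i in n2)
    rows = _load_table_rows(path)
    if len(set(rows)) < len(rows):
        warnings.warn(f"{path}: duplicate rows collapsed", stacklevel=2)
    edges: set = set()
    for a, b in set(rows):
        if a > 0 and a not in n1:
            raise GraphValidationError(f"{path}: scan-1 index {a} not in {sorted(n1)}")
        if b > 0 and b not in n2:
            raise GraphValidationError(f"{path}: scan-2 index {b} not in {sorted(n2)}")
        if a > 0 and b > 0:
            edges.add((a, b))
        elif a > 0:
            edges.add((a, DISAPPEARED))
        else:
            edges.add((NEW, b))
    mentioned1 = {a for a, b in edges if a != NEW}
    mentioned2 = {b for a, b in edges if b != DISAPPEARED}
    missing1 = sorted(n1 - mentioned1)
    missing2 = sorted(n2 - mentioned2)
    if missing1 or missing2:
        warnings.warn(
            f"{path}: auto-completed sentinel edges for unmentioned lesions "
            f"(scan 1: {missing1}, scan 2: {missing2})",
            stacklevel=2,
        )
    edges.update((i, DISAPPEARED) for i in missing1)
    edges.update((NEW, j) for j in missing2)
    g = MatchGraph(n1, n2, frozenset(edges))
    violations = validate_graph(g)
    if violations:
        raise GraphValidationError(f"{path}: inconsistent table: {violations}")
    return g


def write_match_table(g: MatchGraph, path: str | Path) -> None:
    """Write a match graph in the two-column workbook dialect (sorted rows)."""
    rows = []
    for a, b in g.edges:
        rows.append((0 if a == NEW else int(a), 0 if b == DISAPPEARED else int(b)))
    rows.sort()
    df = pd.DataFrame(rows, columns=["scan1", "scan2"])
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Graph JSON
# ---------------------------------------------------------------------------

def read_graph_json(path: str | Path) -> MatchGraph:
    with open(path) as fh:
        return MatchGraph.from_dict(json.load(fh))


def write_graph_json(g: MatchGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(g.to_dict(), fh, indent=1)
        fh.write("\n")
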