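"""Domain types for longitudinal lesion matching.

A pair of scans is described by two label volumes (integer lesion masks on a
physical grid) and a bipartite *match graph* whose two node groups are the
lesion indices of scan 1 and scan 2.  An edge asserts that two labelled
components are the same physical lesion.  Two sentinel nodes extend the graph:
``NEW`` on the scan-1 side (edges ``(NEW, j)`` mark lesions appearing on
scan 2) and ``DISAPPEARED`` on the scan-2 side (edges ``(i, DISAPPEARED)``
mark lesions with no counterpart on scan 2).  Every real lesion is therefore
covered by at least one edge, and a lesion is either matched to one or more
real lesions or carries exactly its sentinel edge — never both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Union

import numpy as np

__all__ = [
    "NEW",
    "DISAPPEARED",
    "Node",
    "Edge",
    "LabelVolume",
    "LesionRecord",
    "MatchGraph",
    "MetricsReport",
    "GraphValidationError",
    "build_graph",
    "validate_graph",
    "restrict_graph",
    "sorted_edges",
]

#: Sentinel node on the scan-1 side: partner of lesions that are new on scan 2.
NEW = "NEW"
#: Sentinel node on the scan-2 side: partner of lesions that disappeared.
DISAPPEARED = "DISAPPEARED"

Node = Union[int, str]
Edge = tuple[Node, Node]


class GraphValidationError(ValueError):
    """A match graph or match table refers to unknown lesion indices."""


def _edge_sort_key(edge: Edge) -> tuple:
    a, b = edge
    # Integers sort before the sentinel on each side; gives a stable canonical
    # ordering for serialized files.
    ka = (0, int(a)) if a != NEW else (1, 0)
    kb = (0, int(b)) if b != DISAPPEARED else (1, 0)
    return (ka, kb)


def sorted_edges(edges: Iterable[Edge]) -> list[Edge]:
    """Canonical (deterministic) ordering of an edge set."""
    return sorted(edges, key=_edge_sort_key)


@dataclass(frozen=True)
class LabelVolume:
    """A 3D integer label map with physical geometry.

    Value 0 is background; each positive integer identifies one lesion.
    ``spacing`` (mm), ``origin`` (mm) and the 3x3 ``direction`` matrix follow
    the ITK physical-space convention, with array axes ordered (z, y, x) and
    geometry vectors ordered (x, y, z).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError(f"label volume must be 3D, got shape {v.shape}")
        if not np.issubdtype(v.dtype, np.integer):
            raise ValueError(f"label volume must be integer-typed, got {v.dtype}")
        if v.size and v.min() < 0:
            raise ValueError("label volume contains negative values")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "direction", tuple(float(d) for d in self.direction))

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def labels(self) -> list[int]:
        """Sorted positive labels present in the volume."""
        u = np.unique(self.voxels)
        return [int(x) for x in u if x > 0]

    def same_geometry(self, other: "LabelVolume", tol: float = 1e-6) -> bool:
        return (
            self.voxels.shape == other.voxels.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )


@dataclass
class LesionRecord:
    """One labelled lesion on its parent grid.

    ``volume_cm3`` is always ``voxel_count × voxel volume (mm³) / 1000``.
    ``dilated_mask`` is populated by the dilation stage and always contains
    ``mask``.
    """

    index: int
    voxel_count: int
    volume_cm3: float
    mask: np.ndarray
    dilated_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.index <= 0:
            raise ValueError("lesion index must be a positive integer")
        if self.dilated_mask is not None and not np.all(
            self.dilated_mask[self.mask]
        ):
            raise ValueError(f"lesion {self.index}: mask not contained in dilated mask")


@dataclass(frozen=True)
class MatchGraph:
    """Bipartite lesion match graph with sentinel nodes.

    ``n1`` / ``n2`` are the real lesion indices on each scan; ``edges`` are
    canonical ``(scan-1 element, scan-2 element)`` pairs where the scan-1
    element is a lesion index or ``NEW`` and the scan-2 element a lesion index
    or ``DISAPPEARED``.  Equality is set equality of nodes and edges.
    """

    n1: frozenset[int]
    n2: frozenset[int]
    edges: frozenset[Edge]

    def __post_init__(self):
        object.__setattr__(self, "n1", frozenset(int(i) for i in self.n1))
        object.__setattr__(self, "n2", frozenset(int(i) for i in self.n2))
        canon = []
        for a, b in self.edges:
            a = NEW if a == NEW else int(a)
            b = DISAPPEARED if b == DISAPPEARED else int(b)
            canon.append((a, b))
        object.__setattr__(self, "edges", frozenset(canon))

    # -- views ------------------------------------------------------------
    @property
    def real_edges(self) -> frozenset[Edge]:
        """Edges between two real lesions (matches)."""
        return frozenset(
            (a, b) for a, b in self.edges if a != NEW and b != DISAPPEARED
        )

    @property
    def disappeared(self) -> frozenset[int]:
        return frozenset(a for a, b in self.edges if b == DISAPPEARED and a != NEW)

    @property
    def new(self) -> frozenset[int]:
        return frozenset(b for a, b in self.edges if a == NEW and b != DISAPPEARED)

    def to_dict(self) -> dict:
        """JSON-ready representation with a stable edge order."""
        return {
            "n1": sorted(self.n1),
            "n2": sorted(self.n2),
            "edges": [list(e) for e in sorted_edges(self.edges)],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MatchGraph":
        edges = []
        for a, b in d["edges"]:
            a = NEW if a == NEW else int(a)
            b = DISAPPEARED if b == DISAPPEARED else int(b)
            edges.append((a, b))
        return cls(frozenset(d["n1"]), frozenset(d["n2"]), frozenset(edges))


@dataclass(frozen=True)
class MetricsReport:
    """Agreement metrics between two edge sets (one ordered scan pair).

    ``f1`` is the harmonic mean of ``precision`` and ``recall``;
    ``n_differences`` the cardinality of the symmetric difference of the edge
    sets.  ``flags`` records degenerate conventions (e.g. an empty edge set,
    where precision/recall default to 1.0).
    """

    precision: float
    recall: float
    f1: float
    n_differences: int
    flags: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "n_differences": self.n_differences,
            "flags": list(self.flags),
        }


def build_graph(
    n1: Iterable[int],
    n2: Iterable[int],
    matches: Iterable[tuple[int, int]],
) -> MatchGraph:
    """Build a match graph from real-lesion matches, adding sentinel edges.

    Every scan-1 index not covered by a match receives an edge to
    ``DISAPPEARED``; every uncovered scan-2 index receives an edge from
    ``NEW``.  Raises :class:`GraphValidationError` if a match refers to an
    index absent from ``n1``/``n2``.
    """
    n1 = frozenset(int(i) for i in n1)
    n2 = frozenset(int(i) for i in n2)
    matches = {(int(a), int(b)) for a, b in matches}
    for a, b in matches:
        if a not in n1:
            raise GraphValidationError(f"match ({a}, {b}): index {a} not in scan-1 set")
        if b not in n2:
            raise GraphValidationError(f"match ({a}, {b}): index {b} not in scan-2 set")
    edges: set[Edge] = set(matches)
    covered1 = {a for a, _ in matches}
    covered2 = {b for _, b in matches}
    edges.update((i, DISAPPEARED) for i in n1 - covered1)
    edges.update((NEW, j) for j in n2 - covered2)
    return MatchGraph(n1, n2, frozenset(edges))


def restrict_graph(
    g: MatchGraph, keep1: Iterable[int], keep2: Iterable[int]
) -> MatchGraph:
    """Restrict a graph to subsets of its real nodes, re-sentineling.

    Edges incident to dropped nodes are removed; a kept lesion left without
    any real match becomes disappeared/new.  Used to limit an evaluation to
    lesions above a volume threshold.
    """
    keep1 = frozenset(int(i) for i in keep1) & g.n1
    keep2 = frozenset(int(i) for i in keep2) & g.n2
    matches = {
        (a, b)
        for a, b in g.edges
        if a != NEW and b != DISAPPEARED and a in keep1 and b in keep2
    }
    return build_graph(keep1, keep2, matches)


def validate_graph(g: MatchGraph) -> list[str]:
    """Check all match-graph invariants; returns human-readable violations.

    An empty list means the graph is valid.  Violations are data, not
    exceptions: readers' workbooks routinely produce inconsistent graphs and
    callers need the full list.
    """
    violations: list[str] = []
    for a, b in g.edges:
        if a == NEW and b == DISAPPEARED:
            violations.append("edge (NEW, DISAPPEARED) is forbidden")
            continue
        if a != NEW and a not in g.n1:
            violations.append(f"edge ({a}, {b}): {a} not a scan-1 node")
        if b != DISAPPEARED and b not in g.n2:
            violations.append(f"edge ({a}, {b}): {b} not a scan-2 node")
    for i in sorted(g.n1):
        real = {b for a, b in g.edges if a == i and b != DISAPPEARED}
        sent = (i, DISAPPEARED) in g.edges
        if not real and not sent:
            violations.append(f"scan-1 lesion {i} has no incident edge")
        elif real and sent:
            violations.append(
                f"scan-1 lesion {i} is both matched and marked disappeared"
            )
    for j in sorted(g.n2):
        real = {a for a, b in g.edges if b == j and a != NEW}
        sent = (NEW, j) in g.edges
        if not real and not sent:
            violations.append(f"scan-2 lesion {j} has no incident edge")
        elif real and sent:
            violations.append(f"scan-2 lesion {j} is both matched and marked new")
    return violations
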