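"""Agreement metrics between two match graphs of the same scan pair.

Used both for inter-reader variability (reader A vs reader B) and for
evaluating the automated matcher (auto vs reader consensus).  All four
metrics operate on the full edge sets, with sentinel edges counting as
ordinary edges — a disagreement of the form "A says the lesion disappeared
and a new one appeared, B says they are the same lesion" contributes three
differing edges.

precision  P(E_A, E_B) = |E_A ∩ E_B| / |E_A|
recall     R(E_A, E_B) = |E_A ∩ E_B| / |E_B|
F1         F = 2PR/(P+R) = 2|E_A∩E_B| / (2|E_A∩E_B| + |E_A\\E_B| + |E_B\\E_A|)
N_d        |E_A \\ E_B| + |E_B \\ E_A|   (symmetric difference)

F1 and N_d are symmetric in their arguments; precision and recall swap when
the arguments are reversed.  An empty edge set makes precision or recall
undefined; by convention the value is reported as 1.0 with an explanatory
flag.
"""

from __future__ import annotations

from typing import AbstractSet, Iterable

from .core import Edge, GraphValidationError, MatchGraph, MetricsReport

__all__ = ["precision", "recall", "f1", "num_differences", "compare_graphs"]


def _as_set(edges: Iterable[Edge]) -> frozenset:
    return edges if isinstance(edges, frozenset) else frozenset(edges)


def precision(e_a: AbstractSet[Edge], e_b: AbstractSet[Edge]) -> float:
    """Fraction of A's edges also present in B (positive predictive value)."""
    e_a, e_b = _as_set(e_a), _as_set(e_b)
    if not e_a:
        return 1.0
    return len(e_a & e_b) / len(e_a)


def recall(e_a: AbstractSet[Edge], e_b: AbstractSet[Edge]) -> float:
    """Fraction of B's edges also present in A (sensitivity)."""
    e_a, e_b = _as_set(e_a), _as_set(e_b)
    if not e_b:
        return 1.0
    return len(e_a & e_b) / len(e_b)


def f1(e_a: AbstractSet[Edge], e_b: AbstractSet[Edge]) -> float:
    """Harmonic mean of precision and recall, via set cardinalities."""
    e_a, e_b = _as_set(e_a), _as_set(e_b)
    inter = len(e_a & e_b)
    denom = 2 * inter + len(e_a - e_b) + len(e_b - e_a)
    if denom == 0:  # both empty
        return 1.0
    return 2 * inter / denom


def num_differences(e_a: AbstractSet[Edge], e_b: AbstractSet[Edge]) -> int:
    """Number of edges present in one graph and not the other."""
    e_a, e_b = _as_set(e_a), _as_set(e_b)
    return len(e_a ^ e_b)


def compare_graphs(g_a: MatchGraph, g_b: MatchGraph) -> MetricsReport:
    """All four metrics for an ordered pair of graphs over identical nodes.

    Raises :class:`GraphValidationError` when the graphs' real node sets
    differ, since the metrics are only meaningful for the same lesion sets.
    """
    if g_a.n1 != g_b.n1 or g_a.n2 != g_b.n2:
        d1 = sorted(g_a.n1 ^ g_b.n1)
        d2 = sorted(g_a.n2 ^ g_b.n2)
        raise GraphValidationError(
            f"graphs have different node sets (scan 1 diff: {d1}, scan 2 diff: {d2})"
        )
    flags = []
    if not g_a.edges:
        flags.append("empty_edge_set_a")
    if not g_b.edges:
        flags.append("empty_edge_set_b")
    return MetricsReport(
        precision=precision(g_a.edges, g_b.edges),
        recall=recall(g_a.edges, g_b.edges),
        f1=f1(g_a.edges, g_b.edges),
        n_differences=num_differences(g_a.edges, g_b.edges),
        flags=tuple(flags),
    )
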