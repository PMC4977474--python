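"""Candidate-threshold construction, signum adjacency and threshold refinement.

The candidate list is read off the sorted association list: the most stringent
threshold t_first is the value at 1-indexed position m-1 (the minimum edge
count for an m-vertex network to be connected), the least stringent t_last the
value at position min(150*m, m(m-1)/2) (empirically, denser models are never
scale-free and are too costly to evaluate).  The interval is split into six
equal subintervals, giving seven equally spaced candidates.

The signum adjacency function binarises associations at a threshold tau:
similarity measures connect a pair when alpha_ij >= tau, distances when
alpha_ij <= tau.  Isolated vertices are removed from each model but the
original gene count is retained so %used can be reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Literal, Sequence

import networkx as nx
import numpy as np

from .association import AssociationMatrix, MeasureSpec, SortedAssociationList

if TYPE_CHECKING:  # pragma: no cover
    from .topology import NetworkStatsRow, Selection


@dataclass
class ThresholdList:
    """Seven equally spaced candidate thresholds, most stringent first."""

    values: list[float]
    step: float
    origin: Literal["initial", "refined", "user"] = "initial"

    def __post_init__(self) -> None:
        if self.origin != "user":
            if len(self.values) != 7:
                raise ValueError("a computed threshold list has exactly 7 values")
            diffs = np.diff(self.values)
            if self.step != 0 and not np.allclose(
                np.abs(diffs), abs(self.step), atol=1e-12
            ):
                raise ValueError("thresholds are not equally spaced by the step")

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)


def threshold_list_from_endpoints(
    t_first: float, t_last: float, origin: Literal["initial", "refined"] = "initial"
) -> ThresholdList:
    """Split [t_first, t_last] into six equal subintervals -> 7 thresholds.

    The step is (t_first - t_last)/6; t_first is the most stringent value and
    comes first regardless of sort direction.
    """
    step = (t_first - t_last) / 6.0
    values = [t_first - k * step for k in range(7)]
    values[-1] = t_last  # exact endpoint, no accumulated round-off
    return ThresholdList(values, step, origin)


def initial_threshold_list(sorted_list: SortedAssociationList, m: int) -> ThresholdList:
    """Candidate thresholds from sorted-list positions m-1 and min(150m, L).

    For m < 301 the nominal last position 150*m exceeds the list length
    m(m-1)/2 and clamps to the weakest association.
    """
    if m < 2:
        raise ValueError("need at least 2 genes")
    L = len(sorted_list)
    if L != m * (m - 1) // 2:
        raise ValueError(
            f"sorted list has {L} entries, expected m(m-1)/2 = {m * (m - 1) // 2}"
        )
    t_first = sorted_list.value_at(m - 1)
    t_last = sorted_list.value_at(min(150 * m, L))
    return threshold_list_from_endpoints(t_first, t_last, origin="initial")


@dataclass
class UnweightedNetwork:
    """A simple undirected network over the genes that kept >= 1 edge.

    ``m_original`` is the gene count before isolate removal, so
    %used = 100 * |V| / m_original.
    """

    graph: nx.Graph
    m_original: int
    threshold: float | None = None

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def pct_used(self) -> float:
        return 100.0 * self.n_vertices / self.m_original

    def has_edges(self) -> bool:
        return self.n_edges > 0


def _network_from_edges(
    edges: Sequence[tuple[str, str]], m_original: int, tau: float
) -> UnweightedNetwork:
    g = nx.Graph()
    g.add_edges_from(edges)
    g.remove_edges_from(nx.selfloop_edges(g))
    return UnweightedNetwork(g, m_original, tau)


def signum_adjacency(
    A: AssociationMatrix, tau: float, measure: MeasureSpec | None = None
) -> UnweightedNetwork:
    """Binarise the association matrix at tau into an unweighted network.

    Similarity: edge iff alpha_ij >= tau; distance: edge iff alpha_ij <= tau.
    Vertices left without any edge are removed.
    """
    measure = measure or A.measure
    iu, ju = np.triu_indices(A.m, k=1)
    vals = A.values[iu, ju]
    keep = vals >= tau if measure.is_similarity else vals <= tau
    ids = A.gene_ids
    edges = [(ids[i], ids[j]) for i, j in zip(iu[keep], ju[keep])]
    return _network_from_edges(edges, A.m, tau)


def network_at_threshold(
    sorted_list: SortedAssociationList, tau: float, m: int | None = None
) -> UnweightedNetwork:
    """Build the network at tau from the sorted association list.

    Because the list is ordered strongest-to-weakest, qualifying pairs form a
    prefix; equal values at the cut qualify together (the rule is value-based,
    not position-based).
    """
    m = m if m is not None else len(sorted_list.gene_ids)
    vals = sorted_list.values
    if sorted_list.measure.is_similarity:
        n_keep = int(np.searchsorted(-vals, -tau, side="right"))
    else:
        n_keep = int(np.searchsorted(vals, tau, side="right"))
    ids = sorted_list.gene_ids
    edges = [
        (ids[i], ids[j])
        for i, j in zip(sorted_list.idx_i[:n_keep], sorted_list.idx_j[:n_keep])
    ]
    return _network_from_edges(edges, m, tau)


def refine_threshold_list(
    stats: "Sequence[NetworkStatsRow]", selection: "Selection"
) -> ThresholdList:
    """One refinement round around the winning threshold.

    Case 1 — other thresholds pass alongside the best: the most and least
    stringent members of {best} + alternates become the new endpoints.
    Case 2 — only the best passes: its immediate neighbours in the evaluated
    list become the endpoints (clamped to the best itself at a list end).
    The new interval is re-split into six equal subintervals; exactly one
    refinement round is performed before statistics are recomputed.
    """
    if not stats:
        raise ValueError("empty statistics table")
    if selection.best is None:
        raise ValueError("no best threshold; refinement skipped")
    evaluated = [row.thresh for row in stats]  # most stringent first
    best = selection.best
    if best not in evaluated:
        raise ValueError(f"best threshold {best} not among evaluated thresholds")
    passing = sorted(
        set(selection.alternates) | {best}, key=evaluated.index
    )
    if len(passing) > 1:
        t_first, t_last = passing[0], passing[-1]
    else:
        k = evaluated.index(best)
        t_first = evaluated[k - 1] if k > 0 else best
        t_last = evaluated[k + 1] if k < len(evaluated) - 1 else best
    return threshold_list_from_endpoints(t_first, t_last, origin="refined")


def user_threshold_list(values: Sequence[float], measure: MeasureSpec) -> ThresholdList:
    """Up to five user-supplied thresholds, reordered most stringent first."""
    vals = [float(v) for v in values]
    if not 1 <= len(vals) <= 5:
        raise ValueError("supply between 1 and 5 thresholds")
    vals = sorted(vals, reverse=measure.is_similarity)
    step = vals[0] - vals[1] if len(vals) > 1 else 0.0
    return ThresholdList(vals, step, origin="user")
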