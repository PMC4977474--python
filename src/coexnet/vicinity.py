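"""Genes-of-interest analysis: maximal cliques, vicinity networks, densities.

A vicinity network (VN) is the immediate neighbourhood of an anchor inside
the chosen 'best' network: for a single gene it is the gene plus all direct
neighbours; for a clique of s genes it is the clique plus the common
neighbours of all s members.  Densities (present edges over possible edges)
quantify how tightly each VN is interconnected; VNs whose density approaches
but does not reach 1 are labelled fuzzy cliques.

Two analysis modes mirror the two ways a gene list can be read: per-gene
(one VN per gene of interest) and clique-based (induce the GoI subgraph,
enumerate its maximal cliques, one VN per clique; a GoI isolated within the
GoI subgraph falls back to its per-gene VN).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Literal, Sequence

import networkx as nx

from .io import AnnotationMap, ExpressionMatrix, GoISet
from .thresholding import UnweightedNetwork

logger = logging.getLogger(__name__)

#: density at and above which a non-complete subnetwork is called a fuzzy clique
FUZZY_DENSITY_MIN = 0.85

#: per-gene mode warns beyond this many genes of interest
PER_GENE_RECOMMENDED_MAX = 20


@dataclass(frozen=True)
class Clique:
    """A completely connected vertex set (j >= 2 members, j(j-1)/2 edges)."""

    members: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(sorted(self.members)))
        if len(self.members) < 2:
            raise ValueError("a clique needs at least 2 members")
        if len(set(self.members)) != len(self.members):
            raise ValueError("clique members must be distinct")

    @property
    def size(self) -> int:
        return len(self.members)


def maximal_cliques(graph: nx.Graph | UnweightedNetwork) -> list[Clique]:
    """Enumerate all maximal cliques of size >= 2 (pivoting Bron-Kerbosch).

    Output order is deterministic: larger cliques first, lexicographic member
    tuples breaking ties.
    """
    g = graph.graph if isinstance(graph, UnweightedNetwork) else graph
    cliques = [Clique(tuple(c)) for c in nx.find_cliques(g) if len(c) >= 2]
    return sorted(cliques, key=lambda c: (-c.size, c.members))


def subnetwork_density(
    net: nx.Graph | UnweightedNetwork, genes: Iterable[str]
) -> float:
    """Induced-subgraph density: present edges over j(j-1)/2 possible."""
    g = net.graph if isinstance(net, UnweightedNetwork) else net
    members = list(dict.fromkeys(genes))
    j = len(members)
    if j < 2:
        raise ValueError("density needs at least 2 genes")
    missing = [m for m in members if m not in g]
    if missing:
        raise KeyError(f"genes not in network: {', '.join(missing[:5])}")
    e = g.subgraph(members).number_of_edges()
    return e / (j * (j - 1) / 2)


@dataclass
class VicinityNetwork:
    """Anchor (gene or clique) plus neighbourhood, with membership stats."""

    index: int
    anchor: tuple[str, ...]
    members: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    goi_count: int
    density: float

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def is_fuzzy_clique(self) -> bool:
        return FUZZY_DENSITY_MIN <= self.density < 1.0

    @property
    def missing_edges(self) -> int:
        j = self.size
        return j * (j - 1) // 2 - len(self.edges)

    def subgraph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.members)
        g.add_edges_from(self.edges)
        return g


def _make_vn(
    g: nx.Graph, anchor: Sequence[str], members: Sequence[str],
    index: int, gois: set[str],
) -> VicinityNetwork:
    members = tuple(sorted(dict.fromkeys(members)))
    sub = g.subgraph(members)
    edges = tuple(sorted((u, v) if u <= v else (v, u) for u, v in sub.edges()))
    density = (
        len(edges) / (len(members) * (len(members) - 1) / 2)
        if len(members) >= 2
        else 1.0
    )
    return VicinityNetwork(
        index=index,
        anchor=tuple(sorted(anchor)),
        members=members,
        edges=edges,
        goi_count=sum(1 for m in members if m in gois),
        density=density,
    )


def vertex_vicinity(
    net: UnweightedNetwork, gene: str, index: int = 1, gois: set[str] | None = None
) -> VicinityNetwork:
    """VN of one gene: the gene, all its direct neighbours, induced edges."""
    g = net.graph
    if gene not in g:
        raise KeyError(f"gene {gene!r} is not in the network")
    members = [gene, *g.neighbors(gene)]
    return _make_vn(g, [gene], members, index, gois or {gene})


def clique_vicinity(
    net: UnweightedNetwork, clique: Clique, index: int = 1, gois: set[str] | None = None
) -> VicinityNetwork:
    """VN of a clique: its s members plus their common neighbours."""
    g = net.graph
    for m in clique.members:
        if m not in g:
            raise KeyError(f"clique member {m!r} is not in the network")
    for i, a in enumerate(clique.members):
        for b in clique.members[i + 1 :]:
            if not g.has_edge(a, b):
                raise ValueError(f"anchor is not a clique: {a!r}-{b!r} missing")
    common = set(g.neighbors(clique.members[0]))
    for m in clique.members[1:]:
        common &= set(g.neighbors(m))
    common -= set(clique.members)
    members = [*clique.members, *common]
    return _make_vn(g, clique.members, members, index, gois or set(clique.members))


@dataclass
class GoIAnalysis:
    """Vicinity networks extracted for a genes-of-interest list."""

    mode: Literal["per_gene", "clique_based"]
    vns: list[VicinityNetwork]
    matched_gois: set[str]
    unmatched_gois: list[str]
    n_gois_supplied: int
    goi_cliques: list[Clique] = field(default_factory=list)
    profiles: dict[int, "dict[str, list[float]]"] = field(default_factory=dict)

    def vn_table(self) -> list[tuple[int, int, int, float]]:
        """Rows (VN index, VN size, GoI count, density) of the summary table."""
        return [(vn.index, vn.size, vn.goi_count, vn.density) for vn in self.vns]


def goi_analysis(
    net: UnweightedNetwork,
    gois: GoISet,
    mode: Literal["per_gene", "clique_based"] = "clique_based",
    annotation: AnnotationMap | None = None,
    expression: ExpressionMatrix | None = None,
) -> GoIAnalysis:
    """Extract vicinity networks around the genes of interest.

    per_gene: one VN per matched gene.  clique_based: induce the GoI-by-GoI
    subgraph of the network, enumerate its maximal cliques and take one
    clique VN per clique; GoIs isolated inside the GoI subgraph (no edge to
    any other GoI) fall back to their single-gene VN.  When an expression
    matrix is supplied, per-VN member expression profiles are attached for
    plotting.
    """
    g = net.graph
    matched = [gid for gid in gois if gid in g]
    unmatched = [gid for gid in gois if gid not in g]
    if unmatched:
        logger.warning(
            "%d of %d genes of interest are not in the network: %s",
            len(unmatched), len(gois), ", ".join(unmatched[:10]),
        )
    goi_set = set(matched)
    vns: list[VicinityNetwork] = []
    goi_cliques: list[Clique] = []
    if matched:
        if mode == "per_gene":
            if len(matched) > PER_GENE_RECOMMENDED_MAX:
                logger.warning(
                    "per-gene mode with %d genes; consider a list of at most %d",
                    len(matched), PER_GENE_RECOMMENDED_MAX,
                )
            for k, gid in enumerate(sorted(matched), start=1):
                vns.append(vertex_vicinity(net, gid, index=k, gois=goi_set))
        elif mode == "clique_based":
            goi_sub = g.subgraph(matched)
            goi_cliques = maximal_cliques(goi_sub)
            covered = {m for c in goi_cliques for m in c.members}
            isolated = sorted(set(matched) - covered)
            k = 0
            for c in goi_cliques:
                k += 1
                vns.append(clique_vicinity(net, c, index=k, gois=goi_set))
            for gid in isolated:
                k += 1
                vns.append(vertex_vicinity(net, gid, index=k, gois=goi_set))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    analysis = GoIAnalysis(
        mode=mode,
        vns=vns,
        matched_gois=goi_set,
        unmatched_gois=unmatched,
        n_gois_supplied=len(gois),
        goi_cliques=goi_cliques,
    )
    if expression is not None:
        for vn in vns:
            analysis.profiles[vn.index] = {
                gid: list(map(float, expression.row(gid)))
                for gid in vn.members
                if gid in expression.gene_ids
            }
    return analysis
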