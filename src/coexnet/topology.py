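"""Per-threshold network topology: degree distributions, power-law fits,
small-world metrics, component reliability, and 'best'-threshold selection.

A model is admissible when (in gate order) its largest component holds at
least 95 % of the network's vertices (otherwise the remaining measures are
skewed by fragmentation), its log-log degree-distribution regression has
R^2 >= 0.80, and the fitted power-law exponent a = -slope lies strictly
inside (1, 3).  Among admissible models the one retaining the most genes from
the original dataset wins; ties go to the more stringent threshold.
Small-world structure (high clustering, short paths relative to a random
graph of matched size and mean degree) is reported as an advisory and can be
promoted to a hard gate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats as sps

from .association import SortedAssociationList
from .thresholding import ThresholdList, UnweightedNetwork, network_at_threshold

logger = logging.getLogger(__name__)


@dataclass
class DegreeDistribution:
    """Empirical degree frequencies of a network with isolates removed.

    Degree 0 is absent by construction; ``counts`` are raw vertex tallies so
    probabilities are exact rationals count/n.  Non-integer weights are also
    accepted, e.g. to represent an analytic distribution for fitting.
    """

    counts: dict[int, float]

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def support(self) -> list[int]:
        return sorted(self.counts)

    @property
    def p_k(self) -> dict[int, float]:
        n = self.n
        return {k: c / n for k, c in sorted(self.counts.items())}


def degree_distribution(net: UnweightedNetwork) -> DegreeDistribution:
    if net.n_edges == 0:
        raise ValueError("empty network has no degree distribution")
    counts: dict[int, int] = {}
    for _, d in net.graph.degree():
        counts[d] = counts.get(d, 0) + 1
    return DegreeDistribution(counts)


@dataclass
class PowerLawFit:
    """OLS on (log k, log p_k): slope, exponent a = -slope, intercept, R^2."""

    slope: float
    intercept: float
    r_squared: float
    reliable: bool = True

    @property
    def a(self) -> float:
        return -self.slope


def fit_power_law(dd: DegreeDistribution) -> PowerLawFit:
    """Linear regression of log p_k on log k over the observed support.

    Only degrees with nonzero frequency enter (log of zero is undefined);
    natural logs — slope and R^2 are base-invariant.  With fewer than three
    support points the fit is flagged unreliable and the model cannot be
    called scale-free.
    """
    ks = np.array(dd.support, dtype=float)
    ps = np.array([dd.counts[int(k)] for k in ks], dtype=float) / dd.n
    if ks.size < 3:
        logger.warning("only %d distinct degrees; power-law fit unreliable", ks.size)
        if ks.size < 2:
            return PowerLawFit(float("nan"), float("nan"), 0.0, reliable=False)
        res = sps.linregress(np.log(ks), np.log(ps))
        return PowerLawFit(res.slope, res.intercept, res.rvalue**2, reliable=False)
    res = sps.linregress(np.log(ks), np.log(ps))
    return PowerLawFit(float(res.slope), float(res.intercept), float(res.rvalue**2))


def mean_cluster_coefficient(net: UnweightedNetwork) -> float:
    """Mean local clustering coefficient over all vertices.

    CC(v) = 2 * (edges among v's neighbours) / (deg (deg - 1)); degree-0/1
    vertices contribute 0 rather than being excluded.
    """
    g = net.graph
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("network has no vertices")
    if n > 3000:  # avoid the dense n x n adjacency
        return float(nx.average_clustering(g, count_zeros=True))
    A = nx.to_numpy_array(g, dtype=float)
    deg = A.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", A, A, A) / 2.0
    denom = deg * (deg - 1) / 2.0
    cc = np.divide(triangles, denom, out=np.zeros_like(deg), where=denom > 0)
    return float(cc.mean())


def mean_path_length(net: UnweightedNetwork) -> float:
    """Mean shortest-path length over same-component unordered vertex pairs.

    Pairs split across components have no path and are excluded from the
    average rather than treated as infinite.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        raise ValueError("network has no edges")
    if g.number_of_nodes() <= 3000:
        from scipy.sparse import csgraph

        A = nx.to_scipy_sparse_array(g, format="csr", dtype=float)
        D = csgraph.shortest_path(A, unweighted=True, directed=False)
        finite = np.isfinite(D) & (D > 0)  # same-component, off-diagonal
        return float(D[finite].sum() / finite.sum())
    total = 0.0
    n_pairs = 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
        n_pairs += len(comp) * (len(comp) - 1) // 2
    # all_pairs_shortest_path_length visits each unordered pair twice
    return total / (2 * n_pairs)


def component_stats(net: UnweightedNetwork) -> tuple[int, float]:
    """(number of components, % of network vertices in the largest one)."""
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("network has no vertices")
    sizes = [len(c) for c in nx.connected_components(g)]
    return len(sizes), 100.0 * max(sizes) / g.number_of_nodes()


@dataclass
class NetworkStatsRow:
    """One candidate model's record: the columns of the network-stats table."""

    thresh: float
    r_squared: float
    slope: float
    mean_cc: float
    mean_path: float
    pct_used: float
    pct_big_comp: float
    n_components: int = 1
    degenerate: bool = False
    fit_reliable: bool = True

    @property
    def a(self) -> float:
        """Power-law exponent implied by the regression slope."""
        return -self.slope


def network_stats_row(net: UnweightedNetwork, m: int, tau: float) -> NetworkStatsRow:
    """All topology columns for one thresholded model."""
    if not net.has_edges():
        return NetworkStatsRow(
            tau, float("nan"), float("nan"), float("nan"), float("nan"),
            0.0, 0.0, 0, degenerate=True, fit_reliable=False,
        )
    fit = fit_power_law(degree_distribution(net))
    n_comp, pct_big = component_stats(net)
    return NetworkStatsRow(
        thresh=tau,
        r_squared=fit.r_squared,
        slope=fit.slope,
        mean_cc=mean_cluster_coefficient(net),
        mean_path=mean_path_length(net),
        pct_used=100.0 * net.n_vertices / m,
        pct_big_comp=pct_big,
        n_components=n_comp,
        fit_reliable=fit.reliable,
    )


def evaluate_thresholds(
    sorted_list: SortedAssociationList,
    thresholds: ThresholdList,
    m: int | None = None,
    keep_networks: bool = False,
) -> list[NetworkStatsRow] | tuple[list[NetworkStatsRow], list[UnweightedNetwork]]:
    """Construct the model at every candidate threshold and score it.

    Returns one stats row per threshold (a threshold that empties the network
    yields a row flagged degenerate).  Edge sets are nested across the
    candidates because relaxing the threshold can only add edges.
    """
    m = m if m is not None else len(sorted_list.gene_ids)
    rows: list[NetworkStatsRow] = []
    nets: list[UnweightedNetwork] = []
    for tau in thresholds:
        net = network_at_threshold(sorted_list, tau, m)
        rows.append(network_stats_row(net, m, tau))
        if keep_networks:
            nets.append(net)
        logger.info(
            "threshold %.3f: %d vertices, %d edges", tau, net.n_vertices, net.n_edges
        )
    return (rows, nets) if keep_networks else rows


@dataclass(frozen=True)
class SelectionCriteria:
    """Gates for the 'best'-model decision; defaults match the method."""

    bigcomp_min: float = 95.0
    r2_min: float = 0.80
    a_range: tuple[float, float] = (1.0, 3.0)  # exclusive bounds
    strict_small_world: bool = False
    sw_cc_ratio: float = 5.0
    sw_path_ratio: float = 2.0


@dataclass
class Selection:
    """Outcome of weighing the candidate models against each other."""

    best: float | None
    alternates: list[float] = field(default_factory=list)
    reasons: dict[float, list[str]] = field(default_factory=dict)
    alert: str | None = None


def _gate_reasons(
    row: NetworkStatsRow, crit: SelectionCriteria, net: UnweightedNetwork | None
) -> list[str]:
    reasons: list[str] = []
    if row.degenerate:
        return ["degenerate: network has no edges"]
    if row.pct_big_comp < crit.bigcomp_min:
        reasons.append(
            f"largest component holds {row.pct_big_comp:.0f}% of vertices "
            f"(< {crit.bigcomp_min:.0f}%); topology measures unreliable"
        )
    if not row.fit_reliable:
        reasons.append("power-law fit unreliable (fewer than 3 distinct degrees)")
    elif row.r_squared < crit.r2_min:
        reasons.append(
            f"low coefficient of determination R2={row.r_squared:.2f} (< {crit.r2_min:.2f})"
        )
    lo, hi = crit.a_range
    if row.fit_reliable and not (lo < row.a < hi):
        reasons.append(f"power-law exponent a={row.a:.2f} outside ({lo:g},{hi:g})")
    if crit.strict_small_world:
        if net is None:
            raise ValueError("strict small-world gating needs the networks")
        if not small_world_report(net).small_world:
            reasons.append("not small-world relative to the random baseline")
    return reasons


def select_best_threshold(
    stats: Sequence[NetworkStatsRow],
    criteria: SelectionCriteria = SelectionCriteria(),
    networks: Sequence[UnweightedNetwork] | None = None,
) -> Selection:
    """Pick the scale-free, well-connected model retaining the most genes.

    Pure function of the stats table and criteria.  When nothing passes, the
    result carries ``best=None`` plus an alert; every model's reasons stay
    accessible either way.
    """
    if not stats:
        raise ValueError("empty statistics table")
    reasons: dict[float, list[str]] = {}
    passing: list[NetworkStatsRow] = []
    for k, row in enumerate(stats):
        net = networks[k] if networks is not None else None
        r = _gate_reasons(row, criteria, net)
        if r:
            reasons[row.thresh] = r
        else:
            passing.append(row)
    if not passing:
        return Selection(
            best=None,
            reasons=reasons,
            alert=(
                "none of the considered network models meets the scale-free, "
                "small-world and component criteria; all models remain accessible"
            ),
        )
    # max %used; tie -> more stringent threshold, i.e. earliest in table order
    best_row = max(passing, key=lambda r: r.pct_used)
    alternates = [r.thresh for r in passing if r is not best_row]
    return Selection(best=best_row.thresh, alternates=alternates, reasons=reasons)


@dataclass
class SmallWorldReport:
    """Clustering and path length relative to a matched random graph.

    Baselines: CC_rand = mean_degree/(|V|-1) and L_rand = ln|V|/ln(mean_degree)
    for an Erdos-Renyi graph of the same size and density.
    """

    mean_cc: float
    mean_path: float
    cc_random: float
    path_random: float
    cc_ratio: float
    path_ratio: float
    small_world: bool
    assessable: bool = True


def small_world_report(
    net: UnweightedNetwork,
    cc_ratio_min: float = 5.0,
    path_ratio_max: float = 2.0,
) -> SmallWorldReport:
    """Advisory small-world call: CC well above and path length comparable to
    the random baseline of matched size and mean degree."""
    if net.n_edges == 0:
        raise ValueError("network has no edges")
    n = net.n_vertices
    k_bar = 2.0 * net.n_edges / n
    if k_bar <= 1.0 or n < 3:
        return SmallWorldReport(
            mean_cluster_coefficient(net), mean_path_length(net),
            float("nan"), float("nan"), float("nan"), float("nan"),
            small_world=False, assessable=False,
        )
    cc = mean_cluster_coefficient(net)
    path = mean_path_length(net)
    cc_rand = k_bar / (n - 1)
    path_rand = math.log(n) / math.log(k_bar)
    cc_ratio = cc / cc_rand if cc_rand > 0 else float("inf")
    path_ratio = path / path_rand
    return SmallWorldReport(
        cc, path, cc_rand, path_rand, cc_ratio, path_ratio,
        small_world=(cc_ratio >= cc_ratio_min and path_ratio <= path_ratio_max),
    )
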