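"""Tab-delimited file contracts: expression matrices, gene lists, annotations,
edge lists, network-statistics tables, vicinity-network reports and run
summaries.

All files are plain UTF-8 TSV.  Both ``\\n`` and ``\\r\\n`` line endings are
accepted on read; ``\\n`` is written.  Gene identifiers are opaque,
case-sensitive strings and are never normalised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .thresholding import UnweightedNetwork
    from .topology import NetworkStatsRow
    from .vicinity import GoIAnalysis

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file violates its declared tab-delimited contract."""


@dataclass
class ExpressionMatrix:
    """An m-gene x n-measurement matrix of expression values.

    Rows are genes, columns are samples/conditions.  Values may be microarray
    intensities or normalised RNA-seq counts; the association measures make no
    distributional assumption beyond what each measure itself requires.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m, n = self.values.shape
        if m != len(self.gene_ids) or n != len(self.sample_ids):
            raise ValueError(
                f"value matrix is {m}x{n} but {len(self.gene_ids)} gene ids "
                f"and {len(self.sample_ids)} sample ids were given"
            )
        if m < 2:
            raise ValueError("need at least 2 genes")
        if n < 2:
            raise ValueError("need at least 2 measurements")
        seen: set[str] = set()
        for g in self.gene_ids:
            if g in seen:
                raise ValueError(f"duplicate gene id {g!r}")
            seen.add(g)

    @property
    def m(self) -> int:
        return len(self.gene_ids)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GoISet:
    """A user-supplied list of genes of interest (duplicates dropped)."""

    gene_ids: list[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("gene-of-interest set is empty")
        deduped: list[str] = []
        seen: set[str] = set()
        for g in self.gene_ids:
            if g in seen:
                logger.warning("duplicate gene of interest %r dropped", g)
            else:
                seen.add(g)
                deduped.append(g)
        self.gene_ids = deduped

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __iter__(self):
        return iter(self.gene_ids)


@dataclass
class AnnotationMap:
    """gene id -> free-text annotation; unknown genes annotate as ''."""

    mapping: dict[str, str] = field(default_factory=dict)

    def get(self, gene_id: str) -> str:
        return self.mapping.get(gene_id, "")

    def __len__(self) -> int:
        return len(self.mapping)


def _read_lines(path: str | Path) -> list[str]:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file: {p}")
    text = p.read_text(encoding="utf-8")
    return text.replace("\r\n", "\n").split("\n")


def read_expression_matrix(path: str | Path, allow_missing: bool = False) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    First row holds the sample labels, first column the gene identifiers,
    remaining cells numeric expression values.  Missing values (empty or
    ``NA`` cells) are rejected unless ``allow_missing`` is set — only the
    mutual-information measure tolerates them downstream.
    """
    lines = [ln for ln in _read_lines(path) if ln.strip() != ""]
    if len(lines) < 3:
        raise FormatError(f"{path}: need a header row and at least 2 gene rows")
    header = lines[0].split("\t")
    # A leading corner label above the gene-id column is optional.
    first_data = lines[1].split("\t")
    n = len(first_data) - 1
    if len(header) == n + 1:
        sample_ids = header[1:]
    elif len(header) == n:
        sample_ids = header
    else:
        raise FormatError(
            f"{path}: header has {len(header)} fields but data rows have {n} values"
        )
    if n < 2:
        raise FormatError(f"{path}: need at least 2 measurement columns")

    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for r, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != n + 1:
            raise FormatError(
                f"{path}: line {r} has {len(fields)} fields, expected {n + 1}"
            )
        gene_ids.append(fields[0])
        row: list[float] = []
        for c, cell in enumerate(fields[1:], start=2):
            stripped = cell.strip()
            if stripped in ("", "NA", "NaN", "nan"):
                if allow_missing:
                    row.append(float("nan"))
                    continue
                raise FormatError(
                    f"{path}: missing value at line {r}, column {c} "
                    f"(only the MI measure accepts missing data)"
                )
            try:
                value = float(stripped)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at line {r}, column {c}"
                ) from None
            if not np.isfinite(value):
                raise FormatError(
                    f"{path}: non-finite value {cell!r} at line {r}, column {c}"
                )
            row.append(value)
        rows.append(row)
    try:
        return ExpressionMatrix(gene_ids, sample_ids, np.array(rows, dtype=float))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_gene_list(path: str | Path) -> GoISet:
    """Read a genes-of-interest file: one gene identifier per line."""
    ids = [ln.strip() for ln in _read_lines(path) if ln.strip() != ""]
    if not ids:
        raise FormatError(f"{path}: gene list is empty")
    return GoISet(ids)


def read_annotation(path: str | Path) -> AnnotationMap:
    """Read a two-column tab-delimited gene -> annotation file."""
    mapping: dict[str, str] = {}
    for lineno, ln in enumerate(_read_lines(path), start=1):
        if ln.strip() == "":
            continue
        fields = ln.split("\t")
        if len(fields) != 2:
            raise FormatError(
                f"{path}: line {lineno} has {len(fields)} columns, expected 2"
            )
        gene, note = fields[0].strip(), fields[1].strip()
        if gene in mapping:
            logger.warning("duplicate annotation for %r; keeping the first", gene)
            continue
        mapping[gene] = note
    if not mapping:
        raise FormatError(f"{path}: annotation file is empty")
    return AnnotationMap(mapping)


def _canonical_edges(net: "UnweightedNetwork | Iterable[tuple[str, str]]") -> list[tuple[str, str]]:
    edges = net.graph.edges() if hasattr(net, "graph") else net
    canon = {(u, v) if u <= v else (v, u) for u, v in edges}
    return sorted(canon)


def write_edge_list(net, path: str | Path) -> None:
    """Write the network as a two-column TSV, one undirected edge per line.

    Each unordered pair appears exactly once, lexicographically smaller gene
    first, lines sorted — byte-stable across runs and directly loadable into
    Cytoscape or Pajek as a simple interaction file.
    """
    edges = _canonical_edges(net)
    if not edges:
        raise ValueError(
            "network has no edges; inspect the threshold list — the most "
            "stringent thresholds can empty the network"
        )
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column edge TSV back to a sorted list of unordered pairs."""
    edges: list[tuple[str, str]] = []
    for lineno, ln in enumerate(_read_lines(path), start=1):
        if ln.strip() == "":
            continue
        fields = ln.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}: line {lineno} is not a two-column edge")
        u, v = fields
        edges.append((u, v) if u <= v else (v, u))
    return sorted(set(edges))


STATS_HEADER = ("thresh", "R2", "slope", "meanCC", "meanPath", "pctUsed", "pctBigComp")


def format_stats_row(row: "NetworkStatsRow") -> str:
    """One stats line: threshold at 3 d.p., topology statistics at 2 d.p."""
    if row.degenerate:
        tail = "\t".join(["NA"] * 6)
        return f"{row.thresh:.3f}\t{tail}"

    def fmt(v: float) -> str:
        return f"{v:.2f}" if np.isfinite(v) else "NA"

    stats = (row.r_squared, row.slope, row.mean_cc, row.mean_path,
             row.pct_used, row.pct_big_comp)
    return f"{row.thresh:.3f}\t" + "\t".join(fmt(v) for v in stats)


def write_network_stats(stats: "Iterable[NetworkStatsRow]", path: str | Path) -> None:
    """Write the per-threshold network statistics table (NetworkStats file)."""
    rows = list(stats)
    if not rows:
        raise ValueError("network statistics table is empty")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(STATS_HEADER) + "\n")
        for row in rows:
            fh.write(format_stats_row(row) + "\n")


def write_vn_report(
    analysis: "GoIAnalysis",
    annotation: AnnotationMap | None,
    out_dir: str | Path,
) -> list[Path]:
    """Write one TSV per vicinity network.

    Columns: gene id, role (GoI|neighbour), degree and cluster coefficient
    within the VN, and annotation (blank when no map is supplied).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ann = annotation or AnnotationMap()
    written: list[Path] = []
    for vn in analysis.vns:
        p = out / f"VN{vn.index}.txt"
        sub = vn.subgraph()
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("gene\trole\tdegree\tclusterCoefficient\tannotation\n")
            for g in sorted(vn.members):
                role = "GoI" if g in analysis.matched_gois else "neighbour"
                deg = sub.degree(g)
                cc = _local_cc(sub, g)
                fh.write(f"{g}\t{role}\t{deg}\t{cc:.2f}\t{ann.get(g)}\n")
        written.append(p)
    return written


def _local_cc(graph, v) -> float:
    deg = graph.degree(v)
    if deg < 2:
        return 0.0
    nbrs = list(graph.neighbors(v))
    links = sum(1 for i, a in enumerate(nbrs) for b in nbrs[i + 1 :] if graph.has_edge(a, b))
    return 2.0 * links / (deg * (deg - 1))


def write_summary(run_state: Mapping, path: str | Path) -> None:
    """Write the analysis summary file.

    Reports the number of genes loaded, genes of interest not present in the
    'best' network, a per-gene degree / cluster-coefficient table, the gene
    membership of each vicinity network and the VN table
    (VN, VNsize, numGoI, density) with densities printed at 2 d.p.
    """
    analysis: "GoIAnalysis | None" = run_state.get("analysis")
    net: "UnweightedNetwork | None" = run_state.get("network")
    with open(path, "w", encoding="utf-8") as fh:
        n_loaded = run_state.get("n_genes_loaded")
        if n_loaded is not None:
            fh.write(f"genes loaded\t{n_loaded}\n")
        if net is not None:
            fh.write(f"genes in best network\t{net.n_vertices}\n")
        if analysis is not None:
            fh.write(f"genes of interest supplied\t{analysis.n_gois_supplied}\n")
            fh.write(
                f"genes of interest not in best network\t{len(analysis.unmatched_gois)}\n"
            )
            for g in analysis.unmatched_gois:
                fh.write(f"unmatched\t{g}\n")
            if not analysis.matched_gois:
                fh.write("all genes of interest are unmatched; no vicinity networks\n")
        if net is not None:
            fh.write("\ngene\tdegree\tclusterCoefficient\n")
            g = net.graph
            for v in sorted(g.nodes):
                fh.write(f"{v}\t{g.degree(v)}\t{_local_cc(g, v):.2f}\n")
        if analysis is not None and analysis.vns:
            fh.write("\n")
            for vn in analysis.vns:
                gois = sorted(set(vn.members) & analysis.matched_gois)
                fh.write(f"VN{vn.index} GoIs\t{','.join(gois)}\n")
            fh.write("\nVN\tVNsize\tnumGoI\tdensity\n")
            for vn in analysis.vns:
                fh.write(f"{vn.index}\t{len(vn.members)}\t{vn.goi_count}\t{vn.density:.2f}\n")
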