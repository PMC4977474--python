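"""High-level orchestration: build network models, pick the best, run the
genes-of-interest downstream analysis, and lay out the output directory.

These functions are the library analogue of the command-line subcommands:
``build_network`` constructs and scores all candidate models, ``downstream``
extracts vicinity networks at a chosen threshold, and ``full_run`` chains the
two.  Every run writes a JSON manifest (config, package version, seed) so a
rerun with an identical manifest reproduces identical stats files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

from . import __version__
from .association import (
    DEFAULT_MEASURE,
    AssociationMatrix,
    MeasureSpec,
    SortedAssociationList,
    compute_association_matrix,
    get_measure,
    sort_association_pairs,
)
from .io import (
    AnnotationMap,
    ExpressionMatrix,
    GoISet,
    read_annotation,
    read_expression_matrix,
    read_gene_list,
    write_edge_list,
    write_network_stats,
    write_summary,
    write_vn_report,
)
from .thresholding import (
    ThresholdList,
    UnweightedNetwork,
    initial_threshold_list,
    network_at_threshold,
    refine_threshold_list,
    user_threshold_list,
)
from .topology import (
    NetworkStatsRow,
    Selection,
    SelectionCriteria,
    evaluate_thresholds,
)
from .topology import select_best_threshold as _select
from .vicinity import GoIAnalysis, goi_analysis

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    expression_path: str | None = None
    goi_path: str | None = None
    annotation_path: str | None = None
    measure: str = DEFAULT_MEASURE.name
    thresholds: list[float] | None = None  # user override, at most 5
    refine: bool = False
    goi_mode: Literal["per_gene", "clique_based"] = "clique_based"
    out_dir: str = "coexnet_out"
    seed: int | None = None
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)

    def __post_init__(self) -> None:
        if self.thresholds is not None and not 1 <= len(self.thresholds) <= 5:
            raise ValueError("supply between 1 and 5 user thresholds")
        get_measure(self.measure)

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["criteria"] = dataclasses.asdict(self.criteria)
        d["package_version"] = __version__
        return d


@dataclass
class BuildResult:
    """Everything the model-construction stage produces."""

    config: RunConfig
    expression: ExpressionMatrix
    association: AssociationMatrix
    sorted_list: SortedAssociationList
    thresholds: ThresholdList
    stats: list[NetworkStatsRow]
    selection: Selection
    refined: bool = False

    @property
    def best_network(self) -> UnweightedNetwork | None:
        if self.selection.best is None:
            return None
        return network_at_threshold(
            self.sorted_list, self.selection.best, self.expression.m
        )


def build_network(
    expression: ExpressionMatrix | str | Path,
    config: RunConfig | None = None,
) -> BuildResult:
    """Construct and score all candidate network models; pick the best.

    Accepts an in-memory matrix or a path to a tab-delimited file.  With
    ``config.refine`` set and a winner found, one refinement round re-splits
    the interval around the passing thresholds and re-scores.
    """
    config = config or RunConfig()
    if not isinstance(expression, ExpressionMatrix):
        expression = read_expression_matrix(
            expression, allow_missing=config.measure == "MI"
        )
    measure = get_measure(config.measure)
    A = compute_association_matrix(expression, measure)
    sorted_list = sort_association_pairs(A)
    if config.thresholds is not None:
        thresholds = user_threshold_list(config.thresholds, measure)
    else:
        thresholds = initial_threshold_list(sorted_list, expression.m)
    stats = evaluate_thresholds(sorted_list, thresholds, expression.m)
    selection = _select(stats, config.criteria)
    refined = False
    if config.refine and config.thresholds is None:
        if selection.best is None:
            logger.warning("no model passed the gates; refinement skipped")
        else:
            thresholds = refine_threshold_list(stats, selection)
            stats = evaluate_thresholds(sorted_list, thresholds, expression.m)
            selection = _select(stats, config.criteria)
            refined = True
    if selection.best is None:
        logger.warning("%s", selection.alert)
    else:
        logger.info(
            "best threshold %.3f (alternates: %s)",
            selection.best,
            ", ".join(f"{t:.3f}" for t in selection.alternates) or "none",
        )
    return BuildResult(
        config, expression, A, sorted_list, thresholds, stats, selection, refined
    )


def write_build_outputs(result: BuildResult, out_dir: str | Path) -> dict[str, Path]:
    """Write stats table, per-threshold edge lists, selection record, manifest."""
    out = Path(out_dir)
    (out / "stats").mkdir(parents=True, exist_ok=True)
    (out / "networks").mkdir(exist_ok=True)
    paths: dict[str, Path] = {}
    stats_path = out / "stats" / "NetworkStats.txt"
    write_network_stats(result.stats, stats_path)
    paths["stats"] = stats_path
    for row in result.stats:
        if row.degenerate:
            continue
        net = network_at_threshold(result.sorted_list, row.thresh, result.expression.m)
        p = out / "networks" / f"network_{row.thresh:.3f}.txt"
        write_edge_list(net, p)
        paths[f"network_{row.thresh:.3f}"] = p
    sel = result.selection
    record = {
        "best": sel.best,
        "alternates": sel.alternates,
        "alert": sel.alert,
        "reasons": {f"{t:.3f}": r for t, r in sel.reasons.items()},
        "refined": result.refined,
    }
    sel_path = out / "selection.json"
    sel_path.write_text(json.dumps(record, indent=2) + "\n", encoding="utf-8")
    paths["selection"] = sel_path
    manifest = out / "manifest.json"
    manifest.write_text(
        json.dumps(result.config.to_manifest(), indent=2, default=str) + "\n",
        encoding="utf-8",
    )
    paths["manifest"] = manifest
    return paths


def downstream(
    result: BuildResult,
    gois: GoISet | str | Path,
    annotation: AnnotationMap | str | Path | None = None,
    mode: Literal["per_gene", "clique_based"] | None = None,
    threshold: float | None = None,
) -> GoIAnalysis:
    """Genes-of-interest vicinity analysis on the (best) network model."""
    if not isinstance(gois, GoISet):
        gois = read_gene_list(gois)
    if annotation is not None and not isinstance(annotation, AnnotationMap):
        annotation = read_annotation(annotation)
    tau = threshold if threshold is not None else result.selection.best
    if tau is None and result.config.thresholds and len(result.config.thresholds) == 1:
        # a single user-chosen threshold is analysed even if it failed the
        # topology gates; every model remains accessible to the advanced user
        tau = result.config.thresholds[0]
        logger.warning(
            "threshold %.3f did not pass the selection gates; analysing it "
            "anyway as the user's explicit choice", tau,
        )
    if tau is None:
        raise ValueError(
            "no best threshold is available; run the build stage first or "
            "pass a threshold explicitly"
        )
    net = network_at_threshold(result.sorted_list, tau, result.expression.m)
    return goi_analysis(
        net,
        gois,
        mode=mode or result.config.goi_mode,
        annotation=annotation,
        expression=result.expression,
    )


def write_downstream_outputs(
    result: BuildResult,
    analysis: GoIAnalysis,
    out_dir: str | Path,
    annotation: AnnotationMap | None = None,
) -> dict[str, Path]:
    """Write the VN reports, per-VN expression profiles and the summary."""
    out = Path(out_dir)
    vns_dir = out / "vns"
    vns_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for p in write_vn_report(analysis, annotation, vns_dir):
        paths[p.stem] = p
    for idx, series in analysis.profiles.items():
        p = vns_dir / f"VN{idx}_profiles.txt"
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("gene\t" + "\t".join(result.expression.sample_ids) + "\n")
            for gid in sorted(series):
                fh.write(gid + "\t" + "\t".join(f"{v:.6g}" for v in series[gid]) + "\n")
        paths[p.stem] = p
    summary_path = out / "summary.txt"
    write_summary(
        {
            "n_genes_loaded": result.expression.m,
            "network": result.best_network,
            "analysis": analysis,
        },
        summary_path,
    )
    paths["summary"] = summary_path
    return paths


def full_run(
    expression: ExpressionMatrix | str | Path,
    gois: GoISet | str | Path,
    annotation: AnnotationMap | str | Path | None = None,
    config: RunConfig | None = None,
) -> tuple[BuildResult, GoIAnalysis]:
    """Build models, select the best, and run the GoI analysis on it."""
    result = build_network(expression, config)
    if annotation is not None and not isinstance(annotation, AnnotationMap):
        annotation = read_annotation(annotation)
    analysis = downstream(result, gois, annotation)
    return result, analysis
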