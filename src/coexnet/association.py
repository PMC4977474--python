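"""Pairwise gene-gene association measures and the sorted association list.

Seven measures are supported: Pearson (PE), Spearman (SP, the default) and
Kendall rank correlations; Euclidean, Manhattan and Canberra distances; and
mutual information (MI).  Correlations and MI are similarities (sorted
descending, strongest first); distances sort ascending.  The sorted list of
all m(m-1)/2 values drives threshold selection, so its ordering must be fully
deterministic: ties are broken by the lexicographic gene-id pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Literal

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .io import ExpressionMatrix


@dataclass(frozen=True)
class MeasureSpec:
    """Name, similarity/distance kind and sort direction of a measure."""

    name: str
    kind: Literal["similarity", "distance"]

    @property
    def sort_direction(self) -> str:
        return "descending" if self.kind == "similarity" else "ascending"

    @property
    def is_similarity(self) -> bool:
        return self.kind == "similarity"


MEASURES: dict[str, MeasureSpec] = {
    "PE": MeasureSpec("PE", "similarity"),
    "SP": MeasureSpec("SP", "similarity"),
    "Kendall": MeasureSpec("Kendall", "similarity"),
    "Euclidean": MeasureSpec("Euclidean", "distance"),
    "Manhattan": MeasureSpec("Manhattan", "distance"),
    "Canberra": MeasureSpec("Canberra", "distance"),
    "MI": MeasureSpec("MI", "similarity"),
}

DEFAULT_MEASURE = MEASURES["SP"]


def get_measure(name: str) -> MeasureSpec:
    try:
        return MEASURES[name]
    except KeyError:
        raise ValueError(
            f"unknown measure {name!r}; choose one of {', '.join(MEASURES)}"
        ) from None


@dataclass
class AssociationMatrix:
    """Symmetric m x m matrix of association values; the diagonal is unused."""

    gene_ids: list[str]
    values: np.ndarray
    measure: MeasureSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m = len(self.gene_ids)
        if self.values.shape != (m, m):
            raise ValueError(f"expected a {m}x{m} matrix, got {self.values.shape}")

    @property
    def m(self) -> int:
        return len(self.gene_ids)


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int | None = None) -> float:
    """Mutual information (nats) from an equal-width joint histogram.

    Pairs with a missing value in either vector are dropped; by default the
    histogram uses ceil(sqrt(n_complete)) bins per axis.  MI(x, x) equals the
    entropy of x's binning, and a constant vector carries zero information.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 complete observation pairs, have {n}")
    if bins is None:
        bins = math.ceil(math.sqrt(n))
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    mi = float(np.sum(p[mask] * np.log(p[mask] / (px @ py)[mask])))
    return max(mi, 0.0)  # clip tiny negative round-off


def _check_correlation_rows(X: ExpressionMatrix) -> None:
    sd = np.nanstd(X.values, axis=1)
    bad = [X.gene_ids[i] for i in np.nonzero(sd == 0)[0]]
    if bad:
        raise ValueError(
            "constant expression rows are not admissible under correlation "
            f"measures: {', '.join(bad[:5])}"
        )
    if not np.all(np.isfinite(X.values)):
        raise ValueError("missing values are only supported by the MI measure")


def compute_association_matrix(
    X: ExpressionMatrix, measure: MeasureSpec = DEFAULT_MEASURE, mi_bins: int | None = None
) -> AssociationMatrix:
    """All pairwise associations between the m gene expression vectors."""
    if X.m < 2:
        raise ValueError("need at least 2 genes")
    V = X.values
    name = measure.name
    if name == "PE":
        _check_correlation_rows(X)
        A = np.corrcoef(V)
    elif name == "SP":
        _check_correlation_rows(X)
        # rank-transform rows, then Pearson on ranks == Spearman
        ranks = stats.rankdata(V, axis=1)
        A = np.corrcoef(ranks)
    elif name == "Kendall":
        _check_correlation_rows(X)
        m = X.m
        A = np.eye(m)
        for i in range(m):
            for j in range(i + 1, m):
                tau = stats.kendalltau(V[i], V[j]).statistic
                A[i, j] = A[j, i] = tau
    elif name in ("Euclidean", "Manhattan", "Canberra"):
        if not np.all(np.isfinite(V)):
            raise ValueError("missing values are only supported by the MI measure")
        metric = {"Euclidean": "euclidean", "Manhattan": "cityblock", "Canberra": "canberra"}[name]
        A = squareform(pdist(V, metric=metric))
    elif name == "MI":
        m = X.m
        A = np.zeros((m, m))
        for i in range(m):
            for j in range(i, m):
                mi = mutual_information(V[i], V[j], bins=mi_bins)
                A[i, j] = A[j, i] = mi
    else:  # pragma: no cover
        raise ValueError(f"unknown measure {name!r}")
    A = np.asarray(A, dtype=float)
    if name in ("PE", "SP", "Kendall"):
        A = np.clip(A, -1.0, 1.0)
    return AssociationMatrix(list(X.gene_ids), A, measure)


@dataclass
class SortedAssociationList:
    """All m(m-1)/2 pair associations, strongest to weakest.

    Positions are 1-indexed, matching how candidate thresholds are addressed
    (the value at position m-1 is the most stringent threshold).
    """

    gene_ids: list[str]
    idx_i: np.ndarray
    idx_j: np.ndarray
    values: np.ndarray
    measure: MeasureSpec

    def __len__(self) -> int:
        return self.values.size

    def value_at(self, position: int) -> float:
        """Association value at a 1-indexed position of the sorted list."""
        if not 1 <= position <= len(self):
            raise IndexError(f"position {position} outside 1..{len(self)}")
        return float(self.values[position - 1])

    def pairs(self) -> Iterator[tuple[str, str, float]]:
        for i, j, v in zip(self.idx_i, self.idx_j, self.values):
            yield self.gene_ids[i], self.gene_ids[j], float(v)


def sort_association_pairs(A: AssociationMatrix) -> SortedAssociationList:
    """Order the strict upper triangle of A from strongest to weakest.

    Similarities descend, distances ascend; ties are broken by the
    lexicographic (gene_i, gene_j) pair so the position-indexed thresholds
    are deterministic.
    """
    m = A.m
    iu, ju = np.triu_indices(m, k=1)
    vals = A.values[iu, ju]
    if not np.all(np.isfinite(vals)):
        raise ValueError("association matrix contains non-finite values")
    order = np.argsort(np.array(A.gene_ids))
    rank = np.empty(m, dtype=int)
    rank[order] = np.arange(m)
    # per-pair lexicographic key on gene ids, smaller id first
    lo = np.minimum(rank[iu], rank[ju])
    hi = np.maximum(rank[iu], rank[ju])
    primary = -vals if A.measure.is_similarity else vals
    idx = np.lexsort((hi, lo, primary))
    # orient each stored pair with the lexicographically smaller id first
    i_sorted, j_sorted = iu[idx], ju[idx]
    flip = rank[i_sorted] > rank[j_sorted]
    i_final = np.where(flip, j_sorted, i_sorted)
    j_final = np.where(flip, i_sorted, j_sorted)
    return SortedAssociationList(
        list(A.gene_ids), i_final, j_final, vals[idx], A.measure
    )
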