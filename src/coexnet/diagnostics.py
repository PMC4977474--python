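"""Distribution diagnostics: histogram with normal overlay and a Q-Q plot.

These guide the choice between parametric (Pearson) and non-parametric
(Spearman, distance, MI) association measures.  They are advisory only —
the pipeline never switches measure automatically on their basis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .io import ExpressionMatrix


@dataclass
class DistributionDiagnostic:
    """Machine-readable histogram + Q-Q diagnostic of the pooled data."""

    bin_edges: np.ndarray
    counts: np.ndarray
    mean: float
    sd: float
    curve_x: np.ndarray        # normal overlay evaluated over the data range
    curve_y: np.ndarray
    qq_theoretical: np.ndarray  # standard-normal quantiles at (i-0.5)/N
    qq_sample: np.ndarray       # sorted data values
    n: int

    def max_qq_deviation(self) -> float:
        """Largest |standardised sample quantile - theoretical quantile|.

        Near zero when the data are close to normal; systematic departures
        (e.g. a convex upper tail for right-skewed data) inflate it.
        """
        z = (self.qq_sample - self.mean) / self.sd
        return float(np.max(np.abs(z - self.qq_theoretical)))


def _n_bins(x: np.ndarray) -> int:
    # Freedman-Diaconis; sqrt rule when the IQR degenerates
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    if iqr > 0:
        width = 2 * iqr / x.size ** (1 / 3)
        n = int(np.ceil((x.max() - x.min()) / width))
        if n >= 1:
            return n
    return int(np.ceil(np.sqrt(x.size)))


def distribution_diagnostic(
    X: ExpressionMatrix | np.ndarray,
    image_path: str | Path | None = None,
    image_format: str = "tiff",
) -> DistributionDiagnostic:
    """Pool all finite expression values; bin them, overlay the moment-fitted
    normal curve over the data range, and compute normal Q-Q points at
    plotting positions (i - 0.5)/N.

    When ``image_path`` is given, a two-panel figure (histogram + Q-Q) is
    rendered there; the machine-readable diagnostic is always returned.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    x = values[np.isfinite(values)].ravel()
    if x.size < 10:
        raise ValueError(f"need at least 10 finite values, have {x.size}")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("zero variance, Q-Q undefined")
    mean = float(np.mean(x))
    counts, edges = np.histogram(x, bins=_n_bins(x))
    curve_x = np.linspace(x.min(), x.max(), 200)
    curve_y = stats.norm.pdf(curve_x, loc=mean, scale=sd)
    xs = np.sort(x)
    pp = (np.arange(1, x.size + 1) - 0.5) / x.size
    qq_theoretical = stats.norm.ppf(pp)
    diag = DistributionDiagnostic(
        bin_edges=edges, counts=counts, mean=mean, sd=sd,
        curve_x=curve_x, curve_y=curve_y,
        qq_theoretical=qq_theoretical, qq_sample=xs, n=x.size,
    )
    if image_path is not None:
        _render(diag, Path(image_path), image_format)
    return diag


def _render(diag: DistributionDiagnostic, path: Path, fmt: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4.5))
    widths = np.diff(diag.bin_edges)
    ax1.bar(diag.bin_edges[:-1], diag.counts / (diag.n * widths),
            width=widths, align="edge", color="#9ecae1", edgecolor="white")
    ax1.plot(diag.curve_x, diag.curve_y, color="#de2d26", lw=2)
    ax1.set_xlabel("expression value")
    ax1.set_ylabel("density")
    ax1.set_title("Histogram with normal overlay")
    z = (diag.qq_sample - diag.mean) / diag.sd
    ax2.plot(diag.qq_theoretical, z, ".", ms=3, color="#3182bd")
    lim = [diag.qq_theoretical.min(), diag.qq_theoretical.max()]
    ax2.plot(lim, lim, color="#de2d26", lw=1.5)
    ax2.set_xlabel("theoretical normal quantile")
    ax2.set_ylabel("standardised sample quantile")
    ax2.set_title("Normal Q-Q plot")
    fig.tight_layout()
    if path.suffix == "":
        path = path.with_suffix("." + fmt)
    fig.savefig(path, format=path.suffix.lstrip("."), dpi=150)
    plt.close(fig)


def write_diagnostic_tsvs(diag: DistributionDiagnostic, out_dir: str | Path) -> list[Path]:
    """Write histogram and Q-Q point tables as TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hist = out / "histogram.txt"
    with open(hist, "w", encoding="utf-8") as fh:
        fh.write("binStart\tbinEnd\tcount\n")
        for lo, hi, c in zip(diag.bin_edges[:-1], diag.bin_edges[1:], diag.counts):
            fh.write(f"{lo:.6g}\t{hi:.6g}\t{int(c)}\n")
    qq = out / "qq.txt"
    with open(qq, "w", encoding="utf-8") as fh:
        fh.write("theoreticalQuantile\tsampleQuantile\n")
        for t, s in zip(diag.qq_theoretical, diag.qq_sample):
            fh.write(f"{t:.6g}\t{s:.6g}\n")
    return [hist, qq]
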