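"""Synthetic expression data and reference graphs with known ground truth.

The modular generator emulates the premise of co-expression analysis: genes
in the same regulatory module share an expression trajectory across samples.
Each module has a latent profile (a Gaussian random walk across samples, so
distinct modules are uncorrelated by construction) and module genes observe
it plus independent Gaussian noise; background genes are pure independent
noise.  An optional negative-binomial transform produces RNA-seq-like counts
(mean exp(profile), fixed dispersion).

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io import ExpressionMatrix
from .topology import DegreeDistribution


@dataclass
class ModularDatasetTruth:
    """Ground truth for a generated dataset."""

    modules: dict[str, list[str]]       # module id -> gene ids
    assignments: dict[str, str]         # gene id -> module id or "background"
    profiles: dict[str, np.ndarray]     # module id -> latent profile
    noise_sd: float
    seed: int


def generate_modular_dataset(
    n_modules: int = 2,
    module_size: int = 20,
    n_background: int = 360,
    n_samples: int = 8,
    noise_sd: float = 0.2,
    seed: int = 0,
    negative_binomial: bool = False,
    nb_dispersion: float = 10.0,
) -> tuple[ExpressionMatrix, ModularDatasetTruth]:
    """Planted-module expression matrix plus its ground truth.

    Module genes are ``M{k}_g{i}``, background genes ``BG_g{i}``.  With
    noise_sd = 0 all genes of a module share the identical profile, so every
    within-module Spearman correlation is exactly 1.
    """
    if min(n_modules, module_size, n_samples) < 1 or n_background < 0:
        raise ValueError("all counts must be >= 1 (background may be 0)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    modules: dict[str, list[str]] = {}
    assignments: dict[str, str] = {}
    profiles: dict[str, np.ndarray] = {}
    for k in range(1, n_modules + 1):
        mod = f"M{k}"
        profile = np.cumsum(rng.normal(0.0, 1.0, size=n_samples))
        profiles[mod] = profile
        modules[mod] = []
        for i in range(1, module_size + 1):
            gid = f"{mod}_g{i}"
            gene_ids.append(gid)
            rows.append(profile + rng.normal(0.0, noise_sd, size=n_samples))
            modules[mod].append(gid)
            assignments[gid] = mod
    for i in range(1, n_background + 1):
        gid = f"BG_g{i}"
        gene_ids.append(gid)
        rows.append(rng.normal(0.0, 1.0, size=n_samples))
        assignments[gid] = "background"
    values = np.array(rows)
    if negative_binomial:
        mu = np.exp(values - values.max() + 5.0)  # keep counts in a sane range
        p = nb_dispersion / (nb_dispersion + mu)
        values = rng.negative_binomial(nb_dispersion, p).astype(float)
    X = ExpressionMatrix(gene_ids, [f"s{j}" for j in range(1, n_samples + 1)], values)
    truth = ModularDatasetTruth(modules, assignments, profiles, noise_sd, seed)
    return X, truth


def generate_powerlaw_degree_sample(
    a: float, k_max: int, n_draws: int, seed: int = 0
) -> DegreeDistribution:
    """Multinomial degree sample from p_k proportional to k^-a on 1..k_max."""
    if a <= 0:
        raise ValueError("exponent a must be positive")
    if k_max < 3:
        raise ValueError("k_max must be >= 3")
    ks = np.arange(1, k_max + 1)
    p = ks.astype(float) ** -a
    p /= p.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_draws, p)
    return DegreeDistribution({int(k): int(c) for k, c in zip(ks, counts) if c > 0})


def generate_reference_graph(kind: str, seed: int = 0, **params) -> nx.Graph:
    """Reference graphs with documented constructions.

    kinds:
      ring_rewire — ring lattice with rewiring probability p (small-world
                    construction); params n, k, p
      er          — Erdos-Renyi with given size and mean degree; params n, k_mean
      ba          — preferential attachment (scale-free); params n, m
    """
    if kind == "ring_rewire":
        n = params.get("n", 500)
        k = params.get("k", 6)
        p = params.get("p", 0.05)
        return nx.watts_strogatz_graph(n, k, p, seed=seed)
    if kind == "er":
        n = params.get("n", 500)
        k_mean = params.get("k_mean", 6)
        n_edges = round(n * k_mean / 2)
        return nx.gnm_random_graph(n, n_edges, seed=seed)
    if kind == "ba":
        n = params.get("n", 500)
        m = params.get("m", 3)
        return nx.barabasi_albert_graph(n, m, seed=seed)
    raise ValueError(f"unknown reference graph kind {kind!r}")


def write_expression_tsv(X: ExpressionMatrix, path) -> None:
    """Write a generated matrix in the tab-delimited input format."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(X.sample_ids) + "\n")
        for gid, row in zip(X.gene_ids, X.values):
            fh.write(gid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
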