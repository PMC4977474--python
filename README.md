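# coexnet

Automated, parameter-free construction of **unweighted gene co-expression
networks** that are explicitly verified to be scale-free and small-world,
followed by genes-of-interest vicinity-network and clique analysis.

`coexnet` is for life scientists with an m-gene × n-sample expression matrix
(microarray intensities or normalised RNA-seq counts) who want a co-expression
network whose hard threshold is chosen objectively instead of by convention.
Rather than asking the user for a correlation cutoff, it reads candidate
thresholds off the sorted list of all m(m−1)/2 pairwise associations, scores
the network model each candidate produces, and selects the model that is
scale-free, well connected, and retains the most genes.

## The method in brief

1. **Association** — all pairwise gene associations under Spearman (default),
   Pearson, Kendall, Euclidean/Manhattan/Canberra distance, or mutual
   information; a histogram/Q-Q diagnostic helps choose between parametric
   and non-parametric measures.
2. **Thresholding** — the signum adjacency function binarises associations at
   threshold τ (edge iff α_ij ≥ τ; reversed for distances).  Candidates span
   t_first (value at sorted position m−1) to t_last (position 150·m), split
   into six equal steps: seven models.
3. **Topology gates** — per model: OLS on the log-log degree distribution
   (scale-free: R² ≥ 0.80 and exponent a = −slope ∈ (1,3)), mean clustering
   coefficient and mean path length (small-world advisory vs. the random
   baselines k̄/(|V|−1) and ln|V|/ln k̄), %used (genes retained) and %bigComp
   (largest-component share, gate at 95 %).  Among passers the model with
   maximal %used wins; an optional refinement round narrows the interval.
4. **Vicinity networks** — genes of interest are expanded to their direct
   neighbourhoods (single gene + neighbours, or maximal clique + common
   neighbours), each reported with membership, GoI count and density;
   densities just below 1 flag *fuzzy cliques*.

See `docs/methods.md` for the full model description and numerical choices.

## Worked example

The selection stage can be driven directly from a published network-statistics
table.  Feeding the seven rows of the worked beetle-transcriptome analysis
(threshold, R², slope, meanCC, meanPath, %used, %bigComp) into the selector:

```python
from coexnet.topology import NetworkStatsRow, select_best_threshold

rows = [NetworkStatsRow(*r) for r in [
    (0.956, 0.84, -1.71, 0.44,  6.89, 21,  22),
    (0.919, 0.90, -1.62, 0.37, 11.13, 50,  85),
    (0.882, 0.89, -1.45, 0.38,  7.19, 72,  94),
    (0.845, 0.86, -1.24, 0.40,  5.66, 86,  97),
    (0.808, 0.82, -1.05, 0.42,  4.71, 94,  99),
    (0.771, 0.77, -0.93, 0.44,  4.04, 98, 100),
    (0.734, 0.71, -0.85, 0.47,  3.55, 99, 100),
]]
sel = select_best_threshold(rows)
print(sel.best, sel.alternates)
```

```
0.808 [0.845]
```

0.808 wins: the three most stringent models are excluded because their
largest component holds < 95 % of vertices, the two weakest for low R²
(0.77, 0.71), and of the two admissible models 0.808 retains more genes
(94 % vs 86 %), leaving 0.845 as the alternate.

End-to-end on synthetic data (`examples/02_goi_vicinity.py`): two planted
20-gene modules among 360 background genes are analysed as genes of interest
and re-emerge as the top vicinity networks —

```
VN	VNsize	numGoI	density	fuzzyClique
1	21	20	1.00	False
2	18	18	1.00	False
...
M1: best-matching VN1 (size 21, density 1.0000, Jaccard 0.95)
M2: best-matching VN2 (size 18, density 1.0000, Jaccard 0.90)
```

Each VN row gives the vicinity-network size, how many supplied genes of
interest it contains, and its density (1.00 = a clique).

## Library, examples, CLI

The importable API is the primary surface (`coexnet.pipeline.build_network`,
`downstream`, `full_run`, plus the per-stage modules `association`,
`thresholding`, `topology`, `vicinity`, `diagnostics`, `simulate`).  Short
narrative scripts live in `examples/`, one per capability:

| script | shows |
|---|---|
| `01_build_network.py` | candidate thresholds and the topology stats table |
| `02_goi_vicinity.py`  | genes-of-interest vicinity networks and densities |
| `03_distribution_check.py` | the histogram/Q-Q measure-choice diagnostic |
| `04_simulate_data.py` | the planted-module synthetic data generator |

A thin CLI wraps the same calls for shell use:

```sh
coexnet simulate --seed 3 --out expr.txt
coexnet build expr.txt --out run/            # models + stats + best threshold
coexnet run expr.txt --goi goi.txt --out run/  # + vicinity networks & summary
coexnet distcheck expr.txt --out run/
```

Outputs are plain tab-delimited text: the edge list loads directly into
Cytoscape or Pajek, and the stats table, VN reports and summary are ordinary
TSVs.

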