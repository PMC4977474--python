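# Methods

## The model

`coexnet` builds unweighted gene co-expression networks from an m-gene ×
n-sample expression matrix and verifies, rather than assumes, that the chosen
model has the two architectural signatures of real biological networks:

- **scale-free** — the degree distribution follows a power law
  p_k = C·k^(−a), diagnosed by ordinary least squares on the log-transformed
  empirical distribution, log p_k = −a·log k + c, recording the coefficient
  of determination R² and the exponent a = −slope;
- **small-world** — mean local clustering well above, and mean shortest-path
  length comparable to, an Erdős–Rényi graph of matched size and mean degree.

Association between two genes is computed over their n-dimensional expression
vectors by one of seven measures: Pearson (PE), Spearman (SP, the default,
because high-throughput expression data are rarely normal), Kendall's tau-b,
Euclidean, Manhattan or Canberra distance, or mutual information (MI).
Correlations and MI are similarities (strong = large), distances are
dissimilarities (strong = small); everything downstream respects the sort
direction.

Edges are defined by the signum adjacency function at threshold τ: for a
similarity measure, genes i and j are connected iff α_ij ≥ τ (≤ τ for
distances).  Vertices left without any edge are removed from the model, and
the fraction retained from the original dataset is reported as %used.

## Threshold candidates and selection

All m(m−1)/2 pairwise associations are sorted strongest→weakest.  Two
positional anchors give the candidate interval:

- t_first = value at 1-indexed position m−1 — the minimum number of edges an
  m-vertex network needs to be connected, hence the most stringent defensible
  threshold;
- t_last = value at position min(150·m, m(m−1)/2) — denser models are
  empirically never power-law and are disproportionately expensive to score.
  For m < 301 the 150·m position exceeds the list length and clamps to the
  weakest association.

The interval is split into six equal subintervals (Δt = (t_first − t_last)/6),
yielding seven equally spaced candidates.  Each candidate network is scored
(R², slope, meanCC, meanPath, %used, %bigComp, component count) and the
'best' model is chosen by gates applied in order:

1. the largest component holds ≥ 95 % of the network's vertices — below
   this, the remaining statistics are skewed by fragmentation and the model
   is excluded from consideration outright;
2. R² ≥ 0.80 for the log-log degree-distribution regression;
3. a = −slope strictly inside (1, 3);
4. among survivors, maximal %used; ties go to the more stringent threshold.

The R² cutoff of 0.80 deserves a note: the worked selection that this package
reproduces accepts models with R² of 0.82–0.90 and rejects 0.77 and 0.71
explicitly for "low coefficient of determination" without printing a cutoff;
0.80 is the midpoint consistent with those decisions and is configurable
(`SelectionCriteria.r2_min`).  The small-world check is advisory by default
(the worked selection is fully determined by the four quantities above); the
flag requires meanCC ≥ 5× and meanPath ≤ 2× the random baselines
CC_rand = k̄/(|V|−1), L_rand = ln|V|/ln k̄, and `--strict-small-world`
promotes it to a fifth gate.

When no candidate passes, the user is alerted and every model (stats row,
edge list, rejection reasons) remains accessible; a single user-supplied
threshold is analysed downstream even when it fails the gates, as the
explicit choice of an advanced user.

An optional single refinement round narrows the interval: if several
thresholds passed, the most and least stringent passers become the new
endpoints; if only the winner passed, its immediate list neighbours do
(clamped at the ends).  The new interval is re-split into six subintervals
and re-scored.  Exactly one round is performed — the procedure is not
recursive.

## Vicinity networks and cliques

Genes of interest (GoIs) are explored through vicinity networks (VNs): for a
single gene, the gene plus all direct neighbours; for a clique of s genes,
the clique plus the common neighbours of all s members.  In clique-based
mode (default) the GoI-induced subgraph's maximal cliques are enumerated
(pivoting Bron–Kerbosch; the GoI subgraph is small, so exact enumeration is
cheap) and each clique is expanded; GoIs isolated within the GoI subgraph
fall back to their single-gene VN.  Per-gene mode emits one VN per gene and
warns for lists longer than 20.

Every VN reports its density (present / possible edges).  A VN with density
in [0.85, 1) is labelled a fuzzy clique — the cutoff follows the worked
analysis, which calls densities 0.86–0.93 fuzzy cliques and 0.52–0.68 not;
it is configurable and the density itself is always reported.

## Numerical choices

- Sorted-list ties are broken by the lexicographic gene-id pair; the
  positional anchors (m−1, 150·m) make a deterministic order mandatory.
- Equal association values at a threshold all qualify together (the edge rule
  is value-based, not position-based), so edge counts can exceed the anchor
  position when ties straddle it.
- Constant gene rows are an error under correlation measures rather than a
  NaN source: silent NaNs would corrupt the position-indexed threshold list.
- The log-log regression uses natural logs (slope and R² are base-invariant)
  and only degrees with nonzero observed frequency (log 0 undefined); fewer
  than three support points mark the fit unreliable and auto-fail the
  scale-free gate.  No log-binning and no maximum-likelihood fitting — the
  regression-on-frequencies recipe is itself part of the method.
- Local clustering of degree ≤ 1 vertices is 0 and they stay in the mean
  (meanCC averages over all vertices).  Mean path length averages over
  unordered same-component pairs only.
- MI uses an equal-width joint histogram with ⌈√n⌉ bins per axis, natural
  log, raw (unnormalised); pairs with a missing value are dropped.  MI is
  the only measure that accepts missing data.
- Display precision follows the published tables: thresholds 3 d.p.,
  topology statistics 2 d.p., VN-table densities 2 d.p., standalone density
  values 4 d.p.  All internal computation is full precision.
- Clustering uses a dense-adjacency triangle count and path lengths a
  compiled BFS for networks up to 3000 vertices, falling back to iterative
  per-component traversal above; both routes are checked against brute-force
  oracles in the test suite.

## Synthetic data

`coexnet.simulate.generate_modular_dataset` emulates the core premise of
co-expression analysis: genes in a regulatory module share an expression
trajectory.  Each module draws one latent random-walk profile across the
samples (random walks rather than sinusoids, so distinct modules are
uncorrelated by construction); module genes observe it plus independent
Gaussian noise (sd 0.2 by default against unit-sd walk steps), and
background genes are independent noise.  Defaults are 2 modules × 20 genes +
360 background genes over 8 samples.  An optional negative-binomial
transform (mean e^profile, dispersion 10) produces RNA-seq-like counts.
All generators are pure functions of (parameters, seed).

What the generator does *not* emulate: batch effects, library-size
artefacts, overlapping modules, hub regulators, or the long-range correlation
structure of real transcriptomes.  The last point matters for interpreting
the tests: real whole-omics matrices (~10⁴ genes) yield heavy-tailed
association structure whose thresholded networks can genuinely be
scale-free, whereas a 400-gene planted-blocks matrix over 8 samples produces
Poisson-like background graphs at every connectivity level, and no threshold
of such a matrix passes the default R² ≥ 0.80 gate while keeping 95 % of
vertices in one component.  The automatic selection therefore (correctly)
alerts rather than picks a model on these fixtures; module recovery is
demonstrated at an explicitly supplied stringent threshold, where both
planted modules re-emerge as density ~1 vicinity networks with truth overlap
(Jaccard) ≥ 0.9.  Passing tests on this generator show the machinery is
correct, not that any particular real dataset will yield a passing model.

Problem sizes used in the test and acceptance suites (chosen to keep the
whole suite a few seconds of compute): planted datasets of 68–400 genes ×
8 samples; oracle batteries of 100 random graphs up to 60 vertices (cliques
to 12 vertices, where power-set enumeration is exact); power-law recovery
from 10⁵ multinomial draws; small-world reference graphs of 500 vertices.

## Known limitations

- Kendall and MI association matrices are computed pairwise in Python
  (O(m²) calls) and are practical to a few thousand genes; PE/SP/distances
  are fully vectorised.
- The power-law fit inherits the known biases of OLS on empirical log-log
  frequencies; this is deliberate fidelity to the method, not a statistical
  recommendation (a Clauset-style ML fit is out of scope).
- Whole-network maximal-clique enumeration is intentionally not exposed;
  enumeration happens only inside GoI subgraphs and vicinity networks, where
  it is provably loss-free for GoI-anchored cliques.
- VN expression-profile output is emitted as data series (TSV); rendered
  profile images are a convenience, not a stable contract.
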