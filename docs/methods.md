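# Methods

`pvatgrn` re-implements, as a tested pipeline, a differential
gene-regulatory-network (GRN) analysis of brown adipocytes from rat
perivascular adipose tissue (PVAT) under control vs high-fat (HF) diet:
condition-specific network inference, centrality-ratio rank-sum
prioritization of transcription factors (TFs), and in-silico TF knockout with
an inner-product perturbation score, together with the supporting
quality-control and cell-type-composition stages. This note describes the
models, the parameters that matter, what the synthetic-data generator does
and does not emulate, and the numerical choices made where the design was
open.

## Condition-specific GRN inference

For each diet condition, every target gene's normalized expression is
regressed on its candidate regulators — candidates come from a base-GRN
prior (promoter/motif-derived TF→target edge list) — with an L2 (ridge)
penalty, over `n_bags` bootstrap resamples of cells. The edge coefficient is
the bag mean. An edge is retained when three screens agree:

1. **sign consistency** ≥ 0.9: the dominant coefficient sign appears in at
   least 90% of bags;
2. **magnitude**: |mean coefficient| ≥ 0.05 on normalized log1p expression;
3. **significance**: the full-data coefficient t-test (ridge sandwich
   covariance, df = n − k − 1) gives p ≤ 0.05.

The third screen exists because bootstrap bags concentrate around the
full-sample estimate, so sign consistency alone does not control false
positives: on label-permuted null data it passes roughly a fifth of
candidate edges, while with the t-test screen the retained fraction stays at
the nominal 5% (verified by a permutation-null test). A pure p-value rule
(`keep_rule="pvalue"`) is available as an alternative.

Defaults: `n_bags=20`, `ridge_penalty=1.0`, `keep_threshold=0.05`,
`sign_consistency_min=0.9`, minimum 20 cells per condition. Normalization is
library-size scaling to a common target sum followed by log1p. The pipeline
sets the target sum to `2 × n_genes` rather than the genome-wide customary
10,000: what matters is that per-gene normalized values land in the 0–5
range where log1p is informative; a 10,000-count target on a ~200-gene panel
would push values into deep logarithmic saturation, a regime no real dataset
occupies.

## Centrality measures and TF prioritization

Three node-importance measures are computed on each condition's fitted
directed network (all genes as nodes):

- **eigenvector centrality** — principal eigenvector of the symmetrized
  absolute-weight adjacency, by power iteration, normalized to unit
  Euclidean norm. Directed GRNs are rarely strongly connected, where the
  directed variant is ill-defined; symmetrization guarantees a real
  non-negative dominant eigenpair (an in-edge directed mode exists for
  comparison). Near-bipartite regulator→target graphs have almost symmetric
  spectra (λ_min ≈ −λ_max), which stalls plain power iteration; a positive
  diagonal shift — scale-invariant, eigenvector-preserving — breaks the tie.
  Tolerance 1e-10, max 1000 iterations, explicit convergence error.
- **degree-centrality-out** — distinct out-neighbors / (n − 1), unweighted.
- **betweenness centrality** — fraction of directed unweighted shortest
  paths through each node, normalized by (n − 1)(n − 2) (Brandes algorithm
  via networkx; tests verify it against brute-force path enumeration on all
  graphs up to 8 nodes).

For every TF with retained out-edges in **both** conditions, each measure's
HF/control ratio is formed as (hf + ε)/(control + ε) with ε = 1e-9
stabilizing zero centralities. Per measure, TFs are ranked by descending
ratio — the largest ratio gets rank 0 — with deterministic tie-breaking
(descending value, then lexicographic TF identifier). The **total score** is
the sum of the three ranks; the TFs with the smallest totals (ties broken by
eigenvector rank, then identifier) are selected for knockout. Four published
20-TF rank tables (females/males × 8/24 weeks on diet) are bundled as worked
examples; recomputing every total from its printed per-measure ranks
reproduces all 80 rows exactly, and top-3 selection on the 24-week female
table returns Nr4a1, Epas1, Nr4a2.

## In-silico knockout and perturbation score

Knocking out TF *g*: its (normalized) expression is set to 0 in every cell
and held there; for `n_steps = 3` iterations, each gene's simulated value is
its original value plus the coefficient-weighted sum of its regulators'
current deltas, clipped at 0 (expression cannot go negative). The shift
matrix is final − original; the knocked-out column equals minus its original
expression.

Two per-cell 2-D vector fields over the embedding are compared:

- **developmental field**: v_i = (1/k) Σ_j (t_j − t_i)(e_j − e_i) over the
  k = 30 nearest embedding neighbors — the local pseudotime gradient. (The
  study derived its developmental vectors from an RNA-velocity dynamical
  model, which is out of scope here; the pseudotime gradient is the
  substituted construction, and the sign/geometry properties the analysis
  relies on are what the tests target.)
- **knockout field**: transition probabilities to neighbors are
  exp(r_ij / kernel_scale) normalized over neighbors, where r_ij is the
  Pearson correlation between cell i's shift vector and the expression
  offset x_j − x_i; the vector is Σ_j p_ij (e_j − e_i) minus the uniform
  baseline (1/k) Σ_j (e_j − e_i), so a no-preference cell maps to zero. The
  knocked-out gene's own (imposed) delta is excluded from the correlation,
  which makes a TF with no retained out-edges yield an exactly zero field.
  Cells with zero-variance shifts get zero vectors.

Knockout simulation and projection run on kNN-smoothed expression (mean over
the k = 100 nearest embedding neighbors plus self — first-moment imputation,
as velocity and perturbation tools use), which suppresses per-cell count
noise while preserving the expression gradient along the trajectory. GRN
fitting deliberately uses unsmoothed expression: in the synthetic data the
identifying TF variation is per-cell and orthogonal to the embedding, so
smoothing would destroy the regression signal.

The **perturbation score** is the per-cell inner product of the two fields
(raw vectors by default; a unit-normalized mode exists). Positive scores mark
cells whose knockout vector aligns with the developmental flow (states
stabilized); negative scores mark opposition (states resisted). Scores are
summarized over 10 equal-width bins of the observed pseudotime range
(half-open bins, last closed): count, mean, quartiles per bin.

## Quality control

Filters run in a fixed order, each on the survivors of the previous step:
doublet score ≥ 0.5 → genes in ≤ 3 cells → cells with < 100 transcripts →
cells with > 15,000 reads or > 4,500 detected genes → cells outside 5 median
absolute deviations of the median of log1p(total counts) or log1p(genes
detected). The MAD is unscaled (no 1.4826 factor), matching the
best-practices convention the thresholds come from; a scaled mode is
available. The relative order of the MAD rule and the fixed thresholds is
not dictated by the source workflow; the implementation applies the fixed
thresholds first and documents the order, and every step's removals are
reported. An optional mitochondrial-fraction cutoff exists but is off by
default (the synthetic data has no mitochondrial annotation). Thresholds of
0 / ∞ disable their steps; an empty result is flagged, not raised.

## Cell-type composition testing

Per-sample proportions are cell counts of a type divided by the sample's
total. Group comparisons use the two-tailed Welch t-test on per-sample
proportions (unequal variances, Welch–Satterthwaite df); both-variances-zero
cases are flagged degenerate (t = 0, p = 1 on equal means; ±∞, p = 0
otherwise) rather than returning NaN. Effect sizes are log2 fold changes of
group-mean proportions against the 8-week control-diet male reference group,
with a configurable pseudocount (default 1e-4) guarding zero proportions.
Raw p-values are reported by default, mirroring the source analysis;
Benjamini–Hochberg adjustment is optional.

## Synthetic data generator

The generator plants a known two-condition network so every downstream claim
is testable without external data.

**Network.** `n_tfs` regulators and `n_targets` targets; candidate edges
drawn Bernoulli(`density` = 0.3) over regulator × gene pairs, with TF→TF
edges restricted to a DAG (lower → higher index) and no self-loops. TF→TF
edges exist so that directed paths longer than one step exist — betweenness
centrality is degenerate on a purely bipartite TF→target graph. Weight
magnitudes are log-normal (median 0.25, log-sd 1.0): regulatory effect sizes
are heavy-tailed, with many weak edges near the detection limit and a few
strong ones. Signs are +1 with probability 0.8 (promoter-prior networks are
activation-biased). A driver TF's outgoing row in the HF matrix is the
control row times `effect_size`; all other rows are identical between
conditions.

**Cells.** Pseudotime t ~ U[0,1]; condition = control below 0.5, high-fat
above (a `step` mode switches the active weights abruptly instead of
interpolating, emulating a settled late time point). TF latent expression is
a Gamma basal draw (mean = the TF's intercept) plus centered contributions
from upstream TFs — centering keeps TF levels at their basal scale instead
of compounding means down the cascade. Target latent mean is intercept +
W(t)-weighted TF sum, clipped at 0, with W(t) the linear interpolation of
the two condition matrices. 150 unregulated background genes pad the panel;
without them the fixed per-cell library makes every network gene's
normalized value co-move with the driver (a compositional confound real
transcriptomes, where one TF's targets are a tiny library fraction, do not
have). Latent means are scaled to a library of 250 counts — about one count
per gene per cell, the per-gene depth of typical single-nucleus data — and
counts are negative-binomial with dispersion 0.3 (variance m + 0.3 m²). The
embedding is (t, Gaussian noise).

**Composition.** A separate generator draws per-sample cell-type labels from
group-specific multinomials over a factorial sex × diet × time design
(default: 3 samples/group, tissue-realistic proportions dominated by
adipocytes, with the high-fat profile shifted modestly from endothelial
toward adipocyte/immune mass).

**What the generator does not emulate** — ambient RNA, doublets beyond a
doublet-score column, batch effects, cell-type-specific networks, condition
effects other than amplitude scaling of driver rows, and any real embedding
geometry. Passing tests therefore demonstrate the machinery is correct and
that the prioritization detects amplitude-driven rewiring under controlled
noise; they do not certify performance on real tissue.

## Known limitations

Under the planted model, a driver's effect is *pure amplitude scaling* with
an identical sparsity pattern, and the base prior equals the true pattern.
In that regime the retained edge topology is nearly the same in both
conditions, so the two unweighted measures (degree-out, betweenness) carry
ratios of ~1 ± noise for every TF; only the weighted eigenvector ratio
responds reliably (the planted driver's eigenvector rank is 0–2 in ~90% of
runs). Summing one informative rank with two noisy ones caps top-3 driver
recovery near 55–65% at the default conditions (10 TFs, effect size 3,
2000 cells); raising the effect size does not change this, because log-scale
fitting compresses amplitude gains. The knockout-reversal readout is far
more robust: the driver's knockout yields a negative mean perturbation score
in the high-fat pseudotime region in ≥ 95% of runs. Both rates are
recomputed by `scripts/acceptance.py`.

Problem sizes throughout (10 TFs, 40 targets, 150 background genes, 2000
cells, 20 replicate seeds) are chosen so the full suite and the acceptance
script run in minutes on a laptop while keeping every statistical readout
stable; they are the package's desk-scale study conditions, not estimates of
the study's real dimensions.
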