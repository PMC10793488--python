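# Methods

This note records the models behind each stage, the defaults and why, and
what the synthetic generators do and do not emulate.

## Expression preprocessing and paired differential expression

Counts-per-million are computed per sample on raw library sizes (no TMM or
other normalization factors) and log-transformed as `log2(CPM + c)` with
pseudocount `c = 1` by default; both are configurable. The low-expression
filter keeps a gene only if its CPM exceeds 1 in strictly more than 3
samples (i.e. in at least 4); CPM for the filter is always computed on the
unfiltered library sizes, which makes the filter idempotent.

The paired test is intentionally simple: per-gene within-subject
differences of log2CPM (case minus control), a two-sided paired t-test on
those differences, and Benjamini-Hochberg FDR across genes (via
`statsmodels`). It is a stand-in for a count-model GLM — adequate here
because every downstream stage consumes only `(log2FC, FDR)` pairs, and
externally computed tables can be loaded in their place
(`expression.load_de_table`). Degenerate genes (zero variance of
differences) get p = 1 when the mean difference is 0, and the smallest
positive float plus a `degenerate` flag otherwise. On null simulations the
test holds its level (empirically 0.049 at nominal 0.05; asserted at
0.05 ± 0.02 over 20 replicates of 2000 genes in the suite).

## Attenuation statistic and resampling null

The ratio of log2 fold changes `fc_yes / fc_no` is defined for genes whose
two fold changes share a sign and whose denominator is nonzero. Ratios in
(0, 1) are "attenuated", above 1 "potentiated", exactly 1 "neutral" (the
boundary is deliberately assigned to neither class; strict inequalities
match the "between 0 and 1" reading), and `fc_yes · fc_no ≤ 0` is
"discordant" with an undefined ratio.

The null distribution draws `n_draw` genes **without replacement** (the
with-replacement variant is an option) from all same-direction analyzed
genes — discordant-direction genes are excluded from the universe before
sampling — and counts ratios strictly inside (0, 1). Sampling is
vectorized (random keys, top-k per iteration) and chunked to bound memory;
the defaults are 100,000 iterations at a draw size equal to the observed
shared-DEG count. The empirical p uses the add-one convention
`(1 + #{null ≥ observed}) / (n_iter + 1)` so it is never zero. Because the
count statistic is lattice-valued, its empirical p is only approximately
uniform under the null; the calibration test uses a draw size large enough
(400 of 4000) that the largest point mass is small compared to the KS
acceptance band.

The equivalent change index is implemented as
`sign(a·b) · min(|a|,|b|) / max(|a|,|b|)` (zero if either input is zero,
undefined when both are): symmetric, bounded by 1 in absolute value, 1
exactly for equal nonzero changes. Published ECI values could not be used
to pin the formula down, so the definition is kept swappable.

## Preranked gene-set enrichment

The enrichment score is the classic weighted KS running sum: hit steps
`|score|^p / Σ_hits |score|^p` (default weight `p = 1`; 0 and 2
supported), miss steps `1/(N − N_hit)`; the ES is the running-sum value at
the position of maximal absolute deviation, and the leading edge is the
in-set genes at or before the peak (after it, for negative ES). Score ties
are broken by lexicographic gene id so rankings serialize stably. If every
in-set hit carries score exactly 0 at positive weight, the hit steps fall
back to unweighted (the weighted statistic is undefined there).

The only null available for preranked input permutes which genes carry the
set labels — equivalently, a same-size random placement of the set; this
is vectorized over permutations. NES divides the observed ES by the mean
|null ES| of matching sign; p-values use the matching-sign null tail
(add-one convention); FDR follows the pooled-NES procedure of the original
GSEA method, capped at 1. Selection thresholds (NES ≥ 2.5, FDR ≤ 0.05)
are inclusive, and results sitting exactly on a threshold carry a
`boundary` flag so the exclusive reading can be audited. Monte-Carlo
p-values are checked against exhaustive enumeration of all set placements
on small rankings in the test suite.

## Consensus metagene, scoring, pooling

Within each exposure group, the majority leading edge keeps genes present
in at least `threshold × n_sets` of the enriched sets' leading edges
(default threshold 0.5, so "≥ 50% of 6 sets" means ≥ 3; a strict-majority
option exists). The consensus signature is the intersection of the two
groups' majority sets, with provenance (source sets, thresholds) stored so
it can be regenerated. Scores are plain unweighted means of log2CPM over
the signature genes present in a matrix; missing genes are dropped with a
warning by default because external cohorts rarely cover every symbol.

Group comparisons use the Wilcoxon rank-sum test (signed-rank when a
complete pairing is supplied). Meta-analytic pooling weights per-study
mean differences by inverse variance (`sd1²/n1 + sd2²/n2`); the
random-effects model adds a DerSimonian-Laird tau² and is the default —
both models are available because either may be the right choice depending
on heterogeneity — and the implementation is cross-checked against
`statsmodels.stats.meta_analysis.combine_effects` in the tests. The 95% CI
is `effect ± 1.96·SE`.

Per-cell module scores subtract an expression-matched background by
default: genes are binned by average expression (24 equal-occupancy bins),
and `n_ctrl = 100` control genes per module gene are sampled from the
module gene's bin; `n_ctrl = 0` gives the plain set mean. Both modes are
provided because the background-matched and plain-mean variants are both
in common use for single-cell signature scoring.

## Guided NMF deconvolution

The guide matrix assigns each marker gene to exactly one state: a gene
gets a 1 for a state iff its log2 fold-enrichment is ≥ 0.58 (the published
marker cutoff); genes passing for several states are ambiguous and dropped
with a warning, genes passing for none silently.

Fitting minimizes `‖X − S·F‖²_F` by multiplicative updates with `S`
initialized on the mask; multiplicative updates preserve zeros, so the
mask is satisfied exactly at every iteration (an explicit clamp guards
drift), and the loss trace is non-increasing. Convergence is a relative
loss change below `tol = 1e-6` or `max_iter = 2000`, whichever first, over
`n_restarts = 10` seeded random restarts (best final loss kept; restart
seeds derive from one seed sequence, so fits are reproducible).

Deconvolution operates on **linear-scale** expression (e.g. CPM) of the
guide genes, since the additive mixing model is only meaningful there.
Because NMF leaves a per-state scale free (`S·D`, `D⁻¹·F`), fractions are
identifiable only under a scale convention: signature columns are
normalized to a common total after fitting and the compensating factor is
absorbed into `F` before the per-sample simplex normalization. The mixture
generator adopts the same convention (state signatures with equal total
signal — the usual "equal total mRNA per cell" assumption), which is why
planted fractions are recovered to machine precision on noiseless data and
within RMSE 0.05 at 10% relative noise in the suite.

## Clustering stability and set overlap

The adjusted Rand index is the Hubert-Arabie chance-corrected form
(computed via scikit-learn) wrapped with item-universe checks; it is
invariant to relabeling. The stability sweep runs a caller-supplied
`(data, resolution, seed) → labeling` contract over a strictly increasing
resolution grid (default 0.10–0.50 in steps of 0.05): one reference run at
the base seed, `n_reseeds = 100` runs at seeds `base_seed + i`, and the
mean ARI against the reference. The chosen resolution is the grid point
immediately before the first **strict** decrease of the mean ARI; if it
never decreases, the last point is chosen and flagged. A reference
clusterer (k-nearest-neighbor graph, k = 15, plus Leiden modularity
communities with the resolution as the modularity resolution parameter)
ships for tests; the sweep itself is algorithm-agnostic.

The overlap coefficient is `|A ∩ B| / min(|A|, |B|)`; pairwise matrices
are exactly symmetric with unit diagonal.

## Synthetic data generators

`simulate_paired_counts` emulates the paired M-MDSC/monocyte design:
negative-binomial counts (mean-dispersion form, gene-wise dispersion
constant at 0.1 by default) around lognormal baseline abundances, a shared
lognormal subject factor (σ = 0.2) multiplying both samples of a pair to
induce the within-pair correlation the paired test exploits, and default
group sizes of 6 exposed and 12 unexposed pairs matching the study design
the package targets. DE genes (default 20%) receive a signed log2FC with
magnitude uniform in [0.5, 1.5] × `mean_abs_log2fc` (default 2.0) in the
unexposed group, multiplied by `attenuation_factor` in the exposed group
and split symmetrically between the two cell types; non-DE genes carry
exactly zero. Library size defaults to 10⁶. Recovered fold-change ratios
track the planted factor (median within ±0.1 over 20 replicates in the
suite).

`simulate_mixtures` draws guide-respecting signatures (uniform-positive on
the mask, zero elsewhere, columns scaled to equal totals), Dirichlet(α)
fractions (default α = 1), and adds zero-truncated Gaussian noise on the
linear scale — Gaussian rather than count noise because deconvolution
consumes linear expression summaries, not raw counts.
`simulate_cells` plants discrete states with disjoint marker sets whose
expected expression is `fold_up` (default 8) times baseline, Poisson
counts elsewhere.

None of the generators attempt to match real library-size distributions,
gene symbols, mean-dispersion trends, doublets or ambient contamination.
Passing tests therefore demonstrate correctness of the statistical
machinery under its stated model, not robustness to every artifact of real
RNA-seq.

## Problem sizes and numerical choices

The test suite runs at deliberately modest scales — 1000–2000 genes, 6–8
pairs, 300-gene rankings with 200–2000 permutations, 2000-iteration
resampling nulls, 40–100 replicate calibration loops — chosen as the
smallest sizes at which the asserted tolerances are statistically
comfortable. Degenerate inputs are handled explicitly throughout: zero
library sizes, zero-variance genes, empty gene sets, all-zero samples and
boundary thresholds all either raise a named error or follow a documented
convention (see module docstrings).

## Known limitations

- The paired t-test stand-in has less power than a count GLM at small n;
  supplementary DE tables can be substituted wherever power matters.
- The pseudocount and normalization of the original log2CPM values are not
  recoverable, so absolute score magnitudes are comparable only within one
  processing pipeline.
- NES magnitudes depend on the permutation count and weighting; they are
  reproducible under a fixed seed but not across GSEA implementations.
- Guided NMF assumes the mixing states are exactly the guided ones;
  unmodeled states bias fractions toward whichever guided state they most
  resemble.
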