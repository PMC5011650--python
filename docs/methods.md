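# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that matter for reproducibility.

## PCA separation score

Samples are projected onto principal components of the gene-centered
expression matrix (genes centered, not scaled, preserving the variance
weighting conventional for expression PCA). For each of the first
`n_axes = 2` components, every threshold between consecutive distinct
projections (evaluated at midpoints, plus the two extremes) and both
group-to-side assignments are scanned; the split minimizing the misplaced
count wins, ties resolved toward the lower axis index. The score is
`1 − min_misplaced / n`, always ≥ 0.5 because both assignments are tried;
swapping the control/test labels, permuting samples, or scaling the matrix
by a positive constant leaves it unchanged. How "out of place" should be
operationalized is genuinely open — only the arithmetic `0.75 = 1 − 3/12`
anchors it — so the simplest rule reproducing that arithmetic was chosen,
and the axis count is configurable. The gate is inclusive: score ≥ 0.75
passes.

## Differential expression

Plain pooled-variance Student *t* with `n1 + n2 − 2` degrees of freedom,
two-sided p, BH step-up across all genes. Genes with zero pooled variance
get p = 1 when the log2 ratio is also 0; otherwise the variance is floored
at the smallest positive pooled variance observed, so an exactly
reproducible shift is still called. A moderated *t* (variances shrunk
toward their median with a fixed prior weight, default 4 pseudo-d.f.) sits
behind `moderated=True`, default off: the downstream stages consume the
thresholded DEG sets, not the variance model, so the simpler statistic is
the default. Thresholds are strict as printed: FDR < 0.05 AND
fold change > 2 with fold change `2^|log2 ratio|`; an FDR of exactly 0.05
or a fold change of exactly 2 is excluded.

The DEG overlap matrix uses the row-set denominator for every entry,
`M[i,j] = |D_i ∩ D_j| / |D_i|`, which keeps the matrix asymmetric and makes
the conservation identity `M[i,j]·|D_i| = |D_i ∩ D_j|` exact. Empty DEG
sets yield undefined (NaN) rows/columns, never zeros.

## Gene-set scoring

**Ranking.** Signal-to-noise `(mean_t − mean_c)/(sd_t + sd_c)` with each
group sd floored at `max(0.2·|group mean|, 0.2)` — the floor keeps
low-variance genes from dominating, as in standard GSEA practice. A
`log2_ratio` metric is available when arms are too small for group sds.
Ties are broken by lexicographically smaller gene symbol, making the
ranking total and the whole stage deterministic.

**Enrichment score.** The weighted running sum (weight p = 1): hits
increment `|r_i|^p` normalized to unit total over the signature's overlap,
misses increment `1/(N − m)`; the ES is the deviation of largest magnitude
and the peak index is the first position attaining it. If every overlap
gene has metric 0 the hit weights degenerate to uniform. ES ∈ [−1, 1] and
both cumulative masses end at exactly 1; a brute-force re-walk is the test
oracle. The leading edge is the overlap at or before the peak (positive
ES) or at or after it (negative ES).

**Permutation null.** Gene-set (signature-label) permutation by default:
the null ES of random same-size gene sets. This is the appropriate scheme
when arms have only 3 samples — phenotype permutation would have ≤ 20
distinct relabelings — and phenotype permutation is available behind
`scheme="phenotype"` for larger designs. Permuted ES values are computed
vectorized from sorted hit positions (the running-sum extremum can only
occur at a hit or immediately before one, so 2m candidates suffice);
the observed ES always uses the plain O(N) walk, and the two routes are
cross-checked in the tests. `NES = ES / mean(same-sign permuted ES)`;
`p = (1 + #{same-sign, at least as extreme}) / (1 + #{same-sign})`, the
add-one rule keeping p in `[1/(k+1), 1]`. A signature with no same-sign
permuted value has undefined NES, is flagged, and is excluded downstream.
Per-signature sub-seeds derive deterministically from the profile seed.

**PAGE.** `z = (S_m − μ)·√m / δ` with μ, δ the mean and sample sd (ddof 1)
of all gene-level log2 ratios; two-sided normal p. Null z-scores are
standard normal to first order (checked by calibration).

**GAGE (simplified).** For every (test, control) sample pair, the per-gene
log2 fold-change vector is formed and the signature genes are compared to
all genes by a Welch t-test; the signed pair z-scores are combined by
Stouffer (`Z = Σz/√k`). The published gamma-mixture refinement is out of
scope; this pairwise+Stouffer form keeps the scorer usable at 3v3.

## Feature selection and clustering

Signatures are retained only when their overlap with *every* dataset's
gene universe lies in [10, 200] (inclusive). The cross-dataset rule keeps
signatures with nominal p < 0.05 in at least `min_datasets` datasets; the
default scales the reference 10-of-18 ratio to the accepted dataset count.
For PAGE/GAGE, selection is per-dataset BH FDR below a threshold in at
least one dataset (the printed thresholds are honored; whether FDR was
pooled or per dataset is not stated, so the rule mirrors the nominal-p
rule's structure with the count configurable). The individual-gene route
selects the top-k genes (default 152) by cross-dataset variance of the
log2 ratio, ties lexicographic.

Clustering is agglomerative with distance `1 − Pearson r` and average
(UPGMA) linkage — the common heatmap default, robust for a dozen items.
`1 − r` rather than `1 − |r|` is deliberate: over- and under-represented
profiles must land in different clusters. Trees are cut into a fixed
number of clusters (default 3 datasets + 3 feature clusters); no automatic
k selection. Cluster labels are renumbered in dendrogram-leaf order so
output is deterministic; scipy's smallest-index merge rule breaks distance
ties. One-way clustering can run either on raw profiles or on the columns
of a precomputed correlation matrix (both readings of the procedure are
supported). Single-feature matrices fall back to Euclidean distance on the
one column, since a length-1 vector has no correlation.

## Derived gene sets

A gene's *frequency of occurrence* is the number of contributing
signatures in whose leading edge it appears in at least one dataset
(distinct signatures, not signature × dataset incidences; the incidence
count is available via `count_incidences=True`). The "top 5%" slice takes
the `ceil(0.05 · n_positive-frequency-genes)` highest frequencies and
includes all ties at the cutoff — frequencies are small integers, and
strict truncation would depend on gene order. The denominator is the set
of genes with positive frequency (not the whole platform), the more
conservative of the two readings.

Genotype signature ranking sums −log10 nominal p over the genotype's
datasets; the top `floor(0.05 · N)` signatures (exactly 300 of 6,002 when
sums are distinct; boundary ties broken by name) are split into PNS
(positive NES in every dataset of the type) and NNS (all negative); mixed
signs fall into neither. Ranking by the sum of −log p is identical to
ranking by the product of p-values, so the multiplicative reading of the
aggregation is available behind `aggregate="product"` without changing the
default ordering. A genotype with no sign-consistent signatures yields an
empty URG or DRG with a warning — at 3 datasets per type this legitimately
happens for an all-down genotype's PNS.

## Term enrichment

One-sided over-representation: p is the hypergeometric upper tail
`P(X ≥ overlap)` for the 2×2 table within the universe (default: genes
present in every accepted dataset). Query genes outside the universe are
dropped with a warning; BH runs across terms; −log10 p is the reporting
scale. Whether the original analyses were one- or two-sided is unstated;
over-representation is the only direction the derived-set queries ask
about.

## Synthetic data: what it emulates, what it does not

Per gene g and sample s:
`x_gs = baseline_g + δ_m(genotype)·[g ∈ module m, s ∈ test] + ε`,
`ε ~ N(0, noise_sd)`, `baseline_g ~ N(baseline_mean, baseline_sd)` drawn
once and shared across datasets. Defaults — the reference study
conditions used throughout the tests: 2,000 genes; three genotypes
(proliferation +δ / EMT −δ; EMT +δ; both −δ) × three datasets; 6v6 arms;
noise_sd 0.5; δ = 1.5 = 3× noise; baseline 7 ± 1 (typical log2 microarray
intensities); two 80-gene modules. The signature collection holds the two
module signatures, 10 "related" signatures per module (the full module
diluted with 0–80 random off-module genes, emulating the redundancy of
curated collections where many sets describe one process at varying
specificity — this redundancy is what gives the selection stage a
non-trivial feature space, exactly as in real signature databases), and
500 size-10–200 decoys drawn from non-module genes.

`degrade_separation` replaces k chosen samples' vectors with draws from
the opposite group's estimated distribution (per-gene group mean, pooled
within-group sd) and verifies by re-scoring that exactly
`min(k, n−k)` samples are misplaced, re-drawing with a fresh sub-seed
(bounded retries) otherwise; beyond half the samples the best-assignment
convention flips, so a fully swapped dataset scores 1.0 again.

Not emulated: probe-level noise, batch/platform effects, correlated gene
backgrounds, heteroskedastic intensity-dependent variance, partial module
penetrance. Passing recovery tests therefore show the machinery is
correct and calibrated under a clean additive Gaussian world, not that
real cross-platform meta-analysis will cluster as cleanly.

Seeding: one master seed; sub-streams for gene assignment, per-dataset
noise, signatures and degradation derive via `SeedSequence([seed, …])`
indexed offsets, so every artifact is reproducible from the single seed
and independent of generation order.

## Problem sizes and numerical choices

The recovery suite runs 20 seeds of the reference simulation through the
full pipeline at 100 gene-set permutations per signature (the permutation
floor `1/(k+1) ≈ 0.02` sits safely below the 0.05 selection threshold);
null calibration uses 1,000 permutations over 500 decoys. Tables are
written with 8 significant digits and round-trip losslessly at 6.
Degenerate cases are errors, not silent zeros: zero-variance matrices in
the PCA, empty universes in Fisher, single-sample arms in the t-test,
signatures overlapping nothing (or everything) in the running sum.

## Known limitations

- NES values are not bit-compatible with the desktop GSEA implementation
  (different permutation streams and ranking-metric details); the running
  sum itself is exact against brute force.
- The moderated-t option is a fixed-prior shrinkage, not a full
  empirical-Bayes fit.
- GAGE omits the gamma-mixture small-sample correction.
- Fisher enrichment treats terms as flat sets; no GO-graph propagation or
  term-redundancy reduction.
- With two planted modules the selected-signature space is low-rank;
  conclusions about clustering robustness at 152 real signatures do not
  follow from it.
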