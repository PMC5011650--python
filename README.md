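# stemsig

Meta-analysis of matched test-vs-control gene-expression contrasts through
molecular-signature enrichment profiles. The package was built around the
study design used for cancer stem cell (CSC) vs non-stem cancer cell (NSC)
comparisons: many small public microarray contrasts, each scored against a
large gene-set collection, then clustered into *genotypes* — groups of
datasets with a shared signature-response pattern (e.g. proliferation-up /
EMT-down vs EMT-up) — from which characteristic gene sets are derived and
functionally annotated.

It is aimed at computational biologists who want the whole chain — quality
gating, differential expression, gene-set scoring, cross-dataset
classification, derived gene sets, term enrichment — as a tested, seedable
library rather than a collection of one-off scripts.

## The method

For each dataset (a log2 expression matrix with control/test arms):

1. **PCA quality gate.** The *PCA score* is the fraction of samples on the
   correct side of the best single-axis threshold split over the first
   principal components: `score = 1 − min_misplaced / n`. Datasets with
   score ≥ 0.75 are kept (e.g. 3 misplaced of 12 ⇒ 0.75, the boundary).
2. **Differential expression (individual-gene route).** Pooled-variance
   two-sample *t* per gene, BH-adjusted; DEGs pass FDR < 0.05 and fold
   change > 2. Pairwise DEG overlap is summarized as the asymmetric matrix
   `M[i,j] = |D_i ∩ D_j| / |D_i|`.
3. **Gene-set scoring (gene-set route).** Signatures are filtered to 10–200
   genes of overlap with every dataset's platform. Each retained signature
   gets a GSEA running-sum enrichment score
   `ES = max-deviation(P_hit − P_miss)` with weight p = 1 on the
   signal-to-noise ranking, a permutation-normalized `NES = ES / mean(same-
   sign permuted ES)` with an add-one nominal p, and its leading-edge genes.
   PAGE (`z = (S_m − μ)·√m / δ`) and a simplified GAGE (pairwise fold-change
   t-tests combined by Stouffer) are available as alternative scorers.
4. **Classification.** Signatures with nominal p < 0.05 in enough datasets
   form the feature set; the datasets × signatures NES matrix is two-way
   hierarchically clustered (distance 1 − Pearson r, average linkage, cut
   into 3 + 3 clusters) into genotypes and signature clusters.
5. **Derived gene sets.** Per signature cluster, the cluster gene set (CGS)
   is the top-5%-frequency slice of the union of leading-edge genes. Per
   genotype, signatures are ranked by summed −log10 p over the genotype's
   datasets, the top 5% split into all-positive-NES (PNS) and
   all-negative-NES (NNS) sets, and the top-5% leading-edge-frequency genes
   of each give the up-regulated (URG) and down-regulated (DRG) gene sets.
6. **Term enrichment.** One-sided Fisher exact (hypergeometric upper tail)
   of each derived set against GO/KEGG-style term collections, BH across
   terms, reported as −log10 p profiles.

A synthetic-data module generates multi-dataset collections with planted,
directional genotype structure so the full pipeline is testable end-to-end
without any external download; see `docs/methods.md` for the model.

## Worked example

```bash
python examples/04_full_pipeline.py
```

prints (abridged):

```
dataset clusters vs planted genotypes:
  cluster T1: ['T2_ds1', 'T2_ds2', 'T2_ds3'] (planted: ['T2'])
  cluster T2: ['T1_ds1', 'T1_ds2', 'T1_ds3'] (planted: ['T1'])
  cluster T3: ['T3_ds1', 'T3_ds2', 'T3_ds3'] (planted: ['T3'])

22 signatures selected (nominal p < 0.05 in enough datasets) out of 522 size-filtered
  T1: |PNS|=11 |NNS|=13 |URG|=80 |DRG|=36
  T2: |PNS|=12 |NNS|=11 |URG|=80 |DRG|=80
  T3: |PNS|=0  |NNS|=15 |URG|=0  |DRG|=80
```

Each recovered cluster contains exactly the datasets of one planted
genotype (cluster labels are arbitrary). The URG of the proliferation-up
genotype recovers all 80 planted module genes; the all-down genotype has an
empty PNS, hence an empty URG — exactly what the sign-consistency rule
should do there. `examples/01–03` demonstrate the individual stages, and
the `stemsig` console script exposes them as subcommands
(`simulate`, `qc`, `deg`, `enrich`, `select`, `cluster`, `derive`,
`term-enrich`, `run-all`).

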