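# moprog

Integrative multi-omics prognostic classification of cutaneous-melanoma-like
cohorts.

Bulk tumor cohorts profiled on several molecular layers — DNA methylation
(450K-style beta values), mRNA-seq, miRNA-seq, overall survival and exome
mutations — can hide survival-relevant patient subgroups that no single layer
resolves on its own. `moprog` implements a complete, testable version of a
classification strategy built around that observation: cluster the cohort
three ways (methylation alone, mRNA alone, and all three layers jointly),
label each cluster by its survival behaviour, pool the labels per patient into
**better / poorer / intermediate** prognostic groups, and then characterize
the groups molecularly. It is aimed at computational biologists who want the
whole procedure as a reusable library and command-line tool rather than a
one-off analysis script.

## What it implements

**Clustering.** Monti-style consensus clustering of one omics block
(resampling items and features at rate 0.90, Ward linkage on the Pearson
dissimilarity `d(i,j) = 1 − r(i,j)` or k-means; CDF-of-consensus area for
choosing *k*), and a multi-block route: feature-centered blocks scaled to
equal Frobenius norm, row-concatenated, decomposed by SVD (consensus PCA),
then Ward-clustered with Tibshirani's gap statistic

```
Gap(k) = (1/B) Σ_b log W*_kb − log W_k,   choose smallest k with Gap(k) ≥ Gap(k+1) − s_{k+1}
```

**Survival labeling and pooling.** Kaplan–Meier curves, the log-rank
(Mantel–Cox) test from observed/expected event accumulation over risk sets,
and the Pike hazard-ratio estimator `HR = (O_a/E_a)/(O_b/E_b)` with
`exp(log HR ± 1.96·√(1/E_a + 1/E_b))` confidence limits. Within each
clustering, a cluster is labeled *better* when it has significantly better OS
(p < 0.01) than at least one other cluster and worse than none; per patient,
the three labels pool to *better*/*poorer* when unopposed or backed by a
two-of-three majority, otherwise *intermediate*.

**Characterization.** Negative-binomial Wald differential expression on
median-of-ratios-normalized counts (|log2FC| > 1, BH-adjusted p < 0.001);
hypergeometric overrepresentation analysis against GMT gene sets;
single-sample GSEA immune/stromal scores (rank-weighted running sum, exponent
0.25); SAM-style permutation differential methylation (fold change > 1.25 or
< 0.8 at q < 0.01) with promoter-based gene calls, genomic-region beta
summaries and Fisher region enrichment; nonsynonymous mutation burden,
per-gene Fisher tests, 96-trinucleotide catalogs and greedy signature
deconvolution.

**Synthetic cohorts.** A seeded generator produces cohorts with the
statistical structure the analysis assumes (three latent groups differing in
methylation level, immune-module expression, survival hazard, mutation burden
and signature mixture), so the entire pipeline runs and is tested without any
external data.

## Worked example

```bash
moprog run-all --seed 1 --out-dir melanoma_run
```

simulates a 447-patient cohort and runs every stage (a couple of minutes on
one CPU). Inspecting the outputs:

```python
>>> import pandas as pd
>>> g = pd.read_csv("melanoma_run/results/prognostic_grouping.tsv", sep="\t")
>>> g["prognostic_group"].value_counts().to_dict()
{'better': 394, 'poorer': 53}
>>> burden = pd.read_csv("melanoma_run/results/burden_tests.tsv", sep="\t")
>>> burden[["group_a", "group_b", "mean_a", "mean_b", "p"]].head(1)
  group_a group_b      mean_a     mean_b             p
0  better  poorer  264.530457  80.226415  9.363734e-65
>>> w = pd.read_csv("melanoma_run/results/signature_weights.tsv", sep="\t")
>>> w[w.signature == "Signature_UV"][["group", "weight"]]
    group    weight
0  better  0.771363
2  poorer  0.412275
```

At this seed the pooling is decisive everywhere, so no patient remains
intermediate (smaller or noisier cohorts produce all three groups). The
pooled better-prognosis group carries roughly 3× the nonsynonymous
mutation burden of the poorer group (t test p ≈ 1e-64 at these planted
effect sizes) and a higher weight of the UV-like mutational signature —
the direction the classification is designed to expose. Per-sample immune
and stromal scores, differential expression/methylation tables, region
enrichments and a pooled Kaplan–Meier plot are written alongside. A
`manifest.json` records input/output hashes per stage, so re-running the
same configuration skips finished stages and a corrupted intermediate file
is recomputed automatically.

Every stage is also a subcommand (`simulate`, `prep`, `cluster`,
`integrate`, `pool`, `dge`, `ora`, `score`, `dmp`, `regions`, `burden`,
`spectra`, `sigfit`) over the same library functions in `moprog.*`.

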