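# Methods

This note documents the models and procedures `moprog` implements, the
design choices made where several reasonable options existed, and what the
synthetic data generator does and does not emulate.

## Cohort model

The unit of analysis is a cohort of tumor samples with up to three omics
blocks — methylation beta values in [0, 1] (features are array probes),
mRNA-seq raw counts, miRNA-seq counts — plus a clinical table (overall
survival in days, death/censoring indicator, age, sex, stage) and a list of
single-nucleotide variants with their trinucleotide contexts. Blocks are
aligned by intersecting sample identifiers; coordinates are 0-based
half-open everywhere (BED is consumed natively and the TSS table is
documented as 0-based), which avoids carrying two coordinate conventions
through the region analyses.

## Feature preparation

Expression values are transformed as `log2(x + 1)`; the pseudocount of 1 is
the conventional choice for RPKM/RPM-scale data with zeros. Features are
ranked by the unscaled median absolute deviation (no 1.4826 consistency
factor — only the ranking matters) and the top fraction retained:
`ceil(fraction · n)` features, ties broken lexicographically by feature id,
survivors kept in their original row order. Defaults are 10% of methylation
probes and 20% of genes/miRNAs. The transform is applied before MAD ranking.

## Consensus clustering of one block

The Monti resampling scheme: for each of `n_resamples` iterations (default
1000; the orchestrated pipeline uses 50, see *Problem sizes*), sample
`ceil(0.9 · n)` items and `ceil(0.9 · p)` features without replacement,
cluster the subsample, and accumulate for every sample pair both a
co-sampling count and a co-clustering count. The consensus matrix entry is
their ratio (0/0 → 0, diagonal 1). Base clusterers:

* **Ward on Pearson dissimilarity** (default): `d(i,j) = 1 − r(i,j)` over
  features, fed to the Lance–Williams Ward update. Ward formally assumes
  squared Euclidean distances; applying it to a correlation dissimilarity is
  the established practice of the consensus-clustering tools this module
  mirrors, and is retained knowingly.
* **k-means** on the raw feature matrix (Euclidean), 20 random restarts,
  best inertia.

Note that the Pearson dissimilarity is translation-invariant per sample: a
group effect that shifts all features by the same constant is invisible to
it. Group differences must be *patterns* across features (the synthetic
generator plants such patterns; see below).

The final assignment at each k is a Ward cut of `1 − consensus`. k is
selected from the empirical CDF of off-diagonal consensus entries: with
A(k) the area under the CDF and Δ(k) = (A(k) − A(k−1))/A(k−1), the smallest
k whose successor gains less than 0.1 relative area is chosen. The 0.1
threshold makes an otherwise by-inspection choice explicit and
reproducible; a `force_k` override reproduces choices made by eye (such as
a four-cluster methylation solution). With high resampling rates on small
cohorts, spurious sub-splits can look stable and inflate Δ; the override
exists for exactly such judgment calls.

## Multi-block integration

Each block is feature-centered and divided by the Frobenius norm of the
centered matrix, so blocks with vastly different feature counts contribute
equally. The centered, scaled blocks are stacked row-wise and decomposed by
exact SVD; the global sample scores are the top `J = 10` right singular
vectors scaled by their singular values (consensus PCA). An iterative
NIPALS multi-block PCA with optional sparse loadings would give the same
subspace in the dense case; the exact SVD is deterministic and directly
testable, which is why it is used. Signs are fixed by making each factor's
largest-magnitude loading positive.

Scores are Ward-clustered for k = 1…12 with the gap statistic: B = 50
reference datasets (30 in the pipeline default) drawn uniformly over each
score dimension's observed range, `Gap(k) = mean_b log W*_kb − log W_k`
with W the within-cluster sum of squared distances to centroids, selecting
the smallest k with `Gap(k) ≥ Gap(k+1) − s_{k+1}`,
`s_k = sd_b · sqrt(1 + 1/B)`.

## Survival statistics

Kaplan–Meier estimation processes deaths before censorings at tied times.
The log-rank test accumulates observed events, expected events and the
hypergeometric covariance over the distinct event times; for g groups the
statistic is the quadratic form of the first g−1 (O−E) components with the
pseudo-inverse of their covariance, chi-squared with g−1 df. The hazard
ratio is the Pike estimator `(O_a/E_a)/(O_b/E_b)` with
`exp(log HR ± 1.96·√(1/E_a + 1/E_b))` limits — chosen over a Cox fit
because it is built from the same O/E quantities as the log-rank test and
keeps the module self-contained; its CI coverage of a planted hazard ratio
is verified by simulation rather than by comparison to any published
estimate. lifelines serves as an independent cross-check in the test suite,
never as the implementation.

### Cluster labeling and pooling

The labeling rule formalizes "this cluster has significantly better OS":
cluster i *beats* j when the pairwise log-rank p < α (default 0.01) and the
Pike HR of i versus j is below 1. A cluster beating at least one other and
beaten by none is **better**; beaten by at least one and beating none,
**poorer**; anything else **neutral**. This is one reasonable formalization
of comparisons usually made selectively by eye; it is therefore
overridable by an explicit cluster→label map. One consequence worth knowing:
a middle-risk cluster that is significantly worse than the best cluster but
lacks power to beat the worst one is labeled *poorer*, not *neutral*, so
decisive cohorts can pool into only two groups.

Pooling takes exactly three labelings (integrated, methylation, mRNA). Per
patient, with b better-labels and p poorer-labels: unopposed labels pool
directly (b ≥ 1, p = 0 → better; p ≥ 1, b = 0 → poorer); conflicting labels
need a two-of-three majority; otherwise the patient is intermediate. The
implementation is verified against an exhaustive 27-case truth table.

## Differential expression

Counts are normalized by median-of-ratios size factors (genes positive in
every sample as the reference set). Per-gene NB dispersions are the larger
of the method-of-moments estimate `(var − μ)/μ²` (clamped at 0) and a
least-squares `a0 + a1/μ` trend fitted across genes — the maximum guards
against the MoM estimate's underestimation at small n, at the cost of a
conservative test (null type-I rate ≈ 0.03 at nominal 0.05, within the
calibration band the tests assert). The Wald z compares log normalized
group means with delta-method variances `(1/n)(1/(μ + 0.5) + α)` per group;
log2 fold changes use a 0.5 pseudocount. Calls require |log2FC| > 1 and
BH-adjusted p < 0.001. This is a deliberately transparent approximation of
an exact NB test with shrinkage; its contract is calibration, not equality
with any particular implementation's output.

ORA is a hypergeometric upper tail on set∩universe overlaps with BH
adjustment; the universe is an explicit, required parameter (results depend
strongly on it, and the choice between all annotated genes and
protein-coding only is the caller's).

## Immune and stromal scores

Single-sample GSEA with exponent 0.25: genes are ranked per sample (average
ranks at ties, highest expression = largest rank); walking the list in
decreasing order, the score is the running-sum integral of the
rank-weighted in-set ECDF (weights `rank^0.25`) minus the uniform
out-of-set ECDF. The score depends on expression only through ranks, hence
is invariant under any strictly monotone per-sample transform — asserted in
tests by brute-force comparison over all 120 orderings of a 5-gene toy. The
immune and stromal signatures are configuration data (GMT); the synthetic
generator ships planted truth sets, and no claim is made about reproducing
published score magnitudes.

Survival splits take the top and bottom tertile (or quartile) of scores,
discard the middle, and log-rank the arms; arm size is `floor(n·fraction)`
with boundary ties broken by stable sample-id order. The prognostic screen
keeps genes whose high-expression arm has significantly better OS
(p < α and HR(high/low) < 1), optionally requiring the same in every
validation cohort (tertile split); genes absent from a validation cohort
are dropped.

## Differential methylation

The SAM scheme on `log2(beta + 1e-3)` intensities: moderated statistic
`d = Δmean/(s + s0)` with s the pooled standard error and the fudge factor
s0 fixed at the median of all s — the percentile search of the original
procedure is omitted for determinism; calibration (null false-call rate) is
the tested contract. q-values come from label permutations (default 100):
at each observed |d| order statistic, the false discovery rate is the mean
permuted count at or above it divided by the observed count, and a probe's
q is the minimum FDR over thresholds that call it (monotone in |d| by
construction). The fold change is the ratio of group geometric means of
beta (the beta-versus-M-value choice is ambiguous in the field; geometric
means of beta are used and documented). Calls: hyper if FC > 1.25 and
q < 0.01, hypo if FC < 0.8 and q < 0.01.

Gene-level calls use promoter probes only (promoter = TSS ± 1500 bp,
half-open, strand-symmetric); genes with both hyper- and hypomethylated
promoter probes are excluded and logged. Region annotation assigns each
probe every interval class it overlaps (5'UTR, exon, intron, 3'UTR,
enhancer — enhancer intervals are user-supplied BED) plus the promoter
window; probes in none get class "none". Region summaries report mean beta
per class × group with pairwise Student t tests on per-sample class means,
and per-class Fisher enrichment of differential calls against the whole
array as background (BH across classes). A fully-called or fully-uncalled
class carries no enrichment information and reports the neutral odds ratio 1.

## Mutation analyses

Burden is the per-patient count of nonsynonymous variants (absent patients
count 0), compared between groups by Student's t test. Per-gene tests
binarize patients (mutated at least once) and apply Fisher's exact test to
the 2×2 group table. Catalogs map each SNV to one of the 96
pyrimidine-centered channels, reverse-complementing purine-reference
records; non-SNVs are skipped with a logged count. Contexts are taken from
the mutation file itself; a reference-FASTA context extractor is a
documented extension point, not a dependency.

Signature fitting is greedy forward selection in the deconstructSigs
style: iteratively re-optimize, for the best single signature at a time, a
weight on [0, current + remaining budget] by bounded scalar minimization of
the sum of squared channel errors, stopping when the relative error
improvement falls below 1e-3; weights below 0.06 are discarded and the
survivors re-fit once. Re-optimization (rather than increment-only
addition) matters: an increment-only greedy cannot undo an initial
overshoot and fails to recover exact mixtures. For the two bundled
signatures the procedure recovers exact mixture weights to machine
precision and sampled mixtures at the binomial information bound
(sd ≈ √(w(1−w)/n)).

## The synthetic cohort generator

`generate_cohort` draws, from a single seed: latent groups (multinomial,
default 0.67/0.12/0.21 better/poorer/intermediate, n = 447); per-probe beta
values from Beta distributions whose means carry a group offset — better
lowest, poorer highest (default separation 0.08), scaled by a per-probe
gamma susceptibility (mean 1) so the groups differ in methylation *pattern*
rather than by a flat shift that a correlation distance could never detect;
NB expression counts (gamma-Poisson, dispersion 0.15) with an immune module
(100 genes) multiplied by 2^1.5 in the better group and 2^−0.75 in the
poorer group, and a weaker stromal module (60 genes); miRNA counts as pure
noise (deliberately: the miRNA layer contributes no structure, matching the
situation where one block is uninformative); exponential survival (baseline
hazard 1/2500 per day, poorer hazard 2.0× better, intermediate 1.4×) with
staggered-entry administrative censoring tuned to a 45% censoring fraction,
and a Weibull shape parameter exposed for non-constant hazards; Poisson
mutation burdens (means 300/80/150 nonsynonymous per patient, plus 15%
"other"-consequence records); per-mutation channels from a two-signature
mixture (UV-like weight 0.8/0.4/0.6 per group), half the records stored on
the purine strand to exercise reverse-complementation; BRAF mutation
carriers at group-dependent frequencies (0.54/0.29/0.40); ages normal
around 57.7/60.6/58.0 years. A deterministic toy genome (one gene per
10 kb, UTR/exon/intron intervals, enhancers at every third gene, probes
cycling through promoter/genic/enhancer/intergenic offsets) provides the
region annotation.

The two bundled signatures are synthetic stand-ins, not COSMIC entries: a
UV-like signature with all mass on C>T channels (double weight at
dipyrimidine 5' contexts) and a clock-like signature uniform over T>C
channels. Their supports are disjoint, which makes mixture weights
maximally identifiable — the estimator-variance analysis above is the
reason for this choice.

`generate_validation_cohorts` produces independent expression+survival
cohorts (default sizes 44/79/45) in which a latent per-patient immune
activity shifts the immune module and scales the hazard
(`exp(−0.5·activity)` by default); setting the association to zero yields
null cohorts for calibration tests.

What the generator does **not** emulate: real 450K probe-level covariance
and genomic autocorrelation, realistic library-size variation, copy-number
or purity effects, non-exponential hazards (beyond the Weibull option),
clinical-covariate confounding, or the marginal distributions of any real
cohort. Passing tests therefore demonstrate that the pipeline's machinery
is correct and calibrated under its own model assumptions — not that it
would make identical calls on real tumor data.

## Problem sizes and numerical choices

The orchestrated pipeline and test suite run at desk scale: 50 consensus
resamples (not 1000), 100 SAM permutations, 30 gap references, and cohorts
of 150–447 samples with 600–2000 probes and 500–1500 genes. These sizes
were chosen so the full synthetic run completes in well under ten minutes
on one CPU while every statistical property remains measurable; all of
them are configuration values that scale up unchanged. Other numerical
conventions: matrix round trips are written at 17 significant digits; the
consensus 0/0 convention is 0; zero-variance-in-both-groups t tests with
equal means return p = 1; Fisher odds ratios at zero cells are ±∞/0 with
the all-zero table rejected; every stochastic routine takes an explicit
seed, and the pipeline derives per-stage seeds from the global one as
`(seed·1009 + stage_index) mod 2³¹`.

## Known limitations

* The cluster-labeling rule is one formalization among several; selective
  pairwise testing, or labeling only extreme clusters, would pool
  differently on borderline cohorts (hence the override map).
* The NB Wald test is conservative at small n; it is a calibration-grade
  approximation, not a drop-in replacement for exact NB tests with
  dispersion shrinkage.
* SAM's s0 is fixed at the median standard error rather than searched.
* The gap statistic with uniform-box references tends to over-merge
  elongated clusters; the override exists for that case too.
* Signature fitting assumes the reference signatures are correct and
  complete; no de-novo extraction is provided.
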