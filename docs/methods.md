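# Methods

This note documents the models, defaults and numerical choices behind each
stage, what the synthetic-data generator does and does not emulate, and the
known limitations.

## Study design and coordinates

The design is a mouse aging cohort: three age groups (1, 5, 21 months), both
sexes, a configurable number of mice per group (default 8, sex-balanced), one
sample per mouse × tissue. Age always enters models in months as a continuous
covariate, so effect sizes are "per month". All genomic coordinates are
0-based half-open; summits are 1-bp intervals; BED round trips are exact.

## Universal peak set

Per-group summits are extended to summit ± h (h = 250 bp default, width
2h + 1 = 501 bp) and merged greedily: pool all groups' peaks, sort by
(score desc, chrom asc, start asc), accept a peak iff it overlaps no accepted
peak. The deterministic tie-break makes the result invariant to input order;
an O(n²) brute-force oracle verifies the implementation on random instances.
The ranking score is the per-group score column of the input BED; the merge
runs in one pooled pass across all groups (a two-level within-tissue-first
variant was considered and not implemented — the pooled pass is what a single
fixed-width universal set implies). Genomic context is decided at the summit
with precedence TSS-promoter (± 1 kb of any TSS) > exon > intron (inside a
gene body) > intergenic; the four labels partition the peak set.

Cell QC reduces to two explicit thresholds — minimum total peak-overlapping
counts (default 100) and minimum promoter fraction (default 0) — rather than
a full doublet-detection procedure, which is out of scope. Pseudobulk
aggregation sums counts over cells sharing a (sample, cell type) label and
conserves totals exactly.

## Entropy specificity

Cell-type pseudobulk profiles are depth-normalised to counts per million
within each cell type, then rescaled per peak to the simplex. Specificity is
S = 1 − H/log₂ K with H the Shannon entropy in bits (0·log 0 := 0). S is 1
iff accessibility is concentrated in one cell type and never increases under
mixing with the uniform distribution. Defaults: S ≥ 0.5 (closed threshold)
and argmax CPM ≥ 1 to call a specific CRE; both configurable. The entropy
formula is isolated in one function (`shannon_entropy_bits`) so a
divergence-based alternative (e.g. Jensen–Shannon specificity) can be swapped
in without touching callers.

## Composition model

Fractions are modelled untransformed by OLS (a logit option exists, off by
default): fraction ~ β₀ + β_age·age + β_sex·1[F] + β_int·age·1[F]. The aging
p-value is the joint F-test of {β_age, β_int} against the sex-only null — a
main-effect t-test would miss cell types whose sexes move oppositely and
leave the marginal slope near zero. The interaction p is the t-test of β_int.
BH correction runs across all tissue × cell-type tests of one analysis level
(one family). Gates: aging-associated iff q_age < 0.05 and R² > 0.4;
direction by the sex-averaged slope β_age + β_int/2; interaction iff
additionally q_int < 0.05, subdivided by which sex has the larger |slope|, or
"opposite" if the sex-specific slopes differ in sign. Single-sex designs are
fitted without sex terms and flagged.

## Sex-dimorphism AUC

Per tissue × cell type × age group, the majority sex is down-sampled to the
minority count and a KNN classifier (k = 25, reduced to ⌊n/2⌋ with a warning
when cells are scarce; 5 folds) scores each held-out cell by the fraction of
female training neighbours; the AUC of that score against true sex is
compared to the 0.9 dimorphism threshold. One seeded global permutation
drives both the down-sampling and a round-robin fold assignment within each
sex; because neither step consults the label names, swapping F/M mirrors the
score around 0.5 and leaves the AUC exactly unchanged (a tested invariant).
k, the fold count and the imbalance handling are documented configuration,
not statements about any external protocol.

## Differential accessibility

Per peak, a log-linear NB2 GLM with a library offset and continuous age. The
model is fitted by IRLS vectorised across peaks (all peaks in a stratum share
one design matrix; the per-peak 2×2 normal equations are assembled with
einsum), which makes thousands of peak fits per stratum essentially free.
α = 0 degenerates to exact Poisson regression; statsmodels GLM serves as the
independent cross-check in tests, never as the implementation.

*Normalization.* Default offsets are median-of-ratios size factors computed
from peaks detected in every sample (falling back to raw library sizes when
fewer than 50 qualify). Raw totals are biased when a non-negligible share of
the library carries true signal — the offset then absorbs part of the fold
change. Known depths can be supplied directly.

*Dispersion.* Per-peak α by moment matching around the Poisson fit, with
squared residuals inflated by n/(n−p) to return the degrees of freedom
consumed by the fitted mean; a trend (running median of raw α across
mean-count bins) provides shrinkage, final α = 0.7·trend + 0.3·raw. The
correction matters: without it the global-null type-I fraction at p < 0.05
sits near 0.065–0.08; with it near 0.05–0.06.

*Testing.* Likelihood-ratio χ²(1) on β₁; logFC reported as β₁/ln 2
(log₂/month); BH within each tissue × cell type × sex stratum; peaks with
fewer than 5 total counts in a stratum are excluded and reported. The LRT is
mildly liberal at very low counts, which is why the exclusion filter exists
and why the end-to-end study (shallow 15-cell pseudobulk) shows a somewhat
higher per-stratum empirical FDR (~0.1) than the focused 30-sample
simulations.

Cross-sex rules: shared = significant (q < 0.05) in both sexes; sex-specific
= significant in one sex **and** |log₂FC/month| < 0.02 in the other — the
floor prevents calling a mere power difference "sex-specific biology".
Cross-cell-type rules: shared-up/down iff ≥ 10 cell types in one direction
and none in the other; opposite iff ≥ 5 in each direction.

## Promoter–CRE linkage

Candidates pair a gene's promoter peak (overlapping TSS ± 1 kb) with
non-promoter peaks whose summit lies within ± 250 kb of the TSS (window
configurable; the default is a conventional cis-regulatory horizon).
Co-accessibility is Pearson correlation of log1p-CPM pseudobulk across
samples within one cell type (Spearman by flag), p from the t transform,
BH across pairs. Linkages keep pairs with q < 0.05, r ≥ 0.3 and a
significant DA CRE; concordance requires the CRE, promoter and expression
directions to agree, evaluated per sex stratum. Zero-variance columns are
dropped with a recorded reason; genes missing from the expression table are
retained with direction "unknown" and concordant = false.

## Regulators

*Backgrounds.* Stratified sampling without replacement from non-query peaks,
matching the query's joint (GC, mean accessibility) decile histogram,
2× query size by default; per-bin shortfalls are topped up from the leftover
pool and reported.

*Motif enrichment.* Hypergeometric upper tail on the 2×2 of (query vs
background) × (motif vs not), plus the motif-frequency difference in
percentage points; motifs absent from the pool get p = 1 and NaN fold with a
flag; BH across motifs.

*Motif deviations.* Expected motif count per group = group depth × Σ over
motif peaks of the global mean read fraction; raw deviation
(observed − expected)/expected; z-score against B = 50 (25 in the CLI stage)
background draws of GC/accessibility-matched peak sets. A motif annotating
every peak has deviation exactly 0 by construction, and the depth-weighted
mean of raw deviations is 0 for any motif.

*Cytokine signatures.* The aging gene set is the union of genes with
significant aging-up promoter peaks and genes receiving up-direction
linkages; both sources are recorded separately so either definition can be
used alone. Enrichment is the hypergeometric upper tail of the overlap with
each signature over the gene universe, BH across cytokines. A signature is
"supported" iff enriched (q < 0.05) and at least one mapped secretion or
receptor gene carries a significant aging-up promoter peak; missing mappings
are reported as such.

## Synthetic data: what is emulated, and what is not

The generator produces every input the pipeline reads, in the exact on-disk
formats (BED, MatrixMarket + index files, TSV, GMT), with `truth.json`
recording all planted effects. Defaults define a 3-tissue × 10-cell-type ×
2,000-peak × 24-mouse study.

- **Composition**: Dirichlet-multinomial per sample around a softmax mean,
  log-baseline + slope·age (+ interaction·age for females); concentration
  300 (a free parameter — replicate-level variance of real fractions has no
  canonical value — exposed in config). The default planted design
  (5 slopes ± 0.03/month, 3 interactions ± 0.04/month) is closure-balanced:
  because fractions sum to one, net-positive planted slopes would induce
  real negative trends in every null cell type; weighting the baselines so
  Σ f·slope = 0 removes that artefact, which is what makes a planted-vs-null
  FDR assessment meaningful. At 2,000 cells/sample and concentration 300,
  the planted slope of 0.03/month gives t ≈ 6 and R² ≈ 0.6 at n = 24 — a
  clearly-powered but not degenerate regime.
- **Counts**: gamma-Poisson (NB) per cell with shared dispersion 0.2;
  planted DA peaks multiply the mean by exp(lfc·age) in the covered sex and
  cell types; cell-type-specific peaks get a ×20 mean in their type (÷20
  elsewhere); planted promoter–CRE pairs share a per-sample bivariate-normal
  log-mean latent (sd 1.0, correlation 0.8). Counting noise attenuates the
  latent correlation in shallow pseudobulk — observed r in the end-to-end
  study is well below 0.8, while the focused linkage fixture (deep
  pseudobulk, n = 30) observes r ≈ 0.76.
- **Embeddings**: isotropic Gaussians per cell type; planted sex dimorphism
  displaces F and M by ± half the stated magnitude along a random unit
  direction. "2σ per dimension in d dimensions" corresponds to magnitude
  2σ√d.
- **Motifs/signatures**: Bernoulli motif hits at background rate 0.1, the
  planted motif at 3× that rate in planted DA peaks; planted cytokine
  signatures overlap the aging gene set by an exact count, unplanted ones
  are uniform draws (hypergeometric null). The gene universe (default 200)
  is kept several-fold larger than the aging gene set so the enrichment test
  has resolution.

Not emulated: raw fragments/FASTQ, barcodes, genome sequence, Tn5 bias,
batch effects, doublets, spatial structure, and realistic peak-width or
GC–accessibility dependence (GC is independent noise). Passing recovery
tests therefore demonstrates correctness of the statistical machinery under
the stated noise models, not robustness to artefacts absent from the
simulation.

## Problem sizes

Tests and the acceptance script run focused simulations at the scales their
statistics need: 100 replicate composition studies of 24 samples; DA
calibration on 30 pseudobulk samples × 2,000 peaks and recovery on 50 seeds
× 200 peaks; 20-seed AUC studies at 1,000 cells; 30 true + 300 decoy linkage
pairs; 1,000-permutation uniformity checks. The end-to-end study default of
150 cells/sample keeps a full simulate-plus-pipeline run at seconds scale.

## Known limitations

- The LRT on β₁ is asymptotic; at very low pseudobulk counts it is mildly
  liberal. A quasi-likelihood F-test would be the next refinement.
- Entropy specificity uses plain Shannon entropy; a Jensen–Shannon variant
  may rank borderline peaks differently.
- Hypergeometric p-values are discrete; calibration statements pool across
  annotations of varying size, where the mixture is near-uniform. A single
  small annotation has conservative, stepped p-values.
- The composition model treats fractions as unconstrained responses;
  centred-log-ratio compositional models are deliberately out of scope.
- Pairwise age-group contrasts exist behind a flag but the continuous-age
  model is the default and the tested path.
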