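# Methods

This note documents the models, parameter choices and numerical
conventions behind `dspsig`, and what the synthetic-data generators do and
do not emulate.

## Preprocessing model

AOI quality control removes AOIs with fewer than 10,000 raw reads,
sequencing saturation below 50%, or fewer than 5% of target genes with a
nonzero count. All three comparisons are strict in the failing direction
(an AOI at exactly 10,000 reads or 50% saturation is retained). The
detected-gene criterion counts raw nonzero genes by default; a switch
(`qc.gene_frac_above_loq`) exists because "detected" could equally be read
as "above the limit of quantitation".

The limit of quantitation per AOI is the platform convention

    LOQ(aoi) = geomean(neg + ε) · geoSD(neg + ε)²,

a two-geometric-SD floor over the negative-probe background, with
pseudo-count ε = 0.5 guarding zero probe counts. A gene is kept if it
exceeds the LOQ in at least 5% of AOIs (inclusive comparison). The LOQ
formula itself is a stated convention, not something the QC thresholds
pin down; it is configurable.

Q3 normalization divides each AOI by its third quartile over retained
genes and rescales by the geometric mean of all AOIs' third quartiles; it
assumes a large, diverse panel so count distributions are comparable
across AOIs. Quantiles use linear interpolation (the type-7 definition)
everywhere, so independent implementations agree to machine precision.
Two exact consequences are tested: after normalization every AOI's Q3
equals the geometric mean of the input Q3s, and renormalizing a
normalized matrix is a no-op. Note that scaling a single column by c
changes the geometric-mean anchor by c^(1/n); what is invariant is that
columns equal up to scale map to the same normalized column.

Batch harmonization fits, per gene, an ordinary least-squares model with
reference-coded batch indicators plus the preserved biological design
(mask, region, tissue) and subtracts only the fitted batch terms.
Reference coding (first batch untouched) was chosen over sum-to-zero
coding; the two differ per gene by a constant that cancels in every
downstream two-group contrast. A design in which batch is collinear with
the preserved labels is refused. PCA outlier flags (> 4 median absolute
deviations on PC1/PC2) are advisory only — on strongly clustered data a
MAD rule can flag entire biological groups, so nothing is removed
automatically.

The fixed processing order is AOI QC → LOQ gene filter → Q3 → log2(x+1) →
batch removal.

## Mask validation

"Cumulative expression" of a marker program is computed as the per-AOI
mean log2 expression of its genes; its distribution in the matching
mask's AOIs is compared to all other masks with a one-sided two-sample
Kolmogorov–Smirnov test (alternative: matching mask stochastically
greater), BH-adjusted across the signature × mask family. One-sidedness
and the mean aggregation are this package's reading of the
cumulative-distribution comparison; a two-sided alternative is available.
The packaged marker lists are the macrophage (CD68, CD163, FCGR1A,
CSF1R), T-cell (CD3D, CD3E, UBASH3A, CD2, TRBC2) and B-cell (MS4A1,
CD79A, CD79B, CD19, PAX5) panels.

## Differential expression

Duplicate cores — AOIs sharing (patient, mask, region, tissue) — are
collapsed to their per-gene mean on the log2 scale before fitting. This
is a deterministic, slightly conservative alternative to modelling a
consensus intra-patient correlation; for technical replicates the two
approaches target the same estimand.

Each contrast (GC vs IF, LZ vs DZ, RLT vs DLBCL, within one mask) is a
pooled two-group fit: log2FC = mean(A) − mean(B), residual variance s²
with df = n_A + n_B − 2. Region labels do not enter as covariates; all
contrasts are pure two-group comparisons.

The empirical-Bayes prior (d0, s0²) is estimated by matching the first
two moments of log s² to their theoretical scaled-F values using
digamma/trigamma functions, including the bias correction
E[log s²] = log σ² + ψ(df/2) − log(df/2). If the observed spread of
log s² does not exceed what a common variance predicts, the trigamma
inversion has no positive solution and d0 = ∞ with posterior variance
s0² for every gene. Moderated statistics are

    t = log2FC / sqrt(post_var · (1/n_A + 1/n_B)),   df_total = d0 + df,

with the normal limit at d0 = ∞ and the ordinary pooled t-test at d0 = 0.
Zero posterior variance yields p = 0 for nonzero log2FC (with a warning)
and p = 1 otherwise. BH adjustment implements the literal step-up
q₍ᵢ₎ = min_{j≥i}(p₍ⱼ₎·m/j) so that it agrees exactly with a brute-force
oracle.

## Signature derivation

DEGs are selected at BH-adjusted p < 0.05 and |log2FC| > 0.58 (both
strict). Percentile ranks of average Q3-normalized expression are
computed per mask over **all** retained genes (ties averaged, percentile
= rank/n); a candidate gene is removed when its CD20 rank strictly
exceeds its CD68 rank. Ranks use all AOIs of each mask rather than only
shared ROIs. The reactive-tissue signature (derived from whole-region
germinal centres, for which no matching CD20 AOIs exist) skips the
filter. `top_k` ranks by signed log2FC within the signature's direction —
equivalent to |log2FC| ranking — with ties broken by smaller p, then gene
id; the default k = 50 mirrors the module-score convention.

## Scoring, stratification, survival

The patient score sums −log10(pᵢ)·xᵢ·Iᵢ over the union of a paired
up/down signature from one contrast, with pᵢ the raw moderated-t p-value
(weights reflect significance; selection used the adjusted p) and Iᵢ the
fold-change sign. The scale of xᵢ is genuinely open; by default xᵢ is the
gene-wise z-score of log2 expression across the cohort so high-abundance
genes do not dominate, and `standardize=False` evaluates the literal
formula. At least 50% of the pair's genes must be present in the cohort;
absent and (under standardization) zero-variance genes are dropped with a
warning.

Tertile cut points are type-7 quantiles at 1/3 and 2/3; score ≤ q1 → low,
score > q2 → high, boundary ties to the lower group (determinism). The
extreme tertiles are compared with a Cox model on the high-vs-low
indicator (Efron tie handling, Wald 95% CI; lifelines' Newton–Raphson),
the log-rank test, Kaplan–Meier curves with Greenwood variance, and a
score test of scaled Schoenfeld residuals against KM-transformed time as
the PH-assumption check (advisory).

Single-cell utilities follow the standard conventions: cells with fewer
than 200 detected genes or more than 10% mitochondrial counts are
removed, then genes present in fewer than 3 cells; module scores subtract
the mean of expression-matched control genes (25 equal-frequency bins of
mean expression, 100 seeded control draws per signature gene), and a cell
is called "expressing" at score > 0.1.

## Association statistics

Group × category associations use the Fisher exact test on the 2×2
overlap table; the default is the two-sided probability-mass rule, with
the one-tailed hypergeometric available (`association.alternative`) since
enrichment-style questions are one-sided. Overlap ratio =
|group ∩ category| / |category|. Gene-set enrichment is the upper-tail
hypergeometric (P[X ≥ count]) with count and gene ratio
(count / set size within the universe). BH families are one per analysis
run: all group × category pairs, or all gene sets.

## Synthetic data generators

All generators are pure functions of (parameters, seed) built on
`numpy.random.default_rng`; identical inputs give byte-identical outputs.
Counts are negative binomial with variance μ + αμ² (α = `nb_dispersion`,
default 0.1, a typical bulk-RNA value). Gene baselines are lognormal
(median 20 counts, log-sd 1.2); per-AOI size factors lognormal (log-sd
0.3); per-batch gene effects normal on the log2 scale (sd 0.1, two
batches); per-patient gene effects (sd 0.1 log2) are shared by duplicate
cores, which otherwise receive independent noise. The default design has
12 AOIs per (tissue × mask × region) stratum — three masks, four RLT
regions plus region-free DLBCL — and 27% of DLBCL patients contribute
duplicate cores. Mask marker genes are boosted 3 log2 units in their own
mask. Planted DEGs (default 5% of 1,500 genes, split over the three
contrasts and two directions, ±1.5 log2 units) are drawn from genes above
the median baseline so the LOQ filter does not erase the planted signal,
and are applied to CD68 AOIs only (they model macrophage biology); a
fraction of the GC-up genes is additionally boosted in all CD20 AOIs to
emulate B-cell contamination. Negative probes (100, mean ≈ 2 counts)
follow the same NB model. Sequencing saturation is synthesized as
1 − exp(−library/φ) with φ = 20,000 and raw reads as 4× the library size,
so the QC thresholds are exercisable.

Cohorts draw a standard-normal latent activity a per patient, shift each
signature gene by a·sign·lfc on the log2 scale over unit Gaussian noise,
and draw Weibull survival (shape 1.2, scale 24 months) with log hazard =
`hazard_coef`·a. The default hazard_coef = 0.42 corresponds to a true
top-vs-bottom-tertile hazard ratio of ≈ 2.5 (the expected latent gap
between extreme tertiles of a standard normal is 2·3·φ(z₍⅔₎) ≈ 2.18, and
e^(0.42·2.18) ≈ 2.5). Censoring is independent uniform with its upper
bound calibrated by bisection so the expected censoring fraction matches
the target (default 0.3). A cell-of-origin-style label (GCB/ABC/UNC) is
cut from a noisy copy of a.

What the generators do **not** emulate: real DSP count distributions or
probe chemistry, spatial coordinates (the analysis uses region labels
only), gene–gene correlation beyond the planted structure, informative
censoring, or cohort-specific platform effects. Passing tests therefore
demonstrate that the algorithms are implemented correctly and recover
known structure under a realistic noise model — not that any particular
biological result holds in real tissue.

## Problem sizes and runtime choices

The default experiment is 1,500 genes × 180 AOIs, which preprocesses and
fits all three contrasts in about two seconds; recovery checks use 1,200
genes with 20 + 20 AOIs; prognosis checks use 600-patient cohorts over 10
seeds and 60 null seeds (the null-uniformity check is a calibration
smoke-test at that size, not a high-resolution KS study). These sizes
were chosen so the whole suite runs in well under a minute per module
while keeping every Monte-Carlo margin comfortable.

## Known limitations

- Only two-group contrasts are supported; covariate-adjusted DE designs
  are out of scope.
- Fold changes are not shrunk — only variances are moderated.
- Only Efron tie handling is implemented for the Cox model (lifelines
  does not provide Breslow).
- The on-disk TSV schema is this package's own export convention, not a
  vendor format; a documented TSV/MTX schema stands in for proprietary
  DSP exports.
- The percentile-rank contamination filter compares masks over all AOIs;
  restricting to shared ROIs would be a stricter variant.
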