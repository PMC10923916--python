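# dspsig

Spatially-resolved macrophage-signature analysis for GeoMx-style digital
spatial profiling (DSP) data.

In DSP experiments on lymphoid tissue, each region of interest (ROI) is
segmented by immunofluorescence masks into cell-type areas of interest
(AOIs): CD68 (macrophage), CD3 (T cell) and CD20 (B cell). Comparing CD68
AOIs between spatial compartments of reactive lymphoid tissue — germinal
centre (GC) vs interfollicular (IF), light zone (LZ) vs dark zone (DZ) —
and between reactive tissue (RLT) and diffuse large B-cell lymphoma
(DLBCL) yields *macrophage signatures* (MacroSigs): signed, weighted gene
sets that can then be scored in bulk expression cohorts to stratify
patient survival.

`dspsig` implements that full chain as a tested, reusable pipeline:

1. **Preprocessing** — AOI QC (≥10,000 raw reads, ≥50% sequencing
   saturation, ≥5% of genes detected), a negative-probe limit of
   quantitation (LOQ = geomean × geoSD² of negative probes), third-quartile
   (Q3) normalization, log2 transform, linear-model batch harmonization and
   advisory PCA outlier flags.
2. **Mask validation** — one-sided two-sample Kolmogorov–Smirnov tests that
   macrophage/T/B marker programs concentrate in their matching mask.
3. **Differential expression** — two-group moderated *t*-tests with
   empirical-Bayes variance shrinkage (prior estimated by matching the
   moments of log s²) and Benjamini–Hochberg correction, after collapsing
   duplicate cores from the same patient.
4. **Signature derivation** — DEGs at BH *p* < 0.05 and |log₂FC| > 0.58,
   minus candidate genes whose percentile rank of Q3-normalized average
   expression is higher in the CD20 mask than in the CD68 mask (B-cell
   contamination), giving one up- and one down-signature per contrast.
5. **Scoring and survival** — per patient,

   score = Σᵢ −log₁₀(pᵢ) · xᵢ · Iᵢ,

   where pᵢ is gene *i*'s moderated-*t* p-value, Iᵢ = sign(log₂FCᵢ) and xᵢ
   its (by default z-scored) cohort expression; patients are cut into score
   tertiles and the extremes compared by Kaplan–Meier, log-rank and Cox
   proportional hazards (Efron ties), with a Schoenfeld-residual check of
   the PH assumption.
6. **Association statistics** — Fisher exact tests of tertile groups
   against clinical categories (overlap ratio, −log₁₀ adjusted-*p*
   enrichment score) and hypergeometric gene-set enrichment (count, gene
   ratio).
7. **Synthetic data** — negative-binomial DSP generators with planted DEGs,
   batch/size-factor structure, duplicate cores and negative probes, plus
   survival cohorts whose hazard follows a latent signature activity; all
   planted truth is recorded so every stage is testable end to end without
   any external download.

## Worked example

```python
import dspsig as ds

# a synthetic DSP experiment with planted spatial effects
exp = ds.simulate_dsp_experiment(ds.SimParams(seed=1))
exp_f, q3, log2, flags = ds.run_preprocess(exp)

dea = ds.run_dea(log2, exp_f.annotations, "LZ_vs_DZ", mask="CD68")
ranks = ds.percentile_ranks(q3, exp_f.annotation_frame["mask"],
                            which_masks=["CD68", "CD20"])
lz = ds.derive_macrosig("MacroSig3_LZ", "LZ_vs_DZ", dea, "up", ranks)
dz = ds.derive_macrosig("MacroSig4_DZ", "LZ_vs_DZ", dea, "down", ranks)
pair = ds.merge_pair(lz, dz)

cohort = ds.simulate_cohort(ds.SimParams(seed=2, n_patients=600), pair)
scores, info = ds.signature_score(cohort, pair)
strat = ds.tertile_stratify(scores, info=info)
res = ds.compare_extreme_tertiles(strat, cohort.survival)
print(f"{len(lz)} LZ genes, {len(dz)} DZ genes")
print(f"top-vs-bottom tertile HR = {res['cox'].hr:.2f} "
      f"({res['cox'].ci_low:.2f}-{res['cox'].ci_high:.2f}), "
      f"log-rank p = {res['logrank_p']:.2e}")
```

prints

```
12 LZ genes, 12 DZ genes
top-vs-bottom tertile HR = 2.47 (1.92-3.18), log-rank p = 3.82e-13
```

i.e. both sides of the LZ/DZ contrast are recovered from the planted
experiment, and the cohort simulated with a latent-activity hazard
(coefficient 0.42, which corresponds to a true extreme-tertile hazard
ratio of about 2.5) is stratified into tertiles whose extreme groups
differ strongly in overall survival.

The same flow is available from the shell:

```sh
dspsig --seed 7 run                 # full pipeline into ./dspsig_out
dspsig show-config                  # every threshold and its default
dspsig --seed 7 simulate --outdir fixture --preset dsp
```

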