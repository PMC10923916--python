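"""Synthetic DSP experiments, survival cohorts and single-cell matrices.

Every generator is a pure function of its parameters (including the seed)
and records the planted structure in a :class:`SyntheticTruth`, so each
downstream stage can be tested against known ground truth without any
external download.

The count model is negative binomial parameterised by (mean mu, dispersion
alpha) with variance mu + alpha*mu^2 — the standard RNA count model.  The
DSP generator emulates the design of a two-tissue study: reactive lymphoid
tissue (RLT) ROIs carry a spatial region (germinal centre GC, interfollicular
IF, light zone LZ, dark zone DZ), tumour (DLBCL) ROIs do not; each ROI is
segmented into cell-type masks (CD68 macrophage, CD3 T cell, CD20 B cell),
and a configurable fraction of DLBCL patients contribute duplicate cores.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .containers import (
    AOIAnnotation,
    CohortDataset,
    DSPExperiment,
    ExpressionMatrix,
    MacroSig,
    Scale,
    SyntheticTruth,
)

MARKER_GENES = {
    "CD68": ["CD68", "CD163", "FCGR1A", "CSF1R"],
    "CD3": ["CD3D", "CD3E", "UBASH3A", "CD2", "TRBC2"],
    "CD20": ["MS4A1", "CD79A", "CD79B", "CD19", "PAX5"],
}

CONTRASTS = ("GC_vs_IF", "LZ_vs_DZ", "RLT_vs_DLBCL")


def default_aoi_design(aois_per_stratum: int = 12) -> dict[tuple[str, str, str], int]:
    """AOI counts per (tissue, mask, region) stratum for the default study."""
    design = {}
    for mask in ("CD68", "CD3", "CD20"):
        for region in ("GC", "IF", "LZ", "DZ"):
            design[("RLT", mask, region)] = aois_per_stratum
        design[("DLBCL", mask, "NONE")] = aois_per_stratum
    return design


@dataclass
class SimParams:
    """Parameters shared by all generators.

    lfc_magnitude is in log2 units; size_factor_sd, batch_sd and patient_sd
    are log-scale standard deviations; nb_dispersion is the dimensionless
    negative-binomial dispersion alpha in var = mu + alpha*mu^2.
    """

    n_genes: int = 1500
    n_neg_probes: int = 100
    aoi_design: Optional[dict] = None
    n_patients: int = 400
    frac_planted: float = 0.05
    frac_contaminant: float = 0.1
    lfc_magnitude: float = 1.5
    contaminant_lfc: float = 2.0
    marker_lfc: float = 3.0
    nb_dispersion: float = 0.1
    size_factor_sd: float = 0.3
    batch_sd: float = 0.1
    patient_sd: float = 0.1
    n_batches: int = 2
    base_mean: float = 20.0
    base_log_sd: float = 1.2
    neg_probe_mean: float = 2.0
    saturation_phi: float = 20000.0
    reads_per_count: float = 4.0
    duplicate_core_frac: float = 0.27
    censor_frac: float = 0.3
    hazard_coef: float = 0.42
    weibull_shape: float = 1.2
    weibull_scale: float = 24.0
    cohort_noise_sd: float = 1.0
    label_assoc: float = 1.0
    cells_per_cluster: int = 150
    sc_base_mean: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_planted", "frac_contaminant", "censor_frac", "duplicate_core_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not np.isfinite(self.hazard_coef):
            raise ValueError("hazard_coef must be finite")
        if self.aoi_design is None:
            self.aoi_design = default_aoi_design()
        for (tissue, mask, region) in self.aoi_design:
            if tissue == "DLBCL" and region != "NONE":
                raise ValueError(
                    f"aoi_design: regions apply to RLT only, got {region!r} for DLBCL"
                )
            if tissue == "RLT" and region == "NONE":
                raise ValueError("aoi_design: RLT strata require a region")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + alpha*mu^2."""
    r = 1.0 / alpha
    p = 1.0 / (1.0 + alpha * np.asarray(mu, dtype=float))
    return rng.negative_binomial(r, p)


def _gene_ids(params: SimParams) -> tuple[list[str], list[str]]:
    markers = [g for genes in MARKER_GENES.values() for g in genes]
    n_bg = params.n_genes - len(markers)
    if n_bg < 10:
        raise ValueError("n_genes too small for the marker panel")
    background = [f"G{i:05d}" for i in range(1, n_bg + 1)]
    return markers + background, markers


def simulate_dsp_experiment(params: SimParams) -> DSPExperiment:
    """Generate a DSP experiment with planted DEGs and recorded truth.

    Planted effects, per contrast within the CD68 mask:

    * ``GC_vs_IF`` — up genes boosted in (RLT, CD68, GC) AOIs, down genes
      boosted in (RLT, CD68, IF);
    * ``LZ_vs_DZ`` — analogous for LZ / DZ;
    * ``RLT_vs_DLBCL`` — up genes boosted in all RLT CD68 AOIs (uniformly
      across regions, so the within-RLT contrasts stay clean), down genes
      boosted in DLBCL CD68 AOIs.

    A fraction of the GC-upregulated genes is additionally boosted in every
    CD20 AOI: these emulate B-cell transcript contamination and are
    recorded in ``truth.planted_contaminants`` for filter testing.
    """
    rng = np.random.default_rng([params.seed, 101])
    gene_ids, markers = _gene_ids(params)
    n_genes = len(gene_ids)

    base = rng.lognormal(np.log(params.base_mean), params.base_log_sd, n_genes)
    base = pd.Series(base, index=gene_ids)
    for mask_markers in MARKER_GENES.values():
        base[mask_markers] = np.maximum(base[mask_markers], params.base_mean * 2)

    # --- planted DEGs: sampled above the median baseline so the limit of
    # quantitation filter does not silently erase the planted signal
    eligible = [
        g for g in gene_ids if g not in set(markers) and base[g] >= base.median()
    ]
    n_planted_total = int(round(params.frac_planted * n_genes))
    n_per_bucket = n_planted_total // 6
    planted = rng.choice(eligible, size=min(6 * n_per_bucket, len(eligible)), replace=False)
    buckets = np.array_split(planted, 6) if n_per_bucket else [np.array([], dtype=object)] * 6
    planted_up = {c: sorted(map(str, b)) for c, b in zip(CONTRASTS, buckets[:3])}
    planted_down = {c: sorted(map(str, b)) for c, b in zip(CONTRASTS, buckets[3:])}
    planted_lfc = {
        g: params.lfc_magnitude
        for genes in (*planted_up.values(), *planted_down.values())
        for g in genes
    }
    gc_up = planted_up["GC_vs_IF"]
    n_cont = int(round(params.frac_contaminant * len(gc_up)))
    contaminants = sorted(map(str, rng.choice(gc_up, size=n_cont, replace=False))) if n_cont else []

    # --- study layout: ROIs per (tissue, region), segmented into mask AOIs
    batches = [f"B{b + 1}" for b in range(params.n_batches)]
    batch_factors = pd.DataFrame(
        0.0, index=gene_ids, columns=batches
    )
    for b in batches[1:]:
        batch_factors[b] = rng.normal(0.0, params.batch_sd, n_genes)

    strata = sorted(params.aoi_design.items())
    rlt_regions = sorted({r for (t, _, r) in params.aoi_design if t == "RLT"})
    n_rlt_rois = max(
        (n for (t, _, r), n in params.aoi_design.items() if t == "RLT"), default=0
    )
    n_dlbcl_rois = max(
        (n for (t, _, r), n in params.aoi_design.items() if t == "DLBCL"), default=0
    )
    # duplicate cores: n_rois = n_pat*(1-f) + 2*n_pat*f  =>  n_pat = n_rois/(1+f)
    f = params.duplicate_core_frac
    n_dlbcl_pat = max(1, int(round(n_dlbcl_rois / (1.0 + f)))) if n_dlbcl_rois else 0
    dlbcl_roi_patient = []
    pat = 0
    while len(dlbcl_roi_patient) < n_dlbcl_rois:
        dlbcl_roi_patient.append(pat % n_dlbcl_pat)
        pat += 1
        if pat >= n_dlbcl_pat:
            pat = 0  # wrap: earlier patients receive the duplicate cores
    rlt_patients = [f"RLT_P{i + 1:02d}" for i in range(n_rlt_rois)]

    patient_ids = sorted(set(rlt_patients) | {f"DLBCL_P{p + 1:02d}" for p in set(dlbcl_roi_patient)})
    patient_effect = pd.DataFrame(
        rng.normal(0.0, params.patient_sd, (n_genes, len(patient_ids))),
        index=gene_ids,
        columns=patient_ids,
    )

    marker_sets = {m: set(gl) for m, gl in MARKER_GENES.items()}
    up_sets = {c: set(g) for c, g in planted_up.items()}
    down_sets = {c: set(g) for c, g in planted_down.items()}
    cont_set = set(contaminants)

    aoi_rows = []
    mu_cols = []
    for (tissue, mask, region), n_aois in strata:
        for j in range(n_aois):
            if tissue == "RLT":
                roi = f"RLT_{region}_{j + 1:02d}"
                patient = rlt_patients[j % len(rlt_patients)]
            else:
                roi = f"DLBCL_{j + 1:02d}"
                patient = f"DLBCL_P{dlbcl_roi_patient[j] + 1:02d}"
            batch = batches[j % len(batches)]
            lfc = pd.Series(0.0, index=gene_ids)
            lfc[list(marker_sets[mask])] += params.marker_lfc
            # planted spatial effects are macrophage biology: CD68 AOIs only
            if mask == "CD68":
                if tissue == "RLT":
                    if region == "GC":
                        lfc[list(up_sets["GC_vs_IF"])] += params.lfc_magnitude
                    elif region == "IF":
                        lfc[list(down_sets["GC_vs_IF"])] += params.lfc_magnitude
                    elif region == "LZ":
                        lfc[list(up_sets["LZ_vs_DZ"])] += params.lfc_magnitude
                    elif region == "DZ":
                        lfc[list(down_sets["LZ_vs_DZ"])] += params.lfc_magnitude
                    lfc[list(up_sets["RLT_vs_DLBCL"])] += params.lfc_magnitude
                else:
                    lfc[list(down_sets["RLT_vs_DLBCL"])] += params.lfc_magnitude
            if mask == "CD20":
                lfc[list(cont_set)] += params.contaminant_lfc
            lfc += batch_factors[batch] + patient_effect[patient]
            aoi_rows.append(
                dict(tissue=tissue, mask=mask, region=region, roi_id=roi,
                     patient_id=patient, batch=batch)
            )
            mu_cols.append(base.to_numpy() * np.exp2(lfc.to_numpy()))

    n_aoi = len(aoi_rows)
    aoi_ids = [f"AOI{i + 1:04d}" for i in range(n_aoi)]
    size_factors = rng.lognormal(0.0, params.size_factor_sd, n_aoi)
    mu = np.column_stack(mu_cols) * size_factors
    counts = _nb_draw(rng, mu, params.nb_dispersion)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=aoi_ids)

    probe_base = rng.lognormal(np.log(params.neg_probe_mean), 0.3, params.n_neg_probes)
    neg_mu = probe_base[:, None] * size_factors[None, :]
    neg = _nb_draw(rng, neg_mu, params.nb_dispersion)
    neg_df = pd.DataFrame(
        neg,
        index=[f"NegProbe{i + 1:03d}" for i in range(params.n_neg_probes)],
        columns=aoi_ids,
    )

    library = counts_df.sum(axis=0).to_numpy() + neg_df.sum(axis=0).to_numpy()
    raw_reads = np.rint(library * params.reads_per_count).astype(int)
    saturation = 1.0 - np.exp(-library / params.saturation_phi)

    annotations = [
        AOIAnnotation(
            aoi_id=aoi_ids[i],
            roi_id=row["roi_id"],
            patient_id=row["patient_id"],
            tissue=row["tissue"],
            mask=row["mask"],
            region=row["region"],
            batch=row["batch"],
            raw_reads=int(raw_reads[i]),
            saturation=float(min(saturation[i], 1.0)),
        )
        for i, row in enumerate(aoi_rows)
    ]

    truth = SyntheticTruth(
        planted_up=planted_up,
        planted_down=planted_down,
        planted_lfc=planted_lfc,
        planted_contaminants=contaminants,
        batch_factors=batch_factors,
        size_factors=pd.Series(size_factors, index=aoi_ids),
        seeds={"dsp": params.seed},
    )
    return DSPExperiment(
        counts=ExpressionMatrix(counts_df, Scale.COUNTS),
        annotations=annotations,
        neg_probes=neg_df,
        truth=truth,
    )


def _calibrate_uniform_censoring(times: np.ndarray, target: float) -> float:
    """Upper bound c_max of Uniform(0, c_max) censoring giving the target
    expected censoring fraction for the drawn event times (bisection)."""
    if target <= 0:
        return np.inf

    def frac(c_max):
        return float(np.mean(np.minimum(times / c_max, 1.0)))

    lo, hi = 1e-9, float(times.max()) * 2
    while frac(hi) > target:
        hi *= 2
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(params: SimParams, signature: MacroSig) -> CohortDataset:
    """Generate a bulk cohort whose hazard depends on latent signature activity.

    Per patient, latent activity ``a`` is standard normal; each signature
    gene's log2 expression is shifted by ``a * sign * lfc_magnitude`` on top
    of Gaussian noise.  Survival times are Weibull with log hazard
    ``hazard_coef * a``; censoring is independent uniform, calibrated so the
    expected censoring fraction matches ``censor_frac``.  A cell-of-origin
    style label (GCB / ABC / UNC) is assigned with strength ``label_assoc``
    of dependence on ``a``.
    """
    if len(signature) == 0:
        raise ValueError("signature must be non-empty")
    rng = np.random.default_rng([params.seed, 202])
    n = params.n_patients
    patients = [f"P{i + 1:04d}" for i in range(n)]
    sig_genes = signature.genes
    signs = signature.entries["sign"].to_numpy(dtype=float)

    n_bg = max(params.n_genes - len(sig_genes), 50)
    bg_genes = [f"BG{i + 1:05d}" for i in range(n_bg)]
    gene_ids = sig_genes + bg_genes
    mu_g = rng.normal(6.0, 1.0, len(gene_ids))

    a = rng.standard_normal(n)
    expr = mu_g[:, None] + rng.normal(0.0, params.cohort_noise_sd, (len(gene_ids), n))
    expr[: len(sig_genes), :] += signs[:, None] * params.lfc_magnitude * a[None, :]
    expr_df = pd.DataFrame(expr, index=gene_ids, columns=patients)

    # Weibull proportional hazards: S(t) = exp(-(t/scale)^shape * e^{beta a})
    u = rng.uniform(size=n)
    t_event = params.weibull_scale * (
        -np.log(u) * np.exp(-params.hazard_coef * a)
    ) ** (1.0 / params.weibull_shape)
    if params.censor_frac > 0:
        c_max = _calibrate_uniform_censoring(t_event, params.censor_frac)
        c = rng.uniform(0.0, c_max, n)
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)
    time = np.maximum(time, 1e-6)
    survival = pd.DataFrame({"time": time, "event": event}, index=pd.Index(patients, name="patient_id"))

    z = np.sqrt(1.0 + params.label_assoc**2)
    u_lab = params.label_assoc * a + rng.standard_normal(n)
    thr = 0.43073 * z  # tertile cut of the latent label variable
    coo = np.where(u_lab > thr, "ABC", np.where(u_lab < -thr, "GCB", "UNC"))
    labels = pd.DataFrame({"COO": coo}, index=pd.Index(patients, name="patient_id"))

    truth = SyntheticTruth(
        hazard_coef=params.hazard_coef,
        latent_activity=pd.Series(a, index=patients),
        seeds={"cohort": params.seed},
    )
    return CohortDataset(
        expression=ExpressionMatrix(expr_df, Scale.LOG2),
        survival=survival,
        labels=labels,
        truth=truth,
    )


MITO_GENES = [f"MT-{i:03d}" for i in range(1, 11)]


def simulate_single_cell(
    params: SimParams, signatures: list[MacroSig]
) -> tuple[ExpressionMatrix, pd.Series]:
    """Sparse single-cell counts with one overexpressing cluster per signature
    plus one background cluster; includes designated mitochondrial genes."""
    if len(signatures) < 1:
        raise ValueError("need at least one signature (>=2 clusters total)")
    seen: set[str] = set()
    for sig in signatures:
        overlap = seen & set(sig.genes)
        if overlap:
            warnings.warn(
                f"signature gene sets overlap across clusters: {sorted(overlap)[:5]}"
            )
        seen |= set(sig.genes)
    rng = np.random.default_rng([params.seed, 303])
    sig_genes = sorted(seen)
    n_bg = max(params.n_genes - len(sig_genes) - len(MITO_GENES), 50)
    gene_ids = sig_genes + [f"SC{i + 1:05d}" for i in range(n_bg)] + MITO_GENES

    base = rng.lognormal(np.log(params.sc_base_mean), 1.0, len(gene_ids))
    base = pd.Series(base, index=gene_ids)
    base[MITO_GENES] = params.sc_base_mean * 10

    clusters = [s.name for s in signatures] + ["background"]
    cells, labels, cols = [], [], []
    for ci, cname in enumerate(clusters):
        boost = pd.Series(0.0, index=gene_ids)
        if cname != "background":
            boost[signatures[ci].genes] = params.lfc_magnitude
        mu = base.to_numpy() * np.exp2(boost.to_numpy())
        for j in range(params.cells_per_cluster):
            cols.append(f"{cname}_c{j + 1:04d}")
            labels.append(cname)
            cells.append(_nb_draw(rng, mu, params.nb_dispersion))
    counts = pd.DataFrame(np.column_stack(cells), index=gene_ids, columns=cols)
    return (
        ExpressionMatrix(counts, Scale.COUNTS),
        pd.Series(labels, index=cols, name="cluster"),
    )


def make_pathway_sets(truth: SyntheticTruth, rng_seed: int, universe: list[str], n_random: int = 10, random_size: int = 40):
    """Synthetic pathway collection: one set per planted contrast direction
    plus random sets, for exercising gene-set enrichment end to end."""
    from .containers import GeneSignature

    rng = np.random.default_rng([rng_seed, 404])
    sets = []
    for contrast, genes in truth.planted_up.items():
        if genes:
            sets.append(GeneSignature(f"PLANTED_UP_{contrast}", list(genes), "planted up"))
    for contrast, genes in truth.planted_down.items():
        if genes:
            sets.append(GeneSignature(f"PLANTED_DOWN_{contrast}", list(genes), "planted down"))
    for i in range(n_random):
        genes = sorted(map(str, rng.choice(universe, size=min(random_size, len(universe)), replace=False)))
        sets.append(GeneSignature(f"RANDOM_{i + 1:02d}", genes, "random set"))
    return sets
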