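"""AOI/gene quality control, Q3 normalization and harmonization.

The fixed processing order is: AOI QC -> limit-of-quantitation gene filter
-> Q3 normalization -> log2 transform -> batch-effect removal (-> advisory
PCA outlier flags).  Re-running the full chain on its own output is a
no-op.  Every filter logs counts before/after at INFO level.

Quantiles everywhere use linear interpolation (the type-7 definition), so
independent implementations agree bit-for-bit.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DSPExperiment, ExpressionMatrix, Scale, annotations_to_frame

logger = logging.getLogger("dspsig")


@dataclass
class QCThresholds:
    """AOI/gene QC cutoffs.

    Defaults follow the standard whole-transcriptome DSP protocol: drop
    AOIs with fewer than 10,000 raw reads or sequencing saturation below
    50%, or detecting under 5% of target genes; keep genes quantified
    above the limit of quantitation in at least 5% of AOIs.
    """

    min_raw_reads: int = 10000
    min_saturation: float = 0.5
    min_gene_frac: float = 0.05
    loq_detect_frac: float = 0.05
    loq_epsilon: float = 0.5

    def __post_init__(self) -> None:
        if self.min_raw_reads <= 0 or self.min_saturation <= 0:
            raise ValueError("thresholds must be positive")
        for f in (self.min_saturation, self.min_gene_frac, self.loq_detect_frac):
            if not 0 < f <= 1:
                raise ValueError("fractional thresholds must be in (0, 1]")


def filter_aois(exp: DSPExperiment, thr: QCThresholds | None = None) -> DSPExperiment:
    """Drop AOIs failing raw-read, saturation or detected-gene-fraction QC.

    Comparisons are strict in the failing direction: raw_reads < cutoff and
    saturation < cutoff are removed, values exactly at the cutoff retained.
    """
    thr = thr or QCThresholds()
    ann = annotations_to_frame(exp.annotations)
    counts = exp.counts.data
    detected_frac = (counts > 0).mean(axis=0)

    fail_reads = ann["raw_reads"] < thr.min_raw_reads
    fail_sat = ann["saturation"] < thr.min_saturation
    fail_genes = detected_frac.reindex(ann.index) < thr.min_gene_frac
    for name, flags in (
        ("raw_reads", fail_reads),
        ("saturation", fail_sat),
        ("gene_fraction", fail_genes),
    ):
        if flags.any():
            logger.info(
                "filter_aois: %d/%d AOIs fail %s", int(flags.sum()), len(ann), name
            )
    keep = ann.index[~(fail_reads | fail_sat | fail_genes)].tolist()
    logger.info("filter_aois: keeping %d/%d AOIs", len(keep), len(ann))
    if not keep:
        raise ValueError("empty experiment after QC")
    return exp.subset_aois(keep)


def compute_loq(neg_probes: pd.DataFrame, epsilon: float = 0.5) -> pd.Series:
    """Per-AOI limit of quantitation from negative-probe counts.

    LOQ(aoi) = geomean(neg + epsilon) * geoSD(neg + epsilon)^2, the platform
    convention of a two-geometric-SD detection floor above background.
    """
    if neg_probes.shape[0] < 2:
        raise ValueError(
            f"compute_loq: need >=2 negative probes per AOI, got {neg_probes.shape[0]}"
        )
    logs = np.log(neg_probes.to_numpy(dtype=float) + epsilon)
    geo_mean = np.exp(logs.mean(axis=0))
    geo_sd = np.exp(logs.std(axis=0, ddof=1))
    loq = pd.Series(geo_mean * geo_sd**2, index=neg_probes.columns, name="loq")
    if not (loq > 0).all():
        raise ValueError("LOQ must be positive for every AOI")
    return loq


def filter_genes_by_loq(
    exp: DSPExperiment, loq: pd.Series, thr: QCThresholds | None = None
) -> DSPExperiment:
    """Keep genes whose count exceeds the AOI's LOQ in >= loq_detect_frac of AOIs."""
    thr = thr or QCThresholds()
    counts = exp.counts.data
    loq = loq.reindex(counts.columns)
    if loq.isna().any():
        raise ValueError("LOQ table does not cover all AOIs")
    above = counts.gt(loq, axis=1)
    frac = above.mean(axis=1)
    keep = frac.index[frac >= thr.loq_detect_frac].tolist()
    logger.info(
        "filter_genes_by_loq: keeping %d/%d genes (detect frac >= %g)",
        len(keep),
        counts.shape[0],
        thr.loq_detect_frac,
    )
    if not keep:
        raise ValueError("zero genes retained after LOQ filter")
    return exp.subset_genes(keep)


def _q3(values: np.ndarray) -> np.ndarray:
    """Column-wise third quartile, linear-interpolation (type-7) definition."""
    return np.quantile(values, 0.75, axis=0, method="linear")


def q3_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Third-quartile normalization.

    Each AOI's counts are divided by that AOI's Q3 and rescaled by the
    geometric mean of all AOIs' Q3s, so every normalized AOI has Q3 equal
    to that geometric mean.  Assumes a large, diverse panel so count
    distributions are comparable across AOIs.
    """
    if m.scale is not Scale.COUNTS:
        raise ValueError(f"q3_normalize expects counts, got scale={m.scale.value}")
    q3 = _q3(m.values)
    if (q3 <= 0).any():
        bad = [s for s, q in zip(m.sample_ids, q3) if q <= 0]
        raise ValueError(f"q3_normalize: Q3 is zero for AOIs {bad[:5]}")
    geo = np.exp(np.mean(np.log(q3)))
    out = m.data / q3 * geo
    return ExpressionMatrix(out, Scale.Q3_NORMALIZED)


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount) of a Q3-normalized matrix."""
    if m.scale is not Scale.Q3_NORMALIZED:
        raise ValueError(f"log_transform expects q3_normalized, got {m.scale.value}")
    if (m.values < 0).any():
        raise ValueError("log_transform: negative input")
    return ExpressionMatrix(np.log2(m.data + pseudocount), Scale.LOG2)


def remove_batch_effect(
    m: ExpressionMatrix, batch: pd.Series, preserve: pd.DataFrame | pd.Series
) -> ExpressionMatrix:
    """Subtract fitted batch terms from a log2 matrix.

    Per gene, a linear model with reference-coded batch indicators plus the
    preserved biological design (mask, and region/tissue where applicable)
    is fit by least squares, and only the batch terms are subtracted.  The
    reference (first) batch is returned untouched; with a single batch the
    output equals the input.
    """
    if m.scale is not Scale.LOG2:
        raise ValueError("remove_batch_effect operates on the log2 scale")
    samples = m.sample_ids
    batch = pd.Series(batch).reindex(samples)
    if batch.isna().any():
        raise ValueError("batch labels missing for some samples")
    levels = sorted(batch.unique())
    if len(levels) == 1:
        return ExpressionMatrix(m.data.copy(), Scale.LOG2)

    if isinstance(preserve, pd.Series):
        preserve = preserve.to_frame()
    preserve = preserve.reindex(samples)
    design_label = preserve.astype(str).agg("|".join, axis=1)
    x_design = pd.get_dummies(design_label, drop_first=False).to_numpy(dtype=float)
    x_batch = pd.get_dummies(
        pd.Categorical(batch, categories=levels), drop_first=True
    ).to_numpy(dtype=float)
    x = np.hstack([x_design, x_batch])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("confounded design: batch is collinear with preserved labels")

    y = m.values.T  # samples x genes
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    beta_batch = beta[x_design.shape[1]:, :]
    corrected = y - x_batch @ beta_batch
    return ExpressionMatrix(
        pd.DataFrame(corrected.T, index=m.gene_ids, columns=samples), Scale.LOG2
    )


def pca_outlier_flags(m: ExpressionMatrix, k_mads: float = 4.0) -> pd.Series:
    """Advisory outlier flags: AOIs whose PC1 or PC2 coordinate lies more
    than ``k_mads`` median-absolute-deviations from the median.

    The caller decides whether to act on the flags; nothing is removed here.
    """
    if m.shape[1] < 3:
        raise ValueError("pca_outlier_flags: need >=3 AOIs")
    x = m.values.T
    x = x - x.mean(axis=0)
    # PCs via SVD of the centred sample matrix
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    coords = u[:, :2] * s[:2]
    flags = np.zeros(x.shape[0], dtype=bool)
    for j in range(min(2, coords.shape[1])):
        c = coords[:, j]
        med = np.median(c)
        mad = np.median(np.abs(c - med))
        if mad == 0:
            continue
        flags |= np.abs(c - med) > k_mads * mad
    out = pd.Series(flags, index=m.sample_ids, name="pca_outlier")
    if out.any():
        logger.info("pca_outlier_flags: %d/%d AOIs flagged", int(out.sum()), len(out))
    return out


def run_preprocess(
    exp: DSPExperiment,
    thr: QCThresholds | None = None,
    log_pseudocount: float = 1.0,
    preserve_columns: tuple[str, ...] = ("mask", "region", "tissue"),
) -> tuple[DSPExperiment, ExpressionMatrix, ExpressionMatrix, pd.Series]:
    """Full preprocessing chain in the fixed order AOI QC -> LOQ gene filter
    -> Q3 -> log2 -> batch removal; returns (filtered experiment,
    Q3-normalized matrix, harmonized log2 matrix, advisory PCA flags)."""
    thr = thr or QCThresholds()
    exp = filter_aois(exp, thr)
    loq = compute_loq(exp.neg_probes, thr.loq_epsilon)
    exp = filter_genes_by_loq(exp, loq, thr)
    normalized = q3_normalize(exp.counts)
    logged = log_transform(normalized, log_pseudocount)
    ann = exp.annotation_frame
    harmonized = remove_batch_effect(
        logged, ann["batch"], ann[list(preserve_columns)]
    )
    flags = pca_outlier_flags(harmonized)
    return exp, normalized, harmonized, flags
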