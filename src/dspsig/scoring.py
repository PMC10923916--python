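"""Patient-level signature scoring, tertile stratification, and single-cell
module scoring.

The patient score for a paired up/down signature is

    score = sum_i  -log10(p_i) * x_i * I_i

over the union of the pair's genes, where p_i is the gene's moderated-t
p-value from the originating spatial contrast, I_i its fold-change sign
and x_i its expression in the bulk cohort.  By default x_i is the gene-wise
z-score of log2 expression across the cohort, so high-abundance genes do
not dominate; ``standardize=False`` uses the literal expression values.
Patients are split into tertiles of the score and the extreme tertiles
compared downstream.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import (
    CohortDataset,
    ExpressionMatrix,
    MacroSig,
    Scale,
    StratificationResult,
)
from .signatures import merge_pair

logger = logging.getLogger("dspsig")


def signature_score(
    cohort: CohortDataset,
    pair: tuple[MacroSig, MacroSig] | MacroSig,
    standardize: bool = True,
) -> tuple[pd.Series, dict]:
    """Per-patient weighted signature score.

    ``pair`` is (up signature, down signature) from one contrast, or an
    already-merged signature.  At least half of the pair's genes must be
    present in the cohort's expression matrix; absent genes (and, under
    standardization, zero-variance genes) are dropped with a warning.
    Returns (scores, info) where info records genes used and dropped.
    """
    sig = merge_pair(*pair) if isinstance(pair, tuple) else pair
    expr = cohort.expression.data
    genes = sig.genes
    present = [g for g in genes if g in expr.index]
    if len(present) < 0.5 * len(genes):
        missing = sorted(set(genes) - set(present))
        raise ValueError(
            f"only {len(present)}/{len(genes)} signature genes present in cohort "
            f"(need >=50%); missing e.g. {missing[:10]}"
        )
    dropped = sorted(set(genes) - set(present))
    if dropped:
        logger.warning("signature_score: %d genes absent from cohort: %s", len(dropped), dropped[:5])

    x = expr.loc[present]
    if standardize:
        mu = x.mean(axis=1)
        sd = x.std(axis=1, ddof=0)
        flat = sd == 0
        if flat.any():
            zv = x.index[flat].tolist()
            logger.warning(
                "signature_score: dropping %d zero-variance genes: %s", len(zv), zv[:5]
            )
            dropped += zv
            x = x.loc[~flat]
            mu, sd = mu[~flat], sd[~flat]
        x = x.sub(mu, axis=0).div(sd, axis=0)
    used = list(x.index)
    w = sig.entries.loc[used, "weight"].to_numpy()
    signs = sig.entries.loc[used, "sign"].to_numpy()
    scores = pd.Series((w * signs) @ x.to_numpy(), index=x.columns, name="score")
    info = {
        "signature": sig.name,
        "n_genes_used": len(used),
        "genes_dropped": dropped,
    }
    return scores, info


def tertile_stratify(
    scores: pd.Series, signature_pair: tuple[str, str] = ("up", "down"), info: dict | None = None
) -> StratificationResult:
    """Assign patients to score tertiles (type-7 quantile cut points).

    score <= q1/3 -> low, score > q2/3 -> high, else mid; boundary ties go
    to the lower group.
    """
    scores = pd.Series(scores).astype(float)
    if len(scores) < 6:
        raise ValueError(f"tertile_stratify: need >=6 patients, got {len(scores)}")
    if scores.nunique() == 1:
        raise ValueError("degenerate score distribution: all scores identical")
    q1, q2 = np.quantile(scores.to_numpy(), [1 / 3, 2 / 3], method="linear")
    group = np.where(scores <= q1, "low", np.where(scores > q2, "high", "mid"))
    table = pd.DataFrame({"score": scores, "group": group}, index=scores.index)
    info = info or {}
    return StratificationResult(
        table=table,
        signature_pair=signature_pair,
        n_genes_used=int(info.get("n_genes_used", 0)),
        genes_dropped=list(info.get("genes_dropped", [])),
        cutpoints=(float(q1), float(q2)),
    )


def sc_qc_filter(
    cells: ExpressionMatrix,
    mito_gene_ids: list[str],
    min_genes_per_cell: int = 200,
    max_mito_frac: float = 0.1,
    min_cells_per_gene: int = 3,
) -> ExpressionMatrix:
    """Single-cell QC: drop low-quality cells (fewer than 200 detected
    genes or more than 10% mitochondrial counts), then genes detected in
    fewer than 3 cells."""
    counts = cells.data
    mito = [g for g in mito_gene_ids if g in counts.index]
    detected = (counts > 0).sum(axis=0)
    total = counts.sum(axis=0)
    mito_frac = counts.loc[mito].sum(axis=0) / total.replace(0, np.nan) if mito else pd.Series(0.0, index=counts.columns)
    mito_frac = mito_frac.fillna(0.0)
    keep_cells = counts.columns[(detected >= min_genes_per_cell) & (mito_frac <= max_mito_frac)]
    logger.info("sc_qc_filter: keeping %d/%d cells", len(keep_cells), counts.shape[1])
    if len(keep_cells) == 0:
        raise ValueError("all cells removed by QC")
    sub = counts[keep_cells]
    keep_genes = sub.index[(sub > 0).sum(axis=1) >= min_cells_per_gene]
    logger.info("sc_qc_filter: keeping %d/%d genes", len(keep_genes), counts.shape[0])
    return ExpressionMatrix(sub.loc[keep_genes].copy(), cells.scale)


def module_score(
    cells: ExpressionMatrix,
    sig: MacroSig,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
    threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-cell module score with expression-matched controls.

    score(cell) = mean expression of signature genes - mean expression of
    control genes, where each signature gene contributes ``n_ctrl`` control
    genes sampled (seeded) from its average-expression bin (``n_bins``
    equal-frequency bins).  Cells with score > ``threshold`` are called
    "expressing" the signature.
    """
    expr = cells.data
    present = [g for g in sig.genes if g in expr.index]
    if not present:
        raise ValueError(f"module_score: no gene of {sig.name!r} present")
    rng = np.random.default_rng(seed)
    gene_means = expr.mean(axis=1)
    order = gene_means.rank(method="first")
    bins = pd.qcut(order, q=min(n_bins, len(order)), labels=False)
    bin_members = {b: idx.tolist() for b, idx in gene_means.groupby(bins).groups.items()}

    ctrl_genes: list[str] = []
    for g in present:
        members = bin_members[int(bins[g])]
        take = min(n_ctrl, len(members))
        ctrl_genes.extend(rng.choice(members, size=take, replace=False))
    sig_mean = expr.loc[present].mean(axis=0)
    # duplicate control draws across signature genes count with multiplicity
    ctrl_mean = expr.loc[ctrl_genes].mean(axis=0)
    score = sig_mean - ctrl_mean
    return pd.DataFrame(
        {"score": score, "expressing": score > threshold}, index=expr.columns
    )
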