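"""Derivation of signed, significance-weighted macrophage signatures.

Each DE contrast yields two signatures: the genes upregulated in the first
group (sign +1) and those upregulated in the second (sign -1), selected at
BH-adjusted p < 0.05 and |log2FC| > 0.58.  Candidate genes whose
percentile rank of Q3-normalized average expression is higher in the
B-cell (CD20) mask than in the macrophage (CD68) mask are removed as
B-cell transcript contamination — except where no matching CD20 data
exists (the reactive-tissue signature), mirroring the derivation protocol.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats

from .containers import ExpressionMatrix, MacroSig, Scale

logger = logging.getLogger("dspsig")


def select_degs(
    dea: pd.DataFrame, alpha: float = 0.05, lfc_min: float = 0.58
) -> tuple[list[str], list[str]]:
    """Split a DEA table into up / down DEG lists.

    up: adj_p < alpha and log2FC > lfc_min; down: adj_p < alpha and
    log2FC < -lfc_min (both strict)."""
    sig = dea["adj_p"] < alpha
    up = dea.index[sig & (dea["log2fc"] > lfc_min)].tolist()
    down = dea.index[sig & (dea["log2fc"] < -lfc_min)].tolist()
    return up, down


def percentile_ranks(
    m: ExpressionMatrix, masks: pd.Series, which_masks: list[str] | None = None
) -> pd.DataFrame:
    """Per-mask percentile rank of each gene's mean Q3-normalized expression.

    Within each mask, gene means across that mask's AOIs are ranked with
    ties averaged; percentile = rank / n_genes, so values lie in (0, 1].
    """
    if m.scale is not Scale.Q3_NORMALIZED:
        raise ValueError("percentile_ranks expects a Q3-normalized matrix")
    if m.shape[0] < 2:
        raise ValueError("need >=2 genes to rank")
    masks = pd.Series(masks).reindex(m.sample_ids)
    which_masks = which_masks or sorted(masks.dropna().unique())
    out = {}
    for mask in which_masks:
        cols = masks.index[masks == mask].tolist()
        if not cols:
            raise ValueError(f"mask {mask!r} has zero AOIs")
        means = m.data[cols].mean(axis=1)
        ranks = scipy.stats.rankdata(means.to_numpy(), method="average")
        out[mask] = ranks / m.shape[0]
    return pd.DataFrame(out, index=m.gene_ids)


def contamination_filter(
    genes: list[str],
    ranks: pd.DataFrame,
    source_mask: str = "CD68",
    contaminant_mask: str = "CD20",
) -> list[str]:
    """Drop genes whose percentile rank is strictly greater in the
    contaminant mask than in the source mask; order preserved."""
    for mask in (source_mask, contaminant_mask):
        if mask not in ranks.columns:
            raise ValueError(f"percentile ranks missing for mask {mask!r}")
    missing = [g for g in genes if g not in ranks.index]
    if missing:
        raise ValueError(f"genes absent from percentile ranks: {missing[:5]}")
    removed = [
        g for g in genes if ranks.at[g, contaminant_mask] > ranks.at[g, source_mask]
    ]
    if removed:
        logger.info(
            "contamination_filter: removed %d/%d genes with %s rank > %s rank: %s",
            len(removed),
            len(genes),
            contaminant_mask,
            source_mask,
            removed[:10],
        )
    dropped = set(removed)
    return [g for g in genes if g not in dropped]


def derive_macrosig(
    name: str,
    contrast: str,
    dea: pd.DataFrame,
    direction: str = "up",
    ranks: pd.DataFrame | None = None,
    apply_filter: bool = True,
    alpha: float = 0.05,
    lfc_min: float = 0.58,
    source_mask: str = "CD68",
    contaminant_mask: str = "CD20",
) -> MacroSig:
    """Build one signed, weighted signature from a DEA table.

    ``direction='up'`` takes the genes upregulated in the contrast's first
    group (sign +1); ``'down'`` the downregulated ones (sign -1).  The
    contamination filter is applied unless ``apply_filter`` is False (the
    exemption used when no matching B-cell mask data exists).
    """
    up, down = select_degs(dea, alpha=alpha, lfc_min=lfc_min)
    genes = up if direction == "up" else down
    n_before = len(genes)
    if apply_filter:
        if ranks is None:
            raise ValueError("apply_filter=True requires percentile ranks")
        genes = contamination_filter(genes, ranks, source_mask, contaminant_mask)
    if not genes:
        raise ValueError(
            f"MacroSig {name!r} is empty: {n_before} DEGs selected "
            f"({direction}), {n_before - len(genes)} removed by the contamination filter"
        )
    sub = dea.loc[genes]
    entries = pd.DataFrame(
        {
            "weight": -np.log10(np.maximum(sub["p"], np.finfo(float).tiny)),
            "sign": np.where(sub["log2fc"] > 0, 1, -1),
            "log2fc": sub["log2fc"],
            "p": sub["p"],
            "adj_p": sub["adj_p"],
        },
        index=sub.index,
    ).sort_index()
    return MacroSig(name=name, contrast=contrast, entries=entries)


def top_k(sig: MacroSig, k: int = 50) -> MacroSig:
    """Keep the k entries with the largest log2 fold change (descending for
    up-signatures, i.e. by signed |log2FC| within the signature's
    direction), ties broken by smaller p then gene id."""
    if len(sig) == 0:
        raise ValueError("top_k: empty signature")
    e = sig.entries.copy()
    e["_gene"] = e.index
    # up-signatures sort log2fc descending; down-signatures ascending
    # (most negative = strongest), equivalent to |log2FC| descending.
    ascending = bool((e["sign"] < 0).all())
    e = e.sort_values(
        by=["log2fc", "p", "_gene"], ascending=[ascending, True, True], kind="mergesort"
    )
    e = e.drop(columns="_gene").head(min(k, len(e)))
    return MacroSig(name=sig.name, contrast=sig.contrast, entries=e)


def merge_pair(up_sig: MacroSig, down_sig: MacroSig) -> MacroSig:
    """Union of a paired up/down signature from the same contrast, used for
    patient-level scoring (signs are carried through)."""
    if up_sig.contrast != down_sig.contrast:
        raise ValueError(
            f"paired signatures must share a contrast "
            f"({up_sig.contrast!r} vs {down_sig.contrast!r})"
        )
    overlap = set(up_sig.genes) & set(down_sig.genes)
    if overlap:
        raise ValueError(f"paired signatures overlap: {sorted(overlap)[:5]}")
    entries = pd.concat([up_sig.entries, down_sig.entries]).sort_index()
    return MacroSig(
        name=f"{up_sig.name}+{down_sig.name}",
        contrast=up_sig.contrast,
        entries=entries,
    )


def derive_all_macrosigs(
    dea_tables: dict[str, pd.DataFrame],
    ranks: pd.DataFrame | None,
    unfiltered_signatures: tuple[str, ...] = ("MacroSig5_RLT",),
    alpha: float = 0.05,
    lfc_min: float = 0.58,
) -> dict[str, MacroSig]:
    """Six signatures from the three contrasts; the reactive-tissue
    signature skips the contamination filter (no matching CD20 AOIs exist
    for whole-region germinal centres)."""
    names = {
        ("GC_vs_IF", "up"): "MacroSig1_GC",
        ("GC_vs_IF", "down"): "MacroSig2_IF",
        ("LZ_vs_DZ", "up"): "MacroSig3_LZ",
        ("LZ_vs_DZ", "down"): "MacroSig4_DZ",
        ("RLT_vs_DLBCL", "up"): "MacroSig5_RLT",
        ("RLT_vs_DLBCL", "down"): "MacroSig6_DLBCL",
    }
    out = {}
    for (contrast, direction), name in names.items():
        if contrast not in dea_tables:
            continue
        apply_filter = name not in unfiltered_signatures
        out[name] = derive_macrosig(
            name,
            contrast,
            dea_tables[contrast],
            direction=direction,
            ranks=ranks,
            apply_filter=apply_filter,
            alpha=alpha,
            lfc_min=lfc_min,
        )
    return out
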