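"""Two-group differential expression with empirical-Bayes variance moderation.

Per gene a pooled two-group contrast is fit on the log2 scale; residual
variances are shrunk toward a common prior estimated by matching the first
two moments of log(s^2) to the theoretical log-F moments (the classic
moderated-t construction), and two-sided p-values come from a t
distribution with d0 + df degrees of freedom.  Duplicate cores (AOIs
sharing patient, mask, region and tissue) are collapsed to their per-gene
mean beforehand — a deterministic, conservative alternative to
consensus-correlation GLS for technical replicates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import digamma, polygamma

from .containers import AOIAnnotation, ExpressionMatrix, Scale, annotations_to_frame

logger = logging.getLogger("dspsig")

# contrast name -> (group A selector, group B selector) on annotation frames;
# all contrasts are evaluated within a single mask (CD68 by default).
CONTRAST_GROUPS = {
    "GC_vs_IF": (
        lambda ann: (ann["tissue"] == "RLT") & (ann["region"] == "GC"),
        lambda ann: (ann["tissue"] == "RLT") & (ann["region"] == "IF"),
    ),
    "LZ_vs_DZ": (
        lambda ann: (ann["tissue"] == "RLT") & (ann["region"] == "LZ"),
        lambda ann: (ann["tissue"] == "RLT") & (ann["region"] == "DZ"),
    ),
    "RLT_vs_DLBCL": (
        lambda ann: ann["tissue"] == "RLT",
        lambda ann: ann["tissue"] == "DLBCL",
    ),
}


@dataclass
class EBPrior:
    """Empirical-Bayes prior on gene-wise variances."""

    d0: float  # prior degrees of freedom, may be inf
    s0_sq: float  # prior variance, (log2 units)^2

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be >= 0")
        if self.s0_sq <= 0:
            raise ValueError("s0_sq must be > 0")


def collapse_duplicates(
    m: ExpressionMatrix, annotations: list[AOIAnnotation]
) -> tuple[ExpressionMatrix, list[AOIAnnotation]]:
    """Average duplicate AOIs (same patient, mask, region, tissue) on the
    log2 scale; the merged AOI keeps the shared annotation keys."""
    ann = annotations_to_frame(annotations).loc[m.sample_ids]
    key = ann[["patient_id", "mask", "region", "tissue"]].astype(str).agg("|".join, axis=1)
    if key.is_unique:
        return m, annotations
    merged_cols, merged_ann = {}, []
    for k, members in key.groupby(key).groups.items():
        members = list(members)
        first = next(a for a in annotations if a.aoi_id == members[0])
        if len(members) == 1:
            merged_cols[first.aoi_id] = m.data[members[0]]
            merged_ann.append(first)
        else:
            new_id = f"merged_{k.replace('|', '_')}"
            merged_cols[new_id] = m.data[members].mean(axis=1)
            merged_ann.append(
                AOIAnnotation(
                    aoi_id=new_id,
                    roi_id=new_id,
                    patient_id=first.patient_id,
                    tissue=first.tissue,
                    mask=first.mask,
                    region=first.region,
                    batch=first.batch,
                    raw_reads=first.raw_reads,
                    saturation=first.saturation,
                )
            )
    logger.info(
        "collapse_duplicates: %d AOIs -> %d after merging duplicate cores",
        m.shape[1],
        len(merged_cols),
    )
    out = ExpressionMatrix(pd.DataFrame(merged_cols, index=m.gene_ids), m.scale)
    return out, merged_ann


def fit_group_contrast(
    m: ExpressionMatrix, groups: pd.Series
) -> pd.DataFrame:
    """Per-gene two-group fit: log2FC = mean(A) - mean(B), pooled residual
    variance and df = n_A + n_B - 2.  ``groups`` is a two-level label
    series over sample ids; the lexicographically *last* level is taken as
    A unless the series is an ordered categorical, in which case the last
    category is A.  Pass labels via :func:`contrast_labels` to get the
    contrast's natural orientation."""
    groups = pd.Series(groups).reindex(m.sample_ids).dropna()
    levels = (
        list(groups.cat.categories)
        if isinstance(groups.dtype, pd.CategoricalDtype)
        else sorted(groups.unique())
    )
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    level_b, level_a = levels
    idx_a = groups.index[groups == level_a]
    idx_b = groups.index[groups == level_b]
    n_a, n_b = len(idx_a), len(idx_b)
    if n_a < 2 or n_b < 2:
        raise ValueError(f"each group needs >=2 samples (got {n_a} vs {n_b})")
    xa = m.data[idx_a].to_numpy()
    xb = m.data[idx_b].to_numpy()
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    df = n_a + n_b - 2
    s_sq = ss / df
    return pd.DataFrame(
        {
            "log2fc": mean_a - mean_b,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "s_sq": s_sq,
            "df": df,
            "n_a": n_a,
            "n_b": n_b,
        },
        index=m.gene_ids,
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if y <= 0:
            y = 1e-8
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def eb_shrink_variances(
    s_sq: pd.Series, df: float | pd.Series
) -> tuple[EBPrior, pd.Series]:
    """Estimate the variance prior (d0, s0^2) by method of moments on
    log variances and return posterior variances
    (d0*s0^2 + df*s^2) / (d0 + df).

    If the trigamma inversion has no positive solution (observed spread of
    log s^2 no larger than expected under a common variance), d0 is
    infinite and every posterior variance equals s0^2.
    """
    s_sq = pd.Series(s_sq).astype(float)
    df_ser = pd.Series(df, index=s_sq.index) if np.isscalar(df) else pd.Series(df).reindex(s_sq.index)
    ok = df_ser >= 1
    if int(ok.sum()) < 10:
        raise ValueError("eb_shrink_variances: need >=10 genes with df >= 1")
    if (s_sq[ok] == 0).all():
        raise ValueError("degenerate variances: all s^2 are zero")

    # moments of log(s^2): E[log s^2] = log(s0^2) + digamma(df/2) - log(df/2)
    # (+ prior terms); var picks up trigamma(df/2) + trigamma(d0/2)
    s_use = s_sq[ok].to_numpy()
    d_use = df_ser[ok].to_numpy(dtype=float)
    tiny = np.finfo(float).tiny
    e = np.log(np.maximum(s_use, tiny)) - digamma(d_use / 2.0) + np.log(d_use / 2.0)
    e_mean = e.mean()
    n = len(e)
    e_var = ((e - e_mean) ** 2).sum() / (n - 1) - float(np.mean(polygamma(1, d_use / 2.0)))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    prior = EBPrior(d0=d0, s0_sq=s0_sq)

    if np.isinf(d0):
        post = pd.Series(s0_sq, index=s_sq.index)
    else:
        post = (d0 * s0_sq + df_ser * s_sq) / (d0 + df_ser)
    return prior, post


def moderated_t_test(
    contrast: pd.DataFrame, prior: EBPrior, post_var: pd.Series
) -> pd.DataFrame:
    """Moderated t statistics and two-sided p-values.

    t = log2FC / sqrt(post_var * (1/n_A + 1/n_B)), referred to a t
    distribution with d0 + df degrees of freedom (standard normal when d0
    is infinite).
    """
    post_var = pd.Series(post_var).reindex(contrast.index)
    inv_n = 1.0 / contrast["n_a"] + 1.0 / contrast["n_b"]
    se = np.sqrt(post_var * inv_n)
    lfc = contrast["log2fc"]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    zero = se == 0
    if zero.any():
        logger.warning(
            "moderated_t_test: %d genes with zero posterior variance; "
            "p set to 0 (nonzero log2FC) or 1",
            int(zero.sum()),
        )
        fallback = np.where(lfc != 0, np.inf * np.sign(lfc), 0.0)
        t = t.where(~zero, fallback)
    df_total = prior.d0 + contrast["df"]
    if np.isinf(prior.d0):
        p = 2.0 * scipy.stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * scipy.stats.t.sf(np.abs(t), df_total)
    p = np.where(zero, np.where(lfc != 0, 0.0, 1.0), p)
    out = contrast.copy()
    out["t_mod"] = t
    out["p"] = p
    out["df_total"] = df_total
    out["adj_p"] = bh_adjust(out["p"])
    return out


def bh_adjust(p) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1 and returned in the
    original order.
    """
    arr = np.asarray(p, dtype=float)
    if arr.size and (np.isnan(arr).any() or arr.min() < 0 or arr.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if arr.size == 0:
        adj = arr
    else:
        m = arr.size
        order = np.argsort(arr, kind="stable")
        ranked = arr[order] * m / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = np.minimum(stepped, 1.0)
    if isinstance(p, pd.Series):
        return pd.Series(adj, index=p.index)
    return adj


def contrast_labels(
    annotations: list[AOIAnnotation] | pd.DataFrame,
    contrast: str,
    mask: str = "CD68",
) -> pd.Series:
    """Two-level ordered label series (B first, A last) selecting the AOIs
    of a named contrast within one mask."""
    if contrast not in CONTRAST_GROUPS:
        raise ValueError(f"unknown contrast {contrast!r} (choose from {sorted(CONTRAST_GROUPS)})")
    ann = annotations if isinstance(annotations, pd.DataFrame) else annotations_to_frame(annotations)
    ann = ann[ann["mask"] == mask]
    sel_a, sel_b = CONTRAST_GROUPS[contrast]
    name_a, name_b = contrast.split("_vs_")
    labels = pd.Series(pd.NA, index=ann.index, dtype=object)
    labels[sel_b(ann)] = name_b
    labels[sel_a(ann)] = name_a
    labels = labels.dropna()
    return pd.Series(
        pd.Categorical(labels, categories=[name_b, name_a], ordered=True),
        index=labels.index,
    )


def run_dea(
    m: ExpressionMatrix,
    annotations: list[AOIAnnotation],
    contrast: str,
    mask: str = "CD68",
) -> pd.DataFrame:
    """Duplicate collapse + contrast fit + EB moderation for one named
    contrast within one mask; returns the full per-gene DEA table."""
    if m.scale is not Scale.LOG2:
        raise ValueError("run_dea expects a log2 matrix")
    collapsed, merged_ann = collapse_duplicates(m, annotations)
    labels = contrast_labels(merged_ann, contrast, mask)
    sub = collapsed.subset(samples=[s for s in collapsed.sample_ids if s in labels.index])
    fit = fit_group_contrast(sub, labels)
    prior, post = eb_shrink_variances(fit["s_sq"], fit["df"].iloc[0])
    return moderated_t_test(fit, prior, post)
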