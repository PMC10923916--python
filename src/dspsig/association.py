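"""Category association and gene-set enrichment statistics.

Patient-group vs clinical-category associations use the Fisher exact test
on 2x2 overlap tables; gene-set enrichment uses the one-tailed
hypergeometric test.  Both report BH-adjusted p-values across the full
family of tests in a run, overlap/gene ratios as defined for the dot-plot
displays, and an enrichment score -log10(adjusted p).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .containers import GeneSignature
from .dea import bh_adjust

logger = logging.getLogger("dspsig")


@dataclass
class AssociationResult:
    group: str
    category: str
    overlap: int
    overlap_ratio: float  # |group & category| / |category|
    odds_ratio: float
    p: float
    adj_p: float = float("nan")
    enrichment_score: float = float("nan")


def fisher_association(
    group_members: set,
    category_members: set,
    universe: set,
    alternative: str = "two-sided",
) -> AssociationResult:
    """Fisher exact test of one group-category overlap within a universe.

    ``two-sided`` uses the probability-mass rule (sum of tables as or less
    probable than observed); ``greater`` gives the one-tailed
    hypergeometric upper tail used for enrichment-style questions.
    """
    group = set(group_members)
    category = set(category_members)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not group <= universe or not category <= universe:
        raise ValueError("group and category must be subsets of the universe")
    a = len(group & category)
    b = len(group - category)
    c = len(category - group)
    d = len(universe) - a - b - c
    _, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
    ratio = a / len(category) if category else np.nan
    return AssociationResult(
        group="",
        category="",
        overlap=a,
        overlap_ratio=ratio,
        odds_ratio=float(odds),
        p=float(p),
    )


def associate(
    groups: dict[str, set],
    categories: dict[str, set],
    universe: set,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """All group x category Fisher tests, BH-adjusted as one family.

    enrichment_score = -log10(adjusted p).
    """
    rows = []
    for gname, g in sorted(groups.items()):
        for cname, c in sorted(categories.items()):
            res = fisher_association(g, c, universe, alternative=alternative)
            res.group, res.category = gname, cname
            rows.append(res)
    df = pd.DataFrame([vars(r) for r in rows])
    df["adj_p"] = bh_adjust(df["p"].to_numpy())
    df["enrichment_score"] = -np.log10(np.maximum(df["adj_p"], np.finfo(float).tiny))
    return df


def geneset_enrichment(
    sig_genes: set,
    genesets: list[GeneSignature],
    universe: set,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each gene set.

    Per set: count = |signature & set|, gene ratio = count / |set within
    universe|, upper-tail hypergeometric p (P[X >= count]), BH across sets.
    Sets disjoint from the universe are skipped with a warning.
    """
    universe = set(universe)
    sig = set(sig_genes)
    if not sig <= universe:
        raise ValueError("signature genes must be contained in the universe")
    n_u, n_sig = len(universe), len(sig)
    rows = []
    for gs in genesets:
        members = set(gs.genes) & universe
        if not members:
            logger.warning("geneset_enrichment: %s disjoint from universe; skipped", gs.name)
            continue
        count = len(sig & members)
        # X ~ Hypergeom(N=n_u, K=|members|, n=n_sig); upper tail includes count
        p = float(scipy.stats.hypergeom.sf(count - 1, n_u, len(members), n_sig))
        rows.append(
            {
                "gene_set": gs.name,
                "count": count,
                "set_size": len(members),
                "gene_ratio": count / len(members),
                "p": p,
            }
        )
    if not rows:
        raise ValueError("no gene set overlaps the universe")
    df = pd.DataFrame(rows).set_index("gene_set")
    df["adj_p"] = bh_adjust(df["p"].to_numpy())
    return df
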