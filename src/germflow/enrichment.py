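"""Introgressed-gene extraction and hypergeometric pathway enrichment.

A gene is "introgressed" when it overlaps a candidate region by at least one
base. Over-representation of a pathway among introgressed genes is tested
with the upper-tail hypergeometric probability (R's ``phyper`` with
``lower.tail=FALSE`` shifted by one), and q-values come from
Benjamini-Hochberg step-up adjustment across pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_core import GeneTable, RegionSet


def genes_overlapping_regions(genes: GeneTable, regions: RegionSet) -> set[str]:
    """Gene ids overlapping any region by >= 1 bp (half-open intervals)."""
    hits: set[str] = set()
    df = genes.df
    for chrom, grp in df.groupby("chrom"):
        for _, row in grp.iterrows():
            if regions.overlap_length(str(chrom), int(row.start), int(row.end)) > 0:
                hits.add(row.gene_id)
    return hits


def hypergeom_upper_tail(k: int, K: int, n: int, Nb: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(Nb, K, n).

    k = introgressed genes in the pathway, K = background genes in the
    pathway, n = introgressed genes, Nb = background universe size.
    """
    if not (0 <= k <= min(K, n)) or K > Nb or n > Nb:
        raise ValueError(
            f"inconsistent counts: k={k}, K={K}, n={n}, Nb={Nb}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, Nb, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EnrichmentRow:
    pathway_id: str
    pathway_name: str
    k: int
    K: int
    n: int
    Nb: int
    p_value: float
    q_value: float
    significant: bool


def enrich(
    regions: RegionSet,
    genes: GeneTable,
    annotation: pd.DataFrame,
    alpha: float = 0.05,
    universe: str = "genome",
) -> pd.DataFrame:
    """Pathway over-representation among genes overlapping ``regions``.

    ``annotation`` needs columns ``gene_id`` and ``pathway_id`` (optional
    ``pathway_name``). ``universe`` chooses the background: every gene in the
    gene table (``"genome"``) or only annotated genes (``"annotated"``).
    Returns one row per pathway with k >= 1 introgressed genes, sorted by
    q-value.
    """
    required = {"gene_id", "pathway_id"}
    if missing := required - set(annotation.columns):
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    if universe not in ("genome", "annotated"):
        raise ValueError("universe must be 'genome' or 'annotated'")

    all_genes = set(genes.df["gene_id"])
    ann = annotation[annotation["gene_id"].isin(all_genes)]
    background = all_genes if universe == "genome" else set(ann["gene_id"])
    intro = genes_overlapping_regions(genes, regions) & background
    if not intro:
        warnings.warn("no introgressed genes; enrichment table is empty")
        return _empty_table()

    Nb, n = len(background), len(intro)
    names = (
        ann.drop_duplicates("pathway_id").set_index("pathway_id")["pathway_name"]
        if "pathway_name" in ann.columns
        else pd.Series(dtype=object)
    )
    rows = []
    for pathway_id, members in ann.groupby("pathway_id")["gene_id"]:
        member_set = set(members) & background
        k = len(member_set & intro)
        if k == 0:
            continue
        K = len(member_set)
        rows.append(
            {
                "pathway_id": pathway_id,
                "pathway_name": names.get(pathway_id, pathway_id),
                "k": k,
                "K": K,
                "n": n,
                "Nb": Nb,
                "p_value": hypergeom_upper_tail(k, K, n, Nb),
            }
        )
    if not rows:
        return _empty_table()
    table = pd.DataFrame(rows)
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    table["significant"] = table["q_value"] < alpha
    return table.sort_values("q_value", kind="mergesort").reset_index(drop=True)


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "pathway_id", "pathway_name", "k", "K", "n", "Nb",
            "p_value", "q_value", "significant",
        ]
    )
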