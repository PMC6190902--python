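"""Genes near reproducibly significant markers, and gene-set
overrepresentation.

Markers detected in both of two independent analyses are intersected; genes
whose bodies lie within a window (default 1 Mb) of any common marker form the
query; each gene set in a GMT collection is tested for overrepresentation of
query genes with the one-sided hypergeometric upper tail, and p-values are
Benjamini-Hochberg adjusted across the collection.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneAnnotation, GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 1_000_000


def intersect_condition_markers(set_a, set_b) -> set:
    """Markers detected under both conditions."""
    return set(set_a) & set(set_b)


def genes_near_markers(
    markers,
    marker_map: pd.DataFrame,
    ann: GeneAnnotation,
    window_bp: int = DEFAULT_WINDOW_BP,
    mode: str = "body",
) -> set:
    """Genes within ``window_bp`` of any marker.

    ``mode="body"`` (default): the gene interval [start, end] intersects
    [pos - window_bp, pos + window_bp], boundaries inclusive, same chromosome.
    ``mode="tss"``: the gene start must fall inside the window.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if mode not in ("body", "tss"):
        raise ValueError(f"unknown mode {mode!r}")
    markers = list(markers)
    missing = [m for m in markers if m not in marker_map.index]
    if missing:
        raise ValueError(f"markers absent from map: {missing[:5]}")
    hits: set = set()
    t = ann.table
    for chrom, grp in marker_map.loc[markers].groupby("chrom", sort=False):
        genes = t[t["chrom"] == str(chrom)]
        if genes.empty:
            continue
        gs = genes["start"].to_numpy()
        ge = genes["end"].to_numpy()
        for pos in grp["bp"].to_numpy():
            lo, hi = pos - window_bp, pos + window_bp
            if mode == "body":
                sel = (gs <= hi) & (ge >= lo)
            else:
                sel = (gs >= lo) & (gs <= hi)
            hits.update(genes.loc[sel, "gene"])
    return hits


def enrich(
    query,
    collection: GeneSetCollection,
    universe,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of ``query`` in each gene set.

    Sets are intersected with the universe before testing.  Returns a frame
    ordered by p with columns set, overlap, set_size, query_size,
    universe_size, p, q (Benjamini-Hochberg across the collection).
    """
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValueError("empty query gene set; nothing to enrich")
    if not query <= universe:
        raise ValueError(
            f"query genes outside universe: {sorted(query - universe)[:5]}")
    N = len(universe)
    q = len(query)
    rows = []
    for name, members in collection.sets.items():
        in_universe = members & universe
        if not in_universe:
            continue
        k = len(in_universe & query)
        K = len(in_universe)
        # upper tail: P(overlap >= k) drawing q from N with K marked
        p = float(stats.hypergeom.sf(k - 1, N, K, q))
        rows.append((name, k, K, q, N, p))
    if not rows:
        raise ValueError("no gene set intersects the universe")
    df = pd.DataFrame(rows, columns=["set", "overlap", "set_size",
                                     "query_size", "universe_size", "p"])
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df = df.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    logger.info("enrichment: %d sets tested, %d with q < 0.05",
                len(df), int((df["q"] < 0.05).sum()))
    return df


__all__ = ["intersect_condition_markers", "genes_near_markers", "enrich",
           "DEFAULT_WINDOW_BP"]
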