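"""Positional gene annotation around significant markers and over-representation.

A gene is reported for a marker when its 1-based inclusive interval
intersects the symmetric window ``[position - window, position + window]``
on the same chromosome (window default 250 kb each side, strand ignored).
The resulting gene list can be tested for term over-representation with an
upper-tail hypergeometric test and Benjamini-Hochberg adjustment over a
user-supplied GMT term map.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneRecord, genes_to_frame

HIT_COLUMNS = [
    "snp_id", "gene_id", "gene_name", "chromosome", "gene_start", "gene_end",
    "distance_bp",
]


def genes_near_markers(
    markers: pd.DataFrame,
    genes: Sequence[GeneRecord] | pd.DataFrame,
    window: int = 250_000,
):
    """Genes whose span intersects the +/-window interval of each marker.

    Parameters
    ----------
    markers:
        DataFrame with ``snp_id, chromosome, position`` (the significant
        markers — all outliers, or signature peaks only).
    genes:
        list of :class:`GeneRecord` or an equivalent DataFrame.
    window:
        bp each side of the marker, inclusive at both edges.

    Returns
    -------
    (hits, unique_gene_ids):
        *hits* has one row per (marker, gene) pair with the signed distance
        from marker to the nearest gene edge (0 when the gene spans the
        marker, negative when the gene lies upstream i.e. before the marker).
        *unique_gene_ids* deduplicates genes in order of first appearance.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    gene_df = genes if isinstance(genes, pd.DataFrame) else genes_to_frame(genes)
    rows = []
    by_chrom = {c: g for c, g in gene_df.groupby("chromosome")}
    for rec in markers.itertuples(index=False):
        sub = by_chrom.get(rec.chromosome)
        if sub is None:
            continue
        start = sub["start"].to_numpy()
        end = sub["end"].to_numpy()
        hit = (start <= rec.position + window) & (end >= rec.position - window)
        for _, g in sub.loc[hit].iterrows():
            if g["start"] <= rec.position <= g["end"]:
                dist = 0
            elif g["end"] < rec.position:
                dist = int(g["end"] - rec.position)  # upstream: negative
            else:
                dist = int(g["start"] - rec.position)
            rows.append(
                (rec.snp_id, g["gene_id"], g["gene_name"], int(rec.chromosome),
                 int(g["start"]), int(g["end"]), dist)
            )
    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    unique_gene_ids = list(dict.fromkeys(hits["gene_id"])) if len(hits) else []
    return hits, unique_gene_ids


def read_gmt(path) -> dict:
    """Parse a GMT file into ``{term_id: (description, set_of_gene_ids)}``."""
    terms = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path} line {lineno}: GMT rows need term, description, >=1 gene")
            terms[fields[0]] = (fields[1], set(g for g in fields[2:] if g))
    return terms


def hypergeometric_enrichment(
    query_genes: Iterable[str],
    term_map: Mapping[str, tuple],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test with BH adjustment.

    For each term with at least one query hit, the p-value is the
    probability of drawing >= k term members when sampling ``n = |query|``
    genes from a universe of ``N`` containing ``K`` term members.  Term
    members outside the universe are ignored.  Terms with zero hits are
    excluded from testing and from the BH family.  Results are sorted by
    adjusted p, then raw p, then term id.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query_genes)
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")
    n = len(query)
    N = len(universe)
    rows = []
    for term_id in sorted(term_map):
        name, members = term_map[term_id]
        members = set(members) & universe
        k = len(query & members)
        if k == 0:
            continue
        K = len(members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, name, k, n, K, N, min(p, 1.0)))
    result = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "n", "K", "N", "p_value"]
    )
    if len(result):
        result["p_adjusted"] = multipletests(result["p_value"], method="fdr_bh")[1]
        result = result.sort_values(
            ["p_adjusted", "p_value", "term_id"], kind="stable"
        ).reset_index(drop=True)
    else:
        result["p_adjusted"] = pd.Series(dtype=float)
    return result
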