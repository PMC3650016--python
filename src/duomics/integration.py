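"""Protein–transcript integration: matching, fold-change correlation, overlap.

Proteins are linked to transcripts through protein-vs-nucleotide alignment
statistics.  An alignment qualifies only if all three filters hold:
E-value < 1e-15, mismatch percentage <= 6, and alignment length >= 30 amino
acids.  Each protein keeps a single best qualifying hit (lowest E-value,
ties broken by longest alignment, then lexicographic transcript id).  Linked
pairs carry both log2 fold changes; their agreement is summarised by the
Pearson correlation, and the transcript/protein significance overlap by a
2x2 table tested with Yates-corrected chi-squared.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, pearsonr

__all__ = [
    "E_VALUE_MAX",
    "MISMATCH_PCT_MAX",
    "ALN_LEN_MIN",
    "match_filter",
    "pearson_r",
    "yates_chi2",
    "OverlapTable",
    "build_links",
]

E_VALUE_MAX = 1e-15
MISMATCH_PCT_MAX = 6.0
ALN_LEN_MIN = 30


def match_filter(
    e_value,
    mismatch_pct,
    aln_len_aa,
    e_value_max: float = E_VALUE_MAX,
    mismatch_pct_max: float = MISMATCH_PCT_MAX,
    aln_len_min: int = ALN_LEN_MIN,
):
    """True where an alignment passes all three matching criteria; vectorises."""
    e_value = np.asarray(e_value, dtype=float)
    mismatch_pct = np.asarray(mismatch_pct, dtype=float)
    aln_len_aa = np.asarray(aln_len_aa)
    ok = (e_value < e_value_max) & (mismatch_pct <= mismatch_pct_max) & (aln_len_aa >= aln_len_min)
    return bool(ok) if ok.ndim == 0 else ok


def pearson_r(x, y) -> float:
    """Sample Pearson correlation of two equal-length sequences (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant coordinate")
    return float(pearsonr(x, y).statistic)


class OverlapTable(NamedTuple):
    """2x2 significance overlap: a = both, b = protein-only, c = transcript-only, d = neither."""

    a: int
    b: int
    c: int
    d: int


def yates_chi2(table: OverlapTable) -> tuple[float, float]:
    """Yates continuity-corrected chi-squared statistic and p (1 df) for a 2x2 table."""
    obs = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("chi-squared undefined with a zero margin")
    res = chi2_contingency(obs, correction=True)
    return float(res.statistic), float(res.pvalue)


def build_links(
    proteins: pd.DataFrame,
    dge: pd.DataFrame,
    alignments: pd.DataFrame,
    transcript_alpha: float = 0.05,
) -> tuple[pd.DataFrame, OverlapTable, float | None]:
    """Link each quantified protein to its best matching transcript.

    Parameters
    ----------
    proteins
        run_proteome output (protein_id, mean_ratio, p_value, call).
    dge
        run_dge output (gene_id, log2_ratio, p_value, call).
    alignments
        Validated alignment-statistics table.
    transcript_alpha
        "Same expression pattern" p cutoff applied to the transcript's exact
        test when scoring significance overlap.

    Returns
    -------
    (links, overlap, r): one row per protein with a qualifying alignment,
    sorted by protein_id; the 2x2 significance OverlapTable over those links;
    the Pearson correlation of the paired log2 fold changes, or None when it
    cannot be computed (fewer than 3 finite pairs, or a constant coordinate).
    """
    passing = alignments[
        match_filter(
            alignments["e_value"], alignments["mismatch_pct"], alignments["aln_len_aa"]
        )
    ]
    best = (
        passing.sort_values(
            ["protein_id", "e_value", "aln_len_aa", "transcript_id"],
            ascending=[True, True, False, True],
            kind="mergesort",
        )
        .groupby("protein_id", sort=True)
        .head(1)
    )

    prot = proteins.set_index("protein_id")
    genes = dge.set_index("gene_id")
    rows = []
    for rec in best.itertuples(index=False):
        if rec.protein_id not in prot.index or rec.transcript_id not in genes.index:
            continue
        p_row = prot.loc[rec.protein_id]
        g_row = genes.loc[rec.transcript_id]
        protein_fc = math.log2(p_row["mean_ratio"])
        mrna_fc = float(g_row["log2_ratio"])
        prot_sig = p_row["call"] != "not_significant"
        mrna_sig = (not math.isnan(g_row["p_value"])) and g_row["p_value"] < transcript_alpha
        concordant = bool(
            prot_sig and mrna_sig and protein_fc * mrna_fc > 0
        )
        rows.append(
            (rec.protein_id, rec.transcript_id, protein_fc, mrna_fc,
             True, concordant, prot_sig, mrna_sig)
        )
    links = pd.DataFrame(
        rows,
        columns=[
            "protein_id", "transcript_id", "protein_log2fc", "mrna_log2fc",
            "passed_filter", "concordant", "protein_significant", "mrna_significant",
        ],
    )

    if len(links):
        a = int((links["protein_significant"] & links["mrna_significant"]).sum())
        b = int((links["protein_significant"] & ~links["mrna_significant"]).sum())
        c = int((~links["protein_significant"] & links["mrna_significant"]).sum())
        d = int((~links["protein_significant"] & ~links["mrna_significant"]).sum())
    else:
        a = b = c = d = 0
    overlap = OverlapTable(a, b, c, d)

    finite = links[
        np.isfinite(links.get("protein_log2fc", pd.Series(dtype=float)))
        & np.isfinite(links.get("mrna_log2fc", pd.Series(dtype=float)))
    ] if len(links) else links
    r: float | None
    try:
        r = pearson_r(finite["protein_log2fc"], finite["mrna_log2fc"]) if len(finite) >= 3 else None
    except ValueError:
        r = None
    return links, overlap, r
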