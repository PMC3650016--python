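"""Hypergeometric over-representation analysis of GO terms / KEGG pathways.

For a term annotated to M of the N items in the annotated universe, with m of
the n differentially expressed items carrying the term, the enrichment
p-value is the exact upper tail P(X >= m) of the hypergeometric distribution
(population N, successes M, draws n).  Two reporting conventions coexist in
practice and both are supported: Bonferroni-corrected p <= alpha (typical for
GO term reports) and raw p <= alpha (typical for KEGG pathway tables);
selected via ``correction``.  The universe is always an explicit caller input
— it is never inferred from the annotation map.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom

__all__ = ["hypergeom_upper_tail", "bonferroni", "run_enrichment"]


def hypergeom_upper_tail(big_n: int, small_n: int, big_m: int, small_m: int) -> float:
    """P(X >= small_m) for X ~ Hypergeometric(N=big_n, M=big_m, n=small_n)."""
    if not (0 <= big_m <= big_n and 0 <= small_n <= big_n):
        raise ValueError("need 0 <= big_m <= big_n and 0 <= small_n <= big_n")
    if not (0 <= small_m <= min(small_n, big_m)):
        raise ValueError("need 0 <= small_m <= min(small_n, big_m)")
    return float(hypergeom.sf(small_m - 1, big_n, big_m, small_n))


def bonferroni(p: float, n_tests: int) -> float:
    """Bonferroni-adjusted p-value min(1, p * n_tests)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p * n_tests)


def run_enrichment(
    de_items: Iterable[str],
    annotation: pd.DataFrame,
    universe: Iterable[str],
    alpha: float = 0.05,
    correction: str = "bonferroni",
    namespace: str | None = None,
) -> pd.DataFrame:
    """Enrichment of every annotated term hit by at least one DE item.

    Parameters
    ----------
    de_items
        Differentially expressed identifiers; must be a subset of *universe*.
    annotation
        Validated annotation map (gene_id, term_id, namespace); rows outside
        the universe are ignored.
    universe
        The annotated expressed background set (defines N).
    alpha
        Significance threshold in (0, 1).
    correction
        'bonferroni' — flag terms with Bonferroni-adjusted p <= alpha;
        'none' — flag on the raw p (the pathway-table convention).
    namespace
        Optionally restrict to 'GO' or 'KEGG' annotation rows.

    Returns a DataFrame sorted ascending by p_value (term_id tie-break) with
    columns term_id, namespace, big_n, small_n, big_m, small_m, p_value,
    p_bonferroni, significant.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    universe = set(universe)
    de = set(de_items)
    if not universe:
        raise ValueError("universe is empty")
    if not de <= universe:
        raise ValueError("de_items must be a subset of the universe")

    ann = annotation
    if namespace is not None:
        ann = ann[ann["namespace"] == namespace]
    ann = ann[ann["gene_id"].isin(universe)]

    big_n = len(universe)
    small_n = len(de)
    rows = []
    for (term, ns), sub in ann.groupby(["term_id", "namespace"], sort=True):
        members = set(sub["gene_id"])
        small_m = len(members & de)
        if small_m == 0:
            continue
        big_m = len(members)
        p = hypergeom_upper_tail(big_n, small_n, big_m, small_m)
        rows.append((term, ns, big_n, small_n, big_m, small_m, p))
    out = pd.DataFrame(
        rows,
        columns=["term_id", "namespace", "big_n", "small_n", "big_m", "small_m", "p_value"],
    )
    n_tests = max(len(out), 1)
    out["p_bonferroni"] = [bonferroni(p, n_tests) for p in out["p_value"]]
    flag_col = "p_bonferroni" if correction == "bonferroni" else "p_value"
    out["significant"] = out[flag_col] <= alpha
    return out.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
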