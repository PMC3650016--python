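"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the code paths they check: exact
rational arithmetic (fractions / math.comb) for the Poisson-exact and
hypergeometric probabilities, and a literal transcription of the step-up
definition for BH-FDR.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest


# ------------------------------------------------------------------ oracles

def ac_exact(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Exact rational p(y|x) = (n2/n1)^y (x+y)! / (x! y! (1+n2/n1)^(x+y+1))."""
    r = Fraction(n2, n1)
    return r**y * math.comb(x + y, y) / (1 + r) ** (x + y + 1)


def ac_pvalue_exact(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Two-sided p by exact finite tail sums: 2*min(P(Y<=y), P(Y>=y)), capped at 1.

    P(Y>=y) = 1 - P(Y<=y-1); both tails are exact rationals.
    """
    lower = sum(ac_exact(x, yy, n1, n2) for yy in range(0, y + 1))
    upper = 1 - sum(ac_exact(x, yy, n1, n2) for yy in range(0, y))
    return min(Fraction(1), 2 * min(lower, upper))


def hypergeom_exact(big_n: int, small_n: int, big_m: int, small_m: int) -> Fraction:
    """Exact P(X >= small_m) by integer-arithmetic pmf summation."""
    denom = math.comb(big_n, small_n)
    total = 0
    for m in range(small_m, min(small_n, big_m) + 1):
        if small_n - m > big_n - big_m:
            continue
        total += math.comb(big_m, m) * math.comb(big_n - big_m, small_n - m)
    return Fraction(total, denom)


def bh_stepup_bruteforce(p: np.ndarray) -> np.ndarray:
    """Literal BH step-up definition: adj_(i) = min_{j>=i} min(1, n*p_(j)/j)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(n)
    for i in range(n):
        adj_sorted[i] = min(min(1.0, n * p[order[j]] / (j + 1)) for j in range(i, n))
    out = np.empty(n)
    out[order] = adj_sorted
    return out


# ------------------------------------------------------------------ fixtures

@pytest.fixture()
def small_counts() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3"],
            "count_s": [10, 0, 250],
            "count_r": [12, 5, 1000],
            "length_nt": [500, 1200, 2000],
        }
    )


@pytest.fixture()
def annotation_small() -> pd.DataFrame:
    rows = []
    for g in [f"g{i}" for i in range(1, 21)]:
        rows.append((g, "koALL", "KEGG"))
    for g in ["g1", "g2", "g3", "g4"]:
        rows.append((g, "ko0001", "KEGG"))
    for g in ["g5", "g6"]:
        rows.append((g, "GO:0001", "GO"))
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "namespace"])
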