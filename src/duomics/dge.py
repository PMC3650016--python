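"""Exact Poisson two-library differential expression (Audic–Claverie test).

Each gene's read count is modelled as Poisson; conditioning on the count x
observed in the first library, the probability of observing y reads in a
second library of relative depth r = n2/n1 under equal expression is

    p(y | x) = r**y * (x + y)! / (x! * y! * (1 + r)**(x + y + 1)),

which is the negative binomial pmf NB(k = y; size = x + 1, p = n1/(n1+n2)).
That identity gives exact tail probabilities through the regularized
incomplete beta function rather than explicit term-by-term summation.  The
two-sided p-value doubles the smaller tail (cap at 1).  Genes are called
up-/down-regulated when the BH-adjusted p (FDR) and the log2 RPKM ratio both
clear their thresholds — the screen's defaults are FDR <= 0.001 and
|log2 ratio| >= 1.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import nbinom
from statsmodels.stats.multitest import multipletests

from .metrics import LibraryStats

__all__ = [
    "ac_probability",
    "ac_pvalue_two_sided",
    "bh_fdr",
    "call_regulation",
    "run_dge",
    "FDR_THRESHOLD",
    "MIN_ABS_LOG2",
]

FDR_THRESHOLD = 0.001
MIN_ABS_LOG2 = 1.0


def _check_counts(x, y, n1, n2) -> None:
    if np.any(np.asarray(x) < 0) or np.any(np.asarray(y) < 0):
        raise ValueError("counts must be >= 0")
    if np.any(np.asarray(n1) < 1) or np.any(np.asarray(n2) < 1):
        raise ValueError("library totals must be >= 1")


def ac_probability(x, y, n1, n2):
    """Conditional probability p(y | x) of equal expression across two libraries.

    Computed in log space with log-gamma; vectorises over arrays.
    """
    _check_counts(x, y, n1, n2)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    log_r = np.log(np.asarray(n2, dtype=float)) - np.log(np.asarray(n1, dtype=float))
    log_1pr = np.logaddexp(0.0, log_r)
    logp = (
        y * log_r
        + gammaln(x + y + 1.0)
        - gammaln(x + 1.0)
        - gammaln(y + 1.0)
        - (x + y + 1.0) * log_1pr
    )
    out = np.exp(logp)
    return float(out) if out.ndim == 0 else out


def ac_pvalue_two_sided(x, y, n1, n2):
    """Two-sided exact p-value: 2 * min(P(Y <= y | x), P(Y >= y | x)), capped at 1.

    Tails are those of NB(size = x + 1, p = n1/(n1+n2)), evaluated exactly.
    """
    _check_counts(x, y, n1, n2)
    x = np.asarray(x)
    y = np.asarray(y)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p_success = n1 / (n1 + n2)
    lower = nbinom.cdf(y, x + 1, p_success)
    upper = nbinom.sf(y - 1, x + 1, p_success)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return float(p) if np.ndim(p) == 0 else p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_regulation(
    log2_ratio: float,
    fdr: float,
    min_abs_log2: float = MIN_ABS_LOG2,
    max_fdr: float = FDR_THRESHOLD,
) -> str:
    """'up' / 'down' / 'not_significant' at the configured thresholds (inclusive)."""
    if math.isnan(log2_ratio):
        raise ValueError("log2_ratio is NaN")
    if math.isnan(fdr):
        return "not_significant"
    if fdr <= max_fdr and log2_ratio >= min_abs_log2:
        return "up"
    if fdr <= max_fdr and log2_ratio <= -min_abs_log2:
        return "down"
    return "not_significant"


def run_dge(
    counts: pd.DataFrame,
    libstats: tuple[LibraryStats, LibraryStats] | None = None,
    fdr_threshold: float = FDR_THRESHOLD,
    min_abs_log2: float = MIN_ABS_LOG2,
    rpkm_denominator: str = "mapped",
) -> pd.DataFrame:
    """Run the exact test on a two-library count table.

    Parameters
    ----------
    counts
        Validated count table (gene_id, count_s, count_r, length_nt).
    libstats
        Optional (susceptible, resistant) library accounting.  The test
        conditions on the total clean-read counts (n1, n2); the log2 ratio
        uses RPKMs whose denominator is selected by *rpkm_denominator*.
        When omitted, both default to the realized column sums.
    fdr_threshold, min_abs_log2
        Call thresholds (inclusive).
    rpkm_denominator
        'mapped' (default), 'total' or 'unique'.

    Returns
    -------
    DataFrame sorted by gene_id with columns gene_id, x, y, n1, n2,
    log2_ratio, p_value, fdr, call.  Genes with zero counts in both
    libraries are not testable: their p_value/fdr are NaN and the call is
    'not_significant'.  A gene with exactly one zero count gets a +/-inf
    log2_ratio and remains eligible for calling.
    """
    if libstats is not None:
        stats_s, stats_r = libstats
        n1, n2 = stats_s.total_reads, stats_r.total_reads
        denom_s = stats_s.denominator(rpkm_denominator)
        denom_r = stats_r.denominator(rpkm_denominator)
    else:
        n1 = int(counts["count_s"].sum())
        n2 = int(counts["count_r"].sum())
        denom_s, denom_r = n1, n2
    if min(n1, n2) < 1:
        raise ValueError("library totals must be >= 1")

    df = counts.sort_values("gene_id", kind="mergesort").reset_index(drop=True)
    x = df["count_s"].to_numpy()
    y = df["count_r"].to_numpy()

    # log2 of the RPKM ratio; gene length cancels, only the depth scaling stays
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_ratio = (np.log2(y / denom_r) - np.log2(x / denom_s)).astype(float)

    testable = (x > 0) | (y > 0)
    p = np.full(len(df), np.nan)
    p[testable] = ac_pvalue_two_sided(x[testable], y[testable], n1, n2)
    fdr = np.full(len(df), np.nan)
    if testable.any():
        fdr[testable] = bh_fdr(p[testable])

    calls = [
        call_regulation(lr, q, min_abs_log2, fdr_threshold) if t else "not_significant"
        for lr, q, t in zip(np.where(testable, log2_ratio, 0.0), fdr, testable)
    ]
    return pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "x": x,
            "y": y,
            "n1": n1,
            "n2": n2,
            "log2_ratio": np.where(testable, log2_ratio, 0.0),
            "p_value": p,
            "fdr": fdr,
            "call": calls,
        }
    )
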