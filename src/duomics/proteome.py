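"""iTRAQ protein quantification from reporter-ion spectrum ratios.

A protein observed in N spectra has N reporter-ion ratios (treated sample
over control label).  Ratios are multiplicative, so they are aggregated on
the log scale: the protein ratio is the geometric mean and the differential
test is a one-sample t-test of the log-ratios against zero (the
confidence-interval construction around the geometric mean that an "error
factor" encodes).  A protein is called up-/down-regulated when the mean
ratio clears the 1.2 / 0.8-fold gates and p <= 0.05 (all inclusive).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

__all__ = ["protein_ratio", "protein_pvalue", "call_protein", "run_proteome"]

UP_FOLD = 1.2
DOWN_FOLD = 0.8
ALPHA = 0.05


def _log_ratios(ratios) -> np.ndarray:
    arr = np.asarray(ratios, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one spectrum ratio")
    if np.any(arr <= 0):
        raise ValueError("spectrum ratios must be > 0")
    return np.log(arr)


def protein_ratio(ratios) -> float:
    """Geometric mean of a protein's spectrum ratios."""
    return float(np.exp(_log_ratios(ratios).mean()))


def protein_pvalue(ratios) -> float:
    """Two-sided one-sample t p-value of the log-ratios against 0.

    Returns NaN for a single spectrum (variance undefined; such a protein is
    reported but never called significant).  Zero spread with a non-zero mean
    is reported as the smallest positive float rather than exactly 0.
    """
    logs = _log_ratios(ratios)
    n = logs.size
    if n < 2:
        return float("nan")
    mean = logs.mean()
    sd = logs.std(ddof=1)
    if sd == 0.0:
        return 1.0 if mean == 0.0 else math.ulp(0.0)
    t = mean / (sd / math.sqrt(n))
    return float(2.0 * t_dist.sf(abs(t), n - 1))


def call_protein(
    mean_ratio: float,
    p: float,
    up_fold: float = UP_FOLD,
    down_fold: float = DOWN_FOLD,
    alpha: float = ALPHA,
) -> str:
    """'up' / 'down' / 'not_significant' at the fold and p thresholds (inclusive)."""
    if math.isnan(mean_ratio):
        raise ValueError("mean_ratio is NaN")
    if math.isnan(p):
        return "not_significant"
    if p <= alpha and mean_ratio >= up_fold:
        return "up"
    if p <= alpha and mean_ratio <= down_fold:
        return "down"
    return "not_significant"


def run_proteome(
    spectra: pd.DataFrame,
    up_fold: float = UP_FOLD,
    down_fold: float = DOWN_FOLD,
    alpha: float = ALPHA,
    exclude_shared: bool = False,
) -> pd.DataFrame:
    """Aggregate a spectrum-ratio table into per-protein quantifications.

    *spectra* needs columns protein_id, spectrum_id, ratio; an optional
    boolean is_shared column marks peptides shared between protein isoforms,
    dropped when *exclude_shared* is set.  Returns one row per protein,
    sorted by protein_id: n_spectra, mean_ratio, sd_log, p_value, call.
    """
    df = spectra
    if exclude_shared and "is_shared" in df.columns:
        df = df[~df["is_shared"].astype(bool)]
    rows = []
    for pid, sub in df.groupby("protein_id", sort=True):
        ratios = sub["ratio"].to_numpy()
        mean_ratio = protein_ratio(ratios)
        p = protein_pvalue(ratios)
        sd_log = float(np.log(ratios).std(ddof=1)) if ratios.size > 1 else float("nan")
        rows.append(
            (pid, ratios.size, mean_ratio, sd_log, p,
             call_protein(mean_ratio, p, up_fold, down_fold, alpha))
        )
    return pd.DataFrame(
        rows, columns=["protein_id", "n_spectra", "mean_ratio", "sd_log", "p_value", "call"]
    )
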