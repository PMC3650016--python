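"""Relative qPCR quantification (2^-ddCt) and enzyme-activity statistics.

qPCR side: target-gene Ct values are normalised to a composite internal
reference (the mean Ct of the endogenous control genes, e.g. EF-1a and
beta-actin, i.e. the geometric mean of their linear quantities), giving dCt
per sample; the fold change of the resistant sample relative to the
susceptible calibrator is 2^-(dCt_r - dCt_s).  Replicates are paired across
samples in replicate order and tested with a paired t-test.

Enzyme side: GST activity is the least-squares slope of the OD340 kinetic
trace per mg protein; P450 O-demethylation (PNOD) activity inverts a linear
p-nitrophenol standard curve at OD405.  Strain summaries follow the usual
agricultural-statistics layout: mean +/- SE, ratio vs the susceptible
strain, one-way ANOVA and protected Fisher-LSD letters (strains sharing a
letter are not significantly different at alpha).
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy.stats import f_oneway, t as t_dist, ttest_rel

from ._round import round_half_up

__all__ = [
    "composite_reference",
    "ddct_fold",
    "analyze_plate",
    "fit_kinetic_slope",
    "gst_activity",
    "pnod_activity",
    "strain_ratios",
    "anova_lsd",
]


# --------------------------------------------------------------------------- qPCR

def composite_reference(ct_refs) -> float:
    """Composite-reference Ct: arithmetic mean of the reference-gene Ct values."""
    arr = np.asarray(ct_refs, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one reference gene")
    return float(arr.mean())


def ddct_fold(ct_target_r: float, ref_r: float, ct_target_s: float, ref_s: float) -> float:
    """Fold change 2^-ddCt with ddCt = (Ct_target,r - ref_r) - (Ct_target,s - ref_s)."""
    ddct = (ct_target_r - ref_r) - (ct_target_s - ref_s)
    return float(2.0 ** (-ddct))


def _significance_code(p: float) -> str:
    if math.isnan(p):
        return "ns"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def analyze_plate(
    plate: pd.DataFrame,
    targets: list[str] | None = None,
    calibrator: str = "TH-S",
    treated: str = "TH-2000",
) -> pd.DataFrame:
    """Per-target relative expression from a Ct plate.

    *plate* is a validated Ct table (sample, replicate, gene_id,
    is_reference, ct).  Reference genes are the rows flagged is_reference;
    replicates are paired across the two samples by replicate number.
    Returns one row per target: fold (2^-mean ddCt, i.e. the geometric mean
    of per-replicate folds), se (of the per-replicate folds), p_paired
    (paired t-test of dCt across samples) and significance code
    (* p<0.05, ** p<0.01).
    """
    refs = plate[plate["is_reference"]]
    if refs.empty:
        raise ValueError("plate contains no reference-gene rows")
    ref_ct = refs.groupby(["sample", "replicate"])["ct"].apply(composite_reference)

    if targets is None:
        targets = sorted(plate.loc[~plate["is_reference"], "gene_id"].unique())

    rows = []
    for gene in targets:
        sub = plate[(plate["gene_id"] == gene) & (~plate["is_reference"])]
        dct = {}
        for sample in (calibrator, treated):
            s = sub[sub["sample"] == sample].set_index("replicate")["ct"]
            dct[sample] = s - ref_ct.loc[sample].reindex(s.index)
        common = sorted(set(dct[calibrator].index) & set(dct[treated].index))
        if len(common) < 2:
            raise ValueError(f"target {gene!r}: need >= 2 paired replicates")
        dct_s = dct[calibrator].loc[common].to_numpy()
        dct_r = dct[treated].loc[common].to_numpy()
        ddct = dct_r - dct_s
        folds = 2.0 ** (-ddct)
        fold = float(2.0 ** (-ddct.mean()))
        se = float(folds.std(ddof=1) / math.sqrt(len(folds)))
        if ddct.std(ddof=1) == 0.0:
            # degenerate paired differences: identical plates -> p=1,
            # a constant non-zero shift -> below machine floor
            p = 1.0 if ddct.mean() == 0.0 else math.ulp(0.0)
        else:
            p = float(ttest_rel(dct_r, dct_s).pvalue)
        rows.append((gene, fold, se, p, _significance_code(p)))
    return pd.DataFrame(rows, columns=["gene_id", "fold", "se", "p_paired", "significant_code"])


# ------------------------------------------------------------------- enzyme assays

def fit_kinetic_slope(times_min, ods) -> float:
    """Least-squares slope (OD per minute) of a kinetic absorbance trace."""
    times_min = np.asarray(times_min, dtype=float)
    ods = np.asarray(ods, dtype=float)
    if times_min.size < 2 or np.ptp(times_min) == 0:
        raise ValueError("need >= 2 distinct time points")
    return float(np.polyfit(times_min, ods, 1)[0])


def gst_activity(slope_od_per_min: float, protein_mg: float) -> float:
    """GST specific activity: kinetic OD340 slope normalised per mg protein."""
    if protein_mg <= 0:
        raise ValueError("protein_mg must be > 0")
    return slope_od_per_min / protein_mg


def pnod_activity(od405: float, std_curve, protein_mg: float = 1.0) -> float:
    """Product amount from a linear p-nitrophenol standard curve at OD405.

    *std_curve* is a sequence of (concentration, od) points; the
    least-squares line od = a + b*conc is inverted at *od405* and the
    result normalised per mg protein.
    """
    if protein_mg <= 0:
        raise ValueError("protein_mg must be > 0")
    pts = np.asarray(std_curve, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or np.ptp(pts[:, 0]) == 0:
        raise ValueError("need >= 2 standard points with distinct concentrations")
    b, a = np.polyfit(pts[:, 0], pts[:, 1], 1)
    scale = max(1.0, float(np.abs(pts[:, 1]).max()))
    if abs(b) <= 1e-12 * scale:
        raise ValueError("flat standard curve cannot be inverted")
    return float((od405 - a) / b / protein_mg)


def strain_ratios(assay: pd.DataFrame, reference_strain: str = "TH-S") -> dict[str, float]:
    """Mean activity of each strain over the reference strain, half-up to 3 dp."""
    means = assay.groupby("strain")["value"].mean()
    if reference_strain not in means.index:
        raise ValueError(f"reference strain {reference_strain!r} absent")
    ref = means[reference_strain]
    if ref == 0:
        raise ValueError("reference strain mean is zero")
    return {strain: round_half_up(m / ref, 3) for strain, m in means.items()}


def _lsd_pairwise_p(mi, mj, ni, nj, mse, df_error) -> float:
    se = math.sqrt(mse * (1.0 / ni + 1.0 / nj))
    if se == 0:
        return 1.0 if mi == mj else 0.0
    t = abs(mi - mj) / se
    return float(2.0 * t_dist.sf(t, df_error))


def _letters_from_runs(names_sorted: list[str], nonsig: dict) -> dict[str, str]:
    # maximal runs of mutually non-different groups in descending-mean order
    k = len(names_sorted)
    runs = []
    for i in range(k):
        j = i
        while j + 1 < k and all(nonsig[frozenset((names_sorted[a], names_sorted[j + 1]))]
                                for a in range(i, j + 1)):
            j += 1
        runs.append((i, j))
    # keep only maximal runs
    maximal = [r for r in runs if not any(o != r and o[0] <= r[0] and r[1] <= o[1] for o in runs)]
    letters: dict[str, str] = {n: "" for n in names_sorted}
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for idx, (i, j) in enumerate(maximal):
        for pos in range(i, j + 1):
            letters[names_sorted[pos]] += alphabet[idx]
    return letters


def anova_lsd(assay: pd.DataFrame, alpha: float = 0.05):
    """One-way ANOVA with protected Fisher-LSD letter grouping.

    Returns (summary, f_stat, p_anova): *summary* has one row per strain in
    descending-mean order with mean, se, n, and the LSD grouping letter
    (strains sharing a letter do not differ at *alpha*; pairwise LSD tests
    use the pooled mean-square error and are only consulted when the ANOVA
    itself is significant).
    """
    groups = {s: sub["value"].to_numpy(dtype=float) for s, sub in assay.groupby("strain")}
    if len(groups) < 2 or any(g.size < 2 for g in groups.values()):
        raise ValueError("need >= 2 strains with >= 2 replicates each")
    names = sorted(groups, key=lambda s: -groups[s].mean())
    values = [groups[n] for n in names]
    n_total = sum(v.size for v in values)
    df_error = n_total - len(values)
    mse = sum((v.size - 1) * v.var(ddof=1) for v in values) / df_error

    all_equal_means = len({v.mean() for v in values}) == 1
    if mse == 0 and all_equal_means:
        f_stat, p_anova = float("nan"), 1.0
    else:
        res = f_oneway(*values)
        f_stat, p_anova = float(res.statistic), float(res.pvalue)

    nonsig = {}
    for a, b in itertools.combinations(names, 2):
        if p_anova > alpha or math.isnan(p_anova):
            p_pair = 1.0  # protected LSD: no pairwise claims without a significant ANOVA
        else:
            p_pair = _lsd_pairwise_p(
                groups[a].mean(), groups[b].mean(), groups[a].size, groups[b].size, mse, df_error
            )
        nonsig[frozenset((a, b))] = p_pair > alpha
    letters = _letters_from_runs(names, nonsig)

    summary = pd.DataFrame(
        {
            "strain": names,
            "mean": [groups[n].mean() for n in names],
            "se": [groups[n].std(ddof=1) / math.sqrt(groups[n].size) for n in names],
            "n": [groups[n].size for n in names],
            "letter": [letters[n] for n in names],
        }
    )
    return summary, f_stat, p_anova
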