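"""Synthetic two-condition omics data with known ground truth.

Every generator is a pure function of (config, seed): independent
deterministic substreams are derived from the single global seed, so the
same configuration always yields the same tables, and all outputs pass the
io-layer schema validation.

What is emulated
----------------
* ``simulate_counts`` — two unreplicated count libraries of (possibly
  unequal) depth.  Per-gene relative abundances are log-uniform over a
  configurable dynamic range; counts are Poisson around depth x abundance,
  matching the sampling model the exact test assumes.  A designated
  fraction of genes is truly differential, with the resistant-library
  concentration scaled by 2^(+/-effect_log2).  An optional over-dispersion
  knob (gamma-mixed Poisson) is provided but defaults off.
* ``simulate_spectra`` — per-protein reporter-ion ratio sets, log-normal
  around the true protein ratio with a given coefficient of variation;
  differential proteins receive true ratios at protein_effect / its
  reciprocal (beyond the 1.2 / 0.8 gates).
* ``simulate_matched_omics`` — paired (mRNA, protein) log2 fold changes
  from a bivariate normal whose population correlation is exactly rho,
  plus one alignment row per pair with configurable fractions violating
  each matching rule (E-value, mismatch, length).
* ``simulate_ct_plate`` — a qPCR plate with two reference genes and a
  target whose treated-sample Ct is shifted by -log2(true_fold), plus
  Gaussian replicate noise.
* ``simulate_enzyme_assays`` — per-strain replicate activity values with
  given means and standard errors (the three-strain endpoint layout), and
  small helpers for kinetic traces and standard curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "simulate_counts",
    "simulate_spectra",
    "simulate_matched_omics",
    "simulate_ct_plate",
    "simulate_enzyme_assays",
    "simulate_kinetic_trace",
    "simulate_standard_curve",
]

# substream tags, one per generator
_COUNTS, _SPECTRA, _OMICS, _CT, _ENZYME = 1, 2, 3, 4, 5


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for all generators.

    Defaults describe the two-library screen the pipeline targets: a few
    thousand genes at around a million clean reads per library, 5% truly
    differential at a 4-fold (|log2| = 2) effect, and an iTRAQ experiment of
    50 proteins with 8 spectra each at 10% ratio CV.
    """

    n_genes: int = 2000
    depth_s: float = 1_000_000.0
    depth_r: float = 1_000_000.0
    frac_de: float = 0.05
    effect_log2: float = 2.0
    length_range_nt: tuple[int, int] = (200, 3000)
    abundance_range: tuple[float, float] = (1.0, 100.0)  # log-uniform relative weights
    overdispersion: float = 0.0  # extra-Poisson gamma CV^2; 0 = pure Poisson
    n_proteins: int = 50
    spectra_per_protein: int = 8
    protein_cv: float = 0.1
    protein_effect: float = 1.5  # true ratio of up-regulated proteins; down = 1/this
    rho_mrna_protein: float = 0.66
    sd_mrna_log2: float = 1.5
    sd_protein_log2: float = 0.5
    frac_fail_evalue: float = 0.1
    frac_fail_mismatch: float = 0.1
    frac_fail_length: float = 0.1
    ct_noise_sd: float = 0.1
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_proteins < 1:
            raise ValueError("n_genes and n_proteins must be >= 1")
        if min(self.depth_s, self.depth_r) <= 0:
            raise ValueError("library depths must be > 0")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must lie in [0, 1]")
        if not -1.0 <= self.rho_mrna_protein <= 1.0:
            raise ValueError("rho_mrna_protein must lie in [-1, 1]")
        if self.length_range_nt[0] < 1 or self.length_range_nt[0] > self.length_range_nt[1]:
            raise ValueError("invalid length_range_nt")
        if self.abundance_range[0] <= 0 or self.abundance_range[0] > self.abundance_range[1]:
            raise ValueError("invalid abundance_range")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stream])


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"gene{str(i + 1).zfill(width)}" for i in range(n)]


def simulate_counts(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-library Poisson count table plus the per-gene truth.

    Non-differential genes share the same underlying concentration in both
    libraries (counts differ only through depth); differential genes have
    the resistant-library concentration multiplied by 2^(+/-effect_log2),
    with up and down effects assigned alternately.

    Returns (counts, truth): counts has gene_id, count_s, count_r,
    length_nt; truth has gene_id, is_de, true_log2fc.
    """
    rng = _rng(cfg, _COUNTS)
    n = cfg.n_genes
    lo, hi = cfg.abundance_range
    weights = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    rel = weights / weights.sum()

    n_de = int(round(cfg.frac_de * n))
    is_de = np.zeros(n, dtype=bool)
    true_log2fc = np.zeros(n)
    if n_de >= 1:
        de_idx = rng.choice(n, size=n_de, replace=False)
        is_de[de_idx] = True
        signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
        true_log2fc[de_idx] = signs * cfg.effect_log2

    lam_s = cfg.depth_s * rel
    lam_r = cfg.depth_r * rel * np.exp2(true_log2fc)
    if cfg.overdispersion > 0:
        shape = 1.0 / cfg.overdispersion
        lam_s = lam_s * rng.gamma(shape, cfg.overdispersion, size=n)
        lam_r = lam_r * rng.gamma(shape, cfg.overdispersion, size=n)
    counts = pd.DataFrame(
        {
            "gene_id": _gene_ids(n),
            "count_s": rng.poisson(lam_s).astype("int64"),
            "count_r": rng.poisson(lam_r).astype("int64"),
            "length_nt": rng.integers(
                cfg.length_range_nt[0], cfg.length_range_nt[1] + 1, size=n
            ).astype("int64"),
        }
    )
    truth = pd.DataFrame({"gene_id": counts["gene_id"], "is_de": is_de, "true_log2fc": true_log2fc})
    return counts, truth


def simulate_spectra(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spectrum-ratio table plus per-protein truth.

    Each protein gets spectra_per_protein reporter-ion ratios, log-normal
    around its true ratio with coefficient of variation protein_cv.  A
    frac_de fraction of proteins is truly differential, alternating between
    protein_effect (up) and 1/protein_effect (down).
    """
    if cfg.spectra_per_protein < 2:
        raise ValueError("spectra_per_protein must be >= 2")
    if cfg.protein_cv <= 0:
        raise ValueError("protein_cv must be > 0")
    rng = _rng(cfg, _SPECTRA)
    n = cfg.n_proteins
    n_de = int(round(cfg.frac_de * n))
    true_ratio = np.ones(n)
    is_de = np.zeros(n, dtype=bool)
    if n_de >= 1:
        de_idx = rng.choice(n, size=n_de, replace=False)
        is_de[de_idx] = True
        true_ratio[de_idx] = np.where(
            np.arange(n_de) % 2 == 0, cfg.protein_effect, 1.0 / cfg.protein_effect
        )

    sigma = np.sqrt(np.log1p(cfg.protein_cv**2))  # log-normal sigma for the given CV
    width = len(str(n))
    pids = [f"prot{str(i + 1).zfill(width)}" for i in range(n)]
    rows = []
    for i, pid in enumerate(pids):
        noise = rng.normal(0.0, sigma, size=cfg.spectra_per_protein)
        ratios = true_ratio[i] * np.exp(noise)
        for k, ratio in enumerate(ratios):
            rows.append((pid, f"{pid}_sp{k + 1}", float(ratio)))
    spectra = pd.DataFrame(rows, columns=["protein_id", "spectrum_id", "ratio"])
    truth = pd.DataFrame({"protein_id": pids, "true_ratio": true_ratio, "is_de": is_de})
    return spectra, truth


def simulate_matched_omics(
    cfg: SimConfig,
    n_pairs: int | None = None,
    protein_ids: list[str] | None = None,
    transcript_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired log2 fold changes with population correlation rho, plus alignments.

    Returns (pairs, alignments).  pairs: protein_id, transcript_id,
    mrna_log2fc, protein_log2fc.  alignments: one row per pair; disjoint
    random fractions are made to violate the E-value, mismatch and length
    rules respectively so the matching filter is exercised.  Identifier
    lists may be supplied to tie the pairs to existing count/spectrum
    tables; otherwise fresh ids are minted.
    """
    rng = _rng(cfg, _OMICS)
    if protein_ids is not None and transcript_ids is not None:
        if len(protein_ids) != len(transcript_ids):
            raise ValueError("protein_ids and transcript_ids must have equal length")
        n = len(protein_ids)
    else:
        n = n_pairs if n_pairs is not None else cfg.n_proteins
    rho = cfg.rho_mrna_protein
    mrna = rng.normal(0.0, cfg.sd_mrna_log2, size=n)
    indep = rng.normal(0.0, 1.0, size=n)
    protein = cfg.sd_protein_log2 * (
        rho * mrna / cfg.sd_mrna_log2 + np.sqrt(max(0.0, 1.0 - rho**2)) * indep
    )
    width = len(str(n))
    pids = protein_ids or [f"prot{str(i + 1).zfill(width)}" for i in range(n)]
    tids = transcript_ids or [f"gene{str(i + 1).zfill(width)}" for i in range(n)]
    pairs = pd.DataFrame(
        {"protein_id": pids, "transcript_id": tids, "mrna_log2fc": mrna, "protein_log2fc": protein}
    )

    # qualifying alignment statistics by default ...
    e_value = np.exp(rng.uniform(np.log(1e-50), np.log(1e-16), size=n))
    mismatch = rng.uniform(0.0, 6.0, size=n)
    aln_len = rng.integers(30, 301, size=n)
    # ... then break each rule on a disjoint designated fraction of rows
    perm = rng.permutation(n)
    k_e = int(round(cfg.frac_fail_evalue * n))
    k_m = int(round(cfg.frac_fail_mismatch * n))
    k_l = int(round(cfg.frac_fail_length * n))
    idx_e, idx_m, idx_l = perm[:k_e], perm[k_e:k_e + k_m], perm[k_e + k_m:k_e + k_m + k_l]
    e_value[idx_e] = np.exp(rng.uniform(np.log(1e-15), np.log(1e-3), size=idx_e.size))
    mismatch[idx_m] = rng.uniform(6.001, 30.0, size=idx_m.size)
    aln_len[idx_l] = rng.integers(5, 30, size=idx_l.size)
    alignments = pd.DataFrame(
        {
            "protein_id": pids,
            "transcript_id": tids,
            "e_value": e_value,
            "mismatch_pct": mismatch,
            "aln_len_aa": aln_len.astype("int64"),
        }
    )
    return pairs, alignments


def simulate_ct_plate(
    cfg: SimConfig,
    true_fold: float,
    gene_id: str = "target",
    ref_genes: tuple[str, ...] = ("EF-1a", "beta-actin"),
    ref_base_ct: tuple[float, ...] = (20.0, 22.0),
    target_base_ct: float = 24.0,
) -> pd.DataFrame:
    """A two-sample Ct plate in which the treated sample's target Ct is
    shifted by -log2(true_fold); every well gets Gaussian noise ct_noise_sd."""
    if true_fold <= 0:
        raise ValueError("true_fold must be > 0")
    rng = _rng(cfg, _CT)
    rows = []
    for sample in ("TH-S", "TH-2000"):
        shift = -np.log2(true_fold) if sample == "TH-2000" else 0.0
        for rep in range(1, cfg.n_replicates + 1):
            for ref, base in zip(ref_genes, ref_base_ct):
                rows.append((sample, rep, ref, True, base + rng.normal(0, cfg.ct_noise_sd)))
            rows.append(
                (sample, rep, gene_id, False,
                 target_base_ct + shift + rng.normal(0, cfg.ct_noise_sd))
            )
    return pd.DataFrame(rows, columns=["sample", "replicate", "gene_id", "is_reference", "ct"])


def simulate_enzyme_assays(
    cfg: SimConfig,
    means: dict[str, float],
    ses: dict[str, float],
) -> pd.DataFrame:
    """Replicate activity values per strain with the given means and standard
    errors (replicate sd = se * sqrt(n_replicates))."""
    rng = _rng(cfg, _ENZYME)
    rows = []
    for strain in means:
        sd = ses[strain] * np.sqrt(cfg.n_replicates)
        for rep in range(1, cfg.n_replicates + 1):
            rows.append((strain, rep, float(means[strain] + rng.normal(0, sd))))
    return pd.DataFrame(rows, columns=["strain", "replicate", "value"])


def simulate_kinetic_trace(
    slope_od_per_min: float,
    n_points: int = 21,
    duration_min: float = 10.0,
    intercept: float = 0.05,
    noise_sd: float = 0.002,
    seed: int = 0,
) -> pd.DataFrame:
    """Linear absorbance-vs-time trace with Gaussian read noise."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration_min, n_points)
    od = intercept + slope_od_per_min * t + rng.normal(0, noise_sd, size=n_points)
    return pd.DataFrame({"time_min": t, "od": od})


def simulate_standard_curve(
    slope_od_per_unit: float,
    concentrations=(0.0, 0.25, 0.5, 1.0, 2.0),
    intercept: float = 0.02,
    noise_sd: float = 0.002,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """(concentration, od) standard points on a noisy straight line."""
    rng = np.random.default_rng(seed)
    return [
        (float(c), float(intercept + slope_od_per_unit * c + rng.normal(0, noise_sd)))
        for c in concentrations
    ]
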