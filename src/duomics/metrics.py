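"""Library-level read accounting and RPKM expression values.

An RNA-seq library is summarised by its clean-read counts (total, mapped,
perfect-match, uniquely mapped) from which the familiar mapping percentages
are derived, and per-gene expression is quantified as RPKM: reads per
kilobase of transcript per million mapped reads,

    RPKM = 1e9 * count / (length_nt * mapped_total).

The RPKM denominator defaults to the library's mapped-read count — that is
what "per million mapped reads" denotes — with total or uniquely-mapped
reads selectable for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from ._round import round_half_up

__all__ = ["LibraryStats", "LibraryPercentages", "library_percentages", "rpkm", "rpkm_vector"]


class UndefinedMetricError(ValueError):
    """A ratio whose denominator is zero was requested."""


@dataclass(frozen=True)
class LibraryStats:
    """Clean-read accounting for one sequencing library."""

    total_reads: int
    mapped_reads: int
    perfect_match_reads: int
    unique_match_reads: int
    total_bp: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.unique_match_reads <= self.mapped_reads <= self.total_reads):
            raise ValueError("need 0 <= unique <= mapped <= total")
        if not (0 <= self.perfect_match_reads <= self.mapped_reads):
            raise ValueError("need 0 <= perfect <= mapped")
        if self.total_bp < 0:
            raise ValueError("total_bp must be >= 0")

    def denominator(self, kind: str) -> int:
        if kind == "mapped":
            return self.mapped_reads
        if kind == "total":
            return self.total_reads
        if kind == "unique":
            return self.unique_match_reads
        raise ValueError(f"unknown denominator kind {kind!r}")


class LibraryPercentages(NamedTuple):
    mapped_pct: float
    perfect_pct: float
    unique_pct: float


def library_percentages(stats: LibraryStats) -> LibraryPercentages:
    """Mapping percentages (mapped, perfect-match, unique) rounded half-up to 2 dp."""
    if stats.total_reads == 0:
        raise UndefinedMetricError("total_reads is zero; percentages undefined")
    total = stats.total_reads
    return LibraryPercentages(
        mapped_pct=round_half_up(100.0 * stats.mapped_reads / total, 2),
        perfect_pct=round_half_up(100.0 * stats.perfect_match_reads / total, 2),
        unique_pct=round_half_up(100.0 * stats.unique_match_reads / total, 2),
    )


def rpkm(count, length_nt, mapped_total) -> float | np.ndarray:
    """Reads per kilobase per million mapped reads; vectorises over arrays."""
    count = np.asarray(count, dtype=float)
    length_nt = np.asarray(length_nt, dtype=float)
    if np.any(length_nt < 1):
        raise ValueError("length_nt must be >= 1")
    if np.any(np.asarray(mapped_total) < 1):
        raise UndefinedMetricError("mapped_total must be >= 1")
    out = 1e9 * count / (length_nt * np.asarray(mapped_total, dtype=float))
    return float(out) if out.ndim == 0 else out


def rpkm_vector(counts: pd.DataFrame, mapped_s: int, mapped_r: int) -> pd.DataFrame:
    """Per-gene RPKM for both libraries of a two-library count table."""
    return pd.DataFrame(
        {
            "gene_id": counts["gene_id"],
            "rpkm_s": rpkm(counts["count_s"], counts["length_nt"], mapped_s),
            "rpkm_r": rpkm(counts["count_r"], counts["length_nt"], mapped_r),
        }
    )
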