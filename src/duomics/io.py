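"""Typed TSV reading and writing for every tabular artifact in the pipeline.

All tables travel as UTF-8 tab-separated files with a header row and
``#``-prefixed comment lines.  Each table kind has a declarative
:class:`TableSchema` (column names, dtypes, per-column range checks and a
uniqueness key) and every read or write passes through full validation, so a
DataFrame obtained from :func:`read_table` is safe to hand to any downstream
stage.  Writing is canonical — column order, ``%.6g`` float rendering,
``\\n`` line endings — which makes ``write(read(f))`` byte-stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import pandas as pd

__all__ = [
    "TableSchemaError",
    "TableParseError",
    "TableIntegrityError",
    "ColumnSpec",
    "TableSchema",
    "COUNT_TABLE",
    "ANNOTATION_MAP",
    "SPECTRUM_RATIOS",
    "ALIGNMENT_STATS",
    "CT_PLATE",
    "ASSAY_TABLE",
    "SCHEMAS",
    "read_table",
    "write_table",
    "validate_table",
]


class TableSchemaError(ValueError):
    """Header does not match the schema (missing/unknown column)."""


class TableParseError(ValueError):
    """A cell could not be converted to the declared dtype."""


class TableIntegrityError(ValueError):
    """Values violate a schema invariant (range check or duplicate key)."""


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    dtype: str  # 'str' | 'int' | 'float' | 'bool'
    check: Callable[[pd.Series], pd.Series] | None = None
    check_msg: str = ""
    allowed: tuple[str, ...] | None = None  # categorical restriction for str columns


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[ColumnSpec, ...]
    key: tuple[str, ...] = field(default_factory=tuple)

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]


COUNT_TABLE = TableSchema(
    name="counts",
    columns=(
        ColumnSpec("gene_id", "str"),
        ColumnSpec("count_s", "int", lambda s: s >= 0, "count_s must be >= 0"),
        ColumnSpec("count_r", "int", lambda s: s >= 0, "count_r must be >= 0"),
        ColumnSpec("length_nt", "int", lambda s: s >= 1, "length_nt must be >= 1"),
    ),
    key=("gene_id",),
)

ANNOTATION_MAP = TableSchema(
    name="annotation",
    columns=(
        ColumnSpec("gene_id", "str"),
        ColumnSpec("term_id", "str", lambda s: s.str.len() > 0, "term_id must be non-empty"),
        ColumnSpec("namespace", "str", allowed=("GO", "KEGG")),
    ),
    key=("gene_id", "term_id"),
)

SPECTRUM_RATIOS = TableSchema(
    name="spectra",
    columns=(
        ColumnSpec("protein_id", "str"),
        ColumnSpec("spectrum_id", "str"),
        ColumnSpec("ratio", "float", lambda s: s > 0, "ratio must be > 0"),
    ),
    key=("protein_id", "spectrum_id"),
)

ALIGNMENT_STATS = TableSchema(
    name="alignments",
    columns=(
        ColumnSpec("protein_id", "str"),
        ColumnSpec("transcript_id", "str"),
        ColumnSpec("e_value", "float", lambda s: s >= 0, "e_value must be >= 0"),
        ColumnSpec(
            "mismatch_pct", "float", lambda s: (s >= 0) & (s <= 100),
            "mismatch_pct must lie in [0, 100]",
        ),
        ColumnSpec("aln_len_aa", "int", lambda s: s >= 1, "aln_len_aa must be >= 1"),
    ),
    key=("protein_id", "transcript_id"),
)

CT_PLATE = TableSchema(
    name="ct_plate",
    columns=(
        ColumnSpec("sample", "str", allowed=("TH-S", "TH-2000")),
        ColumnSpec("replicate", "int", lambda s: s >= 1, "replicate must be >= 1"),
        ColumnSpec("gene_id", "str"),
        ColumnSpec("is_reference", "bool"),
        ColumnSpec("ct", "float", lambda s: s > 0, "ct must be > 0"),
    ),
    key=("sample", "replicate", "gene_id"),
)

ASSAY_TABLE = TableSchema(
    name="assay",
    columns=(
        ColumnSpec("strain", "str", allowed=("TH-S", "TH-R", "TH-2000")),
        ColumnSpec("replicate", "int", lambda s: s >= 1, "replicate must be >= 1"),
        ColumnSpec("value", "float"),
    ),
    key=("strain", "replicate"),
)

SCHEMAS: Mapping[str, TableSchema] = {
    s.name: s
    for s in (COUNT_TABLE, ANNOTATION_MAP, SPECTRUM_RATIOS, ALIGNMENT_STATS, CT_PLATE, ASSAY_TABLE)
}

_TRUE = {"true", "1"}
_FALSE = {"false", "0"}


def _convert_column(raw: pd.Series, spec: ColumnSpec) -> pd.Series:
    if spec.dtype == "str":
        out = raw.fillna("").astype(str)
        return out
    if spec.dtype == "bool":
        lowered = raw.astype(str).str.strip().str.lower()
        bad = ~lowered.isin(_TRUE | _FALSE)
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based + header line
            raise TableParseError(
                f"column '{spec.name}', line {row}: cannot parse {raw[bad.idxmax()]!r} as bool"
            )
        return lowered.isin(_TRUE)
    # numeric: locale-independent — decimal point only, no thousands separators
    cleaned = raw.astype(str).str.strip()
    if cleaned.str.contains(",").any():
        row = int(cleaned.str.contains(",").idxmax()) + 2
        raise TableParseError(f"column '{spec.name}', line {row}: thousands separators not accepted")
    numeric = pd.to_numeric(cleaned, errors="coerce")
    bad = numeric.isna()
    if bad.any():
        row = int(bad.idxmax()) + 2
        raise TableParseError(
            f"column '{spec.name}', line {row}: cannot parse {raw[bad.idxmax()]!r} as {spec.dtype}"
        )
    if spec.dtype == "int":
        if not (numeric == numeric.round()).all():
            bad = numeric != numeric.round()
            row = int(bad.idxmax()) + 2
            raise TableParseError(f"column '{spec.name}', line {row}: non-integer value")
        return numeric.astype("int64")
    return numeric.astype(float)


def validate_table(df: pd.DataFrame, schema: TableSchema) -> pd.DataFrame:
    """Check *df* against *schema*; returns the frame with canonical column order.

    Raises :class:`TableSchemaError` for header problems and
    :class:`TableIntegrityError` for range-check or uniqueness violations.
    """
    missing = [c for c in schema.column_names if c not in df.columns]
    if missing:
        raise TableSchemaError(f"{schema.name}: missing column(s) {missing}")
    df = df[schema.column_names].reset_index(drop=True)
    for spec in schema.columns:
        col = df[spec.name]
        if spec.allowed is not None:
            bad = ~col.isin(spec.allowed)
            if bad.any():
                raise TableIntegrityError(
                    f"{schema.name}.{spec.name}: value {col[bad.idxmax()]!r} "
                    f"not in {spec.allowed}"
                )
        if spec.check is not None:
            ok = spec.check(col)
            if not ok.all():
                raise TableIntegrityError(f"{schema.name}.{spec.name}: {spec.check_msg}")
        if spec.dtype == "float":
            if not col.map(math.isfinite).all():
                raise TableIntegrityError(f"{schema.name}.{spec.name}: non-finite value")
    if schema.key:
        dup = df.duplicated(subset=list(schema.key))
        if dup.any():
            dup_key = tuple(df.loc[dup.idxmax(), list(schema.key)])
            raise TableIntegrityError(f"{schema.name}: duplicate key {dup_key}")
    return df


def read_table(path, schema: TableSchema) -> pd.DataFrame:
    """Read a TSV at *path* as *schema*; row order is preserved."""
    raw = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, encoding="utf-8",
        skip_blank_lines=True, keep_default_na=False, na_values=[],
    )
    unknown = [c for c in raw.columns if c not in schema.column_names]
    if unknown:
        raise TableSchemaError(f"{schema.name}: unknown column(s) {unknown}")
    missing = [c for c in schema.column_names if c not in raw.columns]
    if missing:
        raise TableSchemaError(f"{schema.name}: missing column(s) {missing}")
    converted = {spec.name: _convert_column(raw[spec.name], spec) for spec in schema.columns}
    return validate_table(pd.DataFrame(converted), schema)


def _format_cell(value, dtype: str) -> str:
    if dtype == "bool":
        return "true" if value else "false"
    if dtype == "int":
        return str(int(value))
    if dtype == "float":
        return format(float(value), ".6g")
    return str(value)


def write_table(df: pd.DataFrame, path, schema: TableSchema) -> None:
    """Write *df* (validated against *schema*) to *path* in canonical TSV form."""
    df = validate_table(df, schema)
    lines = ["\t".join(schema.column_names)]
    dtypes = [c.dtype for c in schema.columns]
    for row in df.itertuples(index=False):
        lines.append("\t".join(_format_cell(v, d) for v, d in zip(row, dtypes)))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
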