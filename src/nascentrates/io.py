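"""Typed TSV table I/O with schema validation.

All tables are tab-separated with a header row; the missing-value marker is
``NA``.  Column names embed units (e.g. ``tr_molecules_per_min``) so unit
drift is visible in every file.  Schemas are ordered column -> kind maps
(``str`` | ``int`` | ``float``); reading validates names and types and
reports offending columns/rows.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_MARKER = "NA"

SCHEMAS: dict[str, dict[str, str]] = {
    "catalog": {
        "gene_id": "str",
        "orf_length_bp": "int",
        "probe_start_bp": "int",
        "probe_end_bp": "int",
        "group_label": "str",
    },
    "truth": {
        "gene_id": "str",
        "true_density": "float",
        "true_tr": "float",
        "half_life_min": "float",
        "kd": "float",
        "ra_true": "float",
    },
    "rates": {
        "gene_id": "str",
        "orf_length_bp": "int",
        "tr_au": "float",
        "tr_molecules_per_min": "float",
        "ind_tr_nodil_molecules_per_min": "float",
        "ind_tr_molecules_per_min": "float",
        "ra_molecules_per_cell": "float",
        "half_life_min": "float",
        "density_molecules_per_kb": "float",
        "pols_per_gene": "float",
        "dilution_pct": "float",
    },
    "abundance": {"gene_id": "str", "abundance": "float"},
    "groups": {"gene_id": "str", "group_label": "str"},
}


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def read_table(path, schema: str | dict[str, str]) -> pd.DataFrame:
    """Read a TSV, validating column names and types against a schema.

    ``schema`` is a schema name from :data:`SCHEMAS` or an explicit
    column -> kind mapping.  Unknown or missing columns raise
    :class:`SchemaError`; a non-numeric cell in a numeric column raises a
    parse error naming the row.
    """
    spec = SCHEMAS[schema] if isinstance(schema, str) else schema
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING_MARKER],
                     keep_default_na=False)
    missing = [c for c in spec if c not in df.columns]
    unknown = [c for c in df.columns if c not in spec]
    if missing or unknown:
        raise SchemaError(
            f"{path}: schema mismatch (missing columns: {missing}, unknown: {unknown})"
        )
    out = {}
    for col, kind in spec.items():
        if kind == "str":
            out[col] = df[col].fillna("")
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at data row {row + 1}"
            )
        out[col] = converted.astype(float if kind == "float" else "Int64")
    result = pd.DataFrame(out)[list(spec)]
    logger.info("read %d rows from %s", len(result), path)
    return result


def write_table(df: pd.DataFrame, path) -> None:
    """Write a TSV with header, missing values as ``NA``."""
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING_MARKER)


def read_series(path, value_column: str) -> pd.Series:
    """Read a two-column (gene_id, value) TSV as a float Series."""
    df = read_table(path, {"gene_id": "str", value_column: "float"})
    return pd.Series(df[value_column].to_numpy(),
                     index=pd.Index(df["gene_id"], name="gene_id"),
                     name=value_column)


def write_series(series: pd.Series, path, value_column: str) -> None:
    df = pd.DataFrame({"gene_id": series.index, value_column: series.to_numpy()})
    write_table(df, path)
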