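"""Tab-separated table I/O with header-keyed schema validation.

All pipeline tables are plain TSV with a header row; missing values are
written as ``NA``.  Readers key on column names, so column order is free,
but a missing or surplus-only header (e.g. a file written with the wrong
delimiter) raises a :class:`SchemaError` that names the column diff.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .enrichment import ENRICHMENT_COLUMNS
from .psi import CALL_COLUMNS, DELTA_COLUMNS, PSI_COLUMNS

__all__ = ["SchemaError", "SCHEMAS", "write_table", "read_table"]

SCHEMAS: dict[str, list[str]] = {
    "catalog": ["ase_id", "gene", "size_inclusion_bp", "size_exclusion_bp", "inclusion_is_long"],
    "peaks": ["cell_line", "condition", "batch_day", "ase_id", "amplicon", "called_size_bp", "area"],
    "truth": ["ase_id", "cell_line", "baseline_psi", "effect_dpsi", "discordant"],
    "kd": ["cell_line", "sirna", "kd_fraction"],
    "psi": PSI_COLUMNS,
    "delta_psi": DELTA_COLUMNS,
    "calls": CALL_COLUMNS,
    "enrichment": ENRICHMENT_COLUMNS,
}


class SchemaError(ValueError):
    """A table's header does not match its declared schema."""


def write_table(df: pd.DataFrame, path: str | Path, schema: str | None = None) -> None:
    """Write a TSV; with ``schema`` given, columns are ordered and checked."""
    if schema is not None:
        _check_columns(df.columns, SCHEMAS[schema], path, extra_ok=True)
        df = df[SCHEMAS[schema]]
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(path: str | Path, schema: str | None = None) -> pd.DataFrame:
    """Read a TSV; with ``schema`` given, validate and reorder the columns."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    if schema is not None:
        _check_columns(df.columns, SCHEMAS[schema], path, extra_ok=False)
        df = df[SCHEMAS[schema]]
    return df


def _check_columns(found, expected: list[str], path, extra_ok: bool) -> None:
    found = list(found)
    missing = [c for c in expected if c not in found]
    extra = [c for c in found if c not in expected]
    if missing or (extra and not extra_ok):
        raise SchemaError(
            f"{path}: column mismatch — missing {missing or 'none'}, "
            f"unexpected {extra or 'none'}"
        )
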