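"""Reading, validating and writing the pipeline's tabular formats.

The canonical abundance format is long (tidy): one row per observed
intensity, with columns ``protein_id, gene_symbol, condition, replicate,
temperature_c, intensity``.  Missing observations are absent rows, never
sentinel values.  TSV is the default dialect; CSV is accepted.  A
wide-to-long converter is provided for per-temperature-column exports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "SchemaError",
    "IntegrityError",
    "LoadReport",
    "read_abundance_table",
    "write_abundance_table",
    "read_cetsa_table",
    "write_shift_table",
    "wide_to_long",
]

REQUIRED_COLUMNS = ("protein_id", "condition", "replicate", "temperature_c", "intensity")
KEY_COLUMNS = ("protein_id", "condition", "replicate", "temperature_c")
CONDITIONS = ("treated", "vehicle")

_SEP = {"tab": "\t", "comma": ","}


class SchemaError(ValueError):
    """The table is missing a required column or uses an unknown value."""


class IntegrityError(ValueError):
    """Row-level constraint violated (duplicate keys, bad numerics)."""


@dataclass(frozen=True)
class LoadReport:
    """Summary of a validated table load."""

    n_records: int
    n_proteins: int
    conditions: tuple[str, ...]
    temperatures: tuple[float, ...]
    n_replicates: int
    n_rejected_rows: int
    rejected_lines: tuple[int, ...]  # 1-based file line numbers


def _check_schema(df: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} is missing")


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    bad_cond = set(df["condition"].unique()) - set(CONDITIONS)
    if bad_cond:
        raise SchemaError(
            f"condition values must be one of {CONDITIONS}, found {sorted(bad_cond)}"
        )
    if (df["intensity"] < 0).any():
        row = df.loc[df["intensity"] < 0].iloc[0]
        raise IntegrityError(
            f"negative intensity for protein {row['protein_id']!r} "
            f"at {row['temperature_c']} degC"
        )
    if (df["replicate"] < 1).any():
        raise IntegrityError("replicate must be a positive integer")
    if not np.isfinite(df["temperature_c"]).all():
        raise IntegrityError("temperature_c must be finite")
    dup = df.duplicated(list(KEY_COLUMNS), keep=False)
    if dup.any():
        first = df.loc[dup, list(KEY_COLUMNS)].iloc[0]
        raise IntegrityError(
            "duplicate (protein_id, condition, replicate, temperature_c) tuple: "
            + str(tuple(first))
        )
    return df


def read_abundance_table(
    path, dialect: str = "tab", strict: bool = True
) -> tuple[pd.DataFrame, LoadReport]:
    """Read and validate a long-format abundance table.

    Rows with non-parseable numeric fields are rejected and reported with
    their 1-based file line numbers; in ``strict`` mode any rejected row
    raises :class:`IntegrityError` instead.

    Returns the validated DataFrame plus a :class:`LoadReport`.
    """
    sep = _SEP[dialect]
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.empty:
        raise SchemaError("table contains no data rows")
    _check_schema(df)

    numeric = {
        "replicate": pd.to_numeric(df["replicate"], errors="coerce"),
        "temperature_c": pd.to_numeric(df["temperature_c"], errors="coerce"),
        "intensity": pd.to_numeric(df["intensity"], errors="coerce"),
    }
    bad = (
        numeric["replicate"].isna()
        | numeric["temperature_c"].isna()
        | numeric["intensity"].isna()
        | (df["protein_id"].str.len() == 0)
    )
    rejected_lines = tuple(int(i) + 2 for i in df.index[bad])  # +2: header + 1-based
    if strict and bad.any():
        raise IntegrityError(
            f"{int(bad.sum())} row(s) with non-parseable fields at file line(s) "
            f"{list(rejected_lines)[:10]}"
        )
    out = df.loc[~bad].copy()
    if out.empty:
        raise SchemaError("table contains no valid data rows")
    out["replicate"] = numeric["replicate"][~bad].astype(int)
    out["temperature_c"] = numeric["temperature_c"][~bad].astype(float)
    out["intensity"] = numeric["intensity"][~bad].astype(float)
    if "gene_symbol" not in out.columns:
        out["gene_symbol"] = ""
    out = out[list(REQUIRED_COLUMNS[:1]) + ["gene_symbol"] + list(REQUIRED_COLUMNS[1:])]
    out = _validate(out).reset_index(drop=True)

    report = LoadReport(
        n_records=len(out),
        n_proteins=int(out["protein_id"].nunique()),
        conditions=tuple(sorted(out["condition"].unique())),
        temperatures=tuple(sorted(out["temperature_c"].unique())),
        n_replicates=int(out["replicate"].nunique()),
        n_rejected_rows=int(bad.sum()),
        rejected_lines=rejected_lines,
    )
    return out, report


def write_abundance_table(df: pd.DataFrame, path, dialect: str = "tab") -> None:
    """Write a long-format abundance table (deterministic row order)."""
    _check_schema(df)
    out = df.sort_values(list(KEY_COLUMNS), kind="mergesort")
    out.to_csv(path, sep=_SEP[dialect], index=False)


def read_cetsa_table(path, dialect: str = "tab") -> pd.DataFrame:
    """Read a CETSA densitometry table.

    Expects columns ``target_name, condition, replicate, temperature_c,
    band_intensity``.
    """
    df = pd.read_csv(path, sep=_SEP[dialect])
    needed = ("target_name", "condition", "replicate", "temperature_c", "band_intensity")
    for col in needed:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} is missing")
    if (df["band_intensity"] < 0).any():
        raise IntegrityError("band_intensity must be >= 0")
    return df


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return ""
    if isinstance(x, (bool, np.bool_)):
        return str(bool(x))
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def write_shift_table(results: pd.DataFrame, path) -> None:
    """Write a melting-point shift table with deterministic formatting.

    Rows are ordered by rank (QC-failed, unranked rows last, by
    protein_id); floats are serialized with 6 significant digits, so
    identical inputs yield byte-identical files.
    """
    if results.empty:
        raise ValueError("shift results are empty")
    df = results.copy()
    rank_key = df["rank"].fillna(np.inf) if "rank" in df else np.arange(len(df))
    df = df.assign(_rk=rank_key).sort_values(
        ["_rk", "protein_id"], kind="mergesort"
    ).drop(columns="_rk")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def wide_to_long(
    wide: pd.DataFrame,
    temperature_columns: dict[str, float],
    condition: str,
    replicate: int = 1,
    protein_column: str = "protein_id",
) -> pd.DataFrame:
    """Convert a wide per-temperature-column export to the long schema.

    ``temperature_columns`` maps column names to temperatures in degC.
    Missing (NaN) cells become absent rows.
    """
    records = []
    for col, temp in temperature_columns.items():
        if col not in wide.columns:
            raise SchemaError(f"wide column {col!r} is missing")
        sub = wide[[protein_column, col]].dropna()
        records.append(
            pd.DataFrame(
                {
                    "protein_id": sub[protein_column],
                    "gene_symbol": "",
                    "condition": condition,
                    "replicate": replicate,
                    "temperature_c": float(temp),
                    "intensity": sub[col].astype(float),
                }
            )
        )
    return pd.concat(records, ignore_index=True)
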