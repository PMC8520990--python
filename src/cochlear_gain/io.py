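"""Validated tabular I/O and the packaged equally-effective-masker table.

All data in this package are small CSV tables with explicit schemas.
``read_table``/``write_table`` enforce headers and numeric types and give
row/column context on failure.  ``load_table1`` reads the packaged
per-participant summary of masked signal thresholds for equally effective
on- and off-frequency maskers, with and without a 40-dB SPL on-frequency
precursor (mean, SD and run count per condition; one condition per row).
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .analysis import SummaryCondition

__all__ = [
    "read_table",
    "write_table",
    "load_table1",
    "table1_summary_conditions",
    "provenance_stamp",
]

# column -> required dtype kind ('f' float, 'i' int, 's' string); optional
# columns are marked by a trailing '?'
SCHEMAS: dict[str, dict[str, str]] = {
    "summary_conditions": {
        "participant": "s", "masker_freq_kHz": "f?", "masker_level_dB": "f?",
        "precursor_class": "s", "precursor_level_dB": "f?",
        "mean_threshold_dB": "f", "sd_dB": "f", "n_runs": "i",
        "matched_pair": "f?", "printed_significant": "i?",
    },
    "gain_reduction_points": {
        "participant": "s", "precursor_class": "s", "level_dB": "f",
        "estimate_dB": "f",
    },
    "runs": {
        "experiment": "s?", "participant": "s", "condition": "s",
        "estimate_dB": "f", "reversal_sd_dB": "f", "qc_pass": "s",
        "qc_reason": "s?", "seed": "i",
    },
    "trials": {
        "experiment": "s?", "participant": "s", "condition": "s",
        "trial": "i", "level_dB": "f", "correct": "s", "reversal": "s",
        "step_dB": "f",
    },
}


class TableSchemaError(ValueError):
    """Raised when a table does not match its declared schema."""


def _check(df: pd.DataFrame, schema_name: str, path: str,
           allow_extra: bool = False) -> pd.DataFrame:
    try:
        schema = SCHEMAS[schema_name]
    except KeyError:
        raise TableSchemaError(f"unknown schema {schema_name!r}") from None
    required = {c for c, k in schema.items() if not k.endswith("?")}
    missing = required - set(df.columns)
    if missing:
        raise TableSchemaError(
            f"{path}: missing column(s) {sorted(missing)} for schema "
            f"{schema_name!r}")
    extra = set(df.columns) - set(schema)
    if extra and not allow_extra:
        raise TableSchemaError(
            f"{path}: unexpected column(s) {sorted(extra)}; pass "
            f"allow_extra=True to accept them")
    for col, kind in schema.items():
        if col not in df.columns:
            continue
        k = kind.rstrip("?")
        if k in ("f", "i"):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise TableSchemaError(
                    f"{path}: non-numeric value {df[col].iloc[row]!r} in "
                    f"column {col!r}, row {row}")
            df[col] = coerced.astype(float if k == "f" else "Int64")
    return df


def read_table(path: Union[str, Path], schema: str,
               allow_extra: bool = False) -> pd.DataFrame:
    """Read a CSV and validate it against a named schema."""
    df = pd.read_csv(path)
    return _check(df, schema, str(path), allow_extra=allow_extra)


def write_table(df: pd.DataFrame, path: Union[str, Path], schema: str,
                allow_extra: bool = False) -> None:
    """Validate against a named schema and write as CSV."""
    _check(df.copy(), schema, str(path), allow_extra=allow_extra)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def load_table1() -> pd.DataFrame:
    """The packaged equally-effective-masker summary table."""
    with resources.files("cochlear_gain").joinpath("data/table1.csv").open() as fh:
        df = pd.read_csv(fh)
    return _check(df, "summary_conditions", "table1.csv")


def table1_summary_conditions(df: Optional[pd.DataFrame] = None
                              ) -> list[SummaryCondition]:
    """Typed records for the packaged (or a compatible) summary table."""
    if df is None:
        df = load_table1()
    out = []
    for _, r in df.iterrows():
        out.append(SummaryCondition(
            participant=str(r["participant"]),
            masker_freq_kHz=(None if pd.isna(r["masker_freq_kHz"])
                             else float(r["masker_freq_kHz"])),
            masker_level_dB=(None if pd.isna(r["masker_level_dB"])
                             else float(r["masker_level_dB"])),
            precursor_class=str(r["precursor_class"]),
            precursor_level_dB=(None if pd.isna(r["precursor_level_dB"])
                                else float(r["precursor_level_dB"])),
            mean_threshold_dB=float(r["mean_threshold_dB"]),
            sd_dB=float(r["sd_dB"]),
            n_runs=int(r["n_runs"]),
        ))
    return out


def provenance_stamp(config: Mapping, seed: Optional[int]) -> dict:
    """Config hash + seed, attached to every CLI artifact."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {"config_sha256": hashlib.sha256(blob).hexdigest()[:16],
            "seed": seed}
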