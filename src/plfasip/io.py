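"""Tabular input/output with strict schema validation.

All tables are long-format TSV with an optional leading ``# units:`` comment
declaring the units of the numeric columns.  Wide or locale-mangled files
(comma decimal separators) are rejected with explicit messages rather than
guessed at.  Every write carries a run-metadata JSON (configuration, isotope
constants, seed, flag counts) next to the result tables.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import SchemaError

MEASUREMENT_COLUMNS = {
    "sample_id": str,
    "field": str,
    "stage": str,
    "treatment": str,
    "day": int,
    "biomarker": str,
    "amount_nmolC_per_g": float,
    "delta13C_fame_permil": float,
}
MEASUREMENT_UNITS = {
    "amount_nmolC_per_g": "nmol_C_per_g_dry_soil",
    "delta13C_fame_permil": "permil_vs_VPDB",
}
MEASUREMENT_KEY = ("sample_id", "biomarker")

GAS_COLUMNS = {
    "bottle_id": str,
    "field": str,
    "stage": str,
    "treatment": str,
    "day": int,
    "t0_h": float,
    "t1_h": float,
    "co2_t0": float,
    "co2_t1": float,
    "delta13C_t0": float,
    "delta13C_t1": float,
    "headspace_ml": float,
    "sample_ml": float,
    "soil_dw_g": float,
}
GAS_UNITS = {
    "co2_t0": "ug_C_per_ml",
    "co2_t1": "ug_C_per_ml",
    "delta13C_t0": "permil_vs_VPDB",
    "delta13C_t1": "permil_vs_VPDB",
}
GAS_KEY = ("bottle_id", "day")

TREATMENTS = ("labeled", "unlabeled_control", "no_litter_control")


def _parse_units_header(path: Path) -> Optional[dict]:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                return None
            body = line.lstrip("#").strip()
            if body.startswith("units:"):
                pairs = body[len("units:"):].split()
                return dict(p.split("=", 1) for p in pairs if "=" in p)
    return None


def _read_table(path, columns: dict, key, units: dict) -> pd.DataFrame:
    path = Path(path)
    declared = _parse_units_header(path)
    if declared is not None:
        wrong = {
            col: (declared[col], units[col])
            for col in units
            if col in declared and declared[col] != units[col]
        }
        if wrong:
            items = "; ".join(
                f"{c}: declared {got!r}, expected {want!r}"
                for c, (got, want) in wrong.items()
            )
            raise SchemaError(f"{path.name}: unit declaration mismatch — {items}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(columns) - set(df.columns)
    unknown = set(df.columns) - set(columns)
    problems = []
    if missing:
        problems.append(f"missing columns {sorted(missing)}")
    if unknown:
        problems.append(f"unknown columns {sorted(unknown)}")
    if problems:
        raise SchemaError(f"{path.name}: " + "; ".join(problems))
    for col, typ in columns.items():
        if typ in (int, float):
            has_comma = df[col].str.contains(",", na=False)
            if has_comma.any():
                example = df.loc[has_comma, col].iloc[0]
                raise SchemaError(
                    f"{path.name}: column {col!r} contains {example!r} — comma "
                    "decimal separators are not accepted; re-export with '.' decimals"
                )
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"{path.name}: column {col!r} is not numeric: {exc}")
    dup = df.duplicated(subset=list(key), keep=False)
    if dup.any():
        keys = df.loc[dup, list(key)].drop_duplicates().to_records(index=False).tolist()
        raise SchemaError(f"{path.name}: duplicate {key} keys: {keys[:10]}")
    if "treatment" in df.columns:
        bad = set(df["treatment"]) - set(TREATMENTS)
        if bad:
            raise SchemaError(
                f"{path.name}: unknown treatments {sorted(bad)}; expected {TREATMENTS}"
            )
    return df


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a long-format PLFA measurement table."""
    return _read_table(path, MEASUREMENT_COLUMNS, MEASUREMENT_KEY, MEASUREMENT_UNITS)


def read_gas(path) -> pd.DataFrame:
    """Read and validate a two-point headspace gas table."""
    return _read_table(path, GAS_COLUMNS, GAS_KEY, GAS_UNITS)


def write_table(df: pd.DataFrame, path, units: Optional[dict] = None) -> None:
    """Write a TSV with an optional leading units declaration comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if units:
            fh.write("# units: " + " ".join(f"{k}={v}" for k, v in units.items()) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def write_measurements(df: pd.DataFrame, path) -> None:
    write_table(df, path, MEASUREMENT_UNITS)


def write_gas(df: pd.DataFrame, path) -> None:
    write_table(df, path, GAS_UNITS)


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a serialized configuration."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_run_metadata(metadata: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
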