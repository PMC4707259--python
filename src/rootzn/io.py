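"""Tidy CSV schemas, validated readers/writers, and record types."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError

__all__ = [
    "TIDY_COLUMNS",
    "SOLUTION_COLUMNS",
    "PlantObservation",
    "read_table",
    "write_table",
    "read_solution_table",
    "write_solution_table",
    "to_observations",
]

#: Column order of the plant-level tidy table (field and density experiments).
TIDY_COLUMNS: list[str] = [
    "experiment",
    "genotype",
    "group",
    "treatment",
    "dat",
    "replicate",
    "hill_density",
    "shoot_dw_mg",
    "root_dw_mg",
    "shoot_zn_ug_per_g",
    "crown_roots",
    "rsa_cm2",
    "root_len_fine_cm",
    "root_len_mid_cm",
    "root_len_coarse_cm",
]

#: Column order of the solution (root-regrowth) experiment table.
SOLUTION_COLUMNS: list[str] = [
    "experiment",
    "group",
    "replicate",
    "dap",
    "root_dw_mg",
    "shoot_dw_mg",
    "root_zn_ug_per_g",
    "shoot_zn_ug_per_g",
    "crown_roots",
    "root_zn_ug",
    "shoot_zn_ug",
    "zn_free_solution",
    "roots_excised",
]

_NUMERIC_TIDY = TIDY_COLUMNS[4:]
_ENUMS = {
    "experiment": {"field", "density", "solution"},
    "group": {"tolerant", "sensitive"},
    "treatment": {"minusZn", "plusZn"},
}


@dataclass(frozen=True)
class PlantObservation:
    """One plant at one sampling (field or density experiment)."""

    experiment: str
    genotype: str
    group: str
    treatment: str
    dat: int
    replicate: int
    hill_density: int = 1
    shoot_dw: float = np.nan
    root_dw: float = np.nan
    shoot_zn_conc: float = np.nan
    crown_roots: float = np.nan
    rsa: float = np.nan
    root_len_fine: float = np.nan
    root_len_mid: float = np.nan
    root_len_coarse: float = np.nan


def _check_header(actual: list[str], expected: list[str]) -> None:
    missing = [c for c in expected if c not in actual]
    extra = [c for c in actual if c not in expected]
    if missing:
        raise SchemaError(f"missing columns: {missing}; unexpected: {extra or 'none'}")


def _coerce_numeric(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    for col in columns:
        raw = df[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = coerced.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            rows = [int(i) + 2 for i in df.index[bad][:5]]  # +2: header + 1-based
            raise SchemaError(
                f"non-numeric values in column {col!r} at file rows {rows}"
            )
        df[col] = coerced
    return df


def _check_enums(df: pd.DataFrame) -> None:
    for col, allowed in _ENUMS.items():
        if col not in df.columns:
            continue
        vals = df[col].dropna()
        bad = ~vals.isin(allowed)
        if bad.any():
            rows = [int(i) + 2 for i in vals.index[bad][:5]]
            raise SchemaError(
                f"invalid {col!r} values {sorted(set(vals[bad]))} at file rows {rows}; "
                f"allowed: {sorted(allowed)}"
            )


def read_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a plant-level tidy CSV.

    Raises :class:`SchemaError` naming the offending columns and 1-based
    file row numbers on any violation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    _check_header(list(df.columns), TIDY_COLUMNS)
    df = _coerce_numeric(df, [c for c in _NUMERIC_TIDY if c in df.columns])
    _check_enums(df)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a tidy table; columns are ordered per the schema."""
    path = Path(path)
    cols = [c for c in TIDY_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, columns=cols)
    return path


def read_solution_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a solution-experiment CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    _check_header(list(df.columns), SOLUTION_COLUMNS)
    numeric = [
        "replicate", "dap", "root_dw_mg", "shoot_dw_mg", "root_zn_ug_per_g",
        "shoot_zn_ug_per_g", "crown_roots", "root_zn_ug", "shoot_zn_ug",
    ]
    df = _coerce_numeric(df, numeric)
    _check_enums(df)
    return df


def write_solution_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = [c for c in SOLUTION_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, columns=cols)
    return path


def to_observations(df: pd.DataFrame) -> list[PlantObservation]:
    """Convert validated tidy rows into :class:`PlantObservation` records."""
    obs = []
    for _, r in df.iterrows():
        obs.append(
            PlantObservation(
                experiment=str(r["experiment"]),
                genotype=str(r["genotype"]),
                group=str(r["group"]),
                treatment=str(r["treatment"]),
                dat=int(r["dat"]),
                replicate=int(r["replicate"]),
                hill_density=int(r["hill_density"]) if pd.notna(r["hill_density"]) else 1,
                shoot_dw=float(r["shoot_dw_mg"]),
                root_dw=float(r["root_dw_mg"]),
                shoot_zn_conc=float(r["shoot_zn_ug_per_g"]),
                crown_roots=float(r["crown_roots"]),
                rsa=float(r["rsa_cm2"]),
                root_len_fine=float(r["root_len_fine_cm"]),
                root_len_mid=float(r["root_len_mid_cm"]),
                root_len_coarse=float(r["root_len_coarse_cm"]),
            )
        )
    return obs
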