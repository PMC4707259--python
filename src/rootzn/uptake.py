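"""Estimation of per-plant total Zn uptake from shoot measurements.

Root Zn cannot be measured reliably in plants pulled from puddled soil
(adhering soil inflates apparent root Zn severalfold), so root Zn content
is estimated from shoot Zn concentration via a fixed root:shoot
concentration ratio calibrated in nutrient solution (default 1.7).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "DEFAULT_ROOT_FACTOR",
    "ZnMeasurement",
    "NetUptake",
    "estimate_total_uptake",
    "net_uptake",
    "add_total_uptake",
]

#: Default root:shoot Zn concentration ratio (solution-culture calibration).
DEFAULT_ROOT_FACTOR = 1.7

#: Column this module refuses to use: measured root Zn from soil-grown
#: plants is contamination-dominated and is ignored by design.
MEASURED_ROOT_ZN_COLUMN = "root_zn_ug_per_g"


@dataclass(frozen=True)
class ZnMeasurement:
    """Shoot-based measurements for one plant at one sampling.

    Units: concentrations μg g⁻¹, dry weights mg plant⁻¹, contents μg plant⁻¹.
    """

    shoot_zn_conc: float
    shoot_dw: float
    root_dw: float = 0.0
    seedling_zn_content: float | None = None

    def __post_init__(self) -> None:
        for name in ("shoot_zn_conc", "shoot_dw", "root_dw"):
            val = getattr(self, name)
            if val < 0:
                raise ValueError(f"{name} must be non-negative, got {val}")
        if self.seedling_zn_content is not None and self.seedling_zn_content < 0:
            raise ValueError("seedling_zn_content must be non-negative")
        if self.shoot_zn_conc > 0 and self.shoot_dw == 0:
            raise ValueError("shoot_dw must be > 0 when a concentration is given")


class NetUptake(float):
    """Net uptake value; negative values are flagged as retranslocation-dominated."""

    retranslocation_dominated: bool

    def __new__(cls, value: float) -> "NetUptake":
        obj = super().__new__(cls, value)
        obj.retranslocation_dominated = value < 0
        return obj


def estimate_total_uptake(
    m: ZnMeasurement, root_factor: float = DEFAULT_ROOT_FACTOR
) -> float:
    """Per-plant total Zn content (μg): measured shoot plus estimated root Zn.

    ``shoot_conc·shoot_dw/1000 + root_factor·shoot_conc·root_dw/1000``
    (the /1000 converts mg dry weight to g).
    """
    if root_factor <= 0:
        raise ValueError(f"root_factor must be > 0, got {root_factor}")
    shoot = m.shoot_zn_conc * m.shoot_dw / 1000.0
    root = root_factor * m.shoot_zn_conc * m.root_dw / 1000.0
    return shoot + root


def net_uptake(content_now: float, seedling_content: float) -> NetUptake:
    """Net Zn uptake since transplanting: current content minus seedling content.

    May be negative when growth is supported by retranslocation rather than
    uptake; negative results carry ``retranslocation_dominated=True``.
    """
    if content_now < 0 or seedling_content < 0:
        raise ValueError("contents must be non-negative")
    return NetUptake(content_now - seedling_content)


def add_total_uptake(
    df: pd.DataFrame, root_factor: float = DEFAULT_ROOT_FACTOR
) -> pd.DataFrame:
    """Return *df* with a derived ``total_zn_uptake_ug`` column.

    Rows with missing root dry weight contribute shoot content only.  A
    measured root Zn concentration column, if present, is deliberately
    ignored (soil contamination) with a warning.
    """
    if MEASURED_ROOT_ZN_COLUMN in df.columns:
        warnings.warn(
            f"column {MEASURED_ROOT_ZN_COLUMN!r} is ignored: measured root Zn "
            "from soil-grown plants is contamination-dominated",
            stacklevel=2,
        )
    out = df.copy()
    root_dw = out["root_dw_mg"].fillna(0.0)
    out["total_zn_uptake_ug"] = (
        out["shoot_zn_ug_per_g"] * (out["shoot_dw_mg"] + root_factor * root_dw) / 1000.0
    )
    return out
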