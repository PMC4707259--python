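"""Synthetic plant-level datasets for the three experiment designs.

Generators impose the published group-level effect structure (growth-curve
trajectories, density fold-changes, regrowth-table means) on plant-level
records with multiplicative lognormal noise, so that every analysis stage
can be exercised end-to-end without external data.  At ``noise_cv=0`` the
generated group means equal the target quantities exactly and the full
pipeline reproduces the generating parameters.

Noise is mean-preserving: a CV of c multiplies each trait by
``exp(N(-σ²/2, σ²))`` with ``σ² = ln(1 + c²)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import reference
from .kinetics import ExpCurve, TimeConvention
from .uptake import DEFAULT_ROOT_FACTOR

__all__ = [
    "SimConfig",
    "DensityEffects",
    "generate_field",
    "generate_density",
    "generate_solution",
]


def _default_genotypes() -> dict[str, str]:
    # two tolerant and three sensitive genotypes, as in the original trial
    return {
        "T1": reference.TOLERANT,
        "T2": reference.TOLERANT,
        "S1": reference.SENSITIVE,
        "S2": reference.SENSITIVE,
        "S3": reference.SENSITIVE,
    }


def _default_group_curves() -> dict[str, dict[str, ExpCurve]]:
    return {g: dict(c) for g, c in reference.GROUP_CURVES.items()}


@dataclass(frozen=True)
class DensityEffects:
    """Per-plant fold-changes imposed by planting density.

    Folds are anchored at 1× for single-plant hills and the given folds at
    four plants per hill, interpolated log-linearly in density; with
    ``saturation_at_8`` the effect plateaus beyond four plants.
    """

    uptake_fold_at_4: float = 10.0
    root_dw_fold_at_4: float = 2.5
    saturation_at_8: bool = True

    def __post_init__(self) -> None:
        if self.uptake_fold_at_4 <= 0 or self.root_dw_fold_at_4 <= 0:
            raise ValueError("density folds must be > 0")

    def _fold(self, anchor: float, density: float) -> float:
        d = min(density, 4.0) if self.saturation_at_8 else density
        return anchor ** (math.log(d) / math.log(4.0))

    def uptake_fold(self, density: float) -> float:
        return self._fold(self.uptake_fold_at_4, density)

    def root_dw_fold(self, density: float) -> float:
        return self._fold(self.root_dw_fold_at_4, density)


@dataclass(frozen=True)
class SimConfig:
    """Configuration for all three synthetic experiments."""

    seed: int = 0
    genotypes: dict[str, str] = field(default_factory=_default_genotypes)
    n_reps: int = 4
    sampling_dat: tuple[int, ...] = (7, 14, 21, 28)
    group_curves: dict[str, dict[str, ExpCurve]] = field(
        default_factory=_default_group_curves
    )
    noise_cv: float = 0.10
    shoot_conc_minus_zn: float = 12.0
    root_factor: float = DEFAULT_ROOT_FACTOR
    seedling_zn_ug: float = 1.2
    #: content at 7 DAT relative to 14 DAT (slight decline 7→14 DAT,
    #: growth supported by retranslocation before uptake starts)
    pre_uptake_factor: float = 1.05
    pre_rsa_fraction: float = 0.6
    root_shoot_dw_ratio: float = 0.2
    crown_growth_rate: float = 0.05
    root_len_per_area_cm: float = 3.0
    fine_fraction: dict[str, float] = field(
        default_factory=lambda: {reference.TOLERANT: 0.48, reference.SENSITIVE: 0.54}
    )
    mid_fraction: float = 0.30
    densities: tuple[int, ...] = (1, 2, 4, 8)
    density_dat: int = 28
    density_effects: DensityEffects = field(default_factory=DensityEffects)
    root_dw_per_rsa_mg: float = 0.5
    #: optional (low, high) μg g⁻¹ range of soil-contaminated measured root
    #: Zn concentrations to attach to field rows
    contamination: tuple[float, float] | None = None
    #: regrowth experiment group targets
    solution_totals: dict[int, dict[str, float]] = field(
        default_factory=lambda: {
            dap: {g: reference.REGROWTH_TABLE["total_zn_ug"][dap][g] for g in
                  (reference.TOLERANT, reference.SENSITIVE)}
            for dap in (0, 13)
        }
    )
    retranslocated_ug: dict[str, float] = field(
        default_factory=lambda: dict(reference.RETRANSLOCATED_UG)
    )
    solution_root_shoot_dw_ratio: float = 0.15

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        for group, curves in self.group_curves.items():
            for key in ("uptake", "rsa"):
                if not isinstance(curves.get(key), ExpCurve):
                    raise ValueError(f"group_curves[{group!r}] must map {key!r} to an ExpCurve")
        groups = set(self.genotypes.values())
        if not groups <= set(self.group_curves):
            raise ValueError(f"no curves for groups {groups - set(self.group_curves)}")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def _noise(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def _field_row(cfg: SimConfig, rng, genotype: str, group: str, rep: int, dat: int,
               tc: TimeConvention) -> dict:
    curves = cfg.group_curves[group]
    t = tc.to_model_time(dat)
    if dat >= tc.origin_dat:
        content_true = cfg.seedling_zn_ug + curves["uptake"].value(t)
        rsa_true = curves["rsa"].value(t)
        crown_true = reference.CROWN_ROOTS_AT_ORIGIN[group] * math.exp(
            cfg.crown_growth_rate * t
        )
    else:
        # pre-uptake phase: content slightly above the 14-DAT level
        content_true = cfg.seedling_zn_ug * cfg.pre_uptake_factor
        rsa_true = curves["rsa"].value(0.0) * cfg.pre_rsa_fraction
        crown_true = reference.CROWN_ROOTS_AT_ORIGIN[group] * 0.7

    cv = cfg.noise_cv
    content = content_true * _noise(rng, cv)
    rsa = rsa_true * _noise(rng, cv)
    conc = cfg.shoot_conc_minus_zn * _noise(rng, cv)
    crown = crown_true * _noise(rng, cv)

    # partition dry weight so estimate_total_uptake reproduces `content`
    rho = cfg.root_shoot_dw_ratio
    shoot_dw = 1000.0 * content / (conc * (1.0 + cfg.root_factor * rho))
    root_dw = rho * shoot_dw

    total_len = rsa * cfg.root_len_per_area_cm
    f_fine = cfg.fine_fraction[group]
    fine = total_len * f_fine * _noise(rng, cv)
    mid = total_len * cfg.mid_fraction * _noise(rng, cv)
    coarse = total_len * max(1.0 - f_fine - cfg.mid_fraction, 0.0) * _noise(rng, cv)

    row = {
        "experiment": "field",
        "genotype": genotype,
        "group": group,
        "treatment": "minusZn",
        "dat": dat,
        "replicate": rep,
        "hill_density": 1,
        "shoot_dw_mg": shoot_dw,
        "root_dw_mg": root_dw,
        "shoot_zn_ug_per_g": conc,
        "crown_roots": crown,
        "rsa_cm2": rsa,
        "root_len_fine_cm": fine,
        "root_len_mid_cm": mid,
        "root_len_coarse_cm": coarse,
    }
    if cfg.contamination is not None:
        lo, hi = cfg.contamination
        row["root_zn_ug_per_g"] = float(rng.uniform(lo, hi))
    return row


def generate_field(cfg: SimConfig) -> pd.DataFrame:
    """Plant-level field-experiment table in the tidy schema.

    Group trajectories follow the configured curves at model time
    ``dat − 14``; the 7-DAT sampling is back-filled with pre-uptake values.
    Identical config and seed give identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    tc = TimeConvention()
    rows = [
        _field_row(cfg, rng, genotype, group, rep, dat, tc)
        for genotype, group in cfg.genotypes.items()
        for dat in cfg.sampling_dat
        for rep in range(1, cfg.n_reps + 1)
    ]
    return pd.DataFrame(rows)


def generate_density(cfg: SimConfig) -> pd.DataFrame:
    """Plant-level planting-density experiment table (tidy schema).

    Per-plant net uptake and root dry weight are scaled by the configured
    density effects; per-hill totals are per-plant values times density.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    tc = TimeConvention()
    t = tc.to_model_time(cfg.density_dat)
    eff = cfg.density_effects
    rows = []
    for genotype, group in cfg.genotypes.items():
        curves = cfg.group_curves[group]
        base_uptake = curves["uptake"].value(t)
        base_root_dw = curves["rsa"].value(t) * cfg.root_dw_per_rsa_mg
        for density in cfg.densities:
            fu = eff.uptake_fold(density)
            fr = eff.root_dw_fold(density)
            for rep in range(1, cfg.n_reps + 1):
                cv = cfg.noise_cv
                content = (cfg.seedling_zn_ug + base_uptake * fu) * _noise(rng, cv)
                root_dw = base_root_dw * fr * _noise(rng, cv)
                conc = cfg.shoot_conc_minus_zn * _noise(rng, cv)
                # shoot DW chosen so estimate_total_uptake returns `content`
                shoot_dw = max(
                    1000.0 * content / conc - cfg.root_factor * root_dw, 1.0
                )
                rows.append(
                    {
                        "experiment": "density",
                        "genotype": genotype,
                        "group": group,
                        "treatment": "minusZn",
                        "dat": cfg.density_dat,
                        "replicate": rep,
                        "hill_density": density,
                        "shoot_dw_mg": shoot_dw,
                        "root_dw_mg": root_dw,
                        "shoot_zn_ug_per_g": conc,
                        "crown_roots": np.nan,
                        "rsa_cm2": np.nan,
                        "root_len_fine_cm": np.nan,
                        "root_len_mid_cm": np.nan,
                        "root_len_coarse_cm": np.nan,
                    }
                )
    return pd.DataFrame(rows)


def generate_solution(cfg: SimConfig) -> pd.DataFrame:
    """Plant-level root-regrowth (solution) experiment table.

    Day-0 records describe intact seedlings just before root excision;
    day-13 records the harvest after regrowth in Zn-free solution, whose
    root Zn content is entirely retranslocated shoot Zn.  Contents are
    always concentration × dry weight / 1000 exactly, and per plant the
    retranslocated Zn never exceeds the day-0 shoot reserve.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    conc_tbl = reference.REGROWTH_TABLE
    rows = []
    for group in (reference.SENSITIVE, reference.TOLERANT):
        # day-0 derivation: split total content using the target tissue
        # concentrations and the configured root:shoot DW ratio
        t0 = cfg.solution_totals[0][group]
        c_s0 = conc_tbl["shoot_zn_ug_per_g"][0][group]
        c_r0 = conc_tbl["root_zn_ug_per_g"][0][group]
        rho = cfg.solution_root_shoot_dw_ratio
        shoot_dw0 = 1000.0 * t0 / (c_s0 + c_r0 * rho)
        root_dw0 = rho * shoot_dw0

        # day-13 derivation from the retranslocation target and totals
        retrans = cfg.retranslocated_ug[group]
        t13 = cfg.solution_totals[13][group]
        c_s13 = conc_tbl["shoot_zn_ug_per_g"][13][group]
        c_r13 = conc_tbl["root_zn_ug_per_g"][13][group]
        root_dw13 = 1000.0 * retrans / c_r13
        shoot_dw13 = 1000.0 * (t13 - retrans) / c_s13

        for rep in range(1, cfg.n_reps + 1):
            cv = cfg.noise_cv
            day0 = {
                "root_dw_mg": root_dw0 * _noise(rng, cv),
                "shoot_dw_mg": shoot_dw0 * _noise(rng, cv),
                "root_zn_ug_per_g": c_r0 * _noise(rng, cv),
                "shoot_zn_ug_per_g": c_s0 * _noise(rng, cv),
                "crown_roots": conc_tbl["crown_roots"][0][group] * _noise(rng, cv),
            }
            day13 = {
                "root_dw_mg": root_dw13 * _noise(rng, cv),
                "shoot_dw_mg": shoot_dw13 * _noise(rng, cv),
                "root_zn_ug_per_g": c_r13 * _noise(rng, cv),
                "shoot_zn_ug_per_g": c_s13 * _noise(rng, cv),
                "crown_roots": conc_tbl["crown_roots"][3][group] * _noise(rng, cv),
            }
            shoot_zn0 = day0["shoot_zn_ug_per_g"] * day0["shoot_dw_mg"] / 1000.0
            root_zn13 = day13["root_zn_ug_per_g"] * day13["root_dw_mg"] / 1000.0
            # conservation: retranslocated Zn cannot exceed the shoot reserve
            if root_zn13 > shoot_zn0:
                day13["root_dw_mg"] *= shoot_zn0 / root_zn13
                root_zn13 = shoot_zn0
            for dap, day in ((0, day0), (13, day13)):
                rows.append(
                    {
                        "experiment": "solution",
                        "group": group,
                        "replicate": rep,
                        "dap": dap,
                        **day,
                        "root_zn_ug": day["root_zn_ug_per_g"] * day["root_dw_mg"] / 1000.0,
                        "shoot_zn_ug": day["shoot_zn_ug_per_g"] * day["shoot_dw_mg"] / 1000.0,
                        "zn_free_solution": True,
                        "roots_excised": dap > 0,
                    }
                )
    return pd.DataFrame(rows)
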