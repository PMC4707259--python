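"""Analysis stages and the report-bundle pipeline.

Bridges plant-level tables to the curve-level analyses: extracts group-mean
time series (converting file time, days after transplanting, to model time
once and centrally), fits the growth curves, evaluates root efficiency,
runs the counterfactual decomposition, and emits a deterministic bundle of
JSON/CSV reports with a config-hash provenance log.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .counterfactual import decompose_difference
from .exceptions import RootznError
from .fieldstats import anova_lsd, density_folds, group_summary, significance_code
from .fitting import FitResult, GroupSeries, fit_exp, fit_group_pair
from .kinetics import ANALYSIS_WINDOW, EfficiencyCurve, TimeConvention, root_efficiency
from .redistribution import (
    RedistributionRecord,
    allocation_ratios,
    display_percent,
    group_excess,
    retranslocated_zn,
)
from .simulate import DensityEffects, SimConfig, generate_density, generate_field, generate_solution
from .uptake import DEFAULT_ROOT_FACTOR, add_total_uptake

logger = logging.getLogger("rootzn")

__all__ = [
    "extract_group_series",
    "fit_groups",
    "efficiency_grid",
    "density_report",
    "redistribution_report",
    "run_pipeline",
]


def extract_group_series(
    df: pd.DataFrame,
    time: TimeConvention | None = None,
    root_factor: float = DEFAULT_ROOT_FACTOR,
) -> dict[str, tuple[GroupSeries, GroupSeries]]:
    """Group-mean uptake and RSA series in model time from plant-level data.

    Only samplings at or after the time origin enter the fits (no uptake is
    detectable earlier); uptake is net of the group-mean content at the
    origin sampling, so the fitted uptake curves start near zero.
    """
    tc = time or TimeConvention()
    df = add_total_uptake(df, root_factor=root_factor)
    df = df[df["dat"] >= tc.origin_dat]
    out: dict[str, tuple[GroupSeries, GroupSeries]] = {}
    for group, sub in df.groupby("group"):
        means = sub.groupby("dat")[["total_zn_uptake_ug", "rsa_cm2"]].mean().sort_index()
        if tc.origin_dat not in means.index:
            raise RootznError(
                f"group {group!r} lacks a sampling at the origin ({tc.origin_dat} DAT)"
            )
        times = tuple(tc.to_model_time(d) for d in means.index)
        uptake = tuple(
            means["total_zn_uptake_ug"] - means.loc[tc.origin_dat, "total_zn_uptake_ug"]
        )
        rsa = tuple(means["rsa_cm2"])
        out[str(group)] = (
            GroupSeries(group_id=str(group), times=times, values=uptake, trait="uptake"),
            GroupSeries(group_id=str(group), times=times, values=rsa, trait="rsa"),
        )
    return out


def fit_groups(
    df: pd.DataFrame,
    time: TimeConvention | None = None,
    root_factor: float = DEFAULT_ROOT_FACTOR,
) -> dict[str, EfficiencyCurve]:
    """Fit per-group efficiency curves from plant-level field data."""
    series = extract_group_series(df, time=time, root_factor=root_factor)
    return {
        group: fit_group_pair(up, rsa, time=time)
        for group, (up, rsa) in series.items()
    }


def fit_details(
    df: pd.DataFrame,
    time: TimeConvention | None = None,
    root_factor: float = DEFAULT_ROOT_FACTOR,
) -> dict[str, dict[str, FitResult]]:
    """Per-group, per-trait :class:`FitResult` diagnostics."""
    series = extract_group_series(df, time=time, root_factor=root_factor)
    return {
        group: {"uptake": fit_exp(up, time=time), "rsa": fit_exp(rsa, time=time)}
        for group, (up, rsa) in series.items()
    }


def efficiency_grid(
    curves: dict[str, EfficiencyCurve], step: float = 0.5
) -> pd.DataFrame:
    """Root efficiency sampled on a model-time grid over the analysis window."""
    lo, hi = ANALYSIS_WINDOW
    ts = np.arange(lo, hi + step / 2, step)
    rows = []
    for group, ec in curves.items():
        for t in ts:
            rows.append(
                {
                    "group": group,
                    "t_model": float(t),
                    "dat": ec.time.to_dat(float(t)),
                    "re_ug_cm2_d": root_efficiency(ec, float(t)),
                }
            )
    return pd.DataFrame(rows)


def density_report(
    df: pd.DataFrame,
    seedling_zn_ug: float = 0.0,
    root_factor: float = DEFAULT_ROOT_FACTOR,
) -> pd.DataFrame:
    """Density fold-change table from plant-level density-experiment data.

    Net uptake per plant is estimated total content minus the seedling Zn
    content at transplanting.
    """
    df = add_total_uptake(df, root_factor=root_factor)
    df = df.assign(net_zn_uptake_ug=df["total_zn_uptake_ug"] - seedling_zn_ug)
    return density_folds(df)


def _group_mean_records(sol: pd.DataFrame) -> dict[tuple[str, int], RedistributionRecord]:
    recs = {}
    for (group, dap), sub in sol.groupby(["group", "dap"]):
        recs[(str(group), int(dap))] = RedistributionRecord(
            group=str(group),
            dap=int(dap),
            root_zn_content=float(sub["root_zn_ug"].mean()),
            shoot_zn_content=float(sub["shoot_zn_ug"].mean()),
            root_dw=float(sub["root_dw_mg"].mean()),
            shoot_dw=float(sub["shoot_dw_mg"].mean()),
            root_zn_conc=float(sub["root_zn_ug_per_g"].mean()),
            shoot_zn_conc=float(sub["shoot_zn_ug_per_g"].mean()),
            crown_roots=float(sub["crown_roots"].mean()),
            zn_free_solution=bool(sub["zn_free_solution"].all()),
            roots_excised=bool(sub["roots_excised"].all()),
        )
    return recs


def redistribution_report(sol: pd.DataFrame) -> dict:
    """Regrowth-experiment report: retranslocation, group excesses, ratios,
    and per-metric LSD significance codes."""
    recs = _group_mean_records(sol)
    try:
        tol0, sens0 = recs[("tolerant", 0)], recs[("sensitive", 0)]
        tol13, sens13 = recs[("tolerant", 13)], recs[("sensitive", 13)]
    except KeyError as err:
        raise RootznError(f"missing group/day cell in solution data: {err}") from err

    retrans = {
        "tolerant": retranslocated_zn(tol13),
        "sensitive": retranslocated_zn(sens13),
    }
    report = {
        "retranslocated_ug": retrans,
        "retranslocation_excess_percent": group_excess(
            retrans["tolerant"], retrans["sensitive"]
        ),
        "day0_total_zn_ug": {
            "tolerant": tol0.total_zn_content,
            "sensitive": sens0.total_zn_content,
        },
        "day0_total_excess_percent": group_excess(
            tol0.total_zn_content, sens0.total_zn_content
        ),
        "allocation": allocation_ratios(tol13, sens13),
    }
    report["display"] = {
        "retranslocation_excess_percent": display_percent(
            report["retranslocation_excess_percent"]
        ),
        "day0_total_excess_percent": display_percent(
            report["day0_total_excess_percent"]
        ),
    }
    # per-metric significance of the group contrast at each day
    sig = {}
    for metric, col in [
        ("total_zn_ug", None),
        ("root_zn_ug_per_g", "root_zn_ug_per_g"),
        ("shoot_zn_ug_per_g", "shoot_zn_ug_per_g"),
        ("crown_roots", "crown_roots"),
    ]:
        for dap, sub in sol.groupby("dap"):
            vals = (
                sub["root_zn_ug"] + sub["shoot_zn_ug"] if col is None else sub[col]
            )
            if sub.groupby("group").size().min() < 2:
                continue
            res = anova_lsd(vals.to_numpy(), sub["group"].to_numpy(), timepoint=dap)
            sig[f"{metric}@{int(dap)}"] = {
                "f_pvalue": res.f_pvalue,
                "lsd_05": res.lsd_05,
                "code": significance_code(res.f_pvalue),
            }
    report["significance"] = sig
    return report


# ---------------------------------------------------------------------------
# report-bundle pipeline


_STAGES = ("summary", "fit", "efficiency", "counterfactual", "density", "redistribution")


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def _sim_config(config: dict) -> SimConfig:
    sim = dict(config.get("simulate", {}))
    sim.pop("experiment", None)
    if "density_effects" in sim and isinstance(sim["density_effects"], dict):
        sim["density_effects"] = DensityEffects(**sim["density_effects"])
    if "seed" not in sim and "seed" in config:
        sim["seed"] = config["seed"]
    return SimConfig(**sim)


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run the configured stages and write a deterministic report bundle.

    The config names either an ``input`` CSV or a ``simulate`` block, plus a
    ``stages`` list.  Stage dependencies are checked up front: efficiency
    and counterfactual both require ``fit``.  Returns a manifest of written
    files; a ``log.json`` records the package version and config hash.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", ["summary", "fit", "efficiency", "counterfactual"]))
    for s in stages:
        if s not in _STAGES:
            raise RootznError(f"unknown stage {s!r}; valid: {_STAGES}")
    for dependent in ("efficiency", "counterfactual"):
        if dependent in stages and "fit" not in stages:
            raise RootznError(f"stage {dependent!r} requires stage 'fit'")

    manifest: dict[str, str] = {}
    experiment = config.get("simulate", {}).get("experiment", "field")

    from . import io as rio  # local import to avoid cycle at module load

    if "input" in config:
        path = config["input"]
        df = rio.read_solution_table(path) if experiment == "solution" else rio.read_table(path)
    else:
        cfg = _sim_config(config)
        gen = {
            "field": generate_field,
            "density": generate_density,
            "solution": generate_solution,
        }[experiment]
        df = gen(cfg)
        writer = rio.write_solution_table if experiment == "solution" else rio.write_table
        writer(df, outdir / "dataset.csv")
        manifest["dataset"] = "dataset.csv"

    root_factor = float(config.get("root_factor", DEFAULT_ROOT_FACTOR))
    curves: dict[str, EfficiencyCurve] | None = None

    for stage in stages:
        try:
            if stage == "summary" and experiment != "solution":
                summary = group_summary(
                    df,
                    by=["group", "dat"],
                    values=["shoot_dw_mg", "root_dw_mg", "shoot_zn_ug_per_g",
                            "crown_roots", "rsa_cm2"],
                )
                summary.to_csv(outdir / "summary.csv", index=False)
                manifest["summary"] = "summary.csv"
            elif stage == "fit" and experiment == "field":
                details = fit_details(df, root_factor=root_factor)
                fits_json = {
                    g: {trait: fr.to_dict() for trait, fr in d.items()}
                    for g, d in details.items()
                }
                (outdir / "fits.json").write_text(json.dumps(fits_json, indent=2))
                manifest["fits"] = "fits.json"
                curves = {
                    g: EfficiencyCurve(
                        uptake=d["uptake"].curve, rsa=d["rsa"].curve, group_id=g
                    )
                    for g, d in details.items()
                }
            elif stage == "efficiency" and curves:
                efficiency_grid(curves).to_csv(outdir / "efficiency.csv", index=False)
                manifest["efficiency"] = "efficiency.csv"
            elif stage == "counterfactual" and curves:
                horizons = config.get("counterfactual", {}).get("horizons", [7.0, 14.0])
                baseline = config.get("counterfactual", {}).get("baseline", "sensitive")
                attr = [
                    decompose_difference(
                        curves["tolerant"], curves["sensitive"], float(t1), baseline=baseline
                    ).to_dict()
                    for t1 in horizons
                ]
                (outdir / "attribution.json").write_text(json.dumps(attr, indent=2))
                manifest["attribution"] = "attribution.json"
            elif stage == "density" and experiment == "density":
                seedling = float(config.get("density", {}).get("seedling_zn_ug", 0.0))
                folds = density_report(df, seedling_zn_ug=seedling, root_factor=root_factor)
                folds.to_csv(outdir / "density_folds.csv")
                manifest["density_folds"] = "density_folds.csv"
            elif stage == "redistribution" and experiment == "solution":
                report = redistribution_report(df)
                (outdir / "redistribution.json").write_text(json.dumps(report, indent=2))
                manifest["redistribution"] = "redistribution.json"
        except RootznError as err:
            raise RootznError(f"stage {stage!r} failed: {err}") from err

    log = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "stages": stages,
        "experiment": experiment,
        "outputs": manifest,
    }
    (outdir / "log.json").write_text(json.dumps(log, indent=2))
    manifest["log"] = "log.json"
    logger.info("pipeline complete: %s", manifest)
    return manifest
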