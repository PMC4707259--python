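"""Published reference values from the zinc-deficiency field study.

These are the group-level fitted coefficients and summary-table means
reported for the original trial, bundled so that the worked examples can
be reproduced without any external data.  Values carry the units used
throughout the package: uptake μg plant⁻¹, RSA cm² plant⁻¹, dry weight
mg plant⁻¹, concentration μg g⁻¹, time in days.
"""

from __future__ import annotations

from .kinetics import ExpCurve, EfficiencyCurve, TimeConvention

__all__ = [
    "TOLERANT",
    "SENSITIVE",
    "GROUP_CURVES",
    "group_curves",
    "TREATMENT_MEANS",
    "REGROWTH_TABLE",
    "RETRANSLOCATED_UG",
    "DENSITY_EFFECT",
    "CRITICAL_SHOOT_ZN_UG_PER_G",
    "ROOT_TO_SHOOT_ZN_CONC_FACTOR",
    "RSA_AT_ORIGIN",
    "CROWN_ROOTS_AT_ORIGIN",
]

TOLERANT = "tolerant"
SENSITIVE = "sensitive"

#: Published group-level curve coefficients (model time origin 14 DAT):
#: uptake U(t) = a·exp(b·t) − c and RSA(t) = p·exp(q·t) − s.
GROUP_CURVES: dict[str, dict[str, ExpCurve]] = {
    TOLERANT: {
        "uptake": ExpCurve(1.09, 0.171, 1.09, role="uptake"),
        "rsa": ExpCurve(110.2, 0.082, 22.2, role="rsa"),
    },
    SENSITIVE: {
        "uptake": ExpCurve(0.64, 0.150, 0.63, role="uptake"),
        "rsa": ExpCurve(108.1, 0.045, 37.4, role="rsa"),
    },
}


def group_curves(group: str) -> EfficiencyCurve:
    """Published :class:`EfficiencyCurve` for ``"tolerant"`` or ``"sensitive"``."""
    curves = GROUP_CURVES[group]
    return EfficiencyCurve(
        uptake=curves["uptake"],
        rsa=curves["rsa"],
        group_id=group,
        time=TimeConvention(origin_dat=14),
    )


#: Treatment-level means (SE in parentheses in the source table) for total
#: plant dry weight (mg plant⁻¹) and shoot Zn concentration (μg g⁻¹) at the
#: four samplings, averaged over genotypes.
TREATMENT_MEANS: dict[str, dict[str, dict[int, float]]] = {
    "total_dw_mg": {
        "minusZn": {7: 60.3, 15: 144.7, 21: 262.4, 28: 608.7},
        "plusZn": {7: 58.7, 15: 218.8, 21: 709.2, 28: 2549.9},
    },
    "total_dw_se_mg": {
        "minusZn": {7: 2.3, 15: 6.9, 21: 22.7, 28: 81.0},
        "plusZn": {7: 2.2, 15: 8.3, 21: 47.7, 28: 210.0},
    },
    "shoot_zn_ug_per_g": {
        "minusZn": {7: 31.1, 15: 11.3, 21: 11.9, 28: 12.8},
        "plusZn": {7: 37.9, 15: 23.6, 21: 24.7, 28: 22.9},
    },
    "shoot_zn_se_ug_per_g": {
        "minusZn": {7: 1.7, 15: 0.3, 21: 0.5, 28: 0.5},
        "plusZn": {7: 1.3, 15: 0.5, 21: 1.0, 28: 0.4},
    },
}

#: Critical shoot Zn concentration below which rice is considered deficient.
CRITICAL_SHOOT_ZN_UG_PER_G: float = 15.0

#: Root Zn concentration is taken as this multiple of shoot Zn concentration
#: (nutrient-solution calibration; soil-grown root Zn is unreliable).
ROOT_TO_SHOOT_ZN_CONC_FACTOR: float = 1.7

#: Root-removal regrowth experiment: group means by days after replanting.
#: ``lsd_05`` is the published LSD at P ≤ 0.05 (None where not significant).
REGROWTH_TABLE: dict[str, dict[int, dict[str, float | None]]] = {
    "crown_roots": {
        0: {SENSITIVE: 12.4, TOLERANT: 14.0, "lsd_05": None},
        1: {SENSITIVE: 2.5, TOLERANT: 3.5, "lsd_05": 0.9},
        3: {SENSITIVE: 8.8, TOLERANT: 10.7, "lsd_05": 1.0},
    },
    "total_zn_ug": {
        0: {SENSITIVE: 1.11, TOLERANT: 1.33, "lsd_05": 0.18},
        13: {SENSITIVE: 1.23, TOLERANT: 1.53, "lsd_05": 0.28},
    },
    "root_zn_ug_per_g": {
        0: {SENSITIVE: 49.1, TOLERANT: 55.6, "lsd_05": 4.4},
        13: {SENSITIVE: 24.7, TOLERANT: 22.6, "lsd_05": None},
    },
    "shoot_zn_ug_per_g": {
        0: {SENSITIVE: 36.8, TOLERANT: 39.9, "lsd_05": 2.9},
        13: {SENSITIVE: 14.4, TOLERANT: 12.5, "lsd_05": None},
    },
}

#: Zn retranslocated from shoot to regrown roots (μg plant⁻¹), i.e. harvest
#: root Zn content in the Zn-free regrowth experiment.
RETRANSLOCATED_UG: dict[str, float] = {TOLERANT: 0.45, SENSITIVE: 0.27}

#: Planting-density experiment: published per-plant fold-changes between
#: 1 and 4 seedlings per hill, with saturation at 8 seedlings.
DENSITY_EFFECT: dict[str, float | bool] = {
    "uptake_fold_at_4": 10.0,
    "root_dw_fold_at_4": 2.5,
    "saturation_at_8": True,
}

#: Measured group-mean RSA at 14 DAT (cm² plant⁻¹), equal to the fitted
#: RSA curves evaluated at model time 0.
RSA_AT_ORIGIN: dict[str, float] = {TOLERANT: 88.0, SENSITIVE: 70.7}

#: Measured group-mean crown-root counts at 14 DAT.
CROWN_ROOTS_AT_ORIGIN: dict[str, float] = {TOLERANT: 26.5, SENSITIVE: 20.1}
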