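"""Offset-exponential growth curves and the root-efficiency statistic.

The central model is the three-parameter offset exponential

    value(t) = scale * exp(rate * t) - offset

used both for cumulative Zn uptake per plant (``role="uptake"``, μg plant⁻¹)
and for root surface area per plant (``role="rsa"``, cm² plant⁻¹), with *t*
in model days.  Root efficiency is the instantaneous uptake rate per unit
root surface area,

    RE(t) = (dU/dt) / RSA(t)

in μg cm⁻² d⁻¹.  Model time ``t = 0`` corresponds to the first sampling used
for curve fitting (14 days after transplanting); the :class:`TimeConvention`
record makes that origin explicit, and the analysis window is the fixed
14-day span ``[0, 14]`` of model time (14–28 DAT).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

from .exceptions import DomainViolationError

__all__ = [
    "ANALYSIS_WINDOW",
    "DEFAULT_ORIGIN_DAT",
    "ExpCurve",
    "EfficiencyCurve",
    "TimeConvention",
    "eval_curve",
    "curve_rate",
    "root_efficiency",
]

#: Model-time analysis window in days (14–28 DAT at the default origin).
ANALYSIS_WINDOW: tuple[float, float] = (0.0, 14.0)

#: Days after transplanting corresponding to model time t = 0.
DEFAULT_ORIGIN_DAT: int = 14

Role = Literal["uptake", "rsa"]


@dataclass(frozen=True)
class TimeConvention:
    """Mapping between days-after-transplanting and model time.

    Model time ``t = dat - origin_dat``; all curve evaluation happens in
    model time.  Keeping the conversion in one place prevents silent
    origin bugs when mixing file time (DAT) with fitted-curve time.
    """

    origin_dat: int = DEFAULT_ORIGIN_DAT

    def to_model_time(self, dat: float) -> float:
        return float(dat) - self.origin_dat

    def to_dat(self, t: float) -> float:
        return float(t) + self.origin_dat

    def in_window(self, t: float) -> bool:
        """Whether model time *t* lies in the supported analysis window."""
        lo, hi = ANALYSIS_WINDOW
        return lo <= t <= hi


@dataclass(frozen=True)
class ExpCurve:
    """Offset-exponential curve ``scale * exp(rate * t) - offset``.

    Parameters
    ----------
    scale, rate, offset
        Curve coefficients; ``scale`` and ``offset`` carry the trait units
        (μg plant⁻¹ for uptake, cm² plant⁻¹ for RSA), ``rate`` is in d⁻¹.
    role
        Which trait this curve models; ``"uptake"`` or ``"rsa"``.
    """

    scale: float
    rate: float
    offset: float
    role: Role = "uptake"

    def __post_init__(self) -> None:
        if not (self.scale > 0):
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if not (self.rate > 0):
            raise ValueError(f"rate must be > 0, got {self.rate}")
        if self.role not in ("uptake", "rsa"):
            raise ValueError(f"role must be 'uptake' or 'rsa', got {self.role!r}")

    def value(self, t: float) -> float:
        """Curve value at model time *t* (trait units)."""
        return self.scale * math.exp(self.rate * t) - self.offset

    def derivative(self, t: float) -> float:
        """Instantaneous rate of change at *t* (trait units d⁻¹); always > 0."""
        return self.scale * self.rate * math.exp(self.rate * t)

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "rate": self.rate,
            "offset": self.offset,
            "role": self.role,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExpCurve":
        return cls(
            scale=float(d["scale"]),
            rate=float(d["rate"]),
            offset=float(d["offset"]),
            role=d.get("role", "uptake"),
        )


@dataclass(frozen=True)
class EfficiencyCurve:
    """Paired uptake and RSA curves for one genotype group.

    The pairing yields the root-efficiency statistic
    ``RE(t) = uptake.derivative(t) / rsa.value(t)``.  Construction checks
    that the RSA curve is strictly positive over the analysis window, the
    condition required for RE to be well defined there.
    """

    uptake: ExpCurve
    rsa: ExpCurve
    group_id: str
    time: TimeConvention = field(default_factory=TimeConvention)

    def __post_init__(self) -> None:
        if self.uptake.role != "uptake":
            raise ValueError("uptake curve must have role='uptake'")
        if self.rsa.role != "rsa":
            raise ValueError("rsa curve must have role='rsa'")
        # scale,rate > 0 makes the curve strictly increasing, so positivity
        # over the whole window follows from positivity at its left edge.
        lo = ANALYSIS_WINDOW[0]
        if self.rsa.value(lo) <= 0:
            raise DomainViolationError(
                f"RSA curve for group {self.group_id!r} is non-positive at "
                f"t={lo} ({self.rsa.value(lo):.4g}); RE undefined on window"
            )

    def efficiency(self, t: float) -> float:
        """Root efficiency at model time *t* (μg cm⁻² d⁻¹)."""
        return root_efficiency(self, t)

    def to_dict(self) -> dict:
        return {
            "group_id": self.group_id,
            "origin_dat": self.time.origin_dat,
            "uptake": self.uptake.to_dict(),
            "rsa": self.rsa.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EfficiencyCurve":
        return cls(
            uptake=ExpCurve.from_dict(d["uptake"]),
            rsa=ExpCurve.from_dict(d["rsa"]),
            group_id=str(d["group_id"]),
            time=TimeConvention(int(d.get("origin_dat", DEFAULT_ORIGIN_DAT))),
        )


def eval_curve(curve: ExpCurve, t: float) -> float:
    """Evaluate *curve* at model time *t*.

    Returns ``scale * exp(rate * t) - offset`` in the curve's trait units.
    """
    if not math.isfinite(t):
        raise ValueError(f"t must be finite, got {t}")
    return curve.value(t)


def curve_rate(curve: ExpCurve, t: float) -> float:
    """Analytic derivative of *curve* at *t*: ``scale * rate * exp(rate * t)``.

    Strictly positive for any valid curve.
    """
    if not math.isfinite(t):
        raise ValueError(f"t must be finite, got {t}")
    return curve.derivative(t)


def root_efficiency(ec: EfficiencyCurve, t: float) -> float:
    """Root efficiency ``RE(t) = (dU/dt) / RSA(t)`` in μg cm⁻² d⁻¹.

    Raises
    ------
    DomainViolationError
        If the RSA curve is non-positive at *t*.
    """
    rsa = eval_curve(ec.rsa, t)
    if rsa <= 0:
        raise DomainViolationError(
            f"RSA non-positive ({rsa:.4g}) at t={t} for group {ec.group_id!r}"
        )
    return curve_rate(ec.uptake, t) / rsa
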