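"""Least-squares fitting of offset-exponential curves to group-mean series.

The model ``v(t) = scale·exp(rate·t) − offset`` is linear in ``scale`` and
``offset`` once ``rate`` is fixed, which the fitter exploits: a deterministic
multi-start grid over trial rates seeds bounded nonlinear least squares with
an analytic Jacobian, and the winning solution is polished by re-solving the
linear subproblem at the fitted rate.  Three points and three parameters
interpolate exactly, so roundtrip fits of published coefficients recover
them to reporting precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DegenerateSeriesError
from .kinetics import ExpCurve, EfficiencyCurve, Role, TimeConvention

__all__ = [
    "GroupSeries",
    "FitResult",
    "fit_exp",
    "fit_group_pair",
    "RATE_GRID",
    "DEFAULT_RATE_BOUNDS",
]

#: Deterministic multi-start grid of trial rates (d⁻¹).
RATE_GRID: tuple[float, ...] = (0.02, 0.05, 0.1, 0.2, 0.4)

#: Bounds on the rate coefficient (d⁻¹).
DEFAULT_RATE_BOUNDS: tuple[float, float] = (1e-4, 1.0)

_SCALE_FLOOR = 1e-12


@dataclass(frozen=True)
class GroupSeries:
    """A group-mean trait time-series in model time."""

    group_id: str
    times: tuple[float, ...]
    values: tuple[float, ...]
    trait: Role = "uptake"
    se: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        values = tuple(float(v) for v in self.values)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if self.se is not None:
            object.__setattr__(self, "se", tuple(float(s) for s in self.se))
        if len(times) != len(values):
            raise ValueError("times and values must have equal length")
        if len(times) < 3:
            raise DegenerateSeriesError(
                f"need at least 3 points for a 3-parameter fit, got {len(times)}"
            )
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        if not all(np.isfinite(values)):
            raise ValueError("values must be finite")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a single curve fit."""

    curve: ExpCurve
    rss: float
    converged: bool
    n_points: int
    n_starts_used: int
    time: TimeConvention = field(default_factory=TimeConvention)

    def predictions(self, times: Sequence[float]) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return self.curve.scale * np.exp(self.curve.rate * t) - self.curve.offset

    def to_dict(self) -> dict:
        c = self.curve
        return {
            "curve": c.to_dict(),
            "display": f"{c.scale:.3f} exp({c.rate:.3f} t) - {c.offset:.3f}",
            "rss": self.rss,
            "converged": self.converged,
            "n_points": self.n_points,
            "n_starts_used": self.n_starts_used,
            "origin_dat": self.time.origin_dat,
        }


def _linear_solve(t: np.ndarray, v: np.ndarray, rate: float) -> tuple[float, float, float]:
    """Best (scale, offset) and RSS for a fixed rate; model is linear in both."""
    design = np.column_stack([np.exp(rate * t), -np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    scale, offset = float(coef[0]), float(coef[1])
    resid = design @ coef - v
    return scale, offset, float(resid @ resid)


def _residuals(params: np.ndarray, t: np.ndarray, v: np.ndarray) -> np.ndarray:
    scale, rate, offset = params
    return scale * np.exp(rate * t) - offset - v


def _jacobian(params: np.ndarray, t: np.ndarray, v: np.ndarray) -> np.ndarray:
    scale, rate, _ = params
    e = np.exp(rate * t)
    return np.column_stack([e, scale * t * e, -np.ones_like(t)])


def fit_exp(
    series: GroupSeries,
    bounds: tuple[float, float] = DEFAULT_RATE_BOUNDS,
    time: TimeConvention | None = None,
) -> FitResult:
    """Fit ``scale·exp(rate·t) − offset`` to *series* by least squares.

    Deterministic: every trial rate on :data:`RATE_GRID` (clipped to
    *bounds*) seeds the linear subproblem, the best seed is refined by
    bounded nonlinear least squares with the analytic Jacobian, and the
    linear subproblem is re-solved at the refined rate.

    Raises
    ------
    DegenerateSeriesError
        For constant series or fewer than 3 distinct times, where the rate
        is unidentifiable.
    """
    t = np.asarray(series.times, dtype=float)
    v = np.asarray(series.values, dtype=float)
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError(f"invalid rate bounds {bounds}")

    if len(np.unique(t)) < 3:
        raise DegenerateSeriesError("fewer than 3 distinct times: rate unidentifiable")
    if np.ptp(v) == 0:
        raise DegenerateSeriesError(
            f"constant series (value {v[0]!r}): rate unidentifiable"
        )

    starts = [r for r in RATE_GRID if lo <= r <= hi] or [np.sqrt(lo * hi)]
    best: tuple[float, float, float, float] | None = None  # rss, scale, rate, offset
    for rate in starts:
        scale, offset, rss = _linear_solve(t, v, rate)
        if best is None or rss < best[0]:
            best = (rss, scale, rate, offset)
    assert best is not None
    _, scale0, rate0, offset0 = best
    scale0 = max(scale0, _SCALE_FLOOR)

    res = least_squares(
        _residuals,
        x0=np.array([scale0, rate0, offset0]),
        jac=_jacobian,
        bounds=([_SCALE_FLOOR, lo, -np.inf], [np.inf, hi, np.inf]),
        args=(t, v),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-14,
        max_nfev=2000,
    )
    scale, rate, offset = (float(x) for x in res.x)
    rss = float(res.fun @ res.fun)

    # Polish: the model is linear in (scale, offset) at the fitted rate.
    p_scale, p_offset, p_rss = _linear_solve(t, v, rate)
    if p_rss <= rss and p_scale > 0:
        scale, offset, rss = p_scale, p_offset, p_rss

    curve = ExpCurve(scale=scale, rate=rate, offset=offset, role=series.trait)
    return FitResult(
        curve=curve,
        rss=rss,
        converged=bool(res.status > 0),
        n_points=len(t),
        n_starts_used=len(starts),
        time=time or TimeConvention(),
    )


def fit_group_pair(
    uptake_series: GroupSeries,
    rsa_series: GroupSeries,
    bounds: tuple[float, float] = DEFAULT_RATE_BOUNDS,
    time: TimeConvention | None = None,
) -> EfficiencyCurve:
    """Fit uptake and RSA series of one group into an :class:`EfficiencyCurve`."""
    if uptake_series.group_id != rsa_series.group_id:
        raise ValueError(
            f"group_id mismatch: {uptake_series.group_id!r} vs {rsa_series.group_id!r}"
        )
    if uptake_series.trait != "uptake":
        raise ValueError("uptake_series must have trait='uptake'")
    if rsa_series.trait != "rsa":
        raise ValueError("rsa_series must have trait='rsa'")
    tc = time or TimeConvention()
    up = fit_exp(uptake_series, bounds=bounds, time=tc)
    rs = fit_exp(rsa_series, bounds=bounds, time=tc)
    return EfficiencyCurve(
        uptake=up.curve, rsa=rs.curve, group_id=uptake_series.group_id, time=tc
    )
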