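"""Noncompartmental terminal-phase analysis.

Serum activity after a bolus IV injection declines (multi)exponentially, so
the terminal elimination phase is linear in log10(concentration) versus time.
Ordinary least squares on that line gives the elimination slope ``m`` (log10
units per minute); the elimination half-life is

    t_half = log10(2) / |m|        (the familiar "0.301 / |m|")

equivalently ``t_half = ln 2 / k`` with the natural-log elimination rate
``k = |m| * ln 10``.  The constant is carried at full floating precision;
0.301 and 0.693 are what it rounds to at three decimals.

The slope is invariant to the concentration scale (raw cpm/ml versus %Inj/ml
changes the intercept only), so fits are run on the stored cpm/ml values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._ols import simple_ols
from .errors import DomainError, InsufficientDataError, NoDecayError, SelectionError
from .study import SerumCurve, aggregate_duplicate_times

LOG10_2 = math.log10(2.0)
LN_10 = math.log(10.0)

__all__ = [
    "HalfLifeFit",
    "TerminalPhaseModel",
    "fit_terminal_phase",
    "half_life_from_slope",
    "elimination_rate_from_slope",
    "select_terminal_window",
    "LOG10_2",
]


def half_life_from_slope(slope_m: float) -> float:
    """Half-life (minutes) from a log10-domain elimination slope.

    ``slope_m`` must be negative (decaying concentrations); the result is
    ``log10(2) / |slope_m|``, identical to ``ln 2 / k`` for
    ``k = |slope_m| * ln 10``.
    """
    if not slope_m < 0:
        raise DomainError(f"elimination slope must be negative, got {slope_m}")
    return LOG10_2 / abs(slope_m)


def elimination_rate_from_slope(slope_m: float) -> float:
    """Natural-log elimination rate k (1/min) from a log10 slope."""
    if not slope_m < 0:
        raise DomainError(f"elimination slope must be negative, got {slope_m}")
    return abs(slope_m) * LN_10


@dataclass
class HalfLifeFit:
    """Result of a log-linear terminal-phase fit.

    Attributes
    ----------
    window_min : (float, float)
        Closed time interval actually used.
    slope_m : float
        Elimination slope in log10 units per minute (negative).
    slope_se : float
        Standard error of the slope (NaN for a two-point fit, which has no
        residual degrees of freedom).
    intercept_log10 : float
        log10 concentration at t = 0 of the fitted line (units follow the
        input concentrations).
    r2 : float
        Coefficient of determination.
    n_points : int
        Points used in the fit.
    t_half_min : float
        Elimination half-life, minutes.
    k_elim_per_min : float
        Natural-log elimination rate, ``|slope_m| * ln 10``.
    two_point_warning : bool
        True when the fit used only two points.
    """

    window_min: tuple[float, float]
    slope_m: float
    slope_se: float
    intercept_log10: float
    r2: float
    n_points: int
    t_half_min: float
    k_elim_per_min: float
    two_point_warning: bool = False

    def to_dict(self) -> dict:
        return {
            "window": list(self.window_min),
            "slope_log10": self.slope_m,
            "slope_se": self.slope_se,
            "intercept_log10": self.intercept_log10,
            "r2": self.r2,
            "n": self.n_points,
            "t_half_min": self.t_half_min,
            "k_elim_per_min": self.k_elim_per_min,
            "two_point_warning": self.two_point_warning,
        }

    def summary(self) -> str:
        lines = [
            "Terminal-phase log-linear fit",
            f"  window [min]      : {self.window_min[0]:.3f} .. {self.window_min[1]:.3f}",
            f"  n points          : {self.n_points}",
            f"  slope m [log10/min]: {self.slope_m:.6g} (SE {self.slope_se:.3g})",
            f"  r^2               : {self.r2:.4f}",
            f"  t1/2 [min]        : {self.t_half_min:.3f}",
            f"  k [1/min]         : {self.k_elim_per_min:.6g}",
        ]
        if self.two_point_warning:
            lines.append("  WARNING: two-point fit; no residual degrees of freedom")
        return "\n".join(lines)


class TerminalPhaseModel:
    """Log-linear regression model for the terminal elimination phase.

    Parameters
    ----------
    curve : SerumCurve
        Serum concentration–time data (one tracer).
    window : (float, float), optional
        Closed time interval to fit; defaults to the full sampled range.
        Use ``None`` bounds (or +-inf) for open ends.
    aggregate : {"none", "geometric", "arithmetic"}
        How to treat animals sharing a nominal time.  ``"none"`` (default)
        regresses on every individual point, which is equivalent to averaging
        log-values *after* transformation but weights each time by its number
        of animals; ``"geometric"`` pools per time before fitting.
    """

    def __init__(self, curve: SerumCurve, window=None, aggregate: str = "none"):
        if aggregate not in ("none", "geometric", "arithmetic"):
            raise DomainError(f"unknown aggregate mode {aggregate!r}")
        if aggregate != "none":
            curve = aggregate_duplicate_times(curve, aggregate)
        self.curve = curve
        lo, hi = window if window is not None else (-np.inf, np.inf)
        lo = -np.inf if lo is None else lo
        hi = np.inf if hi is None else hi
        self.window = (lo, hi)

    @classmethod
    def with_auto_window(cls, curve: SerumCurve, min_points: int = 3,
                         r2_min: float = 0.99, aggregate: str = "none"):
        """Build a model using the automatically selected terminal window."""
        window = select_terminal_window(curve, min_points=min_points, r2_min=r2_min)
        return cls(curve, window=window, aggregate=aggregate)

    def fit(self) -> HalfLifeFit:
        lo, hi = self.window
        t = self.curve.times
        c = self.curve.activity
        mask = (t >= lo) & (t <= hi)
        t, c = t[mask], c[mask]
        n = len(t)
        if n < 2 or len(np.unique(t)) < 2:
            raise InsufficientDataError(
                f"terminal-phase fit needs >= 2 distinct times in window "
                f"[{lo}, {hi}], found {n} point(s)"
            )
        res = simple_ols(t, np.log10(c))
        slope = res.slope
        if slope >= 0:
            raise NoDecayError(
                f"fitted slope {slope:.4g} >= 0 in window [{lo}, {hi}]; "
                "no half-life defined"
            )
        two_point = n == 2
        return HalfLifeFit(
            window_min=(float(t.min()), float(t.max())),
            slope_m=slope,
            slope_se=res.slope_se,
            intercept_log10=res.intercept,
            r2=1.0 if two_point else res.r2,
            n_points=n,
            t_half_min=half_life_from_slope(slope),
            k_elim_per_min=elimination_rate_from_slope(slope),
            two_point_warning=two_point,
        )


def fit_terminal_phase(curve: SerumCurve, window=None, aggregate: str = "none") -> HalfLifeFit:
    """OLS of log10(concentration) on time within ``window``; see
    :class:`TerminalPhaseModel`."""
    return TerminalPhaseModel(curve, window=window, aggregate=aggregate).fit()


def select_terminal_window(curve: SerumCurve, min_points: int = 3,
                           r2_min: float = 0.99) -> tuple[float, float]:
    """Automated surrogate for visually picking the terminal phase.

    Returns the longest suffix of distinct time points whose log10-linear fit
    has a negative slope and r^2 >= ``r2_min``.  Suffixes are nested, so the
    answer is unique and deterministic.  Duplicate nominal times are pooled
    geometrically before scanning.
    """
    agg = aggregate_duplicate_times(curve, "geometric")
    t = agg.times
    y = np.log10(agg.activity)
    n = len(t)
    if n < min_points:
        raise InsufficientDataError(
            f"window selection needs >= {min_points} distinct times, found {n}"
        )
    for start in range(0, n - min_points + 1):
        ts, ys = t[start:], y[start:]
        slope, intercept = np.polyfit(ts, ys, 1)
        if slope >= 0:
            continue
        resid = ys - (slope * ts + intercept)
        syy = float(np.sum((ys - ys.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / syy if syy > 0 else 0.0
        if r2 >= r2_min:
            return (float(ts[0]), float(ts[-1]))
    raise SelectionError(
        f"no suffix of >= {min_points} points reaches r^2 >= {r2_min} with a "
        "negative slope; supply a manual window"
    )
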