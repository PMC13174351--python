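"""Patlak multiple-time regression of unidirectional tissue influx.

For a tracer entering tissue irreversibly from blood, tissue activity per
gram follows

    Am(t) = Ki * AUC(t) + Vi * Cp(t)

where ``AUC(t)`` is the integral of serum activity from injection to t.
Dividing by Cp(t) gives the Patlak (multiple-time regression) form

    Am(t)/Cp(t) = Ki * Expt(t) + Vi,     Expt(t) = AUC(t) / Cp(t),

so tissue/serum ratio against exposure time is a line whose slope is the
unidirectional influx constant Ki (ul of serum cleared per g tissue per min)
and whose intercept Vi (ul/g) is the rapidly reversible space (vascular
volume plus fast binding).  Exposure time is a clearance-corrected time axis:
for a tracer that is not cleared it equals t, for a cleared tracer it grows
more slowly.

Tissue/serum ratios are corrected for intravascular tracer by subtracting the
ratio of a co-injected vascular marker (albumin, assumed Ki = 0), giving the
"delta T/S" that is regressed.  Negative delta values are retained: truncating
them would bias Vi.

Because each animal contributes a single terminal sample, Expt is evaluated on
the pooled group serum curve (geometric aggregation over animals sharing a
nominal time), not per animal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from ._ols import simple_ols
from scipy.integrate import cumulative_trapezoid

from .errors import (
    DegenerateDesignError,
    DomainError,
    ExtrapolationError,
    InsufficientDataError,
    PairingError,
    SelectionError,
    ValidationError,
)
from .serum_model import SerumModel, fit_serum_model, log_param_covariance, perturbed
from .study import SerumCurve, TissueMeasurement, TissueSeries, TracerStudy, aggregate_duplicate_times

__all__ = [
    "ExposurePoint",
    "RatioPoint",
    "PatlakFit",
    "PatlakModel",
    "GroupComparison",
    "exposure_time",
    "exposure_profile",
    "tissue_serum_ratio",
    "vascular_corrected_ratios",
    "patlak_points",
    "fit_patlak",
    "select_linear_portion",
    "compare_fits",
]


@dataclass(frozen=True)
class ExposurePoint:
    """Exposure time at one clock time: Expt = AUC(0,t) / Cp(t)."""

    time_min: float
    expt_min: float
    auc_to_t: float  # (cpm/ml)*min on the curve's own scale
    cp_at_t: float  # cpm/ml


@dataclass
class RatioPoint:
    """One animal's Patlak point for one tissue.

    ``ts_ul_per_g`` is the raw tissue/serum ratio; ``delta_ts_ul_per_g`` is
    the vascular-corrected ratio actually regressed (equal to the raw ratio
    when no correction was applied; may be negative).  ``expt_min`` is the
    exposure time of that animal's terminal time on the pooled serum curve.
    """

    animal_id: str
    time_min: float
    ts_ul_per_g: float
    delta_ts_ul_per_g: float
    expt_min: float = float("nan")


# ---------------------------------------------------------------------------
# exposure time


def _log_interp(knot_t: np.ndarray, knot_logc: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Piecewise log-linear interpolation with log-linear end extension."""
    out = np.interp(t, knot_t, knot_logc)
    if len(knot_t) >= 2:
        lo_slope = (knot_logc[1] - knot_logc[0]) / (knot_t[1] - knot_t[0])
        hi_slope = (knot_logc[-1] - knot_logc[-2]) / (knot_t[-1] - knot_t[-2])
        below = t < knot_t[0]
        above = t > knot_t[-1]
        out = np.where(below, knot_logc[0] + lo_slope * (t - knot_t[0]), out)
        out = np.where(above, knot_logc[-1] + hi_slope * (t - knot_t[-1]), out)
    return out


def exposure_profile(
    curve: SerumCurve,
    times,
    *,
    extrapolate_t0: bool = True,
    allow_beyond_last: bool = False,
    grid_step: float | None = None,
    serum_model: SerumModel | None = None,
) -> list[ExposurePoint]:
    """Exposure time at several clock times from one pooled serum curve.

    The curve is aggregated geometrically over duplicate nominal times, then
    interpolated log-linearly (exponential segments); AUC is the trapezoid sum
    on a dense resampled grid whose step defaults to
    ``min(0.01 min, smallest sampling gap / 100)``.  By default Cp is
    back-extrapolated to t = 0 with the log-linear extension of the first two
    samples (a bolus IV dose has finite Cp(0)); with
    ``extrapolate_t0=False`` the integral starts at the first sample.
    Times beyond the last sample raise unless ``allow_beyond_last``.

    Passing ``serum_model`` replaces the numeric route by the model's
    closed-form AUC and Cp (used with input functions fitted to the observed
    curve; exposure time is invariant to the model's amplitude scale).
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if serum_model is not None:
        return [
            ExposurePoint(float(t), float(serum_model.expt(t)) if t > 0 else 0.0,
                          float(serum_model.auc(t)), float(serum_model.cp(t)))
            for t in times
        ]

    agg = aggregate_duplicate_times(curve, "geometric")
    kt = agg.times
    if len(kt) < 2:
        raise InsufficientDataError(
            "exposure time needs >= 2 distinct serum times for interpolation"
        )
    klogc = np.log(agg.activity)
    t_max = float(times.max())
    if t_max > kt[-1] and not allow_beyond_last:
        raise ExtrapolationError(
            f"t={t_max} beyond last serum sample ({kt[-1]}); "
            "pass allow_beyond_last=True to extrapolate"
        )
    t_lo = 0.0 if extrapolate_t0 else float(kt[0])
    step = grid_step if grid_step is not None else min(0.01, float(np.min(np.diff(kt))) / 100.0)
    if step <= 0:
        raise DomainError("grid_step must be positive")
    hi = max(t_max, t_lo)
    grid = np.unique(np.concatenate([
        np.arange(t_lo, hi, step),
        kt[(kt >= t_lo) & (kt <= hi)],
        times[(times >= t_lo) & (times <= hi)],
        [t_lo, hi],
    ]))
    c_grid = np.exp(_log_interp(kt, klogc, grid))
    cum = cumulative_trapezoid(c_grid, grid, initial=0.0)

    out = []
    for t in times:
        cp = float(np.exp(_log_interp(kt, klogc, np.array([t]))[0]))
        if not cp > 0 or not np.isfinite(cp):
            raise DomainError(f"interpolated Cp({t}) is not positive")
        auc = float(np.interp(t, grid, cum)) if t > t_lo else 0.0
        out.append(ExposurePoint(float(t), auc / cp, auc, cp))
    return out


def exposure_time(curve: SerumCurve, t: float, **kwargs) -> ExposurePoint:
    """Exposure time at a single clock time; see :func:`exposure_profile`."""
    return exposure_profile(curve, [t], **kwargs)[0]


# ---------------------------------------------------------------------------
# ratios and vascular correction


def tissue_serum_ratio(m: TissueMeasurement) -> float:
    """Tissue/serum ratio in ul/g: (cpm/g) / (cpm/ml) * 1000."""
    if not m.serum_activity_per_ml > 0:
        raise DomainError("serum activity must be positive")
    return m.activity_per_g / m.serum_activity_per_ml * 1000.0


def vascular_corrected_ratios(
    ligand: TissueSeries,
    marker: TissueSeries,
    pairing: str = "by-animal",
) -> list[RatioPoint]:
    """Delta T/S per ligand measurement: TS_ligand - TS_marker.

    ``pairing="by-animal"`` (default, the co-injection design) subtracts the
    marker ratio measured in the same animal at the same time.
    ``pairing="by-time"`` subtracts the arithmetic mean of all marker ratios
    sharing the nominal time, for designs where the marker was run in
    separate animals.  Ligand points without a counterpart raise
    :class:`PairingError` listing the orphans.  Negative deltas are retained.
    """
    if pairing not in ("by-animal", "by-time"):
        raise DomainError(f"unknown pairing rule {pairing!r}")
    if ligand.tissue != marker.tissue:
        raise ValidationError(
            f"tissue mismatch: ligand {ligand.tissue!r} vs marker {marker.tissue!r}"
        )
    if pairing == "by-animal":
        lookup = {(m.animal_id, m.time_min): tissue_serum_ratio(m)
                  for m in marker.measurements}
        key = lambda m: (m.animal_id, m.time_min)
    else:
        by_time: dict[float, list[float]] = {}
        for m in marker.measurements:
            by_time.setdefault(m.time_min, []).append(tissue_serum_ratio(m))
        lookup = {t: float(np.mean(v)) for t, v in by_time.items()}
        key = lambda m: m.time_min

    orphans = [m.animal_id for m in ligand.measurements if key(m) not in lookup]
    if orphans:
        raise PairingError(
            f"no marker ratio ({pairing}) for ligand animal(s): {', '.join(orphans)}"
        )
    out = []
    for m in ligand.measurements:
        ts = tissue_serum_ratio(m)
        out.append(RatioPoint(m.animal_id, m.time_min, ts, ts - lookup[key(m)]))
    return out


def patlak_points(
    study: TracerStudy,
    tissue: str,
    *,
    corrected: bool = True,
    pairing: str = "by-animal",
    exposure: str = "trapezoid",
    extrapolate_t0: bool = True,
    grid_step: float | None = None,
) -> list[RatioPoint]:
    """Assemble Patlak points for one tissue from a full study.

    ``exposure`` selects how Expt is computed on the pooled ligand serum
    curve: ``"trapezoid"`` (log-linear interpolation + dense trapezoid,
    default) or ``"fitted-model"`` (mono/biexponential input function fitted
    to the pooled curve and integrated in closed form; preferable when the
    curve is well described by two exponentials, as after a bolus dose).
    With ``corrected=False`` the raw T/S ratios are used (no marker needed)
    and ``delta_ts_ul_per_g`` equals ``ts_ul_per_g``.
    """
    if tissue not in study.ligand.tissues:
        raise ValidationError(f"ligand has no measurements for tissue {tissue!r}")
    series = study.ligand.tissues[tissue]
    if corrected:
        pts = vascular_corrected_ratios(series, study.marker_series(tissue), pairing)
    else:
        pts = [
            RatioPoint(m.animal_id, m.time_min, tissue_serum_ratio(m),
                       tissue_serum_ratio(m))
            for m in series.measurements
        ]
    pts, _ = _attach_exposure(study, pts, exposure=exposure,
                              extrapolate_t0=extrapolate_t0, grid_step=grid_step)
    return pts


def _attach_exposure(study, pts, *, exposure, extrapolate_t0, grid_step):
    """Fill ``expt_min`` on each point; with the fitted-model route also
    return the covariance of the exposure times induced by input-function
    estimation (None for the trapezoid route, where no parametric model
    exists to propagate)."""
    model = None
    x_cov = None
    times = sorted({p.time_min for p in pts})
    if exposure == "fitted-model":
        serum = study.ligand.serum
        # fit on every individual animal point: same log-domain estimate as
        # the pooled curve with balanced groups, but a proper residual df
        model = fit_serum_model(serum.times, serum.activity)
        expt_at_t = np.array([model.expt(t) if t > 0 else 0.0 for t in times])
        try:
            cov_p = log_param_covariance(model, serum.times, serum.activity)
        except InsufficientDataError:
            cov_p = None
        if cov_p is not None:
            h = 1e-6
            n_p = cov_p.shape[0]
            grad = np.empty((len(times), n_p))
            for j in range(n_p):
                dp = np.zeros(n_p)
                dp[j] = h
                hi = perturbed(model, dp)
                lo = perturbed(model, -dp)
                grad[:, j] = [
                    ((hi.expt(t) if t > 0 else 0.0) - (lo.expt(t) if t > 0 else 0.0))
                    / (2 * h)
                    for t in times
                ]
            x_cov = grad @ cov_p @ grad.T
    elif exposure != "trapezoid":
        raise DomainError(f"unknown exposure method {exposure!r}")
    eps = exposure_profile(
        study.ligand.serum, times, extrapolate_t0=extrapolate_t0,
        grid_step=grid_step, serum_model=model,
    )
    expt_at = {ep.time_min: ep.expt_min for ep in eps}
    for p in pts:
        p.expt_min = expt_at[p.time_min]
    if x_cov is not None:
        # expand the unique-time covariance to one row/column per point
        idx = np.array([times.index(p.time_min) for p in pts])
        x_cov = x_cov[np.ix_(idx, idx)]
    return pts, x_cov


# ---------------------------------------------------------------------------
# regression


@dataclass
class PatlakFit:
    """Patlak regression result: Ki (slope) and Vi (intercept) with SEs.

    Carries the sufficient statistics of the fit (sums of squares about the
    means, residual sum of squares) so two fits can be compared without the
    raw points.
    """

    ki_ul_per_g_min: float
    ki_se: float
    vi_ul_per_g: float
    vi_se: float
    r: float
    r2: float
    n_points: int
    window_expt: tuple[float, float]
    df_resid: int
    rss: float
    sxx: float
    sxy: float
    syy: float
    xbar: float
    ybar: float

    def to_dict(self) -> dict:
        return {
            "ki": self.ki_ul_per_g_min,
            "ki_se": self.ki_se,
            "vi": self.vi_ul_per_g,
            "vi_se": self.vi_se,
            "r": self.r,
            "r2": self.r2,
            "n": self.n_points,
            "window": list(self.window_expt),
            "df_resid": self.df_resid,
            "rss": self.rss,
            "sxx": self.sxx,
            "sxy": self.sxy,
            "syy": self.syy,
            "xbar": self.xbar,
            "ybar": self.ybar,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PatlakFit":
        return cls(
            ki_ul_per_g_min=d["ki"], ki_se=d["ki_se"],
            vi_ul_per_g=d["vi"], vi_se=d["vi_se"],
            r=d["r"], r2=d["r2"], n_points=d["n"],
            window_expt=tuple(d["window"]), df_resid=d["df_resid"],
            rss=d["rss"], sxx=d["sxx"], sxy=d["sxy"], syy=d["syy"],
            xbar=d["xbar"], ybar=d["ybar"],
        )

    def compare(self, other: "PatlakFit", alpha: float = 0.05) -> "GroupComparison":
        return compare_fits(self, other, alpha=alpha)

    def summary(self) -> str:
        return "\n".join([
            "Patlak multiple-time regression",
            f"  n points            : {self.n_points}",
            f"  Expt window [min]   : {self.window_expt[0]:.3f} .. {self.window_expt[1]:.3f}",
            f"  Ki [ul/(g*min)]     : {self.ki_ul_per_g_min:.3f} +/- {self.ki_se:.3f}",
            f"  Vi [ul/g]           : {self.vi_ul_per_g:.3f} +/- {self.vi_se:.3f}",
            f"  r                   : {self.r:.4f}",
        ])


class PatlakModel:
    """OLS model of delta T/S ratio on exposure time.

    Parameters
    ----------
    expt, delta_ts : array-like
        Exposure times (min) and vascular-corrected tissue/serum ratios
        (ul/g), one entry per animal.
    window_expt : (float, float), optional
        Closed exposure-time interval to fit (the "linear portion");
        defaults to all points.
    x_cov : ndarray, optional
        Covariance of the exposure times induced by estimating the serum
        input function (set by :meth:`from_study` with
        ``exposure="fitted-model"``).  When present, the Ki/Vi standard
        errors add the delta-method contribution of that uncertainty to the
        textbook residual-based terms; the point estimates are unchanged.
    """

    def __init__(self, expt, delta_ts, window_expt=None, x_cov=None):
        x = np.asarray(expt, dtype=float)
        y = np.asarray(delta_ts, dtype=float)
        if x.shape != y.shape:
            raise ValidationError("expt and delta_ts must have equal length")
        order = np.argsort(x, kind="stable")
        self.expt = x[order]
        self.delta_ts = y[order]
        self.x_cov = None if x_cov is None else np.asarray(x_cov)[np.ix_(order, order)]
        lo, hi = window_expt if window_expt is not None else (-np.inf, np.inf)
        lo = -np.inf if lo is None else lo
        hi = np.inf if hi is None else hi
        self.window_expt = (lo, hi)

    @classmethod
    def from_points(cls, points: Sequence[RatioPoint], window_expt=None,
                    x_cov=None) -> "PatlakModel":
        pts = list(points)
        if any(not np.isfinite(p.expt_min) for p in pts):
            raise ValidationError("RatioPoint.expt_min not set; attach exposure times first")
        return cls([p.expt_min for p in pts], [p.delta_ts_ul_per_g for p in pts],
                   window_expt=window_expt, x_cov=x_cov)

    @classmethod
    def from_study(cls, study: TracerStudy, tissue: str, *, window_expt=None,
                   corrected: bool = True, pairing: str = "by-animal",
                   exposure: str = "trapezoid", extrapolate_t0: bool = True,
                   grid_step: float | None = None) -> "PatlakModel":
        if tissue not in study.ligand.tissues:
            raise ValidationError(f"ligand has no measurements for tissue {tissue!r}")
        series = study.ligand.tissues[tissue]
        if corrected:
            pts = vascular_corrected_ratios(series, study.marker_series(tissue), pairing)
        else:
            pts = [RatioPoint(m.animal_id, m.time_min, tissue_serum_ratio(m),
                              tissue_serum_ratio(m)) for m in series.measurements]
        pts, x_cov = _attach_exposure(study, pts, exposure=exposure,
                                      extrapolate_t0=extrapolate_t0,
                                      grid_step=grid_step)
        return cls.from_points(pts, window_expt=window_expt, x_cov=x_cov)

    def fit(self) -> PatlakFit:
        lo, hi = self.window_expt
        mask = (self.expt >= lo) & (self.expt <= hi)
        x, y = self.expt[mask], self.delta_ts[mask]
        n = len(x)
        if n < 3:
            raise InsufficientDataError(
                f"Patlak fit needs >= 3 points in the window, found {n}"
            )
        if np.ptp(x) == 0:
            raise DegenerateDesignError("zero variance in exposure time")
        res = simple_ols(x, y)
        ki, vi = res.slope, res.intercept
        ki_se, vi_se = res.slope_se, res.intercept_se
        rss, xbar, ybar = res.rss, res.xbar, res.ybar
        sxx, sxy, syy = res.sxx, res.sxy, res.syy
        if self.x_cov is not None:
            # delta-method contribution of exposure-time (input-function)
            # uncertainty: d slope / d x_j and d intercept / d x_j at the fit
            cov = self.x_cov[np.ix_(mask.nonzero()[0], mask.nonzero()[0])]
            g_slope = ((y - ybar) - 2.0 * ki * (x - xbar)) / sxx
            g_int = -xbar * g_slope - ki / n
            ki_se = math.sqrt(ki_se**2 + float(g_slope @ cov @ g_slope))
            vi_se = math.sqrt(vi_se**2 + float(g_int @ cov @ g_int))
        r = sxy / math.sqrt(sxx * syy) if syy > 0 else (1.0 if ki >= 0 else -1.0)
        return PatlakFit(
            ki_ul_per_g_min=ki, ki_se=ki_se, vi_ul_per_g=vi, vi_se=vi_se,
            r=r, r2=r * r, n_points=n,
            window_expt=(float(x.min()), float(x.max())),
            df_resid=n - 2, rss=rss, sxx=sxx, sxy=sxy, syy=syy,
            xbar=xbar, ybar=ybar,
        )


def fit_patlak(points: Sequence[RatioPoint], window_expt=None) -> PatlakFit:
    """OLS of delta T/S on exposure time; see :class:`PatlakModel`."""
    return PatlakModel.from_points(points, window_expt=window_expt).fit()


def select_linear_portion(points: Sequence[RatioPoint], min_points: int = 3,
                          r2_min: float = 0.99) -> tuple[float, float]:
    """Automated surrogate for picking the linear portion of a Patlak plot.

    Returns the longest prefix (in exposure-time order) whose linear fit has
    r^2 >= ``r2_min``; uptake that saturates or effluxes departs from the
    line at late exposure times, so prefixes are the natural candidates.
    Deterministic (prefixes are nested).
    """
    pts = sorted(points, key=lambda p: p.expt_min)
    x = np.array([p.expt_min for p in pts])
    y = np.array([p.delta_ts_ul_per_g for p in pts])
    n = len(x)
    if n < min_points:
        raise SelectionError(
            f"linear-portion selection needs >= {min_points} points, found {n}"
        )
    for end in range(n, min_points - 1, -1):
        xs, ys = x[:end], y[:end]
        if np.ptp(xs) == 0:
            continue
        slope, intercept = np.polyfit(xs, ys, 1)
        resid = ys - (slope * xs + intercept)
        syy = float(np.sum((ys - ys.mean()) ** 2))
        rss = float(np.sum(resid**2))
        ok = syy == 0 or 1.0 - rss / syy >= r2_min
        if ok:
            return (float(xs[0]), float(xs[-1]))
    raise SelectionError(
        f"no prefix of >= {min_points} points reaches r^2 >= {r2_min}; "
        "supply a manual window"
    )


# ---------------------------------------------------------------------------
# group comparison


@dataclass
class GroupComparison:
    """Comparison of two Patlak fits: slopes, intercepts, correlations.

    Slopes are compared with the pooled-residual-variance t test
    (df = n_A + n_B - 4); intercepts with the common-slope (ANCOVA) model
    (df = n_A + n_B - 3), flagged ``intercept_conditional`` when the slopes
    already differ at ``alpha`` (an intercept comparison then presumes a
    common slope that the data reject); correlations with Fisher's
    z transform, SE = sqrt(1/(n_A-3) + 1/(n_B-3)).
    """

    slope_diff: float
    slope_se: float
    slope_t: float
    slope_df: int
    slope_p: float
    intercept_diff: float
    intercept_t: float
    intercept_df: int
    intercept_p: float
    intercept_conditional: bool
    r_z_stat: float | None
    r_p: float | None
    alpha: float
    infinite_t: bool = False
    r_comparison_omitted: bool = False

    def to_dict(self) -> dict:
        return {
            "slope_diff": self.slope_diff,
            "slope_se": self.slope_se,
            "slope_t": self.slope_t,
            "slope_df": self.slope_df,
            "slope_p": self.slope_p,
            "intercept_diff": self.intercept_diff,
            "intercept_t": self.intercept_t,
            "intercept_df": self.intercept_df,
            "intercept_p": self.intercept_p,
            "intercept_conditional": self.intercept_conditional,
            "r_z_stat": self.r_z_stat,
            "r_p": self.r_p,
            "alpha": self.alpha,
            "infinite_t": self.infinite_t,
            "r_comparison_omitted": self.r_comparison_omitted,
        }

    def summary(self) -> str:
        lines = [
            "Patlak group comparison",
            f"  Ki difference : {self.slope_diff:.4g} "
            f"(t={self.slope_t:.3g}, df={self.slope_df}, p={self.slope_p:.4g})",
            f"  Vi difference : {self.intercept_diff:.4g} "
            f"(t={self.intercept_t:.3g}, df={self.intercept_df}, p={self.intercept_p:.4g})"
            + (" [conditional on common slope the data reject]"
               if self.intercept_conditional else ""),
        ]
        if self.r_comparison_omitted:
            lines.append("  r comparison  : omitted (n too small or degenerate r)")
        else:
            lines.append(f"  r comparison  : z={self.r_z_stat:.3g}, p={self.r_p:.4g}")
        return "\n".join(lines)


def _t_test(diff: float, se: float, df: int) -> tuple[float, float, bool]:
    """(t, p, infinite-flag) handling the zero-residual degenerate limit."""
    if se == 0 or not np.isfinite(se):
        if diff == 0:
            return 0.0, 1.0, False
        return math.copysign(math.inf, diff), 0.0, True
    t = diff / se
    return t, float(2.0 * stats.t.sf(abs(t), df)), False


def compare_fits(a: PatlakFit, b: PatlakFit, alpha: float = 0.05) -> GroupComparison:
    """Compare two Patlak regressions (slopes, intercepts, correlations)."""
    na, nb = a.n_points, b.n_points
    if na < 3 or nb < 3:
        raise InsufficientDataError("group comparison needs n >= 3 in both fits")

    # slope test, pooled residual variance
    df_slope = na + nb - 4
    s2 = (a.rss + b.rss) / df_slope
    se_slope = math.sqrt(s2 * (1.0 / a.sxx + 1.0 / b.sxx))
    slope_diff = a.ki_ul_per_g_min - b.ki_ul_per_g_min
    slope_t, slope_p, inf_slope = _t_test(slope_diff, se_slope, df_slope)

    # intercept test under the common-slope (ANCOVA) model
    bc = (a.sxy + b.sxy) / (a.sxx + b.sxx)
    rss_c = (a.syy - 2 * bc * a.sxy + bc**2 * a.sxx) \
        + (b.syy - 2 * bc * b.sxy + bc**2 * b.sxx)
    df_int = na + nb - 3
    s2c = max(rss_c, 0.0) / df_int
    int_a = a.ybar - bc * a.xbar
    int_b = b.ybar - bc * b.xbar
    var_int = s2c * (1.0 / na + 1.0 / nb + (a.xbar - b.xbar) ** 2 / (a.sxx + b.sxx))
    int_diff = int_a - int_b
    int_t, int_p, inf_int = _t_test(int_diff, math.sqrt(var_int), df_int)

    # correlation comparison, Fisher z
    r_z = r_p = None
    omitted = False
    if na <= 3 or nb <= 3:
        omitted = True
    else:
        with np.errstate(divide="ignore"):  # |r| = 1 gives inf, handled below
            za, zb = np.arctanh(a.r), np.arctanh(b.r)
        se_z = math.sqrt(1.0 / (na - 3) + 1.0 / (nb - 3))
        if np.isfinite(za) and np.isfinite(zb):
            r_z = float((za - zb) / se_z)
            r_p = float(2.0 * stats.norm.sf(abs(r_z)))
        elif a.r == b.r:
            r_z, r_p = 0.0, 1.0
        else:
            omitted = True  # |r| = 1 in one group only; z undefined

    return GroupComparison(
        slope_diff=slope_diff, slope_se=se_slope, slope_t=slope_t,
        slope_df=df_slope, slope_p=slope_p,
        intercept_diff=int_diff, intercept_t=int_t, intercept_df=df_int,
        intercept_p=int_p, intercept_conditional=slope_p < alpha,
        r_z_stat=r_z, r_p=r_p, alpha=alpha,
        infinite_t=inf_slope or inf_int, r_comparison_omitted=omitted,
    )
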