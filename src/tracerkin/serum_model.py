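"""Closed-form serum input functions (mono/biexponential) and their fitting.

Bolus IV kinetics are summarised as

    Cp(t) = A1 * exp(-lam1 * t) + A2 * exp(-lam2 * t),     lam1 > lam2 > 0,

with A2 = 0 giving the monoexponential special case.  Amplitudes carry
whatever concentration unit the caller uses (%Inj/ml in the simulator,
cpm/ml when fitted to observed curves); every derived ratio (exposure time)
is invariant to that scale.  The antiderivative is available in closed form,

    AUC(t) = A1/lam1 * (1 - exp(-lam1 t)) + A2/lam2 * (1 - exp(-lam2 t)),

which the simulator uses as ground truth and the Patlak pipeline can use as a
high-accuracy alternative to trapezoid integration (``exposure="fitted-model"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, InsufficientDataError

__all__ = ["SerumModel", "fit_serum_model", "log_param_covariance", "perturbed"]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class SerumModel:
    """Biexponential serum decay ``A1 e^(-lam1 t) + A2 e^(-lam2 t)``."""

    a1: float
    lam1: float  # 1/min, fast phase
    a2: float = 0.0
    lam2: float | None = None  # 1/min, slow phase (None when a2 == 0)

    def __post_init__(self):
        if self.a1 < 0 or self.a2 < 0 or (self.a1 + self.a2) <= 0:
            raise DomainError("amplitudes must be >= 0 with a positive sum")
        if not self.lam1 > 0:
            raise DomainError(f"lam1 must be > 0, got {self.lam1}")
        if self.a2 > 0:
            if self.lam2 is None or not self.lam2 > 0:
                raise DomainError(f"lam2 must be > 0, got {self.lam2}")
            if not self.lam1 > self.lam2:
                raise DomainError(
                    f"rates must be ordered lam1 > lam2, got {self.lam1}, {self.lam2}"
                )
        else:  # canonical monoexponential form
            object.__setattr__(self, "lam2", None)

    @classmethod
    def monoexponential(cls, c0: float, t_half_min: float) -> "SerumModel":
        return cls(a1=c0, lam1=_LN2 / t_half_min)

    @classmethod
    def biexponential(cls, a1: float, t_half_fast_min: float,
                      a2: float, t_half_slow_min: float) -> "SerumModel":
        return cls(a1=a1, lam1=_LN2 / t_half_fast_min,
                   a2=a2, lam2=_LN2 / t_half_slow_min)

    @property
    def is_mono(self) -> bool:
        return self.a2 == 0

    @property
    def half_lives_min(self) -> dict[str, float]:
        """Phase half-lives implied by the rates, ln2/lambda."""
        out = {"fast": _LN2 / self.lam1}
        if not self.is_mono:
            out["slow"] = _LN2 / self.lam2
        return out

    def cp(self, t):
        """Concentration at time t (amplitude units)."""
        t = np.asarray(t, dtype=float)
        out = self.a1 * np.exp(-self.lam1 * t)
        if not self.is_mono:
            out = out + self.a2 * np.exp(-self.lam2 * t)
        return float(out) if out.ndim == 0 else out

    def auc(self, t):
        """Closed-form integral of Cp from 0 to t, (amplitude units)*min."""
        t = np.asarray(t, dtype=float)
        out = self.a1 / self.lam1 * (-np.expm1(-self.lam1 * t))
        if not self.is_mono:
            out = out + self.a2 / self.lam2 * (-np.expm1(-self.lam2 * t))
        return float(out) if out.ndim == 0 else out

    def expt(self, t):
        """Exposure time AUC(t)/Cp(t), minutes; scale-invariant."""
        return self.auc(t) / self.cp(t)


def _mono_ls(t: np.ndarray, logc: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(t, logc, 1)
    return float(np.exp(intercept)), float(-slope)


def _log_param_jacobian(model: SerumModel, t: np.ndarray) -> np.ndarray:
    """d log(Cp) / d log(params) at the sample times.

    Parameters are ordered (a1, lam1) for a monoexponential and
    (a1, lam1, a2, lam2) otherwise.
    """
    cp = model.cp(t)
    e1 = model.a1 * np.exp(-model.lam1 * t)
    cols = [e1 / cp, -model.lam1 * t * e1 / cp]
    if not model.is_mono:
        e2 = model.a2 * np.exp(-model.lam2 * t)
        cols += [e2 / cp, -model.lam2 * t * e2 / cp]
    return np.column_stack(cols)


def log_param_covariance(model: SerumModel, times, conc) -> np.ndarray:
    """Covariance of the fitted log-parameters from the log-domain residuals.

    Standard nonlinear-least-squares covariance ``s^2 (J^T J)^{-1}`` with
    ``s^2 = RSS / (n - k)`` on log concentrations.  Zero for noise-free data.
    Used to propagate input-function uncertainty into downstream estimates.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    resid = np.log(model.cp(t)) - np.log(c)
    k = 2 if model.is_mono else 4
    df = len(t) - k
    if df <= 0:
        raise InsufficientDataError(
            f"covariance needs more than {k} points, got {len(t)}"
        )
    s2 = float(resid @ resid) / df
    jac = _log_param_jacobian(model, t)
    return s2 * np.linalg.pinv(jac.T @ jac)


def perturbed(model: SerumModel, delta_logp: np.ndarray) -> SerumModel:
    """Model with log-parameters shifted by ``delta_logp`` (same ordering
    as :func:`log_param_covariance`)."""
    if model.is_mono:
        da1, dl1 = delta_logp
        return SerumModel(a1=model.a1 * math.exp(da1),
                          lam1=model.lam1 * math.exp(dl1))
    da1, dl1, da2, dl2 = delta_logp
    return SerumModel(a1=model.a1 * math.exp(da1), lam1=model.lam1 * math.exp(dl1),
                      a2=model.a2 * math.exp(da2), lam2=model.lam2 * math.exp(dl2))


def fit_serum_model(times, conc, max_terms: int = 2,
                    mono_tol: float = 1e-10) -> SerumModel:
    """Fit a mono- or biexponential input function to a serum curve.

    Fitting is done on log concentrations (multiplicative errors, values
    spanning orders of magnitude).  A monoexponential is accepted outright
    when its maximum log-residual is below ``mono_tol``; otherwise the
    biexponential is initialised by curve peeling (tail fit, subtract, refit
    the head) and polished with Levenberg–Marquardt on log-parameters to
    machine precision.  Noise-free data generated by a :class:`SerumModel`
    are recovered essentially exactly.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    order = np.argsort(t)
    t, c = t[order], c[order]
    if np.any(c <= 0):
        raise DomainError("concentrations must be positive")
    if len(np.unique(t)) < 2:
        raise InsufficientDataError("need >= 2 distinct times to fit a serum model")
    logc = np.log(c)

    a, lam = _mono_ls(t, logc)
    if lam <= 0:
        raise DomainError("serum curve does not decay; cannot fit an input function")
    mono = SerumModel(a1=a, lam1=lam)
    mono_resid = np.max(np.abs(np.log(mono.cp(t)) - logc))
    if max_terms == 1 or mono_resid < mono_tol or len(t) < 5:
        return mono

    # curve peeling: slow phase from the tail, fast phase from the residual head
    n = len(t)
    tail = slice(max(n - max(3, n // 2), 0), n)
    a2, lam2 = _mono_ls(t[tail], logc[tail])
    resid = c - a2 * np.exp(-lam2 * t)
    head = resid > 0
    head[max(3, n // 3):] = False
    if head.sum() >= 2:
        a1, lam1 = _mono_ls(t[head], np.log(resid[head]))
    else:
        a1, lam1 = a2, lam2 * 10.0
    if lam1 <= lam2:
        lam1 = lam2 * 10.0
    x0 = np.log([max(a1, 1e-12 * a2), lam1, a2, lam2])

    def fun(x):
        # guard against overflow excursions of the optimizer; the penalty
        # residual steers it back without raising
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            p = np.exp(np.clip(x, -700.0, 700.0))
            model = p[0] * np.exp(-p[1] * t) + p[2] * np.exp(-p[3] * t)
            r = np.log(model) - logc
        return np.where(np.isfinite(r), r, 1e6)

    sol = least_squares(fun, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15,
                        max_nfev=2000)
    p = np.exp(sol.x)
    pairs = sorted([(p[1], p[0]), (p[3], p[2])], reverse=True)  # by rate, descending
    (lam1, a1), (lam2, a2) = pairs
    if lam1 == lam2 or a2 <= 0 or lam2 <= 0:
        return mono
    bi = SerumModel(a1=a1, lam1=lam1, a2=a2, lam2=lam2)
    bi_resid = np.max(np.abs(np.log(bi.cp(t)) - logc))
    return bi if bi_resid < mono_resid else mono
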