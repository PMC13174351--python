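"""Independent brute-force oracles for the regression machinery.

Everything here is computed longhand from the textbook normal-equations and
ANCOVA formulas (or via an independent dummy-variable regression), never by
calling the code paths under test.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def ols_longhand(x, y):
    """Simple linear regression by explicit normal equations.

    Returns a dict with slope, intercept, their standard errors, r, r2 and
    the residual sum of squares, using the textbook closed forms.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    xbar, ybar = x.sum() / n, y.sum() / n
    sxx = float(((x - xbar) ** 2).sum())
    syy = float(((y - ybar) ** 2).sum())
    sxy = float(((x - xbar) * (y - ybar)).sum())
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    rss = syy - slope * sxy
    s2 = rss / (n - 2) if n > 2 else float("nan")
    return {
        "slope": slope,
        "intercept": intercept,
        "slope_se": math.sqrt(s2 / sxx) if n > 2 else float("nan"),
        "intercept_se": math.sqrt(s2 * (1.0 / n + xbar**2 / sxx)) if n > 2 else float("nan"),
        "r": sxy / math.sqrt(sxx * syy) if syy > 0 else float("nan"),
        "r2": sxy**2 / (sxx * syy) if syy > 0 else float("nan"),
        "rss": rss,
        "n": n,
    }


def ancova_longhand(xa, ya, xb, yb):
    """Homogeneity-of-slopes and common-slope intercept tests via an
    independent dummy-variable regression.

    Group-B indicator d: the slope test is the t statistic on the x:d
    interaction in  y ~ 1 + d + x + x:d  (df = n-4); the intercept test is
    the t statistic on d in the common-slope model  y ~ 1 + d + x
    (df = n-3).  Solved with plain least squares on the design matrices.
    """
    xa, ya = np.asarray(xa, float), np.asarray(ya, float)
    xb, yb = np.asarray(xb, float), np.asarray(yb, float)
    x = np.concatenate([xa, xb])
    y = np.concatenate([ya, yb])
    d = np.concatenate([np.zeros(len(xa)), np.ones(len(xb))])
    n = len(x)

    def tstat(X, y, col):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        df = n - X.shape[1]
        s2 = float(resid @ resid) / df
        cov = s2 * np.linalg.inv(X.T @ X)
        t = beta[col] / math.sqrt(cov[col, col])
        return float(beta[col]), float(t), df, float(2 * stats.t.sf(abs(t), df))

    X_full = np.column_stack([np.ones(n), d, x, x * d])
    diff_b_minus_a, t_slope, df_slope, p_slope = tstat(X_full, y, 3)
    X_common = np.column_stack([np.ones(n), d, x])
    int_b_minus_a, t_int, df_int, p_int = tstat(X_common, y, 1)
    return {
        # sign convention of the package: group A minus group B
        "slope_diff": -diff_b_minus_a,
        "slope_t": -t_slope,
        "slope_df": df_slope,
        "slope_p": p_slope,
        "intercept_diff": -int_b_minus_a,
        "intercept_t": -t_int,
        "intercept_df": df_int,
        "intercept_p": p_int,
    }


def fisher_z_longhand(ra, na, rb, nb):
    za, zb = math.atanh(ra), math.atanh(rb)
    se = math.sqrt(1.0 / (na - 3) + 1.0 / (nb - 3))
    z = (za - zb) / se
    return z, 2 * stats.norm.sf(abs(z))


def suffix_window_scan(times, log10_conc, min_points, r2_min):
    """Exhaustive scan over suffixes: the longest with slope<0, r2>=r2_min."""
    t = np.asarray(times, float)
    y = np.asarray(log10_conc, float)
    for start in range(0, len(t) - min_points + 1):
        o = ols_longhand(t[start:], y[start:])
        if o["slope"] < 0 and o["r2"] >= r2_min:
            return (float(t[start]), float(t[-1]))
    return None


def prefix_window_scan(x, y, min_points, r2_min):
    """Exhaustive scan over prefixes: the longest with r2 >= r2_min."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    for end in range(len(x), min_points - 1, -1):
        o = ols_longhand(x[:end], y[:end])
        if o["r2"] >= r2_min:
            return (float(x[0]), float(x[end - 1]))
    return None
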