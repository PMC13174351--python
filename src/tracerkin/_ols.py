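"""Simple linear regression via centered normal equations.

A deliberate, documented choice over a generic least-squares solver: the
centered sums give bit-exact results in the degenerate limits this package
relies on (a flat response fits slope exactly 0.0 with zero residuals; data
generated on a line reproduce it to rounding), which QR/SVD routes only
approach to ~1e-16.  The test suite cross-checks every output against an
independent library OLS on non-degenerate data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    slope_se: float  # NaN when df_resid == 0
    intercept_se: float
    r: float
    r2: float
    rss: float
    n: int
    xbar: float
    ybar: float
    sxx: float
    sxy: float
    syy: float


def simple_ols(x, y) -> LinearFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    xbar = float(x.mean())
    ybar = float(y.mean())
    dx = x - xbar
    dy = y - ybar
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    sxy = float(dx @ dy)
    if sxx == 0:
        raise ZeroDivisionError("zero variance in x")
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    rss = float(resid @ resid)
    if n > 2:
        s2 = rss / (n - 2)
        slope_se = math.sqrt(s2 / sxx)
        intercept_se = math.sqrt(s2 * (1.0 / n + xbar**2 / sxx))
    else:
        slope_se = intercept_se = float("nan")
    if syy > 0:
        r = sxy / math.sqrt(sxx * syy)
        r2 = r * r
    else:  # flat response: the fit is exact, direction degenerate
        r = 1.0 if slope >= 0 else -1.0
        r2 = 1.0
    return LinearFit(slope, intercept, slope_se, intercept_se, r, r2, rss,
                     n, xbar, ybar, sxx, sxy, syy)
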