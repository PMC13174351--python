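"""Pharmacodynamic quantification: phospho/total normalization and glucose AUC.

Immunoblot time courses are summarised as the ratio of phosphorylated to
total protein per sample, normalized to the mean ratio of the baseline
(t = 0) samples; tolerance tests (glucose vs time) are summarised as the
total area under the measured curve by the trapezoid rule, with no baseline
subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError, ReferenceSampleError, ValidationError

__all__ = [
    "PDSample",
    "GlucoseSeries",
    "normalize_phospho_ratio",
    "auc_trapezoid",
]


@dataclass(frozen=True)
class PDSample:
    """One phospho/total signal pair (densitometry units are arbitrary)."""

    sample_id: str
    treatment: str
    time_min: float
    phospho_signal: float
    total_signal: float

    def __post_init__(self):
        if not self.time_min >= 0:
            raise ValidationError(f"sample {self.sample_id!r}: time_min must be >= 0")
        if not self.phospho_signal > 0 or not self.total_signal > 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: phospho and total signals must be > 0"
            )

    @property
    def ratio(self) -> float:
        return self.phospho_signal / self.total_signal


def normalize_phospho_ratio(
    samples: Sequence[PDSample],
    reference_time: float = 0.0,
    pooling: str = "all-treatments",
) -> np.ndarray:
    """Phospho/total ratios divided by the mean ratio at the reference time.

    With ``pooling="all-treatments"`` (default) the reference is the
    arithmetic mean ratio over *all* samples at ``reference_time``,
    regardless of treatment arm; ``"per-treatment"`` normalizes each arm to
    its own baseline and requires every arm to have reference samples.
    Output order matches the input order.  Idempotent: already-normalized
    data have a reference mean of 1 and pass through unchanged.
    """
    if pooling not in ("all-treatments", "per-treatment"):
        raise DomainError(f"unknown pooling rule {pooling!r}")
    samples = list(samples)
    if not samples:
        raise ValidationError("no samples")
    ratios = np.array([s.ratio for s in samples], dtype=float)

    if pooling == "all-treatments":
        ref = ratios[[s.time_min == reference_time for s in samples]]
        if ref.size == 0:
            raise ReferenceSampleError(
                f"no samples at reference time t={reference_time}"
            )
        return ratios / ref.mean()

    out = np.empty_like(ratios)
    for arm in sorted({s.treatment for s in samples}):
        idx = np.array([s.treatment == arm for s in samples])
        ref = ratios[idx & np.array([s.time_min == reference_time for s in samples])]
        if ref.size == 0:
            raise ReferenceSampleError(
                f"treatment {arm!r} has no samples at reference time t={reference_time}"
            )
        out[idx] = ratios[idx] / ref.mean()
    return out


@dataclass
class GlucoseSeries:
    """Blood glucose time course for one subject (mg/dl vs minutes)."""

    subject_id: str
    times_min: np.ndarray
    glucose: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times_min, dtype=float)
        g = np.asarray(self.glucose, dtype=float)
        if t.shape != g.shape or t.ndim != 1:
            raise ValidationError("times and glucose must be equal-length 1-D arrays")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"subject {self.subject_id!r}: times must be strictly increasing "
                "(aggregate duplicates first)"
            )
        if np.any(g <= 0):
            raise ValidationError(f"subject {self.subject_id!r}: glucose must be > 0")
        self.times_min, self.glucose = t, g


def auc_trapezoid(series: GlucoseSeries) -> float:
    """Total trapezoidal area under the glucose curve, mg*min/dl.

    No baseline subtraction: the area is taken to zero glucose over the
    measured interval.
    """
    if len(series.times_min) < 2:
        raise ValidationError("AUC needs >= 2 points")
    return float(np.trapezoid(series.glucose, series.times_min))
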