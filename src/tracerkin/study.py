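"""Typed data model and CSV interchange for dual-tracer terminal-sampling studies.

A study consists of a radiolabelled ligand and, optionally, a co-injected
vascular marker (e.g. technetium-labelled albumin).  Each animal contributes a
single terminal serum sample (counts/min per ml) and one or more tissue samples
(counts/min per g) taken at the same time, so a concentration–time curve is
assembled *across* animals (cross-sectional design).

Concentrations are stored exactly as read, in cpm/ml and cpm/g; percent of the
injected dose per ml (%Inj/ml) is a derived view, never stored back.  Times are
minutes, real-valued, never rounded.

The single interchange format is a long-format RFC-4180 CSV with columns::

    animal_id, tracer, compartment, tissue, time_min, value, injected_dose_cpm

where ``compartment`` is ``serum`` or ``tissue``; serum rows leave ``tissue``
blank and tissue rows leave ``injected_dose_cpm`` blank (the paired serum
activity of the same animal supplies the denominator for tissue/serum ratios).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DomainError, FormatError, ValidationError

REQUIRED_COLUMNS = (
    "animal_id",
    "tracer",
    "compartment",
    "tissue",
    "time_min",
    "value",
    "injected_dose_cpm",
)

__all__ = [
    "SerumMeasurement",
    "SerumCurve",
    "TissueMeasurement",
    "TissueSeries",
    "TracerArm",
    "TracerStudy",
    "percent_injected_per_ml",
    "aggregate_duplicate_times",
    "read_study_csv",
    "write_study_csv",
    "REQUIRED_COLUMNS",
]


def percent_injected_per_ml(activity_per_ml, injected_dose_cpm):
    """Percent of the injected dose present in one ml of serum.

    Parameters
    ----------
    activity_per_ml : float or array-like
        Serum radioactivity in cpm/ml (may be zero).
    injected_dose_cpm : float or array-like
        Total injected dose in cpm (must be positive).

    Returns
    -------
    float or ndarray
        ``100 * activity_per_ml / injected_dose_cpm`` (%Inj/ml).
    """
    activity = np.asarray(activity_per_ml, dtype=float)
    dose = np.asarray(injected_dose_cpm, dtype=float)
    if np.any(dose <= 0):
        raise DomainError("injected_dose_cpm must be > 0")
    if np.any(activity < 0):
        raise DomainError("activity_per_ml must be >= 0")
    out = 100.0 * activity / dose
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SerumMeasurement:
    """One terminal serum gamma count for one animal."""

    animal_id: str
    time_min: float
    activity_per_ml: float  # cpm/ml
    injected_dose_cpm: float

    def __post_init__(self):
        for name in ("time_min", "activity_per_ml", "injected_dose_cpm"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if not self.time_min >= 0:
            raise ValidationError(
                f"animal {self.animal_id!r}: time_min must be >= 0, got {self.time_min}"
            )
        if not self.activity_per_ml > 0:
            raise ValidationError(
                f"animal {self.animal_id!r}: activity_per_ml must be > 0, "
                f"got {self.activity_per_ml}"
            )
        if not self.injected_dose_cpm > 0:
            raise ValidationError(
                f"animal {self.animal_id!r}: injected_dose_cpm must be > 0, "
                f"got {self.injected_dose_cpm}"
            )

    @property
    def pct_inj_per_ml(self) -> float:
        return percent_injected_per_ml(self.activity_per_ml, self.injected_dose_cpm)


@dataclass
class SerumCurve:
    """Ordered serum concentration–time record for one tracer.

    Points are sorted by time on construction (stable sort, so animals sharing
    a nominal time keep their input order).  Several animals may share a
    nominal time; :func:`aggregate_duplicate_times` collapses them when a
    single-valued curve is needed (interpolation, integration).
    """

    tracer_id: str
    points: tuple[SerumMeasurement, ...]

    def __post_init__(self):
        pts = tuple(sorted(self.points, key=lambda p: p.time_min))
        if not pts:
            raise ValidationError(f"tracer {self.tracer_id!r}: no measurements")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    @property
    def times(self) -> np.ndarray:
        return np.array([p.time_min for p in self.points], dtype=float)

    @property
    def activity(self) -> np.ndarray:
        """Serum activity in cpm/ml, time-ordered."""
        return np.array([p.activity_per_ml for p in self.points], dtype=float)

    @property
    def pct_inj_per_ml(self) -> np.ndarray:
        """Derived %Inj/ml series (never stored)."""
        return percent_injected_per_ml(
            self.activity, np.array([p.injected_dose_cpm for p in self.points])
        )

    @property
    def n_distinct_times(self) -> int:
        return len(np.unique(self.times))

    def restricted(self, t_start: float = -np.inf, t_end: float = np.inf) -> "SerumCurve":
        """Sub-curve with times in the closed interval [t_start, t_end]."""
        pts = tuple(p for p in self.points if t_start <= p.time_min <= t_end)
        if not pts:
            raise ValidationError(
                f"tracer {self.tracer_id!r}: empty window [{t_start}, {t_end}]"
            )
        return SerumCurve(self.tracer_id, pts)


def aggregate_duplicate_times(curve: SerumCurve, method: str = "geometric") -> SerumCurve:
    """Collapse animals sharing a nominal time to one point per distinct time.

    ``method="geometric"`` (default) averages in the log domain, matching the
    log-linear regression and interpolation performed downstream on
    concentrations that span orders of magnitude; ``"arithmetic"`` is the plain
    mean.  Injected doses are averaged the same way, so for the geometric
    method the pooled %Inj/ml equals the geometric mean of the individual
    %Inj/ml values.  Idempotent.
    """
    if method not in ("geometric", "arithmetic"):
        raise DomainError(f"unknown aggregation method {method!r}")
    times = curve.times
    uniq = np.unique(times)
    if len(uniq) == len(times):
        return curve
    pts = []
    for t in uniq:
        sel = [p for p in curve.points if p.time_min == t]
        if len(sel) == 1:
            pts.append(sel[0])
            continue
        act = np.array([p.activity_per_ml for p in sel])
        dose = np.array([p.injected_dose_cpm for p in sel])
        if method == "geometric":
            a, d = float(np.exp(np.mean(np.log(act)))), float(np.exp(np.mean(np.log(dose))))
        else:
            a, d = float(np.mean(act)), float(np.mean(dose))
        pts.append(SerumMeasurement(f"pooled[{len(sel)}]", float(t), a, d))
    return SerumCurve(curve.tracer_id, tuple(pts))


@dataclass(frozen=True)
class TissueMeasurement:
    """Paired tissue and serum counts for one animal at its terminal time."""

    animal_id: str
    tissue: str
    time_min: float
    activity_per_g: float  # cpm/g (Am)
    serum_activity_per_ml: float  # cpm/ml at the same time (Cp)

    def __post_init__(self):
        for name in ("time_min", "activity_per_g", "serum_activity_per_ml"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if not self.time_min >= 0:
            raise ValidationError(
                f"animal {self.animal_id!r}: time_min must be >= 0, got {self.time_min}"
            )
        if not self.activity_per_g > 0:
            raise ValidationError(
                f"animal {self.animal_id!r} tissue {self.tissue!r}: "
                f"activity_per_g must be > 0, got {self.activity_per_g}"
            )
        if not self.serum_activity_per_ml > 0:
            raise ValidationError(
                f"animal {self.animal_id!r} tissue {self.tissue!r}: "
                f"serum_activity_per_ml must be > 0, got {self.serum_activity_per_ml}"
            )


@dataclass
class TissueSeries:
    """All tissue measurements for one tracer in one tissue, time-ordered."""

    tracer_id: str
    tissue: str
    measurements: tuple[TissueMeasurement, ...]

    def __post_init__(self):
        ms = tuple(sorted(self.measurements, key=lambda m: m.time_min))
        if not ms:
            raise ValidationError(
                f"tracer {self.tracer_id!r} tissue {self.tissue!r}: no measurements"
            )
        for m in ms:
            if m.tissue != self.tissue:
                raise ValidationError(
                    f"measurement for tissue {m.tissue!r} placed in series "
                    f"for {self.tissue!r}"
                )
        self.measurements = ms

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def times(self) -> np.ndarray:
        return np.array([m.time_min for m in self.measurements], dtype=float)


@dataclass
class TracerArm:
    """One tracer's serum curve together with its tissue series."""

    serum: SerumCurve
    tissues: dict[str, TissueSeries] = field(default_factory=dict)


@dataclass
class TracerStudy:
    """A ligand arm plus an optional co-injected vascular-marker arm.

    Animals are paired between arms by ``animal_id`` (the two tracers are
    counted in the same samples of the same animal).
    """

    ligand: TracerArm
    marker: TracerArm | None = None

    def require_marker(self) -> TracerArm:
        if self.marker is None:
            raise ValidationError("study has no vascular-marker arm")
        return self.marker

    def marker_series(self, tissue: str) -> TissueSeries:
        marker = self.require_marker()
        if tissue not in marker.tissues:
            raise ValidationError(
                f"vascular marker has no measurements for tissue {tissue!r}"
            )
        return marker.tissues[tissue]


def _apply_schema(fieldnames: Sequence[str], schema: Mapping[str, str] | None) -> dict[str, str]:
    """Map canonical column names to the actual header names."""
    mapping = {c: c for c in REQUIRED_COLUMNS}
    if schema:
        mapping.update({k: v for k, v in schema.items() if k in REQUIRED_COLUMNS})
    missing = [v for v in mapping.values() if v not in fieldnames]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(sorted(missing))}")
    return mapping


def read_study_csv(
    path,
    schema: Mapping[str, str] | None = None,
    ligand: str | None = None,
    marker: str | None = None,
) -> TracerStudy:
    """Read a long-format study CSV into a validated :class:`TracerStudy`.

    Parameters
    ----------
    path : str or path-like
        CSV file with the columns in :data:`REQUIRED_COLUMNS` (or renamed
        versions declared in ``schema``).
    schema : mapping, optional
        Maps canonical column names to the actual header names, e.g.
        ``{"value": "cpm"}``.
    ligand, marker : str, optional
        Tracer labels for the ligand and vascular-marker arms.  With a single
        tracer in the file the ligand is inferred; with exactly two tracers,
        naming either one lets the other be inferred.

    Rows violating type invariants are rejected with row-numbered diagnostics
    (row 1 is the header).  Tissue rows are paired with the serum row of the
    same tracer/animal/time to obtain the serum denominator.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, header required")
        colmap = _apply_schema(reader.fieldnames, schema)
        rows = list(reader)
    if not rows:
        raise ValidationError(f"{path}: no measurements")

    errors: list[str] = []
    serum_rows: dict[str, list[SerumMeasurement]] = {}
    serum_lookup: dict[tuple[str, str, float], float] = {}
    tissue_raw: list[tuple[int, str, str, str, float, float]] = []

    def get(row, name):
        return (row.get(colmap[name]) or "").strip()

    for i, row in enumerate(rows):
        rowno = i + 2  # header is row 1
        tracer = get(row, "tracer")
        compartment = get(row, "compartment").lower()
        animal = get(row, "animal_id")
        try:
            t = float(get(row, "time_min"))
            value = float(get(row, "value"))
        except ValueError:
            errors.append(f"row {rowno}: non-numeric time_min or value")
            continue
        if compartment == "serum":
            try:
                dose = float(get(row, "injected_dose_cpm"))
                m = SerumMeasurement(animal, t, value, dose)
            except (ValueError, ValidationError) as exc:
                errors.append(f"row {rowno}: {exc}")
                continue
            serum_rows.setdefault(tracer, []).append(m)
            serum_lookup[(tracer, animal, t)] = value
        elif compartment == "tissue":
            tissue_raw.append((rowno, tracer, animal, get(row, "tissue"), t, value))
        else:
            errors.append(f"row {rowno}: compartment must be 'serum' or 'tissue', got {compartment!r}")

    tissue_rows: dict[tuple[str, str], list[TissueMeasurement]] = {}
    for rowno, tracer, animal, tissue, t, value in tissue_raw:
        cp = serum_lookup.get((tracer, animal, t))
        if cp is None:
            errors.append(
                f"row {rowno}: no serum measurement for tracer {tracer!r}, "
                f"animal {animal!r} at t={t}"
            )
            continue
        try:
            m = TissueMeasurement(animal, tissue, t, value, cp)
        except ValidationError as exc:
            errors.append(f"row {rowno}: {exc}")
            continue
        tissue_rows.setdefault((tracer, tissue), []).append(m)

    if errors:
        raise ValidationError("; ".join(errors))
    if not serum_rows:
        raise ValidationError(f"{path}: no serum measurements")

    tracers = sorted(serum_rows)
    if ligand is None:
        if len(tracers) == 1:
            ligand = tracers[0]
        elif len(tracers) == 2 and marker in tracers:
            ligand = next(t for t in tracers if t != marker)
        else:
            raise FormatError(
                f"file contains tracers {tracers}; specify ligand (and marker) explicitly"
            )
    if ligand not in serum_rows:
        raise FormatError(f"ligand tracer {ligand!r} not present (found {tracers})")
    if marker is None and len(tracers) == 2:
        marker = next(t for t in tracers if t != ligand)
    if marker is not None and marker not in serum_rows:
        raise FormatError(f"marker tracer {marker!r} not present (found {tracers})")

    def build_arm(tracer_id: str) -> TracerArm:
        serum = SerumCurve(tracer_id, tuple(serum_rows[tracer_id]))
        tissues = {
            tissue: TissueSeries(tracer_id, tissue, tuple(ms))
            for (tr, tissue), ms in sorted(tissue_rows.items())
            if tr == tracer_id
        }
        return TracerArm(serum, tissues)

    return TracerStudy(
        ligand=build_arm(ligand),
        marker=build_arm(marker) if marker is not None else None,
    )


def _study_rows(study: TracerStudy) -> Iterable[list[str]]:
    arms = [study.ligand] + ([study.marker] if study.marker else [])
    for arm in arms:
        tracer = arm.serum.tracer_id
        for p in sorted(arm.serum.points, key=lambda p: (p.time_min, p.animal_id)):
            yield [p.animal_id, tracer, "serum", "", repr(p.time_min),
                   repr(p.activity_per_ml), repr(p.injected_dose_cpm)]
        for tissue in sorted(arm.tissues):
            ms = sorted(arm.tissues[tissue].measurements,
                        key=lambda m: (m.time_min, m.animal_id))
            for m in ms:
                yield [m.animal_id, tracer, "tissue", tissue, repr(m.time_min),
                       repr(m.activity_per_g), ""]


def write_study_csv(study: TracerStudy, path) -> None:
    """Write a study in the canonical long format.

    Numeric fields are written with ``repr`` (shortest round-trip form), so
    ``read_study_csv(write_study_csv(s))`` reproduces every value bit-exactly.
    Rows are canonically sorted: ligand before marker, serum before tissue,
    then tissue name, time and animal id.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REQUIRED_COLUMNS)
        writer.writerows(_study_rows(study))
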