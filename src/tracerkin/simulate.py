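"""Synthetic dual-tracer studies with known ground truth.

The generator mirrors the in-vivo design the analysis targets: a bolus IV
co-injection of a radiolabelled ligand (1e6 cpm) and a vascular marker
(albumin, 5e5 cpm, Ki = 0 by assumption), cross-sectional terminal sampling
(each animal contributes one serum + tissue sample at a single time in the
0.5–225 min range), biexponential serum decay spanning orders of magnitude,
Patlak-linear tissue uptake

    Am(t) = [Ki * AUC(t) + Vi * Cp(t)] / 1000        (cpm/g),

with the closed-form biexponential AUC as ground truth, and multiplicative
lognormal measurement noise, mean-unbiased: each measured quantity is the
true value times ``exp(eps)`` with ``eps ~ N(-s^2/2, s^2)`` and
``s^2 = ln(1 + cv^2)`` so the multiplicative coefficient of variation equals
``noise_cv``.  An optional Poisson stage models gamma-counting noise on raw
cpm.  The recorded tissue/serum pairing uses the same animal's noisy serum
value, as in a real terminal study where one serum sample serves both
purposes.

All randomness flows from the config seed through one
``numpy.random.Generator``; identical configs give byte-identical CSVs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import yaml

from .errors import DomainError, ValidationError
from .serum_model import SerumModel
from .study import (
    SerumCurve,
    SerumMeasurement,
    TissueMeasurement,
    TissueSeries,
    TracerArm,
    TracerStudy,
)

__all__ = [
    "SimulationConfig",
    "simulate_serum_curve",
    "simulate_tissue_uptake",
    "simulate_study",
    "insulin_like_config",
    "slow_ligand_config",
    "DEFAULT_SAMPLE_TIMES",
]

_LN2 = math.log(2.0)

# Terminal sampling grid spanning the 0.5–225 min study range: dense early
# (fast-phase resolution) and log-spread late (terminal phase).
DEFAULT_SAMPLE_TIMES = (0.5, 1.0, 2.5, 7.5, 20.0, 60.0, 120.0, 225.0)


def _noise_sigma(noise_cv: float) -> float:
    if noise_cv < 0:
        raise DomainError(f"noise_cv must be >= 0, got {noise_cv}")
    return math.sqrt(math.log1p(noise_cv**2))


def _lognormal_factors(rng: np.random.Generator, sigma: float, n: int) -> np.ndarray:
    if sigma == 0:
        return np.ones(n)
    return np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=n))


@dataclass
class SimulationConfig:
    """Ground-truth kinetics, sampling design and noise model for one study.

    Serum models are in %Inj/ml; ``ki_true`` (ul/(g*min)) and ``vi_true``
    (ul/g) are per tissue; the marker has Ki = 0 everywhere and a single
    ``marker_vi``.  ``sample_times`` are the terminal times (min) and
    ``animals_per_time`` animals are sacrificed at each.
    """

    serum_ligand: SerumModel
    serum_marker: SerumModel
    ki_true: dict[str, float]
    vi_true: dict[str, float]
    marker_vi: float
    seed: int
    sample_times: tuple[float, ...] = DEFAULT_SAMPLE_TIMES
    animals_per_time: int = 4
    noise_cv: float = 0.10
    injected_dose_cpm: float = 1.0e6
    marker_dose_cpm: float = 5.0e5
    poisson_counts: bool = False
    ligand_id: str = "LIG"
    marker_id: str = "ALB"

    def __post_init__(self):
        if self.animals_per_time < 1:
            raise ValidationError(
                f"animals_per_time must be >= 1, got {self.animals_per_time}"
            )
        if self.noise_cv < 0:
            raise DomainError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if set(self.ki_true) != set(self.vi_true):
            raise ValidationError("ki_true and vi_true must cover the same tissues")
        for tissue, ki in self.ki_true.items():
            if ki < 0:
                raise DomainError(f"ki_true[{tissue!r}] must be >= 0, got {ki}")
        for tissue, vi in self.vi_true.items():
            if not vi > 0:
                raise DomainError(f"vi_true[{tissue!r}] must be > 0, got {vi}")
        if not self.marker_vi > 0:
            raise DomainError(f"marker_vi must be > 0, got {self.marker_vi}")
        if any(t < 0 for t in self.sample_times):
            raise ValidationError("sample times must be >= 0")
        self.sample_times = tuple(float(t) for t in self.sample_times)

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("serum_ligand", "serum_marker"):
            model: SerumModel = getattr(self, key)
            d[key] = {"a1": model.a1, "lam1": model.lam1,
                      "a2": model.a2, "lam2": model.lam2}
        d["sample_times"] = list(self.sample_times)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        for key in ("serum_ligand", "serum_marker"):
            m = d[key]
            d[key] = m if isinstance(m, SerumModel) else SerumModel(**m)
        d["sample_times"] = tuple(d.get("sample_times", DEFAULT_SAMPLE_TIMES))
        d["ki_true"] = dict(d["ki_true"])
        d["vi_true"] = dict(d["vi_true"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def ground_truth(self) -> dict:
        """Machine-readable record of the generating parameters."""
        return {
            "seed": self.seed,
            "ki_true_ul_per_g_min": dict(self.ki_true),
            "vi_true_ul_per_g": dict(self.vi_true),
            "marker_vi_ul_per_g": self.marker_vi,
            "ligand_half_lives_min": self.serum_ligand.half_lives_min,
            "marker_half_lives_min": self.serum_marker.half_lives_min,
            "sample_times_min": list(self.sample_times),
            "animals_per_time": self.animals_per_time,
            "noise_cv": self.noise_cv,
            "injected_dose_cpm": self.injected_dose_cpm,
            "marker_dose_cpm": self.marker_dose_cpm,
        }


def _serum_cpm(model: SerumModel, t, dose: float):
    """cpm/ml from a %Inj/ml model: pct * dose / 100."""
    return np.asarray(model.cp(t)) * dose / 100.0


def simulate_serum_curve(
    model: SerumModel,
    times,
    *,
    noise_cv: float,
    n_animals: int,
    dose: float,
    seed: int,
    tracer_id: str = "LIG",
    poisson_counts: bool = False,
) -> SerumCurve:
    """Cross-sectional serum curve: ``n_animals`` animals per time point.

    Values are ``Cp(t) * dose/100 * exp(eps)`` cpm/ml with mean-unbiased
    lognormal ``eps``; deterministic for a fixed seed.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise DomainError("times must be >= 0")
    if n_animals < 1:
        raise ValidationError(f"n_animals must be >= 1, got {n_animals}")
    sigma = _noise_sigma(noise_cv)
    rng = np.random.default_rng(seed)
    pts = []
    for i, t in enumerate(times):
        true = float(_serum_cpm(model, t, dose))
        factors = _lognormal_factors(rng, sigma, n_animals)
        for k in range(n_animals):
            val = true * factors[k]
            if poisson_counts:
                val = max(1.0, float(rng.poisson(val)))
            pts.append(SerumMeasurement(f"t{i:02d}a{k:02d}", float(t), val, dose))
    return SerumCurve(tracer_id, tuple(pts))


def simulate_tissue_uptake(
    serum_model: SerumModel,
    ki: float,
    vi: float,
    times,
    *,
    noise_cv: float,
    n_animals: int = 1,
    dose: float = 1.0e6,
    seed: int = 0,
    tracer_id: str = "LIG",
    tissue: str = "whole brain",
    poisson_counts: bool = False,
) -> TissueSeries:
    """Tissue series generated from the Patlak forward model.

    Noise-free tissue activity is ``(ki*AUC(t) + vi*Cp(t))/1000`` cpm/g with
    the closed-form biexponential AUC; multiplicative noise is applied
    independently to the tissue count and the paired serum count, and the
    recorded ``serum_activity_per_ml`` is the same animal's noisy serum value.
    """
    if ki < 0:
        raise DomainError(f"ki must be >= 0, got {ki}")
    if not vi > 0:
        raise DomainError(f"vi must be > 0, got {vi}")
    times = np.asarray(times, dtype=float)
    sigma = _noise_sigma(noise_cv)
    rng = np.random.default_rng(seed)
    ms = []
    for i, t in enumerate(times):
        cp_true = float(_serum_cpm(serum_model, t, dose))
        auc_true = float(serum_model.auc(t)) * dose / 100.0
        am_true = (ki * auc_true + vi * cp_true) / 1000.0
        for k in range(n_animals):
            f_serum, f_tissue = _lognormal_factors(rng, sigma, 2)
            cp_val, am_val = cp_true * f_serum, am_true * f_tissue
            if poisson_counts:
                cp_val = max(1.0, float(rng.poisson(cp_val)))
                am_val = max(1.0, float(rng.poisson(am_val)))
            ms.append(TissueMeasurement(f"t{i:02d}a{k:02d}", tissue, float(t),
                                        am_val, cp_val))
    return TissueSeries(tracer_id, tissue, tuple(ms))


def simulate_study(config: SimulationConfig) -> tuple[TracerStudy, dict]:
    """Full dual-tracer study plus its ground-truth record.

    Each simulated animal appears at exactly one terminal time and carries
    both tracers: one ligand serum value, one marker serum value, and for
    every tissue a ligand and a marker tissue count.  The tissue rows reuse
    the animal's serum realization as their serum denominator.
    """
    cfg = config
    sigma = _noise_sigma(cfg.noise_cv)
    rng = np.random.default_rng(cfg.seed)
    tissues = sorted(cfg.ki_true)

    lig_serum, mk_serum = [], []
    lig_tissue: dict[str, list[TissueMeasurement]] = {t: [] for t in tissues}
    mk_tissue: dict[str, list[TissueMeasurement]] = {t: [] for t in tissues}

    def count(value: float) -> float:
        if cfg.poisson_counts:
            return max(1.0, float(rng.poisson(value)))
        return value

    for i, t in enumerate(cfg.sample_times):
        lig_cp_true = float(_serum_cpm(cfg.serum_ligand, t, cfg.injected_dose_cpm))
        mk_cp_true = float(_serum_cpm(cfg.serum_marker, t, cfg.marker_dose_cpm))
        lig_auc_true = float(cfg.serum_ligand.auc(t)) * cfg.injected_dose_cpm / 100.0
        mk_auc_true = float(cfg.serum_marker.auc(t)) * cfg.marker_dose_cpm / 100.0
        for k in range(cfg.animals_per_time):
            animal = f"t{i:02d}a{k:02d}"
            lig_cp = count(lig_cp_true * _lognormal_factors(rng, sigma, 1)[0])
            mk_cp = count(mk_cp_true * _lognormal_factors(rng, sigma, 1)[0])
            lig_serum.append(SerumMeasurement(animal, t, lig_cp, cfg.injected_dose_cpm))
            mk_serum.append(SerumMeasurement(animal, t, mk_cp, cfg.marker_dose_cpm))
            for tissue in tissues:
                am_lig = (cfg.ki_true[tissue] * lig_auc_true
                          + cfg.vi_true[tissue] * lig_cp_true) / 1000.0
                am_mk = cfg.marker_vi * mk_cp_true / 1000.0  # Ki = 0 by assumption
                lig_tissue[tissue].append(TissueMeasurement(
                    animal, tissue, t,
                    count(am_lig * _lognormal_factors(rng, sigma, 1)[0]), lig_cp))
                mk_tissue[tissue].append(TissueMeasurement(
                    animal, tissue, t,
                    count(am_mk * _lognormal_factors(rng, sigma, 1)[0]), mk_cp))

    study = TracerStudy(
        ligand=TracerArm(
            SerumCurve(cfg.ligand_id, tuple(lig_serum)),
            {t: TissueSeries(cfg.ligand_id, t, tuple(lig_tissue[t])) for t in tissues},
        ),
        marker=TracerArm(
            SerumCurve(cfg.marker_id, tuple(mk_serum)),
            {t: TissueSeries(cfg.marker_id, t, tuple(mk_tissue[t])) for t in tissues},
        ),
    )
    return study, cfg.ground_truth()


# ---------------------------------------------------------------------------
# preset study conditions


def insulin_like_config(seed: int = 42, **overrides) -> SimulationConfig:
    """Rapidly cleared ligand: biexponential serum with a ~1.8 min slow phase.

    Sampling covers 0.5–10 min as in a short terminal study; the amplitude
    split puts the apparent (0.5–3 min window) half-life near 1 min while the
    1.5–3 min window approaches the 1.8 min slow phase.
    """
    params = dict(
        serum_ligand=SerumModel.biexponential(48.9, 0.1, 1.1, 1.8),
        serum_marker=SerumModel.monoexponential(50.0, 1600.0),
        ki_true={"whole brain": 0.5},
        vi_true={"whole brain": 10.0},
        marker_vi=10.0,
        sample_times=(0.5, 1.0, 1.5, 2.0, 3.0, 5.0, 7.5, 10.0),
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def slow_ligand_config(seed: int = 42, **overrides) -> SimulationConfig:
    """Slowly cleared ligand: biexponential serum with a ~556 min slow phase.

    Sampling covers 0.5–225 min; the fast phase and amplitude split are set
    so the full-window (0.5–225 min) apparent half-life lands near 58 min
    while the slow phase is 556 min (~9.3 h).
    """
    params = dict(
        serum_ligand=SerumModel.biexponential(39.2, 4.0, 2.8, 556.0),
        serum_marker=SerumModel.monoexponential(50.0, 1600.0),
        ki_true={"whole brain": 0.5},
        vi_true={"whole brain": 10.0},
        marker_vi=10.0,
        sample_times=DEFAULT_SAMPLE_TIMES,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)
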