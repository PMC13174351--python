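import numpy as np
import pytest
from hypothesis import settings

from tracerkin import SerumCurve, SerumMeasurement

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


def make_curve(times, values, dose=1.0e6, tracer="LIG"):
    """Serum curve from parallel time/activity arrays (one animal per point)."""
    pts = tuple(
        SerumMeasurement(f"a{i:02d}", float(t), float(v), float(dose))
        for i, (t, v) in enumerate(zip(times, values))
    )
    return SerumCurve(tracer, pts)


def mono_curve(c0, t_half, times, dose=1.0e6):
    """Noise-free monoexponential serum curve."""
    times = np.asarray(times, float)
    lam = np.log(2.0) / t_half
    return make_curve(times, c0 * np.exp(-lam * times), dose=dose)


@pytest.fixture
def toy_csv(tmp_path):
    """Minimal valid study file: one tracer, 2 serum + 2 tissue rows."""
    path = tmp_path / "toy.csv"
    path.write_text(
        "animal_id,tracer,compartment,tissue,time_min,value,injected_dose_cpm\n"
        "m1,LIG,serum,,1.0,50000.0,1000000.0\n"
        "m2,LIG,serum,,10.0,5000.0,1000000.0\n"
        "m1,LIG,tissue,whole brain,1.0,600.0,\n"
        "m2,LIG,tissue,whole brain,10.0,120.0,\n"
    )
    return path
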