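import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tracerkin import (
    DegenerateDesignError,
    DomainError,
    ExtrapolationError,
    InsufficientDataError,
    PairingError,
    PatlakModel,
    RatioPoint,
    SelectionError,
    SerumModel,
    TissueMeasurement,
    TissueSeries,
    exposure_profile,
    exposure_time,
    fit_patlak,
    select_linear_portion,
    tissue_serum_ratio,
    vascular_corrected_ratios,
)
from conftest import make_curve, mono_curve
from _oracles import ols_longhand, prefix_window_scan


class TestExposureTime:
    def test_constant_cp_gives_clock_time(self):
        curve = make_curve([0.5, 5.0, 20.0, 60.0], [300.0] * 4)
        for t in (0.5, 10.0, 60.0):
            ep = exposure_time(curve, t)
            assert ep.expt_min == pytest.approx(t, rel=1e-6)

    def test_monoexponential_closed_form(self):
        """Expt(10) for Cp = C0 e^(-0.1 t): (e^(0.1*10)-1)/0.1 = 17.1828 min."""
        times = np.linspace(0.0, 12.0, 25)
        curve = make_curve(times, 100.0 * np.exp(-0.1 * times))
        ep = exposure_time(curve, 10.0, grid_step=0.01)
        expected = (math.e - 1.0) / 0.1
        assert ep.expt_min == pytest.approx(expected, rel=1e-3)

    def test_zero_time_zero_exposure(self):
        curve = mono_curve(100.0, 5.0, [0.5, 1, 2, 5])
        assert exposure_time(curve, 0.0).expt_min == 0.0

    def test_beyond_last_sample_requires_opt_in(self):
        curve = mono_curve(100.0, 5.0, [0.5, 1, 2, 5])
        with pytest.raises(ExtrapolationError):
            exposure_time(curve, 10.0)
        ep = exposure_time(curve, 10.0, allow_beyond_last=True)
        assert ep.expt_min > 0

    @given(alpha=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, alpha):
        """Rescaling Cp leaves Expt unchanged (AUC and Cp scale together)."""
        times = [0.5, 1, 2, 5, 10]
        base = mono_curve(100.0, 5.0, times)
        scaled = make_curve(times, base.activity * alpha)
        a = exposure_time(base, 5.0).expt_min
        b = exposure_time(scaled, 5.0).expt_min
        assert b == pytest.approx(a, rel=1e-9)

    def test_strictly_increasing_for_decaying_cp(self):
        curve = mono_curve(50.0, 3.0, [0.5, 1, 2, 5, 10, 15])
        eps = exposure_profile(curve, [0.5, 1, 2, 5, 10, 15])
        expts = [e.expt_min for e in eps]
        assert all(b > a for a, b in zip(expts, expts[1:]))

    def test_closed_form_model_route(self):
        model = SerumModel.biexponential(40.0, 4.0, 5.0, 300.0)
        curve = mono_curve(1.0, 1.0, [1, 2])  # ignored when a model is given
        ep = exposure_time(curve, 30.0, serum_model=model)
        assert ep.expt_min == pytest.approx(model.expt(30.0), rel=1e-14)

    def test_no_extrapolation_option_starts_at_first_sample(self):
        curve = mono_curve(100.0, 5.0, [2.0, 4.0, 8.0])
        with_x = exposure_time(curve, 8.0, extrapolate_t0=True)
        without = exposure_time(curve, 8.0, extrapolate_t0=False)
        assert without.auc_to_t < with_x.auc_to_t


class TestTissueSerumRatio:
    @pytest.mark.parametrize(
        "am,cp,expected",
        [(2000.0, 1000.0, 2000.0), (1500.0, 1500.0, 1000.0), (15.0, 1500.0, 10.0)],
    )
    def test_examples(self, am, cp, expected):
        m = TissueMeasurement("a", "whole brain", 5.0, am, cp)
        assert tissue_serum_ratio(m) == pytest.approx(expected, rel=1e-12)


def _series(tracer, tissue, rows):
    return TissueSeries(
        tracer, tissue,
        tuple(TissueMeasurement(a, tissue, t, am, cp) for a, t, am, cp in rows),
    )


class TestVascularCorrection:
    def test_by_animal_subtraction(self):
        lig = _series("LIG", "b", [("m1", 5.0, 25.0, 1000.0)])
        mk = _series("ALB", "b", [("m1", 5.0, 10.0, 1000.0)])
        (pt,) = vascular_corrected_ratios(lig, mk)
        assert pt.delta_ts_ul_per_g == pytest.approx(15.0, rel=1e-12)

    def test_identical_ratios_give_zero(self):
        lig = _series("LIG", "b", [("m1", 5.0, 10.0, 1000.0)])
        mk = _series("ALB", "b", [("m1", 5.0, 20.0, 2000.0)])
        (pt,) = vascular_corrected_ratios(lig, mk)
        assert pt.delta_ts_ul_per_g == 0.0

    def test_by_time_uses_marker_mean(self):
        lig = _series("LIG", "b", [("m1", 5.0, 25.0, 1000.0)])
        mk = _series("ALB", "b", [("x1", 5.0, 8.0, 1000.0), ("x2", 5.0, 12.0, 1000.0)])
        (pt,) = vascular_corrected_ratios(lig, mk, pairing="by-time")
        assert pt.delta_ts_ul_per_g == pytest.approx(15.0, rel=1e-12)

    def test_orphan_raises_pairing_error(self):
        lig = _series("LIG", "b", [("m1", 5.0, 25.0, 1000.0), ("m2", 9.0, 25.0, 900.0)])
        mk = _series("ALB", "b", [("m1", 5.0, 10.0, 1000.0)])
        with pytest.raises(PairingError, match="m2"):
            vascular_corrected_ratios(lig, mk)

    def test_negative_deltas_are_retained(self):
        lig = _series("LIG", "b", [("m1", 5.0, 5.0, 1000.0)])
        mk = _series("ALB", "b", [("m1", 5.0, 10.0, 1000.0)])
        (pt,) = vascular_corrected_ratios(lig, mk)
        assert pt.delta_ts_ul_per_g == pytest.approx(-5.0)


def _points(x, y):
    return [RatioPoint(f"a{i}", float(i), yi, yi, xi) for i, (xi, yi) in enumerate(zip(x, y))]


class TestFitPatlak:
    def test_exact_line(self):
        x = np.array([2.0, 5.0, 10.0, 20.0, 40.0])
        fit = fit_patlak(_points(x, 0.5 * x + 10.0))
        assert fit.ki_ul_per_g_min == pytest.approx(0.5, rel=1e-9)
        assert fit.vi_ul_per_g == pytest.approx(10.0, rel=1e-9)
        assert fit.r == pytest.approx(1.0, abs=1e-12)
        assert fit.ki_se == pytest.approx(0.0, abs=1e-9)
        assert fit.vi_se == pytest.approx(0.0, abs=1e-8)

    def test_flat_marker_like_line(self):
        x = np.array([2.0, 5.0, 10.0, 20.0])
        fit = fit_patlak(_points(x, np.full(4, 12.0)))
        assert fit.ki_ul_per_g_min == 0.0
        assert fit.vi_ul_per_g == pytest.approx(12.0, rel=1e-14)

    def test_noisy_fit_matches_normal_equations(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(1, 60, 20)
        y = 0.4 * x + 8 + rng.normal(0, 1.0, 20)
        fit = fit_patlak(_points(x, y))
        o = ols_longhand(x, y)
        assert fit.ki_ul_per_g_min == pytest.approx(o["slope"], rel=1e-10)
        assert fit.vi_ul_per_g == pytest.approx(o["intercept"], rel=1e-10)
        assert fit.ki_se == pytest.approx(o["slope_se"], rel=1e-10)
        assert fit.vi_se == pytest.approx(o["intercept_se"], rel=1e-10)
        assert fit.r == pytest.approx(o["r"], rel=1e-10)

    def test_insufficient_points(self):
        with pytest.raises(InsufficientDataError):
            fit_patlak(_points([1.0, 2.0], [1.0, 2.0]))

    def test_degenerate_design(self):
        with pytest.raises(DegenerateDesignError):
            fit_patlak(_points([3.0, 3.0, 3.0], [1.0, 2.0, 3.0]))

    def test_window_restriction(self):
        x = np.array([1.0, 2.0, 5.0, 10.0, 50.0, 80.0])
        y = 0.5 * x + 10.0
        y[-2:] = [20.0, 21.0]  # plateau outside the linear portion
        fit = fit_patlak(_points(x, y), window_expt=(None, 10.0))
        assert fit.n_points == 4
        assert fit.ki_ul_per_g_min == pytest.approx(0.5, rel=1e-9)

    def test_json_round_trip(self):
        from tracerkin import PatlakFit

        rng = np.random.default_rng(9)
        x = rng.uniform(1, 60, 10)
        fit = fit_patlak(_points(x, 0.4 * x + 8 + rng.normal(0, 1, 10)))
        back = PatlakFit.from_dict(fit.to_dict())
        assert back == fit


class TestModelConsistency:
    """The central forward/inverse oracle: tissue data generated from
    Am = Ki*AUC + Vi*Cp lie exactly on delta T/S = Ki*Expt + Vi."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_exact_recovery_any_design(self, seed):
        rng = np.random.default_rng(seed)
        model = SerumModel.biexponential(
            rng.uniform(10, 60), rng.uniform(0.5, 10),
            rng.uniform(1, 20), rng.uniform(50, 600),
        )
        ki, vi = rng.uniform(0.05, 2.0), rng.uniform(2, 30)
        times = np.sort(rng.uniform(0.5, 200, rng.integers(3, 10)))
        ts = (ki * model.auc(times) + vi * model.cp(times)) / model.cp(times)
        pts = [RatioPoint(f"a{i}", t, float(v), float(v), float(model.expt(t)))
               for i, (t, v) in enumerate(zip(times, ts))]
        fit = fit_patlak(pts)
        assert fit.ki_ul_per_g_min == pytest.approx(ki, rel=1e-12)
        assert fit.vi_ul_per_g == pytest.approx(vi, rel=1e-10)


class TestSelectLinearPortion:
    def test_fully_linear_full_range(self):
        x = np.linspace(1, 50, 8)
        win = select_linear_portion(_points(x, 0.5 * x + 3), 3, 0.99)
        assert win == (1.0, 50.0)

    def test_plateau_truncates_at_linear_prefix(self):
        x = np.array([2.0, 10.0, 20.0, 35.0, 50.0, 70.0, 90.0])
        y = np.where(x <= 50, 0.5 * x + 10, 0.5 * 50 + 10)  # saturating uptake
        pts = _points(x, y)
        win = select_linear_portion(pts, 3, 0.999)
        oracle = prefix_window_scan(x, y, 3, 0.999)
        assert win == oracle
        assert win == (2.0, 50.0)

    def test_min_points_exceeds_n(self):
        with pytest.raises(SelectionError):
            select_linear_portion(_points([1.0, 2.0], [1.0, 2.0]), 3, 0.9)
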