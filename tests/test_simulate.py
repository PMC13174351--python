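import numpy as np
import pytest

from tracerkin import (
    DomainError,
    PatlakModel,
    SerumModel,
    SimulationConfig,
    ValidationError,
    fit_terminal_phase,
    insulin_like_config,
    slow_ligand_config,
    simulate_serum_curve,
    simulate_study,
    simulate_tissue_uptake,
    tissue_serum_ratio,
    write_study_csv,
)


class TestSimulateSerumCurve:
    def test_noise_free_equals_closed_form(self):
        model = SerumModel.biexponential(40.0, 4.0, 2.8, 556.0)
        times = [0.5, 5.0, 60.0]
        curve = simulate_serum_curve(model, times, noise_cv=0.0, n_animals=2,
                                     dose=1e6, seed=0)
        expected = np.repeat(model.cp(np.array(times)) * 1e6 / 100.0, 2)
        np.testing.assert_allclose(curve.activity, expected, rtol=1e-14)

    def test_same_seed_identical(self):
        model = SerumModel.monoexponential(50.0, 1.8)
        a = simulate_serum_curve(model, [1, 2, 3], noise_cv=0.1, n_animals=3,
                                 dose=1e6, seed=99)
        b = simulate_serum_curve(model, [1, 2, 3], noise_cv=0.1, n_animals=3,
                                 dose=1e6, seed=99)
        assert a.points == b.points

    def test_noise_is_mean_unbiased_with_stated_cv(self):
        """Law of large numbers: 10,000 animals at one time reproduce the
        true mean within 1% and a CV of 0.1 within 10%."""
        model = SerumModel.monoexponential(50.0, 100.0)
        curve = simulate_serum_curve(model, [10.0], noise_cv=0.1,
                                     n_animals=10_000, dose=1e6, seed=123)
        true = model.cp(10.0) * 1e6 / 100.0
        vals = curve.activity
        assert vals.mean() == pytest.approx(true, rel=0.01)
        assert vals.std() / vals.mean() == pytest.approx(0.1, rel=0.1)

    def test_negative_noise_rejected(self):
        model = SerumModel.monoexponential(50.0, 1.8)
        with pytest.raises(DomainError):
            simulate_serum_curve(model, [1.0], noise_cv=-0.1, n_animals=1,
                                 dose=1e6, seed=0)


class TestSimulateTissueUptake:
    def test_pure_vascular_tracer_has_constant_ts(self):
        model = SerumModel.biexponential(40.0, 4.0, 2.8, 556.0)
        series = simulate_tissue_uptake(model, ki=0.0, vi=12.0,
                                        times=[0.5, 5, 20, 60, 225],
                                        noise_cv=0.0, seed=0)
        for m in series.measurements:
            assert tissue_serum_ratio(m) == pytest.approx(12.0, rel=1e-12)

    def test_points_lie_on_patlak_line_by_construction(self):
        model = SerumModel.biexponential(40.0, 4.0, 2.8, 556.0)
        ki, vi = 0.5, 10.0
        times = np.array([0.5, 5.0, 20.0, 60.0, 225.0])
        series = simulate_tissue_uptake(model, ki=ki, vi=vi, times=times,
                                        noise_cv=0.0, seed=0)
        for m in series.measurements:
            expected = ki * model.expt(m.time_min) + vi
            assert tissue_serum_ratio(m) == pytest.approx(expected, rel=1e-10)

    def test_negative_ki_rejected(self):
        model = SerumModel.monoexponential(50.0, 1.8)
        with pytest.raises(DomainError):
            simulate_tissue_uptake(model, ki=-0.1, vi=10.0, times=[1.0],
                                   noise_cv=0.0, seed=0)


class TestSimulateStudy:
    def test_insulin_like_round_trip_noise_free(self):
        cfg = insulin_like_config(
            seed=0, noise_cv=0.0, animals_per_time=1,
            serum_ligand=SerumModel.monoexponential(50.0, 1.8),
        )
        study, truth = simulate_study(cfg)
        fit = fit_terminal_phase(study.ligand.serum)
        assert fit.t_half_min == pytest.approx(1.8, rel=1e-9)
        assert truth["ligand_half_lives_min"]["fast"] == pytest.approx(1.8)

    def test_slow_phase_recovered_where_fast_phase_has_decayed(self):
        """With a 58/556-min biexponential, a late window where the fast
        term is provably below 1e-7 of the slow term recovers 556 min to
        1e-6 relative."""
        model = SerumModel.biexponential(39.2, 58.0, 2.8, 556.0)
        times = np.array([1800.0, 2200.0, 2600.0, 3000.0])
        # contamination bound at the earliest window time
        contamination = (model.a1 / model.a2) * np.exp(-(model.lam1 - model.lam2) * times[0])
        assert contamination < 1e-7
        curve = simulate_serum_curve(model, times, noise_cv=0.0, n_animals=1,
                                     dose=1e6, seed=0)
        fit = fit_terminal_phase(curve)
        assert fit.t_half_min == pytest.approx(556.0, rel=1e-6)

    def test_cross_sectional_design(self):
        cfg = slow_ligand_config(seed=3, animals_per_time=2)
        study, _ = simulate_study(cfg)
        times_by_animal = {}
        for p in study.ligand.serum.points:
            times_by_animal.setdefault(p.animal_id, set()).add(p.time_min)
        assert all(len(ts) == 1 for ts in times_by_animal.values())
        # marker measured in the same animals (co-injection)
        assert {p.animal_id for p in study.marker.serum.points} == set(times_by_animal)

    def test_byte_identical_csv_for_same_seed(self, tmp_path):
        for name in ("a.csv", "b.csv"):
            study, _ = simulate_study(slow_ligand_config(seed=11))
            write_study_csv(study, tmp_path / name)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_full_patlak_round_trip_noise_free(self):
        cfg = slow_ligand_config(seed=0, noise_cv=0.0, animals_per_time=1)
        study, truth = simulate_study(cfg)
        fit = PatlakModel.from_study(study, "whole brain",
                                     exposure="fitted-model").fit()
        ki = truth["ki_true_ul_per_g_min"]["whole brain"]
        assert fit.ki_ul_per_g_min == pytest.approx(ki, rel=1e-9)
        # marker Vi equals ligand Vi here, so the corrected intercept is 0
        assert fit.vi_ul_per_g == pytest.approx(0.0, abs=1e-9)

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            slow_ligand_config(animals_per_time=0)
        with pytest.raises(DomainError):
            slow_ligand_config(noise_cv=-0.5)
        with pytest.raises(DomainError):
            slow_ligand_config(ki_true={"whole brain": -1.0})
        with pytest.raises(ValidationError):
            slow_ligand_config(ki_true={"whole brain": 0.5, "muscle": 0.1})

    def test_yaml_round_trip(self, tmp_path):
        cfg = slow_ligand_config(seed=5)
        path = tmp_path / "sim.yaml"
        cfg.to_yaml(path)
        back = SimulationConfig.from_yaml(path)
        assert back == cfg

    def test_poisson_counting_noise_stays_positive(self):
        cfg = slow_ligand_config(seed=2, poisson_counts=True, noise_cv=0.05)
        study, _ = simulate_study(cfg)
        assert np.all(study.ligand.serum.activity > 0)
        assert all(float(v).is_integer() for v in study.ligand.serum.activity)
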