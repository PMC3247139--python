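"""Error model, chi-square merit and multi-experiment fitting."""

import numpy as np
import pytest

from plateletsig import (
    H0,
    H3,
    BasalConstants,
    DomainError,
    ExperimentSeries,
    ParameterSpec,
    StimulusProtocol,
    build_default_specs,
    chi2_merit,
    error_sigma,
    fit_variants,
    multi_experiment_fit,
)
from plateletsig.calibrate import ParameterError, data_fingerprint
from plateletsig.synth import StudyDesign, generate_study


class TestErrorSigma:
    def test_formula_arithmetic(self):
        sigma = error_sigma([10.0, 100.0])
        np.testing.assert_allclose(sigma, [0.1 * 10 + 0.05 * 100,
                                           0.1 * 100 + 0.05 * 100])

    def test_constant_series(self):
        np.testing.assert_allclose(error_sigma([7.0, 7.0, 7.0]), 0.15 * 7.0)

    def test_sigma_floor_on_degenerate_series(self):
        assert np.all(error_sigma([0.0, 0.0]) == 1e-6)

    def test_sigma_is_per_series_not_pooled(self):
        # the range term uses each experiment's own maximum
        lo = error_sigma([1.0, 2.0])
        hi = error_sigma([1.0, 200.0])
        assert lo[0] == pytest.approx(0.1 + 0.05 * 2.0)
        assert hi[0] == pytest.approx(0.1 + 0.05 * 200.0)

    def test_sem_scaling(self):
        np.testing.assert_allclose(error_sigma([10.0], n_replicates=4),
                                   error_sigma([10.0]) / 2.0)


def _two_point_series(eid, values, sigma=None):
    return ExperimentSeries(eid, StimulusProtocol(), "cAMP",
                            np.array([0.0, 5.0]), np.asarray(values, float),
                            sigma)


class TestChi2Merit:
    def test_zero_on_noise_free_self_generated_data(self):
        exps, truth = generate_study(StudyDesign(seed=3, noise_scale=0.0,
                                                 doses={"Milrinone": (10.0,)}))
        params = {"ki:Milrinone": truth["ki:Milrinone"], "kf1": truth["kf1"],
                  "kf2": truth["kf2"]}
        assert chi2_merit(params, exps, H3) == pytest.approx(0.0, abs=1e-8)

    def test_one_sigma_offset_gives_unit_chi2(self):
        exps, _ = generate_study(StudyDesign(seed=3, noise_scale=0.0,
                                             doses={"Milrinone": (10.0,)}))
        series = exps[0]
        shifted = ExperimentSeries(
            series.experiment_id, series.protocol, series.observable,
            series.times,
            series.values + np.eye(1, series.n_points, 2)[0] * series.sigma,
            series.sigma)
        chi2 = chi2_merit({"ki:Milrinone": 2.0, "kf1": 0.05, "kf2": 0.15},
                          [shifted], H3)
        assert chi2 == pytest.approx(1.0, abs=1e-6)

    def test_additive_over_experiments_brute_force(self):
        # hand-rolled double loop over points on a 3-experiment fixture
        exps, truth = generate_study(StudyDesign(
            seed=9, doses={"Milrinone": (10.0,), "Iloprost": (10.0, 100.0)}))
        params = {"ki:Milrinone": truth["ki:Milrinone"],
                  "influx:Iloprost:10": truth["influx:Iloprost:10"],
                  "influx:Iloprost:100": truth["influx:Iloprost:100"],
                  "kf1": truth["kf1"], "kf2": truth["kf2"]}
        total = chi2_merit(params, exps, H3)
        by_hand = sum(chi2_merit(params, [e], H3) for e in exps)
        assert total == pytest.approx(by_hand, rel=1e-12)
        brute = 0.0
        from plateletsig.calibrate import evaluate_model_curves
        from plateletsig.params import ParameterContext
        from plateletsig import DrugParameters

        ctx = ParameterContext(BasalConstants(), DrugParameters())
        for name, value in params.items():
            ctx.set(name, value)
        curves = evaluate_model_curves(exps, ctx, H3)
        for e, curve in zip(exps, curves):
            for i in range(e.n_points):
                brute += ((e.values[i] - curve[i]) / e.sigma[i]) ** 2
        assert total == pytest.approx(brute, rel=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(DomainError):
            _two_point_series("x", [1.0, 2.0], sigma=np.array([0.1, 0.0]))


class TestMultiExperimentFit:
    def test_noise_free_fit_recovers_truth(self, small_design):
        design = StudyDesign(seed=small_design.seed, doses=small_design.doses,
                             noise_scale=0.0)
        exps, truth = generate_study(design)
        specs = build_default_specs(exps, H3)
        fit = multi_experiment_fit(exps, specs, H3, seed=0)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-6)
        for spec in specs:
            assert fit.parameters[spec.name] == pytest.approx(
                truth[spec.name], rel=0.01)

    def test_chi2_never_worse_than_initial_guess(self, small_design):
        exps, _ = generate_study(small_design)
        specs = build_default_specs(exps, H3)
        from plateletsig.calibrate import MultiExperimentProblem

        problem = MultiExperimentProblem(exps, specs, H3)
        chi2_init = problem.chi2(problem.initial_internal())
        fit = multi_experiment_fit(exps, specs, H3, seed=0)
        assert fit.chi2 <= chi2_init + 1e-9

    def test_restart_determinism(self, small_design):
        exps, _ = generate_study(small_design)
        specs = build_default_specs(exps, H3)
        a = multi_experiment_fit(exps, specs, H3, n_restarts=2, seed=11)
        b = multi_experiment_fit(exps, specs, H3, n_restarts=2, seed=11)
        assert a.chi2 == b.chi2
        assert a.parameters == b.parameters

    def test_bounds_respected(self, small_design):
        exps, _ = generate_study(small_design)
        specs = build_default_specs(exps, H3)
        fit = multi_experiment_fit(exps, specs, H3, seed=0)
        for spec in specs:
            assert spec.lower <= fit.parameters[spec.name] <= spec.upper

    def test_local_parameters_instantiated_per_dose(self, small_design):
        exps, _ = generate_study(small_design)
        specs = build_default_specs(exps, H3)
        locals_ = [s for s in specs if s.role == "local"]
        assert {s.name for s in locals_} == {"influx:Iloprost:10",
                                             "influx:Iloprost:100"}

    def test_nested_dominance_of_chi2(self, small_design):
        exps, _ = generate_study(small_design)
        fits = fit_variants(exps, seed=2, ftol=1e-8, xtol=1e-8, rk_step=0.05)
        tol = 1e-6 * max(fits["H0"].chi2, 1.0)
        assert fits["H3"].chi2 <= fits["H1"].chi2 + tol
        assert fits["H3"].chi2 <= fits["H2"].chi2 + tol
        assert fits["H1"].chi2 <= fits["H0"].chi2 + tol
        assert fits["H2"].chi2 <= fits["H0"].chi2 + tol

    def test_n_less_than_p_rejected(self):
        series = _two_point_series("tiny", [4.0, 5.0])
        specs = [ParameterSpec(f"ki:Milrinone", 10.0, 1e-2, 1e3),
                 ParameterSpec("kf1", 0.0, -1.0, 1.0, log=False),
                 ParameterSpec("kf2", 0.0, -1.0, 1.0, log=False)]
        from plateletsig.model import ConfigurationError

        with pytest.raises(ConfigurationError):
            multi_experiment_fit([series], specs, H3)

    def test_data_fingerprint_sensitive_to_values(self):
        a = _two_point_series("x", [1.0, 2.0])
        b = _two_point_series("x", [1.0, 2.0001])
        assert data_fingerprint([a]) != data_fingerprint([b])
        assert data_fingerprint([a]) == data_fingerprint([
            _two_point_series("x", [1.0, 2.0])])


class TestParameterSpec:
    def test_bounds_validation(self):
        with pytest.raises(ParameterError):
            ParameterSpec("k11", 8.0, 10.0, 5.0)
        with pytest.raises(ParameterError):
            ParameterSpec("k11", 8.0, np.inf, -np.inf)
        with pytest.raises(ParameterError):
            ParameterSpec("k11", 8.0, -1.0, 10.0, log=True)

    def test_log_round_trip(self):
        spec = ParameterSpec("ki:Milrinone", 2.0, 1e-2, 1e4)
        assert spec.from_internal(spec.to_internal(3.7)) == pytest.approx(3.7)
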