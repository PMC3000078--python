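"""Joint multi-thermogram fitting, holdout prediction, counter-fits."""

import numpy as np
import pytest

from calorikin import (
    DomainModel,
    ExcessCurve,
    FitProblem,
    KineticParameters,
    OneStageDomain,
    TwoStageDomain,
    check_one_stage,
    constrained_counterfit,
    estimate_uncertainty,
    fit_model,
    predict_holdout,
    simulate_model,
    simulate_one_stage,
)
from calorikin.globalfit import model_to_vector, parameter_names
from calorikin.kinetics import anneal_model, default_grid

NU = 1.0


def _observations(cfg, data):
    names = ["native"] + [f"annealed_{h[0]:.2f}K_{h[1]:.0f}min"
                          for h in cfg.annealing_schedule]
    hists = [None, *cfg.annealing_schedule]
    return tuple((data["excess"][n], h) for n, h in zip(names, hists))


def _template_from_peel(peel):
    t3, t2, t1 = peel.transitions
    return DomainModel((
        OneStageDomain(KineticParameters(t1.E_a, t1.T_star), t1.dH),
        TwoStageDomain(KineticParameters(t2.E_a, t2.T_star),
                       KineticParameters(t3.E_a, t3.T_star), t2.dH, t3.dH),
    ))


@pytest.fixture(scope="module")
def joint_fit(noiseless_set, native_peel):
    cfg, data = noiseless_set
    problem = FitProblem(_observations(cfg, data), _template_from_peel(native_peel))
    return cfg, problem, fit_model(problem, n_starts=4)


class TestFitModel:
    def test_noiseless_recovery_of_all_parameters(self, joint_fit, s1_model):
        cfg, _, result = joint_fit
        assert result.converged
        truth = dict(zip(parameter_names(s1_model), model_to_vector(s1_model)))
        for name, value in result.parameters.items():
            kind = name.rsplit(".", 1)[-1]
            if kind == "T_star":
                assert value == pytest.approx(truth[name], abs=0.1), name
            elif kind == "E_a":
                assert value == pytest.approx(truth[name], abs=10.0), name
            else:
                assert value == pytest.approx(truth[name], rel=0.02), name

    def test_single_curve_fit_matches_one_stage_check(self):
        d = OneStageDomain(KineticParameters(300.0, 320.0), 150.0)
        g = default_grid()
        ex = simulate_one_stage(d, g, NU)
        rep = check_one_stage(ex, NU)
        result = fit_model(FitProblem(((ex, None),), DomainModel((d,))), n_starts=1)
        assert result.parameters["d0.E_a"] == pytest.approx(rep.E_a, abs=0.5)
        assert result.parameters["d0.T_star"] == pytest.approx(rep.T_star, abs=0.01)
        assert result.parameters["d0.dH"] == pytest.approx(rep.dH, rel=1e-3)

    def test_all_frozen_returns_template(self, noiseless_set, s1_model):
        cfg, data = noiseless_set
        problem = FitProblem(_observations(cfg, data), s1_model,
                             frozen=frozenset(parameter_names(s1_model)))
        result = fit_model(problem)
        np.testing.assert_allclose(model_to_vector(result.model),
                                   model_to_vector(s1_model))
        assert result.converged

    def test_unknown_frozen_name_rejected(self, noiseless_set, s1_model):
        cfg, data = noiseless_set
        with pytest.raises(ValueError):
            FitProblem(_observations(cfg, data), s1_model, frozen=frozenset({"bogus"}))


class TestPredictHoldout:
    def test_holdout_prediction_matches_truth_curve(self, joint_fit, s1_model, grid):
        cfg, _, result = joint_fit
        pred = predict_holdout(result.model, cfg.holdout_annealing, NU, grid)
        truth = simulate_model(anneal_model(s1_model, *cfg.holdout_annealing), grid, NU)
        peak = float(np.max(truth.excess_heat_capacity))
        assert np.max(np.abs(pred.excess_heat_capacity
                             - truth.excess_heat_capacity)) < 0.01 * peak

    def test_zero_hold_equals_native_simulation(self, s1_model, grid):
        pred = predict_holdout(s1_model, (317.15, 0.0), NU, grid)
        native = simulate_model(s1_model, grid, NU)
        np.testing.assert_allclose(pred.excess_heat_capacity,
                                   native.excess_heat_capacity, rtol=1e-12)

    def test_harsh_annealing_prediction_non_negative(self, s1_model, grid):
        pred = predict_holdout(s1_model, (322.0, 60.0), NU, grid)
        assert np.all(pred.excess_heat_capacity >= 0.0)


COUNTERFIT_NOISE = 0.0005


@pytest.fixture(scope="module")
def noisy_problem(s1_model, grid):
    # small noise so holdout residuals are noise- not roundoff-limited;
    # the holdout is a mild hold that leaves the disputed domain
    # partially alive, which is what discriminates its T*
    rng = np.random.default_rng(5)
    schedule = [None, (319.15, 15.0), (315.15, 20.0)]
    obs = []
    for hist in schedule:
        m = s1_model if hist is None else anneal_model(s1_model, *hist)
        ex = simulate_model(m, grid, NU)
        peak = float(np.max(ex.excess_heat_capacity))
        noisy = (ex.excess_heat_capacity
                 + COUNTERFIT_NOISE * peak * rng.standard_normal(grid.size))
        obs.append((ExcessCurve(grid, noisy, heating_rate=NU), hist))
    hold_hist = (313.15, 15.0)
    hold = simulate_model(anneal_model(s1_model, *hold_hist), grid, NU)
    peak = float(np.max(hold.excess_heat_capacity))
    hold_noisy = ExcessCurve(
        grid, hold.excess_heat_capacity
        + COUNTERFIT_NOISE * peak * rng.standard_normal(grid.size),
        heating_rate=NU)
    problem = FitProblem(tuple(obs), s1_model)
    return problem, [(hold_noisy, hold_hist)]


class TestConstrainedCounterfit:

    def test_wrong_equality_rejected_by_prediction(self, noisy_problem):
        # freezing the least stable domain's T* at a wrong average value
        # must degrade the holdout prediction clearly
        problem, holdouts = noisy_problem
        report = constrained_counterfit(problem, {"d0.T_star": 318.3}, holdouts)
        assert report["holdout_sd_ratio"][0] > 3.0

    def test_true_value_constraint_is_harmless(self, noisy_problem):
        problem, holdouts = noisy_problem
        report = constrained_counterfit(problem, {"d0.T_star": 317.5}, holdouts)
        assert report["holdout_sd_ratio"][0] < 1.2

    def test_already_frozen_parameter_rejected(self, noiseless_set, s1_model):
        cfg, data = noiseless_set
        problem = FitProblem(_observations(cfg, data), s1_model,
                             frozen=frozenset({"d0.T_star"}))
        with pytest.raises(ValueError):
            constrained_counterfit(problem, {"d0.T_star": 318.3}, [])

    def test_constraint_never_improves_objective(self, noisy_problem):
        problem, holdouts = noisy_problem
        report = constrained_counterfit(problem, {"d0.T_star": 318.3}, holdouts)
        assert report["constrained"].cost >= report["unconstrained"].cost


class TestUncertainty:
    def test_noiseless_uncertainties_equal_floors(self, joint_fit):
        _, problem, result = joint_fit
        unc = estimate_uncertainty(problem, result, n_starts=1)
        for name, value in unc.items():
            kind = name.rsplit(".", 1)[-1]
            if kind == "T_star":
                assert value == pytest.approx(0.4)
            elif kind == "E_a":
                assert value == pytest.approx(40.0)
            else:
                assert value == pytest.approx(0.10 * abs(result.parameters[name]))
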