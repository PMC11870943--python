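"""Pooled-likelihood evaluation, fitting, precision, and diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ironpbpk import (
    DoseEvent,
    ErrorModelSpec,
    ObservationSet,
    compute_rse,
    fit_naive_pooled,
    gof_table,
    neg2_loglik,
    predict_observations,
    simulate,
)
from ironpbpk.estimation import EvaluationError, FitResult, hessian_standard_errors
from ironpbpk.synthetic_data import generate_mouse_study

from conftest import MOUSE_SAMPLING


def make_obs(times, compartment, values, dose_amount=0.005, dose_time=0.0,
             group="g1"):
    records = pd.DataFrame({
        "time_h": times,
        "compartment": compartment,
        "value": values,
        "units": "umol/L",
        "group": group,
        "dose_id": "d1",
    })
    doses = pd.DataFrame({
        "dose_id": ["d1"], "time_h": [dose_time], "amount": [dose_amount],
        "amount_units": ["umol"], "route": ["iv_plasma"],
    })
    return ObservationSet(records=records, doses=doses)


class TestPredictions:
    def test_match_direct_simulation(self, mouse_phys, diet_params):
        obs = generate_mouse_study(sigma=0.0, seed=0)
        mask = obs.records["group"] == "iron_adequate"
        sub = ObservationSet(records=obs.records[mask].reset_index(drop=True),
                             doses=obs.doses)
        pred = predict_observations(mouse_phys, diet_params, sub)
        res = simulate(mouse_phys, diet_params, sub.doses_for_group("iron_adequate"),
                       MOUSE_SAMPLING)
        for comp in sub.compartments:
            rows = sub.records["compartment"] == comp
            t = sub.records.loc[rows, "time_h"].to_numpy()
            idx = np.searchsorted(np.array(MOUSE_SAMPLING), t)
            np.testing.assert_allclose(pred[rows.to_numpy()],
                                       res.observed(comp)[idx], rtol=1e-9)

    def test_paper_schedule_gives_seven_predictions_per_compartment(
            self, mouse_phys, diet_params):
        obs = generate_mouse_study(sigma=0.0, seed=0)
        counts = obs.records.groupby(["group", "compartment"]).size()
        assert (counts == 7).all()
        pred = predict_observations(mouse_phys, diet_params, obs)
        assert pred.shape == (3 * 13 * 7,)

    def test_zero_before_any_dose(self, mouse_phys, diet_params):
        obs = make_obs([0.0, 1.0, 30.0], "plasma", [0.0, 0.0, 0.0],
                       dose_time=24.0)
        pred = predict_observations(mouse_phys, diet_params, obs)
        assert pred[0] == 0.0 and pred[1] == 0.0 and pred[2] > 0.0

    def test_serum_baseline_added(self, mouse_phys, diet_params):
        obs = make_obs([1.0], "serum", [1.0])
        base = predict_observations(mouse_phys, diet_params, obs)
        shifted = predict_observations(
            mouse_phys, diet_params, obs,
            errspec=ErrorModelSpec(serum_baseline=5.0))
        assert shifted[0] == pytest.approx(base[0] + 5.0)

    def test_unknown_compartment_raises(self, mouse_phys, diet_params):
        obs = make_obs([1.0], "thymus", [1.0])
        with pytest.raises(EvaluationError, match="thymus"):
            predict_observations(mouse_phys, diet_params, obs)


class TestNeg2LogLik:
    def test_zero_residuals_additive_unit_sigma(self):
        n = 12
        values = np.linspace(1.0, 3.0, n)
        obs = make_obs(np.linspace(1, 12, n), "plasma", values)
        spec = ErrorModelSpec(default_kind="additive", sigmas={"blood": 1.0})
        assert neg2_loglik(obs, values, spec) == pytest.approx(
            n * math.log(2 * math.pi))

    def test_proportional_single_record_hand_value(self):
        obs = make_obs([1.0], "plasma", [1.1])
        spec = ErrorModelSpec(sigmas={"blood": 0.1})
        expected = math.log(2 * math.pi) + math.log(0.01) + 1.0
        assert neg2_loglik(obs, np.array([1.0]), spec) == pytest.approx(expected)
        assert expected == pytest.approx(-1.7673, abs=1e-4)

    def test_matches_independent_record_by_record_summation(self):
        rng = np.random.default_rng(3)
        n = 50
        comps = rng.choice(["plasma", "liver", "rbc", "bone"], size=n)
        pred = rng.uniform(0.5, 5.0, size=n)
        values = pred * rng.uniform(0.8, 1.2, size=n)
        records = pd.DataFrame({
            "time_h": np.arange(1.0, n + 1), "compartment": comps,
            "value": values, "units": "umol/L", "group": "g",
            "dose_id": "d1"})
        doses = pd.DataFrame({"dose_id": ["d1"], "time_h": [0.0],
                              "amount": [1.0], "amount_units": ["umol"],
                              "route": ["iv_plasma"]})
        obs = ObservationSet(records=records, doses=doses)
        spec = ErrorModelSpec(kinds={"liver": "additive"},
                              sigmas={"blood": 0.15, "tissue": 0.3})
        # independent oracle: sum scipy normal log-densities one by one
        total = 0.0
        for y, yh, c in zip(values, pred, comps):
            sigma = 0.15 if c in ("plasma", "rbc") else 0.3
            sd = sigma if c == "liver" else sigma * yh
            total += -2.0 * stats.norm.logpdf(y, loc=yh, scale=sd)
        assert neg2_loglik(obs, pred, spec) == pytest.approx(total, rel=1e-12)

    def test_zero_prediction_under_proportional_error_is_flagged(self):
        obs = make_obs([1.0], "plasma", [0.5])
        spec = ErrorModelSpec(sigmas={"blood": 0.1})
        with pytest.raises(EvaluationError):
            neg2_loglik(obs, np.array([0.0]), spec)

    def test_scale_equivariance_under_proportional_error(self):
        rng = np.random.default_rng(9)
        n = 20
        pred = rng.uniform(0.5, 4.0, n)
        values = pred * (1 + 0.1 * rng.standard_normal(n))
        obs = make_obs(np.arange(1.0, n + 1), "plasma", values)
        spec = ErrorModelSpec(sigmas={"blood": 0.1})
        base = neg2_loglik(obs, pred, spec)
        c = 7.3
        scaled_obs = make_obs(np.arange(1.0, n + 1), "plasma", c * values)
        # multiplying observations and predictions by c shifts -2LL by
        # exactly 2 n log c (the variance scales with the prediction)
        assert neg2_loglik(scaled_obs, c * pred, spec) == pytest.approx(
            base + 2 * n * math.log(c), rel=1e-12)


class TestFit:
    def test_all_parameters_fixed_returns_init(self, mouse_phys, diet_params,
                                               diet):
        obs = generate_mouse_study(params_by_diet={diet: diet_params},
                                   sigma=0.05, seed=4)
        from ironpbpk.estimation import parameter_names

        fit = fit_naive_pooled(mouse_phys, obs, diet_params,
                               fixed_mask=parameter_names(mouse_phys))
        assert fit.params.to_dict() == diet_params.to_dict()
        assert fit.n_iter == 0 and fit.success
        assert fit.neg2_loglik == fit.neg2_loglik_init

    def test_objective_never_worse_than_init_and_order_invariant(self, mouse_phys):
        from ironpbpk import load_parameters
        from ironpbpk.estimation import parameter_names

        truth = load_parameters("mouse_iron_adequate")
        obs = generate_mouse_study(params_by_diet={"iron_adequate": truth},
                                   sigma=0.05, seed=12)
        init = truth.replace(q_e=truth.q_e * 1.6, t_rbc=truth.t_rbc * 0.7)
        free = {"q_e", "t_rbc"}
        fixed = tuple(n for n in parameter_names(mouse_phys) if n not in free)
        fit = fit_naive_pooled(mouse_phys, obs, init, fixed_mask=fixed,
                               n_starts=1, seed=0)
        assert fit.neg2_loglik <= fit.neg2_loglik_init
        # permuting record order changes nothing
        perm = obs.records.sample(frac=1.0, random_state=5).reset_index(drop=True)
        obs2 = ObservationSet(records=perm, doses=obs.doses)
        fit2 = fit_naive_pooled(mouse_phys, obs2, init, fixed_mask=fixed,
                                n_starts=1, seed=0)
        # the pooled objective sorts its summands, so the optimization
        # trajectory is bit-identical under record permutation
        assert fit2.params.q_e == fit.params.q_e
        assert fit2.params.t_rbc == fit.params.t_rbc
        # and the fit moved materially toward the generating values
        assert fit.params.t_rbc == pytest.approx(truth.t_rbc, rel=0.1)

    def test_likelihood_at_truth_beats_perturbed_parameters(self, mouse_phys):
        from ironpbpk import load_parameters

        truth = load_parameters("mouse_iron_adequate")
        spec = ErrorModelSpec(sigmas={"blood": 0.05, "tissue": 0.05})
        wins = 0
        for seed in range(10):
            obs = generate_mouse_study(params_by_diet={"iron_adequate": truth},
                                       sigma=0.05, seed=seed)
            perturbed = truth.replace(
                kp={o: 2 * v for o, v in truth.kp.items()},
                q_e=2 * truth.q_e, t_rbc=2 * truth.t_rbc,
                cl_loss=2 * truth.cl_loss)
            at_truth = neg2_loglik(
                obs, predict_observations(mouse_phys, truth, obs), spec)
            at_perturbed = neg2_loglik(
                obs, predict_observations(mouse_phys, perturbed, obs), spec)
            wins += at_truth < at_perturbed
        assert wins >= 9


class TestPrecision:
    def test_quadratic_objective_gives_exact_standard_error(self):
        v = 0.37
        se = hessian_standard_errors(lambda x: 0.5 * (x[0] - 1.2) ** 2 / v,
                                     np.array([1.2]))
        assert se[0] == pytest.approx(math.sqrt(v), rel=1e-6)

    def test_singular_information_yields_none(self):
        se = hessian_standard_errors(lambda x: 0.0 * x.sum(), np.zeros(2))
        assert se is None

    def test_rse_shrinks_with_replicate_count(self, mouse_phys):
        from ironpbpk import load_parameters
        from ironpbpk.estimation import parameter_names

        truth = load_parameters("mouse_iron_adequate")
        free = ("q_e", "t_rbc", "kp_liver")
        fixed = tuple(n for n in parameter_names(mouse_phys) if n not in free)
        spec = ErrorModelSpec(sigmas={"blood": 0.05, "tissue": 0.05})
        rses = []
        for reps in (1, 4, 16):
            obs = generate_mouse_study(params_by_diet={"iron_adequate": truth},
                                       sigma=0.05, replicates=reps,
                                       mean_data=False, seed=21)
            fit = FitResult(
                params=truth, sigmas={}, neg2_loglik=0.0, neg2_loglik_init=0.0,
                success=True, n_iter=0, message="", free_names=free,
                fixed_names=fixed,
                x_opt=np.log([truth.q_e, truth.t_rbc, truth.kp["liver"]]),
                n_obs=obs.n_records())
            fit = compute_rse(fit, mouse_phys, obs, spec)
            rses.append(fit.rse_percent["t_rbc"])
        # information grows linearly in replicates: RSE ~ 1/sqrt(R)
        assert rses[1] == pytest.approx(rses[0] / 2, rel=0.25)
        assert rses[2] == pytest.approx(rses[0] / 4, rel=0.25)

    def test_bootstrap_se_within_factor_two_of_hessian_se(self, mouse_phys):
        from ironpbpk import load_parameters
        from ironpbpk.estimation import parameter_names

        truth = load_parameters("mouse_iron_adequate")
        free = ("t_rbc",)
        fixed = tuple(n for n in parameter_names(mouse_phys) if n not in free)
        spec = ErrorModelSpec(sigmas={"blood": 0.05, "tissue": 0.05})
        obs = generate_mouse_study(params_by_diet={"iron_adequate": truth},
                                   sigma=0.05, seed=30)
        fit = fit_naive_pooled(mouse_phys, obs, truth, spec, fixed_mask=fixed,
                               n_starts=1, seed=0)
        fit = compute_rse(fit, mouse_phys, obs, spec)
        hess_se = fit.se["t_rbc"]
        rng = np.random.default_rng(31)
        boots = []
        for _ in range(12):
            resampled = obs.records.sample(frac=1.0, replace=True,
                                           random_state=rng.integers(2**31))
            bobs = ObservationSet(records=resampled.reset_index(drop=True),
                                  doses=obs.doses)
            bfit = fit_naive_pooled(mouse_phys, bobs, truth, spec,
                                    fixed_mask=fixed, n_starts=1, seed=0)
            boots.append(bfit.params.t_rbc)
        boot_se = float(np.std(boots, ddof=1))
        assert hess_se / 2 < boot_se < hess_se * 2


class TestGof:
    def test_zero_residuals_and_record_count(self, mouse_phys, diet_params,
                                             diet):
        obs = generate_mouse_study(params_by_diet={diet: diet_params},
                                   sigma=0.0, seed=0)
        pred = predict_observations(mouse_phys, diet_params, obs)
        table = gof_table(obs, pred, sigmas={"blood": 0.05, "tissue": 0.05})
        assert len(table) == obs.n_records()
        assert np.abs(table["residual"]).max() == 0.0
        assert np.abs(table["weighted_residual"]).max() == 0.0

    def test_weighted_residuals_standard_normal_under_generating_model(
            self, mouse_phys):
        from ironpbpk import load_parameters

        truth = load_parameters("mouse_iron_adequate")
        obs = generate_mouse_study(params_by_diet={"iron_adequate": truth},
                                   sigma=0.05, replicates=30, mean_data=False,
                                   seed=8)
        pred = predict_observations(mouse_phys, truth, obs)
        table = gof_table(obs, pred, sigmas={"blood": 0.05, "tissue": 0.05})
        w = table["weighted_residual"].to_numpy()
        assert np.mean(w) == pytest.approx(0.0, abs=0.05)
        assert np.std(w) == pytest.approx(1.0, rel=0.05)
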