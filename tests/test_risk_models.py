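"""Propensity and Cox model fitting: oracle agreement (independent
maximization of the written partial likelihood, statsmodels, lifelines),
parameter recovery from known generators, degenerate designs,
absolute-risk prediction and serialization."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import t2dmace as t
from t2dmace._design import build_covariate_design, covariate_design_columns
from t2dmace.risk_models import (
    HazardModel,
    ModelFitError,
    PredictionError,
    PropensityModelSet,
    _cox_efron_newton,
    _logistic_newton,
)


def _force_group_config(group, n, seed):
    """Simulation config that places every person in one exposure group."""
    cfg = t.SimulationConfig(n_persons=n, seed=seed)
    gldt = group in ("WC_GLDT", "PC_GLDT")
    norm = group in ("WC_GLDT", "REMISSION")
    cfg.gldt_coeffs = {"intercept": 30.0 if gldt else -30.0}
    cfg.normalise_coeffs = {"intercept": 30.0 if norm else -30.0, "gldt": 0.0}
    return cfg


class TestLogistic:
    def test_intercept_only_equals_proportion(self):
        X = np.ones((100, 1))
        y = np.zeros(100)
        y[:30] = 1
        beta, _, _ = _logistic_newton(X, y)
        assert 1 / (1 + np.exp(-beta[0])) == pytest.approx(0.30, abs=1e-10)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(8)
        X = np.column_stack([np.ones(400), rng.normal(size=(400, 3))])
        y = (rng.random(400) < 1 / (1 + np.exp(-X @ [0.2, 0.7, -0.4, 0.1]))).astype(float)
        beta, se, _ = _logistic_newton(X, y)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.allclose(beta, ref.params, atol=1e-8)
        assert np.allclose(se, ref.bse, atol=1e-6)

    def test_constant_mediator_falls_back_to_empirical(self, fixed_cohort):
        cohort = fixed_cohort.copy()
        cohort["m_statin"] = 0
        prop = t.fit_mediator_propensities(cohort)
        model = prop.models[("WC_GLDT", "statin")]
        assert model.kind == "empirical"
        X = build_covariate_design(cohort)
        assert np.all(prop.predict("WC_GLDT", "statin", X) <= 1e-9)

    def test_propensity_coefficient_recovery_3se(self):
        """Known logistic coefficients recovered within 3 asymptotic SE for
        the vast majority of coefficients, per group, at n=20,000."""
        from t2dmace.risk_models import _fit_logistic_ladder

        checks = []
        for gi, group in enumerate(t.EXPOSURE_LEVELS):
            cfg = _force_group_config(group, 20000, 500 + gi)
            cohort = t.simulate_cohort(cfg)
            assert (cohort["exposure"] == group).all()
            X = build_covariate_design(cohort)
            cols = covariate_design_columns()
            for med in ("statin", "rasi"):
                model = _fit_logistic_ladder(
                    X, cohort[f"m_{med}"].to_numpy(dtype=float), cols, group, med
                )
                assert model.kind == "mle"
                true = cfg.mediator_coeffs[group][med]
                full = model.full_coef()
                full_se = np.full(len(cols), np.nan)
                full_se[model.kept] = model.se
                for j, c in enumerate(cols):
                    if np.isnan(full_se[j]):
                        continue
                    checks.append(abs(full[j] - true.get(c, 0.0)) <= 3 * full_se[j])
        assert np.mean(checks) >= 0.95


class TestCox:
    def test_matches_brute_force_partial_likelihood(self):
        """On tie-free data the fit agrees with direct numerical
        maximization of the written Cox partial likelihood to 1e-6."""
        rng = np.random.default_rng(11)
        n = 60
        X = rng.normal(size=(n, 2))
        times = rng.exponential(1 / (0.3 * np.exp(X @ [0.8, -0.5])))
        event = rng.random(n) < 0.75
        assert len(np.unique(times)) == n  # no ties

        def neg_partial_loglik(beta):
            lp = X @ beta
            ll = 0.0
            for i in np.flatnonzero(event):
                risk = times >= times[i]
                ll += lp[i] - np.log(np.sum(np.exp(lp[risk])))
            return -ll

        ours, _, _ = _cox_efron_newton(X - X.mean(0), times, event.astype(int))
        ref = minimize(neg_partial_loglik, np.zeros(2), method="BFGS", tol=1e-12)
        assert np.allclose(ours, ref.x, atol=1e-6)

    def test_matches_lifelines_efron_with_ties(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(3)
        n = 500
        X = rng.normal(size=(n, 3))
        T = np.ceil(rng.exponential(1 / (0.1 * np.exp(X @ [0.5, -0.3, 0.2]))) * 12) / 12
        C = rng.exponential(8, n)
        times, event = np.minimum(T, C), (T <= C).astype(int)
        ours, H, _ = _cox_efron_newton(X - X.mean(0), times, event)
        df = pd.DataFrame(X, columns=["a", "b", "c"]).assign(T=times, E=event)
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        assert np.allclose(ours, cph.params_.to_numpy(), atol=1e-6)
        assert np.allclose(
            np.sqrt(np.diag(np.linalg.inv(H))), cph.standard_errors_.to_numpy(), atol=1e-6
        )

    def test_breslow_baseline_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(5)
        n = 300
        df = pd.DataFrame({"x": rng.normal(size=n)})
        T = np.ceil(rng.exponential(1 / (0.2 * np.exp(0.6 * df["x"]))) * 12) / 12
        C = rng.exponential(6, n)
        df["T"], df["E"] = np.minimum(T, C), (T <= C).astype(int)
        beta, _, _ = _cox_efron_newton(
            df[["x"]].to_numpy() - df["x"].mean(), df["T"].to_numpy(), df["E"].to_numpy()
        )
        from t2dmace.risk_models import _breslow_baseline

        bt, bh = _breslow_baseline(df[["x"]].to_numpy(), df["T"].to_numpy(), df["E"].to_numpy(), beta)
        cph = lifelines.CoxPHFitter(baseline_estimation_method="breslow").fit(df, "T", "E")
        ll_ch = cph.baseline_cumulative_hazard_["baseline cumulative hazard"]
        # step-evaluate ours at lifelines' grid; lifelines centers at the
        # covariate mean, so rescale our raw-zero baseline accordingly
        grid = ll_ch.index.to_numpy()
        idx = np.searchsorted(bt, grid, side="right") - 1
        ours_at_mean = np.where(idx >= 0, bh[np.maximum(idx, 0)], 0.0) * np.exp(
            beta[0] * df["x"].mean()
        )
        assert np.allclose(ours_at_mean, ll_ch.to_numpy(), rtol=1e-6, atol=1e-12)

    def test_parameter_recovery_within_3se(self):
        """Cox coefficients from a known proportional-hazards generator lie
        within 3 asymptotic SE of truth at n=5,000, and the Breslow
        baseline recovers the constant cumulative hazard."""
        cfg = t.SimulationConfig(n_persons=5000, seed=42)
        cohort = t.simulate_cohort(cfg)
        model = t.fit_mace_hazard(cohort)
        cols = np.array(model.columns)[model.kept]
        checks = [
            abs(b - cfg.hazard.log_hr.get(c, 0.0)) <= 3 * s
            for c, b, s in zip(cols, model.beta, model.se)
        ]
        assert np.mean(checks) >= 0.9
        lam5 = cfg.hazard.rate * 5
        assert model.cumhaz_at(5.0) == pytest.approx(lam5, rel=0.25)

    def test_zero_variance_design_reduces_to_nelson_aalen(self):
        n = 80
        rng = np.random.default_rng(6)
        times = np.ceil(rng.exponential(3.0, n) * 4) / 4
        event = rng.integers(0, 2, n)
        event[0] = 1
        X = np.zeros((n, 3))  # all columns constant
        model = HazardModel.fit_arrays(
            X[:, :0], np.array(["WC_GLDT"] * n, dtype=object),
            np.zeros(n), np.zeros(n), times, event,
        )
        # all exposure/mediator columns constant too -> empty design
        assert model.kept.sum() == 0
        # Nelson-Aalen: sum of d/n over event times
        order = np.argsort(times)
        na = 0.0
        for tt in np.unique(times[event == 1]):
            na += (event[times == tt]).sum() / (times >= tt).sum()
        assert model.cumhaz_at(times.max()) == pytest.approx(na, abs=1e-12)

    def test_monotone_likelihood_raises_with_advice(self):
        n = 60
        rng = np.random.default_rng(7)
        times = rng.exponential(1.0, n) + 0.01
        event = np.zeros(n, dtype=int)
        flag = np.zeros(n)
        flag[:20] = 1.0
        event[20:40] = 1  # events only where flag == 0
        X = flag[:, None]
        with pytest.raises(ModelFitError, match="reduc"):
            HazardModel.fit_arrays(
                X, np.array(["WC_GLDT"] * n, dtype=object),
                np.zeros(n), np.zeros(n), times, event,
            )


class TestPrediction:
    def test_risk_zero_at_time_zero(self, fixed_cohort, fitted_models):
        _, haz = fitted_models
        risks = t.predict_absolute_risk(haz, fixed_cohort.head(5), "WC_GLDT", 0, 0, 0.0)
        assert np.all(risks == 0.0)

    def test_closed_form_risk(self):
        # Lambda0(5)=0.10 at linear predictor 0 -> 1 - exp(-0.10)
        model = HazardModel(
            columns=[], kept=np.zeros(0, bool), beta=np.zeros(0), se=np.zeros(0),
            baseline_times=np.array([1.0]), baseline_cumhaz=np.array([0.10]),
        )
        assert 1 - np.exp(-0.10) == pytest.approx(float(model.cumhaz_at(5.0) and 1 - np.exp(-model.cumhaz_at(5.0))))

    def test_risk_nondecreasing_in_time(self, fixed_cohort, fitted_models):
        _, haz = fitted_models
        grid = [0.5, 1.0, 2.0, 5.0]
        risks = np.column_stack(
            [t.predict_absolute_risk(haz, fixed_cohort.head(20), "PERSISTENT", 1, 0, tt) for tt in grid]
        )
        assert np.all(np.diff(risks, axis=1) >= -1e-15)

    def test_unseen_level_raises_naming_it(self, fixed_cohort, fitted_models):
        _, haz = fitted_models
        broken = fixed_cohort.head(3).copy()
        broken["sex"] = "X"
        with pytest.raises((PredictionError, ValueError), match="X"):
            t.predict_absolute_risk(haz, broken, "WC_GLDT", 0, 0, 5.0)

    def test_reference_level_invariance(self, fixed_cohort):
        """Re-parameterizing with another reference exposure changes the
        coefficients but not a single predicted risk."""
        m1 = t.fit_mace_hazard(fixed_cohort, reference="WC_GLDT")
        m2 = t.fit_mace_hazard(fixed_cohort, reference="PERSISTENT")
        for a in t.EXPOSURE_LEVELS:
            r1 = t.predict_absolute_risk(m1, fixed_cohort, a, 1, 0, 5.0)
            r2 = t.predict_absolute_risk(m2, fixed_cohort, a, 1, 0, 5.0)
            assert np.allclose(r1, r2, atol=1e-8)

    def test_mean_predicted_risk_close_to_km(self, fixed_cohort):
        """Averaged model-based risks track the pooled Kaplan–Meier risk on
        proportional-hazards data."""
        haz = t.fit_mace_hazard(fixed_cohort)
        risks = haz.predict_absolute_risk(
            build_covariate_design(fixed_cohort),
            fixed_cohort["exposure"].to_numpy(),
            fixed_cohort["m_statin"].to_numpy(),
            fixed_cohort["m_rasi"].to_numpy(),
            5.0,
        )
        _, km = t.kaplan_meier_cuminc(
            fixed_cohort["followup_years"].to_numpy(), fixed_cohort["event"].to_numpy(), horizon=5.0
        )
        assert risks.mean() == pytest.approx(km["all"], abs=0.03)


class TestSerialization:
    def test_round_trip_exact(self, fixed_cohort, fitted_models):
        prop, haz = fitted_models
        doc = json.loads(json.dumps({"p": prop.to_json_dict(), "h": haz.to_json_dict()}))
        prop2 = PropensityModelSet.from_json_dict(doc["p"])
        haz2 = HazardModel.from_json_dict(doc["h"])
        X = build_covariate_design(fixed_cohort)
        for g in t.EXPOSURE_LEVELS:
            for med in ("statin", "rasi"):
                assert np.allclose(
                    prop.predict(g, med, X), prop2.predict(g, med, X), atol=0
                )
        r1 = t.predict_absolute_risk(haz, fixed_cohort, "REMISSION", 0, 1, 5.0)
        r2 = t.predict_absolute_risk(haz2, fixed_cohort, "REMISSION", 0, 1, 5.0)
        assert np.array_equal(r1, r2)
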