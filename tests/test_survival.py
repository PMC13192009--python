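"""Weighted KM, Cox engine (vs independent oracles), PH test, Weibull PH."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from frailtypaths.survival import fit_cox, fit_weibull_ph, km_weighted
from frailtypaths.survival import test_proportional_hazards as ph_test

from conftest import weibull_ph_sample


def brute_force_cox_score(beta, df, time_col="followup_time"):
    """Score of the explicit partial likelihood by direct risk-set
    enumeration; its root is the Cox MLE (one covariate, no ties)."""
    t = df[time_col].to_numpy(float)
    e = df["event"].to_numpy(int)
    x = df["x"].to_numpy(float)
    score = 0.0
    for i in np.where(e == 1)[0]:
        at_risk = t >= t[i]
        r = np.exp(beta * x[at_risk])
        score += x[i] - float(x[at_risk] @ r) / r.sum()
    return score


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        df = pd.DataFrame({"followup_time": [1., 2., 3.], "event": [0, 0, 0]})
        (curve,) = km_weighted(df)
        assert len(curve.times) == 0

    def test_hand_product_limit(self):
        """times (1..5), events (1,1,0,1,0): S = 0.8, 0.6, 0.3."""
        df = pd.DataFrame({"followup_time": [1., 2., 3., 4., 5.],
                           "event": [1, 1, 0, 1, 0]})
        (curve,) = km_weighted(df)
        assert np.allclose(curve.times, [1., 2., 4.])
        assert np.allclose(curve.survival, [0.8, 0.6, 0.3])

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "followup_time": rng.exponential(2, 100),
            "event": rng.binomial(1, .6, 100),
            "w": rng.uniform(.5, 3, 100),
        })
        (a,) = km_weighted(df, weight_col="w")
        df["w"] *= 7.3
        (b,) = km_weighted(df, weight_col="w")
        assert np.allclose(a.survival, b.survival)

    def test_integer_weights_equal_replication(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "followup_time": rng.exponential(2, 40).round(2) + .01,
            "event": rng.binomial(1, .7, 40),
            "w": rng.integers(1, 4, 40),
        })
        (wk,) = km_weighted(df, weight_col="w")
        rep = df.loc[df.index.repeat(df["w"])]
        (uk,) = km_weighted(rep)
        assert np.allclose(wk.survival, uk.survival)
        assert np.allclose(wk.se, uk.se)

    def test_matches_lifelines_weighted(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "followup_time": rng.exponential(3, 200),
            "event": rng.binomial(1, .5, 200),
            "w": rng.uniform(.2, 5, 200),
        })
        (c,) = km_weighted(df, weight_col="w")
        kmf = KaplanMeierFitter()
        kmf.fit(df["followup_time"], df["event"], weights=df["w"])
        ours = pd.Series(c.survival, index=c.times)
        theirs = kmf.survival_function_["KM_estimate"]
        for t0, s in ours.items():
            assert theirs.loc[t0] == pytest.approx(s, abs=1e-10)

    def test_nonpositive_weight_rejected(self):
        df = pd.DataFrame({"followup_time": [1., 2.], "event": [1, 0],
                           "w": [1.0, 0.0]})
        with pytest.raises(ValueError, match="weight"):
            km_weighted(df, weight_col="w")


class TestCox:
    def test_six_subject_fixture_matches_brute_force(self, six_subject_survival):
        """Engine equals the root of the explicit partial-likelihood score."""
        fit = fit_cox(six_subject_survival, ["x"], ties="breslow")
        root = optimize.brentq(
            lambda b: brute_force_cox_score(b, six_subject_survival),
            -5.0, 5.0, xtol=1e-13)
        assert fit.params["x"] == pytest.approx(root, abs=1e-8)

    def test_equal_weights_match_unweighted(self, six_subject_survival):
        df = six_subject_survival.assign(w=2.5)
        a = fit_cox(six_subject_survival, ["x"])
        b = fit_cox(df, ["x"], weight_col="w")
        assert b.params["x"] == pytest.approx(a.params["x"], abs=1e-8)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(7)
        df = weibull_ph_sample(rng, 5000, [0.5, -0.3])
        fit = fit_cox(df, ["x0", "x1"])
        se = np.sqrt(np.diag(fit.cov_model))
        assert abs(fit.params["x0"] - 0.5) < 3 * se[0]
        assert abs(fit.params["x1"] + 0.3) < 3 * se[1]

    def test_time_rescaling_invariance(self):
        rng = np.random.default_rng(8)
        df = weibull_ph_sample(rng, 300, [0.4])
        a = fit_cox(df, ["x0"])
        df2 = df.assign(followup_time=df["followup_time"] * 37.5)
        b = fit_cox(df2, ["x0"])
        assert b.params["x0"] == pytest.approx(a.params["x0"], abs=1e-10)

    def test_matches_lifelines_with_ties_and_weights(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(9)
        df = weibull_ph_sample(rng, 500, [0.5, -0.2])
        df["followup_time"] = np.ceil(df["followup_time"] * 4) / 4
        df["w"] = rng.uniform(.5, 2, len(df))
        fit = fit_cox(df, ["x0", "x1"], weight_col="w")
        cph = CoxPHFitter()
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df[["followup_time", "event", "x0", "x1", "w"]],
                    "followup_time", "event", weights_col="w")
        assert np.allclose(fit.params.values, cph.params_.values, atol=2e-6)

    def test_attained_age_scale_equals_delayed_entry(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(10)
        df = weibull_ph_sample(rng, 800, [0.4])
        df["age"] = rng.uniform(50, 80, len(df))
        fit = fit_cox(df, ["x0"], time_scale="attained_age")
        ll = df.assign(entry=df["age"], exit=df["age"] + df["followup_time"])
        cph = CoxPHFitter()
        cph.fit(ll[["entry", "exit", "event", "x0"]], "exit", "event",
                entry_col="entry")
        assert fit.params["x0"] == pytest.approx(cph.params_["x0"], abs=2e-6)

    def test_stratified_baseline(self):
        rng = np.random.default_rng(11)
        df = weibull_ph_sample(rng, 600, [0.5])
        df["cohort"] = rng.choice(["A", "B"], len(df))
        fit = fit_cox(df, ["x0"], strata_col="cohort")
        assert set(fit.baseline) == {"A", "B"}
        for key, bl in fit.baseline.items():
            assert (np.diff(bl["dLambda0"].cumsum()) >= 0).all()
            assert np.isfinite(bl["dLambda0"]).all() and (bl["dLambda0"] > 0).all()

    def test_baseline_hazard_finite_at_last_event(self):
        rng = np.random.default_rng(12)
        df = weibull_ph_sample(rng, 200, [0.3])
        fit = fit_cox(df, ["x0"])
        bl = fit.baseline[0]
        total = bl["dLambda0"].sum() * np.exp(df["x0"].mean()
                                              * fit.params["x0"])
        assert np.isfinite(total) and total > 0

    def test_separation_reported(self):
        df = pd.DataFrame({
            "followup_time": [1, 2, 3, 4, 5, 6.],
            "event": [1, 1, 1, 0, 0, 0],
            "x": [1, 1, 1, 0, 0, 0.],
        })
        with pytest.raises(RuntimeError, match="monotone|separation"):
            fit_cox(df, ["x"])

    def test_no_events_rejected(self):
        df = pd.DataFrame({"followup_time": [1., 2.], "event": [0, 0],
                           "x": [0., 1.]})
        with pytest.raises(ValueError, match="event"):
            fit_cox(df, ["x"])


class TestProportionalHazards:
    def test_statistic_invariant_to_affine_time_transform(self):
        """The test centres and normalises g(t), so rescaling event times
        leaves the identity-transform statistic unchanged."""
        rng = np.random.default_rng(21)
        df = weibull_ph_sample(rng, 300, [0.5])
        fit = fit_cox(df, ["x0"])
        a = ph_test(fit, transform="identity")
        df2 = df.assign(followup_time=5.0 * df["followup_time"] + 2.0)
        fit2 = fit_cox(df2, ["x0"])
        b = ph_test(fit2, transform="identity")
        assert b.loc["x0", "chi2"] == pytest.approx(a.loc["x0", "chi2"],
                                                    rel=1e-8)

    def test_detects_strong_time_interaction(self):
        rng = np.random.default_rng(13)
        n = 2000
        x = rng.binomial(1, .5, n).astype(float)
        # effect reverses over time -> scaled Schoenfeld drifts
        t1 = rng.exponential(1 / np.exp(1.2 * x))
        t2 = 1.0 + rng.exponential(1 / np.exp(-1.2 * x))
        T = np.where(t1 < 1.0, t1, t2)
        t = np.minimum(T, 3.0)
        df = pd.DataFrame({"followup_time": t, "event": (T <= 3.0).astype(int),
                           "x": x})
        fit = fit_cox(df, ["x"])
        tab = ph_test(fit)
        assert tab.loc["x", "p"] < 0.01

    def test_agrees_with_lifelines_km_transform(self):
        from lifelines import CoxPHFitter
        from lifelines.statistics import proportional_hazard_test
        rng = np.random.default_rng(14)
        df = weibull_ph_sample(rng, 400, [0.5, -0.3])
        fit = fit_cox(df, ["x0", "x1"])
        tab = ph_test(fit, transform="km")
        cph = CoxPHFitter()
        cph.fit(df[["followup_time", "event", "x0", "x1"]],
                "followup_time", "event")
        ref = proportional_hazard_test(cph, df, time_transform="km")
        for cov in ("x0", "x1"):
            assert tab.loc[cov, "chi2"] == pytest.approx(
                ref.summary.loc[cov, "test_statistic"].squeeze(), rel=0.05)

    def test_too_few_events_rejected(self, six_subject_survival):
        df = six_subject_survival.assign(event=[1, 0, 0, 0, 0, 0])
        fit = fit_cox(df, ["x"], max_iter=100, tol=1e-6)
        with pytest.raises(ValueError, match="events"):
            ph_test(fit)


class TestWeibullPH:
    def test_exponential_special_case(self):
        """With shape ~1 the MLE matches the closed-form exponential fit."""
        rng = np.random.default_rng(15)
        n = 3000
        T = rng.exponential(1 / 0.2, n)
        t = np.minimum(T, 8.0)
        df = pd.DataFrame({"followup_time": t,
                           "event": (T <= 8.0).astype(int)})
        fit = fit_weibull_ph(df, [])
        rate_mle = df["event"].sum() / df["followup_time"].sum()
        assert fit.shape == pytest.approx(1.0, abs=0.05)
        # at shape=1 the scale is the exponential rate
        assert fit.scale == pytest.approx(rate_mle, rel=0.05)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(16)
        df = weibull_ph_sample(rng, 5000, [0.5], shape=1.5)
        fit = fit_weibull_ph(df, ["x0"])
        se_b = np.sqrt(fit.cov.loc["x0", "x0"])
        se_logp = np.sqrt(fit.cov.loc["log_shape", "log_shape"])
        assert abs(fit.params["x0"] - 0.5) < 3 * se_b
        assert abs(np.log(fit.shape) - np.log(1.5)) < 3 * se_logp

    def test_agrees_with_cox_on_weibull_data(self):
        rng = np.random.default_rng(17)
        df = weibull_ph_sample(rng, 5000, [0.5, -0.3], shape=1.3)
        wf = fit_weibull_ph(df, ["x0", "x1"])
        cf = fit_cox(df, ["x0", "x1"])
        for c in ("x0", "x1"):
            joint_se = np.sqrt(wf.cov.loc[c, c] + cf.cov_model.loc[c, c])
            assert abs(wf.params[c] - cf.params[c]) < 3 * joint_se

    def test_weighted_fit_and_cluster_robust(self):
        rng = np.random.default_rng(18)
        df = weibull_ph_sample(rng, 1000, [0.4])
        df["w"] = rng.uniform(.5, 2, len(df))
        df["psu"] = rng.integers(0, 15, len(df))
        fit = fit_weibull_ph(df, ["x0"], weight_col="w", cluster_col="psu")
        assert np.isfinite(fit.summary().loc["x0", "se"])
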