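"""Prognostic models: preprocessing round-trips, penalized-logistic
oracles, importance scaling, and Cox parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from facesym.errors import ModelError
from facesym.prognosis import (
    EffectModel,
    apply_preprocess,
    dichotomize,
    fit_effect_model,
    fit_importance_table,
    fit_time_to_contraction,
    importance_scale,
    inverse_preprocess,
    predict_prognosis,
    preprocess,
)


def random_design(n=60, seed=0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "age": rng.normal(40, 12, n),
            "female": rng.integers(0, 2, n),
            "duration": rng.lognormal(2.8, 0.8, n),
            "cause_trauma": rng.integers(0, 2, n),
            "preop_fngs_grade": rng.integers(2, 7, n).astype(float),
        }
    )


class TestPreprocess:
    def test_binary_columns_pass_through(self):
        df = random_design()
        out, spec = preprocess(df)
        assert set(spec.passthrough) == {"female", "cause_trauma"}
        np.testing.assert_array_equal(out["female"], df["female"].astype(float))

    def test_round_trip_recovers_original(self):
        df = random_design(seed=4)
        out, spec = preprocess(df)
        back = inverse_preprocess(out, spec)
        for col in df.columns:
            np.testing.assert_allclose(back[col], df[col].astype(float), atol=1e-9)

    def test_constant_column_error_names_column(self):
        df = random_design()
        df["duration"] = 7.0
        with pytest.raises(ModelError, match="duration"):
            preprocess(df)

    def test_training_mean_maps_to_zero(self):
        df = random_design(seed=5)
        _, spec = preprocess(df)
        mean_patient = pd.DataFrame({c: [df[c].mean()] for c in ("age", "duration")})
        out = apply_preprocess(mean_patient, spec)
        assert out.iloc[0]["age"] == pytest.approx(0.0, abs=1e-12)
        assert out.iloc[0]["duration"] == pytest.approx(0.0, abs=1e-12)

    def test_out_of_domain_values_clip_with_warning(self):
        df = random_design(seed=6)
        _, spec = preprocess(df)
        extreme = pd.DataFrame({"age": [-1e4], "duration": [30.0]})
        with pytest.warns(UserWarning, match="age"):
            apply_preprocess(extreme, spec)


def two_by_two_dataset() -> tuple[pd.DataFrame, np.ndarray]:
    """Exposed: 8 events / 2 non-events; unexposed: 4 / 6 -> OR = 6."""
    x = np.array([1] * 10 + [0] * 10)
    y = np.array([1] * 8 + [0] * 2 + [1] * 4 + [0] * 6)
    return pd.DataFrame({"x": x}), y


class TestEffectModel:
    def test_zero_penalty_matches_log_odds_ratio(self):
        X, y = two_by_two_dataset()
        model = fit_effect_model(X, y, C=1e8, seed=0)
        assert model.coefficients["x"] == pytest.approx(np.log(6.0), abs=1e-3)

    def test_zero_penalty_matches_unpenalized_logistic_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(120, 3)), columns=list("abc"))
        y = rng.binomial(1, expit(0.8 * X["a"] - 0.5 * X["c"]))
        model = fit_effect_model(X, y, C=1e8, seed=0)
        oracle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        for col in X.columns:
            assert model.coefficients[col] == pytest.approx(oracle.params[col], abs=1e-3)

    def test_infinite_penalty_shrinks_to_zero(self):
        X, y = two_by_two_dataset()
        model = fit_effect_model(X, y, C=1e-8, seed=0)
        assert abs(model.coefficients["x"]) < 1e-6

    def test_constant_outcome_raises(self):
        X, _ = two_by_two_dataset()
        with pytest.raises(ModelError, match="constant"):
            fit_effect_model(X, np.ones(len(X), dtype=int), seed=0)

    def test_small_sample_warns(self):
        X, y = two_by_two_dataset()
        with pytest.warns(UserWarning, match="n=20"):
            fit_effect_model(X, y, C=1.0, seed=0)

    def test_parameter_recovery_on_synthetic_cohort(self):
        rng = np.random.default_rng(21)
        n, true = 500, np.array([1.0, 0.0, -0.5, 0.0, 0.8])
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=[f"v{i}" for i in range(5)])
        y = rng.binomial(1, expit(X.to_numpy() @ true))
        model = fit_effect_model(X, y, folds=5, seed=3)
        est = model.coefficients.to_numpy()
        nonzero = true != 0
        assert np.all(np.sign(est[nonzero]) == np.sign(true[nonzero]))
        assert np.abs(est[~nonzero]).max() < np.abs(est[nonzero]).min()

    def test_fixed_seed_reproduces_coefficients_bitwise(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(80, 3)), columns=list("abc"))
        y = rng.binomial(1, expit(X["a"]))
        m1 = fit_effect_model(X, y, folds=4, seed=42)
        m2 = fit_effect_model(X, y, folds=4, seed=42)
        assert (m1.coefficients == m2.coefficients).all()
        assert m1.C == m2.C


class TestImportanceScale:
    def test_linear_scaling(self):
        imp = importance_scale(np.array([0.2, -0.4, 0.1]))
        np.testing.assert_allclose(imp, [50.0, 100.0, 25.0])

    def test_all_zeros_map_to_zeros(self):
        np.testing.assert_array_equal(importance_scale(np.zeros(4)), np.zeros(4))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        coefs = rng.normal(size=6)
        perm = rng.permutation(6)
        np.testing.assert_allclose(
            importance_scale(coefs[perm]), importance_scale(coefs)[perm]
        )

    def test_scale_free(self):
        coefs = np.array([0.3, -1.2, 0.0, 0.7])
        np.testing.assert_allclose(
            importance_scale(coefs * 17.3), importance_scale(coefs), atol=1e-12
        )

    def test_max_importance_is_100_when_any_nonzero(self):
        imp = importance_scale(pd.Series({"a": 0.0, "b": -0.01}))
        assert imp.max() == 100.0 and imp["a"] == 0.0


def exponential_cox_data(n, beta, rng):
    x = rng.integers(0, 2, n)
    times = rng.exponential(1.0, n) * np.exp(-beta * x)
    return pd.DataFrame({"x": x}), times, np.ones(n, dtype=bool)


class TestCox:
    def test_recovers_hazard_ratio_two(self):
        rng = np.random.default_rng(17)
        X, t, e = exponential_cox_data(800, np.log(2.0), rng)
        res = fit_time_to_contraction(X, t, e)
        assert 1.7 <= res.summary.loc["x", "hr"] <= 2.3

    def test_null_covariate_ci_covers_one(self):
        rng = np.random.default_rng(23)
        covered = 0
        for _ in range(200):
            X, t, e = exponential_cox_data(100, 0.0, rng)
            s = fit_time_to_contraction(X, t, e).summary.loc["x"]
            covered += s["ci_lower"] <= 1.0 <= s["ci_upper"]
        assert covered >= 186  # >= 93% of 200 replicates

    def test_error_shrinks_with_sample_size(self):
        # consistency: average absolute log-HR error decreases over a
        # 4x-spaced n ladder (common random numbers per replicate)
        beta = np.log(2.0)
        errors = {}
        for n in (100, 400, 1600):
            errs = []
            for rep in range(40):
                rng = np.random.default_rng(1000 + rep)
                X, t, e = exponential_cox_data(n, beta, rng)
                est = fit_time_to_contraction(X, t, e).summary.loc["x", "log_hr"]
                errs.append((est - beta) ** 2)
            errors[n] = np.sqrt(np.mean(errs))
        assert errors[100] > errors[400] > errors[1600]

    def test_collinear_design_raises(self):
        rng = np.random.default_rng(3)
        X, t, e = exponential_cox_data(50, 0.0, rng)
        X["x2"] = X["x"]
        with pytest.raises(ModelError, match="rank"):
            fit_time_to_contraction(X, t, e)

    def test_all_censored_raises(self):
        rng = np.random.default_rng(3)
        X, t, _ = exponential_cox_data(50, 0.0, rng)
        with pytest.raises(ModelError, match="censored"):
            fit_time_to_contraction(X, t, np.zeros(50, dtype=bool))


class TestPrediction:
    def test_patient_at_training_mean_gets_logistic_intercept(self):
        df = random_design(seed=30)
        Xt, spec = preprocess(df)
        rng = np.random.default_rng(30)
        y = rng.binomial(1, 0.5, len(df))
        model = fit_effect_model(Xt, y, C=1.0, seed=0)
        mean_patient = pd.DataFrame(
            {c: [df[c].mean() if c not in spec.passthrough else 0.0] for c in df.columns}
        )
        out = predict_prognosis(mean_patient, spec, {"y": model})
        assert out.iloc[0]["p_y"] == pytest.approx(expit(model.intercept), abs=1e-12)

    def test_missing_predictor_column_raises(self):
        df = random_design(seed=31)
        _, spec = preprocess(df)
        with pytest.raises(ModelError, match="duration"):
            predict_prognosis(df.drop(columns=["duration"]), spec, {})

    def test_predicted_risk_ranks_time_to_contraction(self):
        from scipy.stats import kendalltau

        from facesym.simulate import CohortGeneratorConfig, generate_cohort

        cohort = generate_cohort(
            CohortGeneratorConfig(n=500, seed=77), with_faces=False
        )
        truth = cohort.truth.patients
        X_raw = truth[["age", "female", "duration", "cause_trauma", "preop_fngs_grade"]]
        Xt, spec = preprocess(X_raw)
        res = fit_time_to_contraction(
            Xt, truth["event_time"], np.ones(len(truth), dtype=bool)
        )
        pred = predict_prognosis(X_raw, spec, {}, cox_coefficients=res.summary["log_hr"])
        tau = kendalltau(pred["cox_risk_score"], truth["lp_cox"]).statistic
        assert tau > 0.3


class TestImportanceTable:
    def test_table_shape_and_bounds(self):
        rng = np.random.default_rng(40)
        df = random_design(n=120, seed=40)
        Xt, _ = preprocess(df)
        outcomes = pd.DataFrame(
            {
                "index_a": rng.normal(size=120),
                "index_b": rng.binomial(1, 0.5, 120),
            }
        )
        coefs, importance, models = fit_importance_table(Xt, outcomes, C=1.0, seed=0)
        assert list(importance.index) == ["index_a", "index_b"]
        assert list(importance.columns) == list(df.columns)
        assert ((importance >= 0) & (importance <= 100)).all().all()
        for name in coefs.index:
            if (coefs.loc[name] != 0).any():
                assert importance.loc[name].max() == pytest.approx(100.0)

    def test_threshold_dichotomization_rule(self):
        s = pd.Series([1.0, 2.9, 3.0, 5.05])
        np.testing.assert_array_equal(dichotomize(s, 3.0), [0, 0, 1, 1])
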