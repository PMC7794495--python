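import numpy as np
import pandas as pd
import pytest

from owlfam import model_selection as ms


def stub_model(name, loglik, k, n):
    """FittedModel carrying only the AICc bookkeeping fields."""
    est = pd.Series([0.0], index=["Intercept"])
    vc = pd.DataFrame([[1.0]], index=["Intercept"], columns=["Intercept"])
    return ms.FittedModel(name, "gaussian", "identity", False, (), loglik,
                          k, n, est, vc)


class TestAicc:
    def test_direct_arithmetic(self):
        assert ms.aicc(-100, 3, 10) == pytest.approx(210.0)

    def test_large_n_limit_is_aic(self):
        assert ms.aicc(-50, 4, 10**9) == pytest.approx(108.0, abs=1e-5)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ms.aicc(-10, 5, 6)

    def test_two_parameter_null_near_study_scale(self):
        # -2*(-1065.03) + 4 = 2134.06 plus a vanishing correction at large n
        assert ms.aicc(-1065.03, 2, 5776) == pytest.approx(2134.06, abs=0.01)


class TestFitGlm:
    def test_binomial_intercept_only_closed_form(self):
        y = np.array([1.0] * 7 + [0.0] * 3)
        X = pd.DataFrame({"Intercept": np.ones(10)})
        fm = ms.fit_glm(y, X, "binomial")
        assert fm.estimate("Intercept") == pytest.approx(np.log(0.7 / 0.3),
                                                         abs=1e-6)

    def test_poisson_intercept_only_mean_matching(self):
        fm = ms.fit_glm(np.array([2.0, 2, 2]),
                        pd.DataFrame({"I": np.ones(3)}), "poisson")
        assert fm.estimate("I") == pytest.approx(np.log(2), abs=1e-8)

    def test_zip_all_zero_data_degenerates_to_loglik_zero(self):
        fm = ms.fit_glm(np.zeros(12), pd.DataFrame({"I": np.ones(12)}),
                        "poisson", zero_inflated=True)
        assert fm.loglik == 0.0
        assert fm.extra["zero_inflation_prob"] == 1.0

    def test_zip_recovers_inflation_mass(self):
        rng = np.random.default_rng(3)
        zero = rng.random(2000) < 0.3
        y = np.where(zero, 0, rng.poisson(3.0, 2000)).astype(float)
        fm = ms.fit_glm(y, pd.DataFrame({"I": np.ones(2000)}), "poisson",
                        zero_inflated=True)
        # structural zeros plus Poisson zeros; pi is the structural part
        assert fm.extra["zero_inflation_prob"] == pytest.approx(0.3, abs=0.05)
        assert fm.k == 2

    def test_negative_binomial_counts_dispersion_in_k(self):
        rng = np.random.default_rng(4)
        y = rng.negative_binomial(2, 0.4, 500).astype(float)
        fm = ms.fit_glm(y, pd.DataFrame({"I": np.ones(500)}),
                        "negative_binomial")
        assert fm.k == 2
        assert fm.estimate("I") == pytest.approx(np.log(y.mean()), abs=0.05)

    def test_rank_deficient_design_rejected(self):
        X = pd.DataFrame({"a": np.ones(10), "b": np.ones(10)})
        with pytest.raises(ms.ConvergenceError):
            ms.fit_glm(np.zeros(10), X, "gaussian")


class TestFitRandomIntercept:
    def test_zero_between_group_variance_matches_glm(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=600)
        y = rng.poisson(np.exp(0.2 + 0.5 * x)).astype(float)
        X = pd.DataFrame({"Intercept": np.ones(600), "x": x})
        g = np.repeat(np.arange(30), 20)
        fm_mixed = ms.fit_random_intercept(y, X, "poisson", {"grp": g})
        fm_glm = ms.fit_glm(y, X, "poisson")
        assert fm_mixed.estimate("x") == pytest.approx(fm_glm.estimate("x"),
                                                       abs=0.02)
        assert fm_mixed.extra["sigma_grp"] < 0.1

    def test_poisson_random_intercept_sd_recovery(self):
        rng = np.random.default_rng(1)
        g = np.repeat(np.arange(50), 50)
        u = rng.normal(0, 0.5, 50)
        y = rng.poisson(np.exp(0.3 + u[g])).astype(float)
        X = pd.DataFrame({"Intercept": np.ones(2500)})
        fm = ms.fit_random_intercept(y, X, "poisson", {"grp": g})
        assert fm.extra["sigma_grp"] == pytest.approx(0.5, abs=0.15)
        assert fm.k == 2  # intercept + variance component

    def test_single_group_rejected(self):
        X = pd.DataFrame({"I": np.ones(10)})
        with pytest.raises(ValueError):
            ms.fit_random_intercept(np.zeros(10), X, "gaussian",
                                    {"g": np.zeros(10)})

    def test_crossed_gaussian_matches_lme4_oracle(self):
        # independent oracle: lme4::lmer ML fit on the same small dataset
        rng = np.random.default_rng(7)
        a = np.repeat(np.arange(8), 12)
        b = np.tile(np.arange(12), 8)
        y = 1.0 + rng.normal(0, 0.4, 8)[a] + rng.normal(0, 0.3, 12)[b] \
            + rng.normal(0, 0.5, 96)
        X = pd.DataFrame({"Intercept": np.ones(96)})
        fm = ms.fit_random_intercept(y, X, "gaussian", {"a": a, "b": b})
        import subprocess, tempfile, json, textwrap, os
        with tempfile.TemporaryDirectory() as td:
            pd.DataFrame({"y": y, "a": a, "b": b}).to_csv(
                os.path.join(td, "d.csv"), index=False)
            script = textwrap.dedent(f"""
                suppressMessages(library(lme4))
                d <- read.csv('{td}/d.csv')
                m <- lmer(y ~ 1 + (1|a) + (1|b), data=d, REML=FALSE)
                cat(jsonlite::toJSON(list(
                  beta=unname(fixef(m)), ll=as.numeric(logLik(m)))))
            """)
            out = subprocess.run(["Rscript", "-e", script],
                                 capture_output=True, text=True)
            ref = json.loads(out.stdout)
        assert fm.estimate("Intercept") == pytest.approx(ref["beta"][0],
                                                         abs=1e-3)
        assert fm.loglik == pytest.approx(ref["ll"][0], abs=0.05)


class TestModelSet:
    def test_single_model(self):
        s = ms.build_model_set([stub_model("only", -10, 2, 100)])
        assert s.table["delta"].iloc[0] == 0.0
        assert s.table["weight"].iloc[0] == 1.0

    def test_delta_two_weights(self):
        # AICc gap of 2: weights (1/(1+e^-1), e^-1/(1+e^-1)) = (0.731, 0.269)
        models = [stub_model("best", -10, 2, 1000),
                  stub_model("worse", -11, 2, 1000)]
        s = ms.build_model_set(models)
        np.testing.assert_allclose(s.table["weight"], [0.7310586, 0.2689414],
                                   atol=1e-6)

    def test_weights_sum_to_one_and_sorted(self):
        rng = np.random.default_rng(0)
        models = [stub_model(f"m{i}", -100 - 10 * rng.random(), i + 1, 500)
                  for i in range(8)]
        s = ms.build_model_set(models)
        assert s.table["weight"].sum() == pytest.approx(1.0)
        assert s.table["aicc"].is_monotonic_increasing
        assert s.table["delta"].min() == 0.0

    def test_weights_invariant_to_constant_loglik_shift(self):
        base = [(-100, 2), (-98, 3), (-97, 5)]
        s1 = ms.build_model_set([stub_model(f"m{i}", ll, k, 400)
                                 for i, (ll, k) in enumerate(base)])
        s2 = ms.build_model_set([stub_model(f"m{i}", ll + 50, k, 400)
                                 for i, (ll, k) in enumerate(base)])
        np.testing.assert_allclose(s1.table["weight"], s2.table["weight"],
                                   atol=1e-12)

    def test_tie_break_by_name_is_stable(self):
        s = ms.build_model_set([stub_model("zeta", -10, 2, 100),
                                stub_model("alpha", -10, 2, 100)])
        assert s.table["model"].tolist() == ["alpha", "zeta"]

    def test_mixed_n_rejected(self):
        with pytest.raises(ValueError):
            ms.build_model_set([stub_model("a", -10, 2, 100),
                                stub_model("b", -10, 2, 101)])


class TestModelAverage:
    def test_all_weight_on_one_model(self):
        dominant = stub_model("big", -10, 2, 1000)
        dominant.estimates["x"] = 2.5
        dominant.vcov.loc["x", "x"] = 0.04
        dominant.vcov.loc["x", "Intercept"] = 0.0
        dominant.vcov.loc["Intercept", "x"] = 0.0
        minor = stub_model("small", -200, 2, 1000)
        s = ms.build_model_set([dominant, minor])
        (a,) = ms.model_average(s, ["x"])
        assert a.estimate == pytest.approx(2.5, abs=1e-6)

    def test_zero_substitution_equal_weights(self):
        m1 = stub_model("with", -10, 2, 1000)
        m1.estimates["x"] = 1.0
        m1.vcov.loc["x", "x"] = 0.0
        m1.vcov.loc["x", "Intercept"] = 0.0
        m1.vcov.loc["Intercept", "x"] = 0.0
        m2 = stub_model("without", -10, 2, 1000)
        s = ms.build_model_set([m1, m2])
        (a,) = ms.model_average(s, ["x"])
        assert a.estimate == pytest.approx(0.5)
        assert a.ci_low <= a.estimate <= a.ci_high

    def test_unknown_term_rejected(self):
        s = ms.build_model_set([stub_model("a", -10, 2, 100)])
        with pytest.raises(ValueError):
            ms.model_average(s, ["nonexistent"])


class TestFormulaInterface:
    def test_random_term_parsed(self):
        rng = np.random.default_rng(2)
        d = pd.DataFrame({"y": rng.poisson(2.0, 200).astype(float),
                          "year": np.repeat(np.arange(10), 20)})
        fm = ms.fit_formula(d, "y ~ 1 + (1|year)", "poisson")
        assert fm.random_intercept == ("year",)
        assert fm.k == 2

    def test_fixed_only_formula_uses_glm(self):
        rng = np.random.default_rng(2)
        d = pd.DataFrame({"y": (rng.random(100) < 0.4).astype(float),
                          "x": rng.normal(size=100)})
        fm = ms.fit_formula(d, "y ~ x", "binomial")
        assert fm.random_intercept == ()
        assert set(fm.estimates.index) == {"Intercept", "x"}
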