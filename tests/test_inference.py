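import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from foxnets import inference as inf


class TestModelSpec:
    def test_unknown_family(self):
        with pytest.raises(ValueError, match="family"):
            inf.ModelSpec("y", "tweedie", [])

    def test_missing_column_detected(self):
        spec = inf.ModelSpec("y", "gaussian", ["nope"])
        with pytest.raises(ValueError, match="nope"):
            spec.validate_columns(pd.DataFrame({"y": [1.0, 2.0]}))

    def test_formula(self):
        assert inf.ModelSpec("y", "poisson", ["a", "a:b"]).formula == "y ~ a + a:b"
        assert inf.ModelSpec("y", "poisson", []).formula == "y ~ 1"


class TestFitModel:
    def test_poisson_recovery_within_3se(self, rng):
        n = 5000
        winter = rng.random(n) < 0.5
        y = rng.poisson(np.exp(np.log(0.2) + 0.5 * winter))
        df = pd.DataFrame({"y": y, "season": np.where(winter, "winter", "spring")})
        fit = inf.fit_model(inf.ModelSpec("y", "poisson", ["season"]), df)
        for name, truth in (("Intercept", math.log(0.2)),
                            ("season[T.winter]", 0.5)):
            assert abs(fit.params[name] - truth) < 3 * fit.bse[name]
        assert fit.converged

    def test_poisson_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 400
        x = rng.normal(size=n)
        y = rng.poisson(np.exp(0.3 + 0.4 * x))
        df = pd.DataFrame({"y": y, "x": x})
        fit = inf.fit_model(inf.ModelSpec("y", "poisson", ["x"]), df)
        ref = sm.GLM(y, sm.add_constant(x), family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.bse.to_numpy(), ref.bse, atol=1e-5)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_gaussian_matches_ols(self, rng):
        import statsmodels.api as sm

        n = 200
        x = rng.normal(size=n)
        y = 1.0 + 2.0 * x + rng.normal(size=n)
        df = pd.DataFrame({"y": y, "x": x})
        fit = inf.fit_model(inf.ModelSpec("y", "gaussian", ["x"]), df)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params, atol=1e-10)
        np.testing.assert_allclose(fit.bse.to_numpy(), ref.bse, atol=1e-8)

    def test_single_group_equals_ols(self, rng):
        # degenerate mixed model: one grouping level -> OLS fixed effects
        n = 150
        x = rng.normal(size=n)
        y = 0.5 + 1.5 * x + rng.normal(size=n)
        df = pd.DataFrame({"y": y, "x": x, "grp": "g0"})
        mixed = inf.fit_model(inf.ModelSpec("y", "gaussian", ["x"], ["grp"]), df)
        ols = inf.fit_model(inf.ModelSpec("y", "gaussian", ["x"]), df)
        np.testing.assert_allclose(mixed.params.to_numpy(), ols.params.to_numpy(),
                                   atol=1e-4)

    def test_zero_variance_grouping_factor(self, rng):
        n = 300
        g = rng.integers(0, 10, size=n).astype(str)
        y = 2.0 + rng.normal(size=n)  # no group effect at all
        df = pd.DataFrame({"y": y, "grp": g})
        fit = inf.fit_model(inf.ModelSpec("y", "gaussian", [], ["grp"]), df)
        assert fit.vc["grp"] < 0.05

    def test_mixed_gaussian_recovers_variance(self, rng):
        g = np.repeat(np.arange(40), 8)
        y = rng.normal(scale=1.5, size=40)[g] + rng.normal(size=320)
        df = pd.DataFrame({"y": y, "grp": g.astype(str)})
        fit = inf.fit_model(inf.ModelSpec("y", "gaussian", [], ["grp"]), df)
        assert fit.vc["grp"] == pytest.approx(1.5 ** 2, rel=0.5)

    def test_mixed_poisson_laplace_recovery(self, rng):
        g = np.repeat(np.arange(40), 25)
        x = rng.choice([0.0, 1.0], size=1000)
        y = rng.poisson(np.exp(0.2 + 0.5 * x + rng.normal(scale=0.4, size=40)[g]))
        df = pd.DataFrame({"y": y, "x": x, "grp": g.astype(str)})
        fit = inf.fit_model(inf.ModelSpec("y", "poisson", ["x"], ["grp"]), df)
        assert fit.params["x"] == pytest.approx(0.5, abs=0.15)
        assert fit.vc["grp"] > 0.0

    def test_lognormal_transform_path(self, rng):
        y = rng.uniform(0, 5, size=100)
        df = pd.DataFrame({"y": y})
        fit = inf.fit_model(inf.ModelSpec("y", "lognormal", []), df)
        assert fit.params["Intercept"] == pytest.approx(np.log10(y + 1).mean())


class TestStepwiseReduce:
    def test_noise_removed_signal_kept(self, rng):
        n = 1500
        sex = rng.choice(["F", "M"], n)
        season = rng.choice(["spring", "winter"], n)
        noise = rng.normal(size=n)
        y = rng.poisson(np.exp(-0.5 + 0.6 * ((sex == "M") & (season == "winter"))))
        df = pd.DataFrame({"y": y, "sex": sex, "season": season, "noise": noise})
        spec = inf.ModelSpec("y", "poisson", ["sex * season", "noise"])
        red, hist = inf.stepwise_reduce(spec, df)
        assert "noise" not in red.fixed_effects
        assert "sex * season" in red.fixed_effects

    def test_empty_floor_is_intercept_only(self, rng):
        df = pd.DataFrame({"y": rng.poisson(1.0, 400),
                           "x": rng.normal(size=400)})
        red, _ = inf.stepwise_reduce(inf.ModelSpec("y", "poisson", ["x"]), df)
        assert red.fixed_effects == []

    def test_marginality_respected(self, rng):
        # a main effect under a retained interaction is never removable
        n = 2000
        a = rng.choice(["x", "y"], n)
        b = rng.choice(["u", "v"], n)
        y = rng.poisson(np.exp(0.8 * ((a == "y") & (b == "v"))))
        df = pd.DataFrame({"y": y, "a": a, "b": b})
        spec = inf.ModelSpec("y", "poisson", ["a", "b", "a:b"])
        red, _ = inf.stepwise_reduce(spec, df)
        assert "a:b" in red.fixed_effects
        assert {"a", "b"} <= set(red.fixed_effects)


class TestSidakAndTukey:
    def test_identity_for_single_test(self):
        np.testing.assert_allclose(inf.sidak_adjust([0.03], m=1), [0.03])

    def test_closed_form(self):
        assert inf.sidak_adjust([0.01], m=6)[0] == pytest.approx(1 - 0.99 ** 6)

    def test_pairwise_grid(self, rng):
        n = 2500
        sex = rng.choice(["F", "M"], n)
        season = rng.choice(["spring", "summer", "autumn", "winter"], n)
        y = rng.poisson(np.exp(-1.0 - 0.6 * ((sex == "M") & (season == "winter"))))
        df = pd.DataFrame({"y": y, "sex": sex, "season": season})
        fit = inf.fit_model(inf.ModelSpec("y", "poisson", ["sex * season"]), df)
        tc = inf.tukey_contrasts(fit, df, ["sex", "season"])
        sex_fams = tc[tc["factor"] == "sex"]
        assert len(sex_fams) == 4  # F-M within each season
        season_fams = tc[tc["factor"] == "season"]
        assert len(season_fams) == 2 * 6  # 6 season pairs within each sex
        winter = sex_fams[sex_fams["within"].str.contains("winter")]
        assert winter["estimate"].iloc[0] > 0  # F - M positive in winter
        assert (tc["p_sidak"] >= tc["p"] - 1e-12).all()


class TestHurdle:
    @staticmethod
    def _simulate(rng, n=1500, pi_pos=0.3, mu=200.0, alpha=0.5, beta_bm=0.8):
        bm = rng.random(n) < 0.5
        from scipy.special import logit
        eta_z = logit(pi_pos) + 1.0 * bm
        pos = rng.random(n) < 1 / (1 + np.exp(-eta_z))
        mu_i = mu * np.exp(beta_bm * bm)
        k = 1 / alpha
        y = np.zeros(n, dtype=int)
        for i in np.nonzero(pos)[0]:
            while True:
                v = rng.negative_binomial(k, k / (k + mu_i[i]))
                if v > 0:
                    break
            y[i] = v
        return pd.DataFrame({"duration_s": y, "before_midnight": bm,
                             "dyad": rng.choice([f"d{j}" for j in range(40)], n)})

    def test_recovery_within_3se(self, rng):
        df = self._simulate(rng)
        res = inf.fit_hurdle_duration(df, fixed_effects=["before_midnight"],
                                      random_effect=None)
        z = res.zero_part
        assert abs(z.params["before_midnight[T.True]"] - 1.0) < 3 * z.bse["before_midnight[T.True]"]
        p = res.positive_part
        assert abs(p.params["before_midnight[T.True]"] - 0.8) < 3 * p.bse["before_midnight[T.True]"]
        assert abs(p.params["Intercept"] - math.log(200)) < 3 * p.bse["Intercept"]

    def test_predicted_mean_matches_simulation(self, rng):
        df = self._simulate(rng, n=4000)
        res = inf.fit_hurdle_duration(df, fixed_effects=["before_midnight"],
                                      random_effect=None)
        grid = pd.DataFrame({"before_midnight": [False, True]})
        pred = res.predicted_mean(grid)
        emp = df.groupby("before_midnight")["duration_s"].mean()
        assert pred[0] == pytest.approx(emp[False], rel=0.15)
        assert pred[1] == pytest.approx(emp[True], rel=0.15)

    def test_all_positive_degenerate(self, rng):
        df = pd.DataFrame({"duration_s": rng.integers(1, 100, 50),
                           "before_midnight": rng.random(50) < 0.5})
        res = inf.fit_hurdle_duration(df, fixed_effects=["before_midnight"],
                                      random_effect=None)
        assert res.degenerate == "all_positive"

    def test_all_zero_degenerate(self):
        df = pd.DataFrame({"duration_s": np.zeros(50, dtype=int),
                           "before_midnight": [True, False] * 25})
        res = inf.fit_hurdle_duration(df, fixed_effects=["before_midnight"],
                                      random_effect=None)
        assert res.degenerate == "all_zero"
        assert res.positive_part is None

    def test_non_integer_durations_rejected(self):
        df = pd.DataFrame({"duration_s": [1.5, 2.0], "before_midnight": [True, False]})
        with pytest.raises(ValueError, match="whole seconds"):
            inf.fit_hurdle_duration(df, fixed_effects=["before_midnight"],
                                    random_effect=None)


class TestPredictRates:
    def test_intercept_only_rate(self, rng):
        df = pd.DataFrame({"y": rng.poisson(2.0, 4000), "x": 0.0})
        fit = inf.fit_model(inf.ModelSpec("y", "poisson", []), df)
        pred = inf.predict_rates(fit, pd.DataFrame({"x": [0.0]}))
        assert pred.loc[0, "predicted"] == pytest.approx(2.0, rel=0.05)
        assert pred.loc[0, "ci_low"] < pred.loc[0, "predicted"] < pred.loc[0, "ci_high"]

    def test_monotone_in_positive_coefficient(self, rng):
        df = pd.DataFrame({"x": rng.uniform(0, 10, 2000)})
        df["y"] = rng.poisson(np.exp(-1 + 0.2 * df["x"]))
        fit = inf.fit_model(inf.ModelSpec("y", "poisson", ["x"]), df)
        grid = pd.DataFrame({"x": [10.0, 20.0, 30.0, 40.0]})
        pred = inf.predict_rates(fit, grid)
        assert (np.diff(pred["predicted"]) > 0).all()

    def test_link_roundtrip(self):
        x = np.linspace(-20, 20, 101)
        np.testing.assert_allclose(np.log(np.exp(x)), x, atol=1e-10)

    def test_ci_coverage(self, rng):
        hits = 0
        for _ in range(60):
            df = pd.DataFrame({"y": rng.poisson(1.5, 300), "x": 0.0})
            fit = inf.fit_model(inf.ModelSpec("y", "poisson", []), df)
            pred = inf.predict_rates(fit, pd.DataFrame({"x": [0.0]}))
            hits += pred.loc[0, "ci_low"] <= 1.5 <= pred.loc[0, "ci_high"]
        assert hits >= 50  # ~95% coverage, generous slack


class TestDaysBetweenAssociations:
    @pytest.mark.parametrize("rate,expected", [
        (0.073, 14), (0.037, 27), (0.459, 2), (0.237, 4), (1.0, 1)])
    def test_values(self, rate, expected):
        assert inf.days_between_associations(rate) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            inf.days_between_associations(0.0)
        with pytest.raises(ValueError):
            inf.days_between_associations(-1.0)


class TestICC:
    @staticmethod
    def _simulate(rng, var_ind, var_terr, var_resid, n_ind=150, n_seasons=4,
                  n_terr=40):
        # enough territory levels that the realised territory variance is
        # close to nominal; with few territories the ICC denominator is noisy
        fox = np.repeat(np.arange(n_ind), n_seasons)
        terr = fox % n_terr
        y = (rng.normal(scale=np.sqrt(var_ind), size=n_ind)[fox]
             + rng.normal(scale=np.sqrt(var_terr), size=n_terr)[terr]
             + rng.normal(scale=np.sqrt(var_resid), size=n_ind * n_seasons))
        return pd.DataFrame({"v": y, "fox": fox.astype(str),
                             "territory": terr.astype(str)})

    def test_zero_individual_variance(self, rng):
        df = self._simulate(rng, 0.0, 0.0, 1.0)
        res = inf.icc_repeatability(df, "v")
        assert res.icc == pytest.approx(0.0, abs=0.05)
        assert res.repeatability == "low"

    def test_equal_thirds(self, rng):
        df = self._simulate(rng, 1.0, 1.0, 1.0, n_ind=300)
        res = inf.icc_repeatability(df, "v")
        assert res.icc == pytest.approx(1 / 3, abs=0.08)

    def test_half_share(self, rng):
        df = self._simulate(rng, 2.0, 1.0, 1.0, n_ind=300)
        res = inf.icc_repeatability(df, "v")
        assert res.icc == pytest.approx(0.5, abs=0.08)
        assert res.repeatability == "moderate"

    def test_single_observation_unidentifiable(self):
        df = pd.DataFrame({"v": [1.0, 2.0], "fox": ["a", "b"],
                           "territory": ["t", "t"]})
        with pytest.raises(ValueError, match="single observation"):
            inf.icc_repeatability(df, "v")


class TestNonresidentSexTest:
    def test_extreme_ranking_gives_w_zero(self):
        res = inf.nonresident_sex_test([5, 4, 6, 3, 7, 2, 5], [1, 0, 2, 1, 3, 0, 2])
        assert res["W"] == 0.0
        assert res["r"] < 0
        assert res["p"] < 0.05

    def test_identical_pairs_undefined(self):
        with pytest.raises(ValueError):
            inf.nonresident_sex_test([1, 2, 3], [1, 2, 3])

    def test_matches_exact_enumeration_oracle(self, rng):
        # sign-flip enumeration for n = 8 distinct differences
        d = np.array([3.0, -1.5, 2.2, 4.1, -0.7, 5.3, 1.1, -2.8])
        males = 10 + d
        females = np.full(8, 10.0)
        res = inf.nonresident_sex_test(males, females)
        ranks = stats.rankdata(np.abs(d))
        total = ranks.sum()
        t_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        count = 0
        for signs in itertools.product([0, 1], repeat=8):
            t_plus = sum(r for r, s in zip(ranks, signs) if s)
            if min(t_plus, total - t_plus) <= t_obs:
                count += 1
        p_exact = count / 2 ** 8
        assert res["p"] == pytest.approx(p_exact, abs=1e-10)


class TestCollinearity:
    def test_identical_covariates_flagged(self, rng, caplog):
        import logging

        x = rng.normal(size=80)
        with caplog.at_level(logging.WARNING):
            res = inf.collinearity_check(pd.DataFrame({"a": x, "b": x}))
        assert res["vif"]["a"] == math.inf or res["vif"]["a"] > 1e6

    def test_orthogonal_near_one(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=500), "b": rng.normal(size=500)})
        res = inf.collinearity_check(df)
        assert res["vif"]["a"] == pytest.approx(1.0, abs=0.1)

    def test_matches_statsmodels_vif_oracle(self, rng):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        df = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        df["c"] = df["a"] * 0.7 + df["c"] * 0.3
        res = inf.collinearity_check(df)
        X = np.column_stack([np.ones(200), df.to_numpy()])
        for j, col in enumerate(df.columns):
            ref = variance_inflation_factor(X, j + 1)
            assert res["vif"][col] == pytest.approx(ref, rel=1e-6)

    def test_constant_covariate_undefined(self, rng):
        df = pd.DataFrame({"a": np.ones(50), "b": rng.normal(size=50)})
        res = inf.collinearity_check(df)
        assert math.isinf(res["vif"]["a"])

    def test_single_covariate_rejected(self):
        with pytest.raises(ValueError):
            inf.collinearity_check(pd.DataFrame({"a": [1.0, 2.0]}))


class TestDispersionRatio:
    def test_near_one_for_poisson_data(self, rng):
        df = pd.DataFrame({"y": rng.poisson(2.0, 3000), "x": 0.0})
        fit = inf.fit_model(inf.ModelSpec("y", "poisson", []), df)
        assert inf.dispersion_ratio(fit, df, "y") == pytest.approx(1.0, abs=0.15)
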