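"""GLM fitting, prediction, LOOIC comparison and predictor screening."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from coraldemog import bayes_models as bm
from coraldemog import env_metrics as em


class TestFitValidation:
    def test_interaction_members_must_be_predictors(self):
        with pytest.raises(ValueError, match="interaction"):
            bm.ModelSpec("y", ("a",), (("a", "b"),), "gaussian")

    def test_unknown_family(self):
        with pytest.raises(ValueError, match="family"):
            bm.ModelSpec("y", family="poisson")

    def test_bernoulli_requires_binary(self, quick_mcmc):
        data = pd.DataFrame({"y": [0, 1, 2]})
        with pytest.raises(ValueError, match="\\{0,1\\}"):
            bm.fit_glm(bm.ModelSpec("y", family="bernoulli_logit"), data, quick_mcmc)

    def test_negbin_requires_counts(self, quick_mcmc):
        data = pd.DataFrame({"y": [0.5, 1.0]})
        with pytest.raises(ValueError, match="integer"):
            bm.fit_glm(bm.ModelSpec("y", family="negbin_log"), data, quick_mcmc)

    def test_retained_draw_arithmetic(self):
        s = bm.MCMCSettings(chains=3, iterations=4000, warmup=200, thin=5)
        assert s.retained_per_chain == 760  # (4000 - 200) / 5


class TestConjugateOracle:
    def test_intercept_only_bernoulli_matches_beta_posterior(self, rng):
        """Against the Beta(k+1, n-k+1) conjugate posterior under a flat prior."""
        import arviz as az

        n, p_true = 2000, 0.65
        y = (rng.random(n) < p_true).astype(int)
        k = int(y.sum())
        fit = bm.fit_glm(
            bm.ModelSpec("y", family="bernoulli_logit"),
            pd.DataFrame({"y": y}),
            bm.MCMCSettings(chains=3, iterations=3000, warmup=500, thin=2, seed=3),
            bm.Priors(intercept_scale=20.0),  # effectively flat on the logit
        )
        p_draws = expit(fit.draws["Intercept"])
        beta_mean = (k + 1) / (n + 2)
        ess = float(az.ess(az.convert_to_dataset({"p": p_draws}))["p"].values)
        mc_se = p_draws.std() / np.sqrt(max(ess, 1.0))
        assert abs(p_draws.mean() - beta_mean) < 3 * mc_se + 1e-3

    def test_zero_variance_gaussian_concentrates_at_constant(self, quick_mcmc):
        data = pd.DataFrame({"y": np.full(50, 3.7)})
        with pytest.warns(UserWarning):
            fit = bm.fit_glm(bm.ModelSpec("y", family="gaussian"), data, quick_mcmc)
        assert fit.medians["Intercept"] == pytest.approx(3.7, abs=1e-3)


class TestRecovery:
    def test_negbin_planted_mean_and_dispersion(self, rng, quick_mcmc):
        mu, phi, n = np.exp(3.0), 5.0, 500
        y = rng.negative_binomial(phi, phi / (phi + mu), n)
        fit = bm.fit_glm(bm.ModelSpec("y", family="negbin_log"),
                         pd.DataFrame({"y": y}), quick_mcmc)
        lo, hi = fit.hpd95["Intercept"]
        assert lo <= 3.0 <= hi or abs(fit.medians["Intercept"] - 3.0) < 0.1
        plo, phi_hi = fit.hpd95["phi"]
        assert plo <= 5.0 <= phi_hi
        assert fit.converged

    def test_end_to_end_planted_logistic_recovery(self, quick_mcmc):
        """Planted bleaching intercept/slope recovered from a generated survey."""
        from coraldemog import synth
        from coraldemog.size_structure import preprocess

        slope_true, rate = 0.5, 0.3
        model = synth.solve_size_params(66.42, 0.51, -0.03, n_per_stratum=10_000)
        cond = synth.ConditionModel(
            bleach_intercept=float(logit(rate)), bleach_slope=slope_true,
            logarea_center=model.mean_log, partial_capture_rate=0.0,
        )
        table = synth.generate_colony_table(
            {("Pocillopora", "inshore"): model}, {"Pocillopora": cond},
            synth.SurveyDesign(sites={"A": "inshore"}, surveys=[(2016, 4)]),
            seed=21,
        )
        table = preprocess(table)
        fit = bm.fit_glm(
            bm.ModelSpec("bleached", ("log_area",), family="bernoulli_logit"),
            table,
            bm.MCMCSettings(chains=3, iterations=2000, warmup=400, thin=2, seed=9),
        )
        # map the planted coefficients onto the standardized-predictor scale
        la = table["log_area"].to_numpy()
        m, s = la.mean(), la.std(ddof=0)
        slope_std = slope_true * s
        intercept_std = float(logit(rate)) + slope_true * (m - cond.logarea_center)
        lo, hi = fit.hpd95["log_area"]
        assert lo <= slope_std <= hi
        lo, hi = fit.hpd95["Intercept"]
        assert lo <= intercept_std <= hi


class TestPrediction:
    def _toy_fit(self, intercept_draws, slope_draws):
        spec = bm.ModelSpec("y", ("logArea",), family="bernoulli_logit")
        enc = bm._PredictorEncoding("logArea", "continuous", mean=0.0, sd=1.0,
                                    lo=-5.0, hi=5.0, columns=["logArea"])
        info = bm.DesignInfo({"logArea": enc}, (), ["Intercept", "logArea"])
        draws = {"Intercept": np.asarray(intercept_draws, float).reshape(1, -1),
                 "logArea": np.asarray(slope_draws, float).reshape(1, -1)}
        return bm.FitResult(
            spec=spec, settings=bm.MCMCSettings(), param_names=list(draws),
            draws=draws, medians={}, hpd95={}, rhat={}, bayes_r2=0.0,
            bayes_r2_hpd95=(0.0, 0.0), loo_elpd=0.0, loo_se=0.0, looic=0.0,
            ppc={}, acceptance_rate=1.0, converged=True, design_info=info,
            y=np.array([0.0, 1.0]),
        )

    def test_zero_logit_intercept_gives_half(self):
        fit = self._toy_fit(np.zeros(100), np.zeros(100))
        p, (lo, hi) = bm.predict_probability(fit, {"logArea": 2.0})
        assert p == 0.5 and lo == hi == 0.5

    def test_zero_slope_gives_identical_predictions(self):
        fit = self._toy_fit(np.full(100, 0.3), np.zeros(100))
        p1, _ = bm.predict_probability(fit, {"logArea": -3.0})
        p2, _ = bm.predict_probability(fit, {"logArea": 3.0})
        assert p1 == p2

    def test_unknown_level_rejected(self, rng, quick_mcmc):
        data = pd.DataFrame({
            "y": rng.integers(0, 2, 60),
            "taxa": rng.choice(["Acropora", "Pocillopora"], 60),
        })
        fit = bm.fit_glm(bm.ModelSpec("y", ("taxa",), family="bernoulli_logit"),
                         data, quick_mcmc)
        with pytest.raises(ValueError, match="unknown level"):
            bm.predict_probability(fit, {"taxa": "Porites"})

    def test_extrapolation_warns(self, rng, quick_mcmc):
        data = pd.DataFrame({"y": rng.integers(0, 2, 80),
                             "x": rng.normal(0, 1, 80)})
        fit = bm.fit_glm(bm.ModelSpec("y", ("x",), family="bernoulli_logit"),
                         data, quick_mcmc)
        with pytest.warns(UserWarning, match="extrapolation"):
            bm.predict_probability(fit, {"x": 50.0})


class TestComparison:
    def test_weight_ratio_for_delta_two(self):
        w = bm.weights_from_looic([100.0, 102.0])
        assert w[0] / w[1] == pytest.approx(np.e)
        assert w.sum() == pytest.approx(1.0)

    def test_permutation_equivariance(self):
        looic = [210.0, 205.5, 230.0]
        w = bm.weights_from_looic(looic)
        w_perm = bm.weights_from_looic(looic[::-1])
        assert np.allclose(w, w_perm[::-1])

    def test_identical_models_split_weight(self, rng, quick_mcmc):
        data = pd.DataFrame({"y": rng.normal(0, 1, 100)})
        fit = bm.fit_glm(bm.ModelSpec("y", family="gaussian", name="m"),
                         data, quick_mcmc)
        comp = bm.compare_models([fit, fit])
        assert comp.weights == pytest.approx((0.5, 0.5))

    def test_true_predictor_dominates(self, rng, quick_mcmc):
        n = 200
        x = rng.normal(0, 1, n)
        y = 2.0 * x + rng.normal(0, 0.5, n)
        data = pd.DataFrame({"y": y, "x": x})
        fits, comp = bm.fit_model_set(
            [bm.ModelSpec("y", family="gaussian", name="null"),
             bm.ModelSpec("y", ("x",), family="gaussian", name="slope")],
            data, quick_mcmc,
        )
        assert comp.best == "slope"
        assert dict(zip(comp.names, comp.weights))["slope"] > 0.9

    def test_mismatched_responses_rejected(self, rng, quick_mcmc):
        d1 = pd.DataFrame({"y": rng.normal(0, 1, 50)})
        d2 = pd.DataFrame({"y": rng.normal(0, 1, 50)})
        f1 = bm.fit_glm(bm.ModelSpec("y", family="gaussian"), d1, quick_mcmc)
        f2 = bm.fit_glm(bm.ModelSpec("y", family="gaussian"), d2, quick_mcmc)
        with pytest.raises(ValueError, match="same response"):
            bm.compare_models([f1, f2])


class TestCollinearityScreen:
    def test_duplicated_column_dropped(self, rng):
        x = rng.normal(0, 1, 100)
        table = pd.DataFrame({"SST_mean": x, "Chla_mean": rng.normal(0, 1, 100),
                              "DHW0": x})
        res = bm.collinearity_screen(table)
        assert ("SST_mean" in res.retained) ^ ("DHW0" in res.retained)
        assert "Chla_mean" in res.retained

    def test_independent_predictors_all_retained(self, rng):
        table = pd.DataFrame(rng.normal(0, 1, (10_000, 4)),
                             columns=["SST_mean", "Chla_mean", "DHW0", "DCW1"])
        res = bm.collinearity_screen(table)
        assert set(res.retained) == set(table.columns)

    def test_constant_predictor_flagged(self, rng):
        table = pd.DataFrame({"SST_mean": rng.normal(0, 1, 50),
                              "DHW0": rng.normal(0, 1, 50),
                              "DCW1": np.full(50, 2.0)})
        res = bm.collinearity_screen(table)
        assert res.constant == ("DCW1",)
        assert "DCW1" in res.dropped

    def test_dcw_variants_collinear_and_dcw1_kept(self, rng):
        """The two cold-stress metrics from one SST record are near-collinear."""
        idx = pd.date_range("2010-01-01", "2013-12-31", freq="D")
        sst = pd.Series(
            22.0 + 3.0 * np.cos(2 * np.pi * idx.dayofyear / 365.25)
            + rng.normal(0, 0.4, len(idx)),
            index=idx, name="s",
        )
        clim = em.compute_climatology(sst)
        stress = em.build_stress_series(sst, clim).frame.dropna()
        table = pd.DataFrame({
            "DCW0": -stress["dcw0"].to_numpy(),
            "DCW1": -stress["dcw1"].to_numpy(),
            "SST_mean": rng.normal(0, 1, len(stress)),
        })
        res = bm.collinearity_screen(table)
        assert abs(res.correlations.loc["DCW0", "DCW1"]) > 0.8
        assert "DCW1" in res.retained
        assert "DCW0" not in res.retained


class TestSmallCoralModels:
    def test_model_set_size(self):
        specs = bm.small_coral_model_set(("SST_mean", "Chla_mean", "DHW0", "DCW1"))
        assert len(specs) == 16  # 15 non-empty subsets + intercept-only
        assert all(s.family == "negbin_log" for s in specs)
        specs2 = bm.small_coral_model_set(("SST_mean", "DHW0"))
        assert len(specs2) == 4

    def test_empty_join_rejected(self):
        colonies = pd.DataFrame({
            "genus": ["Acropora"], "site": ["A"], "year": [2010],
            "size_class": ["small"],
        })
        env = pd.DataFrame({"site": ["B"], "year": [2016], "sst_mean": [22.0],
                            "chla_mean": [0.5], "dhw0_max": [1.0],
                            "dcw1_maxmag": [2.0]})
        with pytest.raises(ValueError, match="no overlapping"):
            bm.small_coral_table(colonies, env, "Acropora")

    def test_join_counts_small_per_site_year(self):
        colonies = pd.DataFrame({
            "genus": ["Acropora"] * 5,
            "site": ["A", "A", "A", "B", "B"],
            "year": [2010, 2010, 2010, 2010, 2010],
            "size_class": ["small", "small", "large", "medium", "small"],
        })
        env = pd.DataFrame({"site": ["A", "B"], "year": [2010, 2010],
                            "sst_mean": [22.0, 23.0], "chla_mean": [0.5, 0.4],
                            "dhw0_max": [1.0, 2.0], "dcw1_maxmag": [2.0, 1.0]})
        out = bm.small_coral_table(colonies, env, "Acropora")
        counts = out.set_index("site")["n_small"]
        assert counts["A"] == 2 and counts["B"] == 1
        assert {"SST_mean", "Chla_mean", "DHW0", "DCW1"} <= set(out.columns)

    @pytest.mark.parametrize(
        "planted, expect_in_best",
        [
            ({"Chla_mean": 1.0}, ("Chla_mean",)),
            ({"DHW0": -0.9, "DCW1": -0.9}, ("DHW0", "DCW1")),
        ],
        ids=["chla-driven", "thermal-stress-driven"],
    )
    def test_generative_driver_recovery(self, planted, expect_in_best,
                                        rng, quick_mcmc):
        n = 48
        table = pd.DataFrame(rng.normal(0, 1, (n, 4)),
                             columns=["SST_mean", "Chla_mean", "DHW0", "DCW1"])
        eta = 2.5 + sum(c * table[k].to_numpy() for k, c in planted.items())
        mu = np.exp(eta)
        phi = 10.0
        table["n_small"] = rng.negative_binomial(phi, phi / (phi + mu))
        specs = bm.small_coral_model_set()
        fits, comp = bm.fit_model_set(specs, table, quick_mcmc, force=True)
        best = fits[comp.best]
        for pred in expect_in_best:
            assert pred in best.spec.predictors
            median = best.medians[pred]
            assert np.sign(median) == np.sign(planted[pred])
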