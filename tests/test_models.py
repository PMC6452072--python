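"""Quasi-GLM machinery against independent likelihood oracles; AICc; distances."""

import numpy as np
import pandas as pd
import pytest
import scipy.optimize
import scipy.stats

from polliscape.io import PlantRecord, ValidationError, standardize_reproduction
from polliscape.models import (
    aicc_selection,
    distance_similarity,
    fit_quasi_glm,
    haversine_km,
    landuse_comparisons,
    reproduction_models,
)


def _design(x):
    return pd.DataFrame({"intercept": np.ones(len(x)), "x": np.asarray(x, float)})


class TestFitQuasiGlm:
    def test_intercept_only_quasipoisson_matches_log_mean(self):
        y = np.array([2.0, 4.0, 6.0])
        fit = fit_quasi_glm(y, pd.DataFrame({"intercept": np.ones(3)}), "quasipoisson_log")
        assert fit.coefficients["intercept"] == pytest.approx(np.log(4.0))

    def test_quasipoisson_point_estimates_equal_poisson_mle(self):
        """The quasi fit solves the same score equations as Poisson ML."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = rng.poisson(np.exp(0.5 + 0.8 * x) * rng.gamma(2, 0.5, 30))
        fit = fit_quasi_glm(y, _design(x), "quasipoisson_log")

        def nll(beta):
            eta = beta[0] + beta[1] * x
            return np.sum(np.exp(eta) - y * eta)

        mle = scipy.optimize.minimize(nll, [0.0, 0.0], method="BFGS").x
        assert fit.coefficients["intercept"] == pytest.approx(mle[0], abs=1e-5)
        assert fit.coefficients["x"] == pytest.approx(mle[1], abs=1e-5)

    def test_weighted_gaussian_matches_normal_equations(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 2.9, 5.2, 6.8, 9.1, 11.2])
        w = np.array([1.0, 2.0, 0.5, 1.5, 1.0, 3.0])
        fit = fit_quasi_glm(y, _design(x), "gaussian_identity", weights=w)
        X = np.column_stack([np.ones(6), x])
        beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
        assert fit.coefficients["intercept"] == pytest.approx(beta[0])
        assert fit.coefficients["x"] == pytest.approx(beta[1])

    def test_quasibinomial_matches_likelihood_maximizer(self):
        x = np.array([-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0])
        y = np.array([0.1, 0.2, 0.35, 0.5, 0.6, 0.75, 0.9])
        fit = fit_quasi_glm(y, _design(x), "quasibinomial_logit")

        def nll(beta):
            eta = beta[0] + beta[1] * x
            return float(np.sum(np.log1p(np.exp(eta)) - y * eta))

        mle = scipy.optimize.minimize(nll, [0.0, 0.0], method="BFGS").x
        assert fit.coefficients["intercept"] == pytest.approx(mle[0], rel=1e-6, abs=1e-6)
        assert fit.coefficients["x"] == pytest.approx(mle[1], rel=1e-6, abs=1e-6)

    def test_dispersion_scales_standard_errors(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = rng.poisson(np.exp(1.0 + 0.3 * x) * rng.gamma(1.0, 1.0, 40))  # overdispersed
        fit = fit_quasi_glm(y, _design(x), "quasipoisson_log")
        assert fit.dispersion > 1.0
        assert fit.df_resid == 38

    def test_weight_validation(self):
        y = np.array([1.0, 2.0, 3.0])
        X = pd.DataFrame({"intercept": np.ones(3)})
        with pytest.raises(ValidationError):
            fit_quasi_glm(y, X, "gaussian_identity", weights=[0.0, 0.0, 0.0])
        with pytest.raises(ValidationError):
            fit_quasi_glm(y, X, "gaussian_identity", weights=[1.0, -1.0, 1.0])

    def test_needs_more_observations_than_parameters(self):
        with pytest.raises(ValidationError):
            fit_quasi_glm([1.0, 2.0], _design([0.0, 1.0]), "gaussian_identity")


def _plants(site, props, seeds_mean, n_flowers=20):
    out = []
    for i, p in enumerate(props):
        pods = int(round(p * n_flowers))
        seeds = tuple(seeds_mean + (k % 3) - 1 for k in range(pods))  # nonzero spread
        out.append(
            PlantRecord(site, f"{site}_{i}", 3, n_flowers - pods, pods, seeds)
        )
    return out


class TestReproductionModels:
    def test_requires_five_matched_sites(self):
        metrics = pd.DataFrame({"site_id": ["a", "b"], "c": [0.1, 0.2], "d_prime": [0.5, 0.6]})
        plants = _plants("a", [0.4, 0.5], 3) + _plants("b", [0.5, 0.6], 4)
        with pytest.raises(ValidationError):
            reproduction_models(metrics, standardize_reproduction(plants))

    def test_recovers_direction_of_a_strong_gradient(self):
        sites = [f"s{i}" for i in range(8)]
        cvals = np.linspace(0.05, 0.75, 8)
        plants = []
        for s, c in zip(sites, cvals):
            base = 0.2 + 0.6 * c  # reproduction increases with c
            plants += _plants(s, [base - 0.05, base, base + 0.05], 4)
        metrics = pd.DataFrame({"site_id": sites, "c": cvals, "d_prime": 1 - cvals})
        fits = reproduction_models(metrics, standardize_reproduction(plants))
        assert fits["fert_prop~c"].coefficients["c"] > 0
        assert fits["fert_prop~d_prime"].coefficients["d_prime"] < 0
        assert set(fits) == {"fert_prop~c", "fert_prop~d_prime", "seeds~c", "seeds~d_prime"}


class TestLanduseComparisons:
    def test_identical_responses_give_null_f(self):
        df = pd.DataFrame({"land_use": ["a"] * 4 + ["b"] * 4, "y": [5.0] * 8})
        fit = landuse_comparisons(df, {"y": "gaussian_identity"})["y"]
        assert fit.f_stat == pytest.approx(0.0, abs=1e-10)
        assert fit.f_p == pytest.approx(1.0)

    def test_gaussian_factor_model_reproduces_group_means(self):
        df = pd.DataFrame(
            {"land_use": ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
             "y": [1.0, 1.2, 0.8, 3.0, 3.1, 2.9, 5.0, 5.2, 4.8]}
        )
        fit = landuse_comparisons(df, {"y": "gaussian_identity"})["y"]
        means = df.groupby("land_use")["y"].mean()
        assert fit.coefficients["intercept"] == pytest.approx(means["a"])
        assert fit.coefficients["intercept"] + fit.coefficients["land_use[b]"] == pytest.approx(means["b"])
        assert fit.coefficients["intercept"] + fit.coefficients["land_use[c]"] == pytest.approx(means["c"])

    def test_single_land_use_is_an_error(self):
        df = pd.DataFrame({"land_use": ["a"] * 4, "y": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValidationError):
            landuse_comparisons(df, {"y": "gaussian_identity"})

    def test_depressed_group_detected(self):
        """A group with visitation rate halved gets a negative contrast."""
        rng = np.random.default_rng(3)
        recovered = 0
        for _ in range(20):
            y = np.r_[rng.poisson(30, 5), rng.poisson(60, 15)]
            df = pd.DataFrame({"land_use": ["forest"] * 5 + ["other"] * 15, "y": y.astype(float)})
            fit = landuse_comparisons(df, {"y": "quasipoisson_log"})["y"]
            if fit.coefficients["land_use[other]"] > 0:  # forest (baseline) lower
                recovered += 1
        assert recovered >= 19


class TestDistanceSimilarity:
    def test_haversine_closed_form(self):
        assert haversine_km(0.0, 0.0, 1.0, 0.0) == pytest.approx(111.19, abs=0.01)
        assert haversine_km(-17.4, 145.5, -17.4, 145.5) == 0.0

    def test_identical_metrics_give_exact_zero_slope(self):
        df = pd.DataFrame(
            {"site_id": ["a", "b", "c"], "latitude": [0.0, 0.1, 0.2],
             "longitude": [0.0, 0.1, 0.2], "c": [0.4] * 3, "d_prime": [0.2] * 3}
        )
        fits = distance_similarity(df)
        assert fits["c"].coefficients["distance_km"] == pytest.approx(0.0, abs=1e-12)
        assert any("not independent" in n for n in fits["c"].notes)

    def test_missing_coordinates_reported(self):
        df = pd.DataFrame(
            {"site_id": ["a", "b", "c"], "latitude": [0.0, np.nan, 0.2],
             "longitude": [0.0, 0.1, 0.2], "c": [0.1, 0.2, 0.3], "d_prime": [0.1, 0.2, 0.3]}
        )
        with pytest.raises(ValidationError, match="b"):
            distance_similarity(df)


class TestAiccSelection:
    def test_strong_predictor_ranks_first(self):
        rng = np.random.default_rng(4)
        x1 = rng.normal(size=30)
        x2 = rng.normal(size=30)
        y = 2.0 + 3.0 * x1 + rng.normal(scale=0.3, size=30)
        sel = aicc_selection(y, {"x1": x1, "x2": x2})
        assert sel.best == "x1"
        assert not sel.best_is_intercept_only
        tab = sel.table.set_index("model")
        assert tab.loc["intercept_only", "delta_aicc"] > 2.0
        assert sel.suitable_models == ["x1"]

    def test_intercept_guard_on_pure_noise(self):
        """On noise the intercept-only model usually wins and blocks the rest."""
        rng = np.random.default_rng(5)
        wins = 0
        for _ in range(20):
            y = rng.normal(size=20)
            preds = {f"x{i}": rng.normal(size=20) for i in range(2)}
            sel = aicc_selection(y, preds)
            if sel.best_is_intercept_only:
                wins += 1
                assert sel.suitable_models == []
        # P(spurious predictor beats the AICc penalty) ~ 0.1 each, so the
        # guard fires in ~80% of replicates
        assert wins >= 11

    def test_aicc_approaches_aic_for_large_n(self):
        n = 100_000
        rng = np.random.default_rng(6)
        x = rng.normal(size=n)
        y = 1.0 + x + rng.normal(size=n)
        sel = aicc_selection(y, {"x": x})
        import statsmodels.api as sm

        X = pd.DataFrame({"intercept": np.ones(n), "x": x})
        res = sm.OLS(y, X).fit()
        aic = -2 * res.llf + 2 * 3  # k = 2 coefficients + variance
        row = sel.table.set_index("model").loc["x"]
        assert row["aicc"] == pytest.approx(aic, abs=1e-3)

    def test_small_sample_guard(self):
        with pytest.raises(ValidationError):
            aicc_selection(np.array([1.0, 2.0, 3.0, 4.0]), {"x": np.array([1.0, 2.0, 3.0, 4.0])})
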