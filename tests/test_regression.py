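import numpy as np
import pandas as pd
import pytest

from pollinet.regression import (
    delta_meta,
    fit_count_model,
    fit_gaussian_model,
    inverse_distance_weights,
    morans_i,
    resolution_compare,
    subset_select_aic,
    vif_screen,
)


def design(rng, n, p, names=None):
    X = pd.DataFrame(rng.normal(size=(n, p)))
    X.columns = names or [f"x{i}" for i in range(p)]
    return X


class TestVIF:
    def test_orthogonal_predictors_all_retained(self):
        n = 40
        t = np.arange(n)
        X = pd.DataFrame(
            {"a": np.cos(2 * np.pi * t / n), "b": np.sin(2 * np.pi * t / n)}
        )
        kept, dropped = vif_screen(X, cutoff=3.0)
        assert kept == ["a", "b"] and dropped == []

    def test_pairwise_vif_closed_form(self, rng):
        x = rng.normal(size=200)
        y = 0.8 * x + rng.normal(0, 0.6, size=200)
        X = pd.DataFrame({"x": x, "y": y})
        r = np.corrcoef(x, y)[0, 1]
        expected = 1.0 / (1.0 - r**2)
        # force one iteration by using a cutoff below the closed-form VIF
        kept, dropped = vif_screen(X, cutoff=expected - 0.01)
        assert len(dropped) == 1
        assert dropped[0][1] == pytest.approx(expected, rel=1e-6)

    def test_collinear_synthetic_bare_soil_dropped(self, small_dataset):
        """Bare-soil cover is generated collinear with impervious surface,
        so the screen keeps only one of the pair."""
        _, _, _, predictors = small_dataset
        X = predictors[["imperv_100", "bare_soil", "veg_height"]]
        kept, dropped = vif_screen(X, cutoff=3.0)
        assert len(dropped) >= 1
        assert not {"imperv_100", "bare_soil"} <= set(kept)
        assert "veg_height" in kept

    def test_perfect_collinearity_dropped_with_warning(self, rng):
        x = rng.normal(size=50)
        X = pd.DataFrame({"x": x, "twice_x": 2 * x, "z": rng.normal(size=50)})
        with pytest.warns(UserWarning, match="collinear"):
            kept, dropped = vif_screen(X, cutoff=3.0)
        assert dropped and np.isinf(dropped[0][1])


class TestCountModels:
    def test_poisson_slope_recovery(self, rng):
        n = 500
        x = rng.normal(size=n)
        y = rng.poisson(np.exp(1.0 + 0.5 * x))
        res = fit_count_model(y, pd.DataFrame({"x": x}))
        assert res.family == "poisson"
        assert abs(res.params["x"] - 0.5) < 2 * res.bse["x"]

    def test_overdispersion_triggers_negative_binomial(self, rng):
        n = 400
        x = rng.normal(size=n)
        mu = np.exp(1.0 + 0.4 * x)
        k = 0.8  # strong overdispersion
        y = rng.negative_binomial(k, k / (k + mu))
        res = fit_count_model(y, pd.DataFrame({"x": x}))
        assert res.family == "negative_binomial"
        assert res.dispersion > 1.5

    def test_nb_converges_to_poisson_without_overdispersion(self, rng):
        n = 600
        x = rng.normal(size=n)
        y = rng.poisson(np.exp(1.2 + 0.3 * x))
        X = pd.DataFrame({"x": x})
        pois = fit_count_model(y, X)
        forced_nb = fit_count_model(y, X, dispersion_threshold=-1.0)
        assert forced_nb.family == "negative_binomial"
        # ML dispersion is near zero on equidispersed data, so the NB slope
        # sits on top of the Poisson slope
        assert forced_nb.params["x"] == pytest.approx(pois.params["x"], abs=1e-2)

    def test_non_integer_response_rejected(self):
        with pytest.raises(ValueError):
            fit_count_model([1.5, 2.0], pd.DataFrame({"x": [0.0, 1.0]}))

    def test_zero_variance_predictor_rejected_before_fit(self, rng):
        y = rng.poisson(3.0, size=30)
        X = pd.DataFrame({"x": rng.normal(size=30), "flat": np.ones(30)})
        with pytest.warns(UserWarning, match="zero-variance"):
            res = fit_count_model(y, X)
        assert "flat" not in res.predictors


class TestSubsetSelection:
    def test_intercept_only_when_max_terms_zero(self, rng):
        X = design(rng, 50, 3)
        y = rng.poisson(2.0, size=50)
        res = subset_select_aic(y, X, max_terms=0)
        assert res.predictors == []

    def test_number_of_fitted_subsets(self, rng):
        X = design(rng, 80, 6)
        y = rng.normal(size=80)
        res = subset_select_aic(y, X, max_terms=3, family="gaussian")
        # 1 + C(6,1) + C(6,2) + C(6,3) = 42
        assert len(res.ranking) == 42

    def test_true_predictor_selected(self, rng):
        n = 300
        X = design(rng, n, 5)
        y = rng.normal(2.0 + 1.0 * X["x1"], 1.0)
        res = subset_select_aic(y, X, family="gaussian")
        assert "x1" in res.predictors

    def test_noise_predictor_raises_aic_in_expectation(self, rng):
        worse = 0
        for _ in range(60):
            n = 60
            x = rng.normal(size=n)
            noise = rng.normal(size=n)
            y = rng.normal(1.0 + 0.8 * x, 1.0)
            a1 = fit_gaussian_model(y, pd.DataFrame({"x": x})).aic
            a2 = fit_gaussian_model(y, pd.DataFrame({"x": x, "junk": noise})).aic
            worse += a2 > a1
        assert worse > 30  # adding pure noise usually costs AIC


class TestMoransI:
    def test_expected_value_closed_form(self, rng):
        coords = rng.uniform(0, 10, size=(11, 2))
        res = morans_i(rng.normal(size=11), coords)
        assert res.expected == pytest.approx(-1.0 / 10.0)

    def test_linear_gradient_is_positively_autocorrelated(self):
        xy = np.array([[i, j] for i in range(3) for j in range(3)], dtype=float)
        z = xy[:, 0] + xy[:, 1]
        res = morans_i(z, xy)
        assert res.i > 0
        assert res.p < 0.05

    def test_normal_p_close_to_permutation_p(self):
        """The randomisation variance reproduces the permutation variance,
        and the normal-approximation p tracks the Monte-Carlo permutation p
        across small layouts up to the normal-shape error."""
        diffs = []
        for s in range(6):
            rng = np.random.default_rng(300 + s)
            xy = rng.uniform(0, 5, size=(8, 2))
            z = rng.normal(size=8)
            w = inverse_distance_weights(xy)
            res = morans_i(z, xy)
            n, s0 = 8, w.sum()

            def stat(v):
                vc = v - v.mean()
                return (n / s0) * float(vc @ w @ vc) / float(vc @ vc)

            perm = np.array([stat(rng.permutation(z)) for _ in range(20000)])
            assert res.variance == pytest.approx(perm.var(), rel=0.03)
            p_perm = (
                np.abs(perm - res.expected) >= abs(res.i - res.expected)
            ).mean()
            diffs.append(abs(res.p - p_perm))
        assert np.median(diffs) <= 0.04
        assert max(diffs) <= 0.08

    def test_coincident_coordinates_error(self):
        xy = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="coincident"):
            morans_i(np.arange(4.0), xy)


class TestMetaStatistics:
    def test_identical_vectors(self):
        a = np.array([0.1, 0.4, -0.2, 0.3])
        cmp_ = resolution_compare(a, a)
        assert cmp_["r"] == pytest.approx(1.0)
        assert cmp_["t"] == 0.0

    def test_constant_delta_vector_errors(self):
        with pytest.raises(ValueError, match="variance"):
            delta_meta([0.3, 0.3, 0.3, 0.3])

    def test_delta_meta_matches_scipy_power(self, rng):
        """Rejection rate of the one-sample t-test at alpha=0.05 under
        Delta ~ N(0.3, 0.1), n=11, matches direct Monte-Carlo power."""
        n_rep = 400
        rejections = 0
        for _ in range(n_rep):
            x = rng.normal(0.3, 0.1, size=11)
            _, p = delta_meta(x)
            rejections += p < 0.05
        # analytic power at ncp = 0.3/(0.1/sqrt(11)) ~ 10: essentially 1
        assert rejections / n_rep > 0.99
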