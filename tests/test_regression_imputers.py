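import numpy as np
import pandas as pd
import pytest

from impbench.core_data import (
    MixedDataset,
    VariableSchema,
    build_mask,
    check_preservation,
)
from impbench.donor_imputers import ImputationError
from impbench.regression_imputers import (
    bayes_regression_draw,
    irmi_impute,
    midas_kappa,
    midas_probs,
    midastouch_impute,
    pmm_impute,
    robust_fit,
)


def _xy_dataset(x, y):
    schema = [VariableSchema("x", "continuous"), VariableSchema("y", "continuous")]
    return MixedDataset(schema, pd.DataFrame({"x": x, "y": y}))


class TestBayesDraw:
    def test_noise_free_posterior_collapses(self):
        x = np.arange(10.0)[:, None]
        y = 1.0 + 2.0 * x[:, 0]
        draw = bayes_regression_draw(x, y, seed=0)
        assert np.allclose(draw.beta_star, draw.beta_hat)
        assert np.allclose(draw.beta_hat, [1.0, 2.0])

    def test_posterior_mean_centred_on_beta_hat(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((40, 1))
        y = 0.5 + 1.5 * x[:, 0] + rng.normal(0, 0.8, 40)
        ref = bayes_regression_draw(x, y, seed=0)
        draws = np.array(
            [bayes_regression_draw(x, y, seed=s).beta_star for s in range(10_000)]
        )
        # posterior sd of each coefficient estimated from the draws themselves
        mc_se = draws.std(axis=0) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - ref.beta_hat) < 4 * mc_se)

    def test_same_seed_identical(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((20, 2))
        y = x @ [1.0, -1.0] + rng.standard_normal(20)
        a = bayes_regression_draw(x, y, seed=7).beta_star
        b = bayes_regression_draw(x, y, seed=7).beta_star
        assert np.array_equal(a, b)

    def test_rank_deficiency_rejected(self):
        x = np.ones((10, 2))
        with pytest.raises(ImputationError):
            bayes_regression_draw(x, np.arange(10.0), seed=0)


class TestPmm:
    def test_constant_observed_response(self):
        d = _xy_dataset(np.arange(8.0), [5.0] * 6 + [np.nan] * 2)
        s = pmm_impute(d, m=2, k_donors=3, seed=0)
        for comp in s:
            assert (comp.frame["y"] == 5.0).all()

    def test_imputed_values_in_observed_support(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(30)
        y[rng.choice(30, 6, replace=False)] = np.nan
        d = _xy_dataset(rng.standard_normal(30), y)
        support = set(d.frame["y"].dropna())
        for comp in pmm_impute(d, m=3, seed=1):
            assert set(comp.frame["y"]) <= support | set(d.frame["y"].dropna())
            assert check_preservation(d, comp)

    def test_nearest_prediction_donor_oracle_k1(self):
        # noise-free y = 2x: with k_donors=1 the recipient takes the observed y
        # of the donor whose prediction is closest — an exhaustive search
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 2.6])
        y = 2.0 * x
        y[-1] = np.nan
        d = _xy_dataset(x, y)
        s = pmm_impute(d, m=3, k_donors=1, seed=5)
        # predictions are exact (sigma_hat = 0, beta* = beta_hat): donor = x=3
        expected_donor = np.argmin(np.abs(x[:-1] - 2.6))
        for comp in s:
            assert comp.frame.loc[7, "y"] == 2.0 * x[expected_donor]

    def test_multiple_copies_differ_only_in_imputed_cells(self):
        rng = np.random.default_rng(6)
        y = 1 + 0.5 * np.arange(40.0) + rng.standard_normal(40)
        y[rng.choice(40, 10, replace=False)] = np.nan
        d = _xy_dataset(np.arange(40.0), y)
        mask = build_mask(d)
        s = pmm_impute(d, mask, m=4, seed=2)
        obs = ~mask.entries[:, 1]
        a, b = s[0].frame["y"].to_numpy(), s[1].frame["y"].to_numpy()
        assert np.array_equal(a[obs], b[obs])
        assert not np.array_equal(a[~obs], b[~obs])


class TestMidasKappa:
    def test_reference_value_about_ten(self):
        assert round(midas_kappa(0.9, 1e-4)) == 10

    def test_zero_r2(self):
        assert midas_kappa(0.0) == 0.0

    def test_half_r2_closed_form(self):
        assert midas_kappa(0.5, delta=0.0) == pytest.approx(50 ** (3 / 8))

    def test_r2_one_without_delta_rejected(self):
        with pytest.raises(ImputationError):
            midas_kappa(1.0, delta=0.0)


class TestMidasProbs:
    def test_equal_inputs_uniform(self):
        p = midas_probs(np.ones(4), np.ones(4), kappa=2.0)
        assert np.allclose(p, 0.25)

    def test_hand_computed_two_donor_case(self):
        p = midas_probs(np.array([1.0, 2.0]), np.array([1.0, 1.0]), kappa=1.0)
        assert np.allclose(p, [2 / 3, 1 / 3])

    def test_kappa_zero_uses_omegas_only(self):
        p = midas_probs(np.array([1.0, 9.0]), np.array([3.0, 1.0]), kappa=0.0)
        assert np.allclose(p, [0.75, 0.25])

    def test_zero_distance_absorbs_mass(self):
        p = midas_probs(np.array([0.0, 0.0, 1.0]), np.ones(3), kappa=2.0)
        assert np.allclose(p, [0.5, 0.5, 0.0])

    def test_sums_to_one_and_scale_invariant(self):
        rng = np.random.default_rng(7)
        d = rng.uniform(0.1, 5.0, 8)
        w = rng.uniform(0.5, 2.0, 8)
        p1 = midas_probs(d, w, kappa=3.3)
        p2 = midas_probs(10.0 * d, w, kappa=3.3)
        assert abs(p1.sum() - 1.0) < 1e-12
        assert np.allclose(p1, p2)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ImputationError):
            midas_probs(np.ones(3), np.zeros(3), kappa=1.0)


class TestMidastouch:
    def test_identical_predictors_reduce_to_weighted_coin_flip(self):
        # all donors share one predictor row: distances equal, so donor choice
        # is driven by bootstrap frequencies alone -> near-uniform on average
        counts = {10.0: 0, 20.0: 0, 30.0: 0}
        for s in range(3000):
            d = _xy_dataset([1.0] * 4, [10.0, 20.0, 30.0, np.nan])
            val = midastouch_impute(d, m=1, seed=s)[0].frame.loc[3, "y"]
            counts[val] += 1
        p = 1 / 3
        se = np.sqrt(p * (1 - p) * 3000)
        for v, c in counts.items():
            assert abs(c - 3000 * p) < 4 * se

    def test_imputed_values_in_observed_support(self):
        rng = np.random.default_rng(8)
        y = np.arange(20.0) + rng.standard_normal(20)
        y[[3, 11, 17]] = np.nan
        d = _xy_dataset(np.arange(20.0), y)
        support = set(d.frame["y"].dropna())
        for comp in midastouch_impute(d, m=3, seed=4):
            assert set(comp.frame["y"].iloc[[3, 11, 17]]) <= support
            assert check_preservation(d, comp)


class TestRobustFit:
    def test_clean_data_equals_least_squares(self):
        x = np.linspace(0, 10, 30)[:, None]
        y = 2.0 + 3.0 * x[:, 0]
        fit = robust_fit(x, y, family="continuous")
        assert np.allclose(fit.coefficients, [2.0, 3.0], atol=1e-8)

    def test_leverage_outliers_downweighted(self):
        rng = np.random.default_rng(9)
        n = 60
        x = np.linspace(0, 10, n)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.3, n)
        x_c, y_c = x.copy(), y.copy()
        bad = rng.choice(n, 6, replace=False)  # 10% gross leverage points
        x_c[bad], y_c[bad] = 30.0, -50.0
        robust = robust_fit(x_c[:, None], y_c, family="continuous")
        ols = robust_fit(x_c[:, None], y_c, family="continuous", robust=False)
        assert abs(robust.coefficients[1] - 2.0) < abs(ols.coefficients[1] - 2.0)

    def test_semicontinuous_two_stage(self):
        rng = np.random.default_rng(10)
        n = 100
        x = rng.standard_normal(n)
        spike = x < -0.25  # ~40% exact zeros, driven by x
        y = np.where(spike, 0.0, 5.0 + 2.0 * x + rng.normal(0, 0.1, n))
        fit = robust_fit(x[:, None], y, family="semicontinuous")
        pred = fit.predict(np.array([[-2.0], [2.0]]))
        assert pred[0] == 0.0
        assert pred[1] == pytest.approx(9.0, abs=0.5)

    def test_binary_fit_predicts_classes(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((80, 1))
        y = np.where(x[:, 0] > 0, "1", "0")
        fit = robust_fit(x, y, family="binary")
        assert list(fit.predict(np.array([[3.0], [-3.0]]))) == ["1", "0"]

    def test_count_fit_positive_predictions(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0, 2, 60)
        y = rng.poisson(np.exp(0.5 + 0.7 * x))
        fit = robust_fit(x[:, None], y.astype(float), family="count")
        assert (fit.predict(np.array([[0.0], [2.0]])) > 0).all()


class TestIrmi:
    def test_no_missing_returns_input(self, correlated_gaussian):
        s = irmi_impute(correlated_gaussian, seed=0)
        assert s.diagnostics.iterations == 0 and s.diagnostics.converged
        pd.testing.assert_frame_equal(s[0].frame, correlated_gaussian.frame)

    def test_exact_linear_recovery_noise_free(self):
        x = np.linspace(0, 5, 30)
        y = 1.0 + 2.0 * x
        d = _xy_dataset(x, y)
        truth = y.copy()
        miss = np.arange(0, 30, 5)  # 20% of y missing
        d.frame.loc[miss, "y"] = np.nan
        d = MixedDataset(d.schema, d.frame)
        s = irmi_impute(d, seed=1, noise=False)
        assert np.allclose(s[0].frame["y"].to_numpy()[miss], truth[miss], atol=1e-6)

    def test_leverage_outliers_barely_disturb_robust_variant(self):
        # criterion: with gross leverage rows the robust IRMI's max error stays
        # within 10x the clean-case error; the OLS variant exceeds that bound
        x = np.linspace(0, 5, 40)
        y = 1.0 + 2.0 * x
        miss = np.arange(1, 40, 8)
        clean = _xy_dataset(x, y)
        clean.frame.loc[miss, "y"] = np.nan
        clean = MixedDataset(clean.schema, clean.frame)
        err_clean = np.max(np.abs(
            irmi_impute(clean, seed=2, noise=False)[0].frame["y"].to_numpy()[miss]
            - y[miss]
        ))
        x_c, y_c = x.copy(), y.copy()
        out_rows = np.array([0, 8, 16, 24, 32])
        x_c[out_rows], y_c[out_rows] = 20.0, -80.0
        cont = _xy_dataset(x_c, y_c)
        cont.frame.loc[miss, "y"] = np.nan
        cont = MixedDataset(cont.schema, cont.frame)
        err_rob = np.max(np.abs(
            irmi_impute(cont, seed=2, noise=False)[0].frame["y"].to_numpy()[miss]
            - y[miss]
        ))
        err_ols = np.max(np.abs(
            irmi_impute(cont, seed=2, noise=False, robust=False)[0]
            .frame["y"].to_numpy()[miss] - y[miss]
        ))
        bound = 10 * max(err_clean, 1e-6)
        assert err_rob <= bound
        assert err_ols > bound

    def test_multiple_copies_fresh_noise(self):
        rng = np.random.default_rng(13)
        x = np.arange(50.0)
        y = x + rng.standard_normal(50)
        d = _xy_dataset(x, y)
        d.frame.loc[::7, "y"] = np.nan
        d = MixedDataset(d.schema, d.frame)
        mask = build_mask(d)
        s = irmi_impute(d, mask, seed=3, multiple=3)
        assert s.m == 3
        a, b = s[0].frame["y"].to_numpy(), s[1].frame["y"].to_numpy()
        obs = ~mask.entries[:, 1]
        assert np.array_equal(a[obs], b[obs])
        assert not np.array_equal(a[~obs], b[~obs])
        assert check_preservation(d, s[0])

    def test_mixed_scales_complete(self):
        rng = np.random.default_rng(14)
        n = 80
        g = rng.choice(["0", "1"], n)
        x = rng.standard_normal(n) + (g == "1") * 2
        y = 1 + x + rng.normal(0, 0.2, n)
        schema = [
            VariableSchema("g", "binary", categories=("0", "1")),
            VariableSchema("x", "continuous"),
            VariableSchema("y", "continuous"),
        ]
        frame = pd.DataFrame({"g": g, "x": x, "y": y})
        frame.loc[rng.choice(n, 8, replace=False), "g"] = np.nan
        frame.loc[rng.choice(n, 8, replace=False), "y"] = np.nan
        d = MixedDataset(schema, frame)
        s = irmi_impute(d, seed=4)
        assert not s[0].frame.isna().any().any()
        assert check_preservation(d, s[0])

    def test_stepwise_stub_rejected(self, correlated_gaussian):
        with pytest.raises(NotImplementedError):
            irmi_impute(correlated_gaussian, stepwise=True)
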