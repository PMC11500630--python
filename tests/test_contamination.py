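import numpy as np
import pandas as pd
import pytest
from scipy import stats

from impbench.contamination import (
    ContaminationError,
    EnergySimSpec,
    IncomeSimSpec,
    ampute_mar,
    ampute_mcar,
    flag_outliers_mcd,
    inject_leverage_outliers,
    inject_misclassifications,
    simulate_energy,
    simulate_income,
)
from impbench.core_data import MixedDataset, VariableSchema, build_mask


class TestSimulateIncome:
    def test_sample_means_near_population(self):
        spec = IncomeSimSpec()
        d = simulate_income(spec, seed=5)
        se_age = np.sqrt(spec.covariance[0, 0] / spec.n)
        se_inc = np.sqrt(spec.covariance[1, 1] / spec.n)
        assert abs(d.frame["AGE"].mean() - 40) < 4 * se_age
        assert abs(d.frame["INCOME"].mean() - 1500) < 4 * se_inc

    def test_single_row(self):
        d = simulate_income(IncomeSimSpec(n=1), seed=0)
        assert d.n == 1 and np.isfinite(d.frame.to_numpy(dtype=float)).all()

    def test_deterministic_under_seed(self):
        a = simulate_income(seed=9).frame
        b = simulate_income(seed=9).frame
        pd.testing.assert_frame_equal(a, b)

    def test_covariance_readings(self):
        raw = IncomeSimSpec().covariance
        assert np.allclose(raw, [[10, 44], [44, 300]])
        ew = IncomeSimSpec(covariance_reading="elementwise").covariance
        assert np.allclose(ew, [[100, 1936], [1936, 90000]])

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ContaminationError):
            IncomeSimSpec(cross_param=100.0).validate()  # 100^2 > 10*300


class TestInjectLeverageOutliers:
    def test_k_zero_is_identity(self):
        d = simulate_income(seed=1)
        out, flags = inject_leverage_outliers(d, 0, seed=2)
        pd.testing.assert_frame_equal(out.frame, d.frame)
        assert flags.outlier_rows.size == 0

    def test_elementwise_centers(self):
        # under the element-wise covariance reading the four centers are
        # mu +/- 0.8 * diag(Sigma) = (40 +/- 80, 1500 +/- 72000)
        spec = IncomeSimSpec(
            covariance_reading="elementwise",
            outlier_variance_ratio=1e-12,
            outlier_placement="per_outlier",
        )
        d = simulate_income(spec, seed=3)
        out, flags = inject_leverage_outliers(d, 50, spec, seed=4)
        vals = out.frame.iloc[flags.outlier_rows].to_numpy(dtype=float)
        assert np.all(np.min(np.abs(vals[:, [0]] - np.array([[-40.0, 120.0]])), axis=1) < 0.01)
        assert np.all(
            np.min(np.abs(vals[:, [1]] - np.array([[-70500.0, 73500.0]])), axis=1) < 0.01
        )

    def test_untouched_rows_bit_identical(self):
        spec = IncomeSimSpec()
        d = simulate_income(spec, seed=5)
        out, flags = inject_leverage_outliers(d, 80, spec, seed=6)
        assert flags.outlier_rows.size == 80
        clean = np.setdiff1d(np.arange(200), flags.outlier_rows)
        assert np.array_equal(
            out.frame.iloc[clean].to_numpy(dtype=float),
            d.frame.iloc[clean].to_numpy(dtype=float),
        )

    def test_per_replicate_placement_uses_one_corner(self):
        spec = IncomeSimSpec(outlier_variance_ratio=1e-12)
        d = simulate_income(spec, seed=7)
        out, flags = inject_leverage_outliers(d, 30, spec, seed=8)
        vals = np.round(out.frame.iloc[flags.outlier_rows].to_numpy(dtype=float), 3)
        assert len(np.unique(vals, axis=0)) == 1

    def test_k_beyond_n_rejected(self):
        d = simulate_income(IncomeSimSpec(n=10), seed=0)
        with pytest.raises(ContaminationError):
            inject_leverage_outliers(d, 11, IncomeSimSpec(n=10), seed=0)


class TestSimulateEnergy:
    def test_noise_free_closed_forms(self):
        # energy = exp(2 + I(type=1) - 0.1 log runtime): runtime=1 gives e^2 / e^3
        spec = EnergySimSpec(noise_var=0.0, n=500)
        d = simulate_energy(spec, seed=11)
        t = d.frame["type"].to_numpy(dtype=object)
        rt = d.frame["runtime"].to_numpy(dtype=float)
        en = d.frame["energy"].to_numpy(dtype=float)
        expected = np.exp(2 + (t == "1").astype(float) - 0.1 * np.log(rt))
        assert np.allclose(en, expected, rtol=1e-12)
        assert np.isclose(np.exp(2.0), 7.389, atol=5e-4)
        assert np.isclose(np.exp(3.0), 20.086, atol=5e-4)

    def test_mean_log_runtime_matches_closed_form(self):
        # E[log X] for X ~ Exp(rate) is -log(rate) - Euler gamma
        d = simulate_energy(EnergySimSpec(n=100_000), seed=12)
        target = np.log(100) - np.euler_gamma
        mean = np.log(d.frame["runtime"].to_numpy(dtype=float)).mean()
        assert abs(mean - target) < 4 * np.pi / np.sqrt(6 * 100_000)  # 4 MC SE

    def test_group_mean_target_value(self):
        assert np.isclose(EnergySimSpec().true_group_mean_log_energy, 2.5972, atol=1e-4)


class TestInjectMisclassifications:
    def test_k_zero_identity(self):
        d = simulate_energy(seed=1)
        out, flags = inject_misclassifications(d, 0, seed=2)
        pd.testing.assert_frame_equal(out.frame, d.frame)

    def test_flip_all_is_involution(self):
        d = simulate_energy(EnergySimSpec(n=50), seed=3)
        once, _ = inject_misclassifications(d, 50, seed=4)
        twice, _ = inject_misclassifications(once, 50, seed=5)
        assert (once.frame["type"] != d.frame["type"]).all()
        pd.testing.assert_frame_equal(twice.frame, d.frame)

    def test_flags_and_energy_untouched(self):
        d = simulate_energy(seed=6)
        out, flags = inject_misclassifications(d, 40, seed=7)
        assert flags.misclassified_rows.size == 40
        assert np.array_equal(
            out.frame["energy"].to_numpy(dtype=float),
            d.frame["energy"].to_numpy(dtype=float),
        )


class TestFlagOutliersMcd:
    def test_gross_outlier_flagged(self):
        rng = np.random.default_rng(21)
        x = rng.standard_normal((50, 2))
        x = np.vstack([x, [100.0, 100.0]])
        d = MixedDataset(
            [VariableSchema("a", "continuous"), VariableSchema("b", "continuous")],
            pd.DataFrame(x, columns=["a", "b"]),
        )
        res = flag_outliers_mcd(d)
        assert res.flagged[50]
        # sanity: classical distance on the clean part agrees the row is extreme
        clean = x[:50]
        dist = (np.array([100.0, 100.0]) - clean.mean(0)) @ np.linalg.inv(
            np.cov(clean.T)
        ) @ (np.array([100.0, 100.0]) - clean.mean(0))
        assert dist > res.cutoff

    def test_clean_normal_false_flag_rate(self):
        rng = np.random.default_rng(22)
        x = rng.standard_normal((10_000, 2))
        d = MixedDataset(
            [VariableSchema("a", "continuous"), VariableSchema("b", "continuous")],
            pd.DataFrame(x, columns=["a", "b"]),
        )
        res = flag_outliers_mcd(d, prob=0.99, df=2)
        assert abs(res.flagged.mean() - 0.01) < 0.02

    def test_deterministic(self):
        d = simulate_income(seed=23)
        a = flag_outliers_mcd(d)
        b = flag_outliers_mcd(d)
        assert np.array_equal(a.flagged, b.flagged)


class TestAmputeMcar:
    def test_exact_counts(self):
        rng_frame = pd.DataFrame(np.random.default_rng(0).standard_normal((100, 2)),
                                 columns=["a", "b"])
        d = MixedDataset(
            [VariableSchema("a", "continuous"), VariableSchema("b", "continuous")],
            rng_frame,
        )
        _, mask = ampute_mcar(d, 0.1, seed=1)
        assert list(mask.per_column_counts) == [10, 10]

    def test_zero_rate(self, mixed_toy):
        complete = mixed_toy.copy()
        complete.frame = complete.frame.dropna().reset_index(drop=True)
        complete = MixedDataset(complete.schema, complete.frame)
        _, mask = ampute_mcar(complete, 0.0, seed=1)
        assert mask.n_missing == 0

    def test_protected_rows_fully_observed(self):
        d = simulate_income(seed=2)
        protected = np.arange(5)
        out, mask = ampute_mcar(d, 0.3, protected=protected, seed=3)
        assert not mask.entries[protected].any()
        assert not out.frame.iloc[protected].isna().any().any()

    def test_all_protected_with_positive_rate_rejected(self):
        d = simulate_income(IncomeSimSpec(n=5), seed=0)
        with pytest.raises(ContaminationError):
            ampute_mcar(d, 0.5, protected=np.arange(5), seed=0)


class TestAmputeMar:
    def test_exact_count_30_percent(self):
        d = simulate_income(seed=4)
        _, mask = ampute_mar(d, "INCOME", "AGE", 0.3, seed=5)
        assert mask.per_column_counts[1] == 60
        assert mask.per_column_counts[0] == 0

    def test_rank_weighting_targets_high_driver(self):
        d = simulate_income(IncomeSimSpec(n=100), seed=6)
        age = d.frame["AGE"].to_numpy(dtype=float)
        top = np.argsort(age)[-10:]
        bottom = np.argsort(age)[:10]
        hits_top = hits_bottom = 0
        for r in range(2000):
            _, mask = ampute_mar(d, "INCOME", "AGE", 0.3, seed=r)
            hits_top += mask.entries[top, 1].sum()
            hits_bottom += mask.entries[bottom, 1].sum()
        assert hits_top > 2 * hits_bottom

    def test_constant_driver_degrades_to_mcar(self):
        # with equal weights positions should be uniform: chi-square GOF
        n, reps = 20, 2000
        frame = pd.DataFrame({"y": np.arange(n, dtype=float), "c": np.ones(n)})
        d = MixedDataset(
            [VariableSchema("y", "continuous"), VariableSchema("c", "continuous")],
            frame,
        )
        counts = np.zeros(n)
        for r in range(reps):
            _, mask = ampute_mar(d, "y", "c", 0.3, seed=r)
            counts += mask.entries[:, 0]
        expected = counts.sum() / n
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, n - 1) > 0.01

    def test_protected_rows_never_amputed(self):
        d = simulate_income(seed=8)
        prot = np.arange(0, 200, 2)
        _, mask = ampute_mar(d, "INCOME", "AGE", 0.3, protected=prot, seed=9)
        assert not mask.entries[prot].any()
        assert mask.per_column_counts[1] == 30  # 30% of 100 eligible

    def test_driver_must_be_observed(self, mixed_toy):
        with pytest.raises(ContaminationError):
            ampute_mar(mixed_toy, "grp", "x", 0.3, seed=0)
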