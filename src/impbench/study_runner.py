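"""Config-driven simulation harness.

Four studies are provided:

* :func:`run_outlier_study` — the income setting: draw (AGE, INCOME),
  replace k rows by high-leverage outliers, ampute 30% of INCOME under MAR
  on AGE (outlier rows protected), impute, and estimate the mean INCOME of
  the regular rows with a 95% interval (Rubin pooling for multiple
  imputation, t-interval otherwise).  Aggregated per (method, k): bias,
  variance, RMSE and coverage.
* :func:`run_misclassification_study` — the energy setting: simulate
  machines, flip k recorded types, log-transform energy and runtime,
  ampute 30% of log-energy under MAR on log-runtime (misclassified rows
  protected), impute, and estimate the type-1 group mean of log-energy.
* :func:`run_precision_study` — flag outliers by MCD, repeatedly ampute
  10% MCAR per variable (flagged rows protected), impute, and score MAPE /
  NRMSE / MSECOR / FC against the known truth.
* :func:`run_classification_study` — hold-out split, 10% MCAR in the
  training features, impute, train a random-forest classifier, F1 on the
  untouched test set.

Replicate r of every method consumes identical simulated data and masks
(common random numbers), so method contrasts are paired; per-method
imputation seeds are derived from (base_seed, contamination, replicate,
method) via numpy SeedSequence spawn keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .contamination import (
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
from .core_data import (
    CompletedDataset,
    MissingMask,
    MixedDataset,
    VariableSchema,
    build_mask,
)
from .donor_imputers import impute_hotdeck, impute_knn, impute_mean
from .evaluation import (
    ConfusionCounts,
    EstimatorReplicates,
    EvaluationPair,
    coverage_rate,
    estimator_summary,
    f1_accuracy,
    false_classification_rate,
    mape,
    msecor,
    nrmse,
    rubin_pool,
    t_interval,
)
from .regression_imputers import irmi_impute, midastouch_impute, pmm_impute
from .tree_imputers import BoostConfig, ForestConfig, boosted_impute, forest_impute


class StudyError(ValueError):
    pass


@dataclass
class StudyConfig:
    """Declarative description of one simulation grid."""

    setting: str  # income_outliers | energy_misclassification | precision | classification
    methods: list[str]
    contamination_grid: list[int] = field(default_factory=lambda: [0])
    replications: int = 1000
    m: int = 5
    base_seed: int = 0
    level: float = 0.95
    missing_rate: float | None = None  # defaults per setting
    income_spec: IncomeSimSpec = field(default_factory=IncomeSimSpec)
    energy_spec: EnergySimSpec = field(default_factory=EnergySimSpec)
    mar_adjusted_complete_case: bool = False
    forest_trees: int = 50
    boost_rounds: int = 50

    def validate(self) -> None:
        if self.replications < 1:
            raise StudyError("replications must be >= 1")
        if not self.methods:
            raise StudyError("methods must be non-empty")
        if any(k < 0 for k in self.contamination_grid):
            raise StudyError("contamination counts must be >= 0")


@dataclass
class StudyResult:
    """Per-replicate long table plus per-cell aggregates."""

    config: StudyConfig
    replicates: pd.DataFrame
    aggregates: pd.DataFrame
    theta_true: float | None = None


KNOWN_METHODS = (
    "complete_case",
    "mean",
    "median",
    "hotdeck",
    "knn",
    "pmm",
    "midastouch",
    "irmi",
    "irmi_si",
    "irmi_ols",
    "forest",
    "boost",
    "oracle",
)


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def _impute_with(
    method: str,
    data: MixedDataset,
    mask: MissingMask,
    m: int,
    seed: int,
    config: StudyConfig,
) -> list[CompletedDataset]:
    if method == "mean":
        return [impute_mean(data, mask, statistic="mean")]
    if method == "median":
        return [impute_mean(data, mask, statistic="median")]
    if method == "hotdeck":
        return [impute_hotdeck(data, mask, seed=seed)]
    if method == "knn":
        return [impute_knn(data, mask, seed=seed, on_undefined="median")]
    if method == "pmm":
        return list(pmm_impute(data, mask, m=m, seed=seed))
    if method == "midastouch":
        return list(midastouch_impute(data, mask, m=m, seed=seed))
    if method == "irmi":
        return list(irmi_impute(data, mask, seed=seed, multiple=m))
    if method == "irmi_si":
        return list(irmi_impute(data, mask, seed=seed, multiple=1))
    if method == "irmi_ols":
        return list(irmi_impute(data, mask, seed=seed, multiple=m, robust=False))
    if method == "forest":
        return [forest_impute(data, mask, ForestConfig(trees=config.forest_trees), seed=seed)]
    if method == "boost":
        return list(
            boosted_impute(data, mask, m=m, config=BoostConfig(rounds=config.boost_rounds), seed=seed)
        )
    raise StudyError(f"unknown method {method!r}")


def _estimate_mean(
    completions: list[CompletedDataset],
    column: str,
    rows: np.ndarray,
    level: float,
) -> tuple[float, float, float]:
    """Point estimate and CI for the mean of ``column`` over ``rows``:
    Rubin pooling across copies when m > 1, plain t-interval otherwise."""
    if len(completions) == 1:
        vals = completions[0].frame[column].to_numpy(dtype=float)[rows]
        est, _, (lo, hi) = t_interval(vals, level)
        return est, lo, hi
    ests, wvars, n = [], [], None
    for comp in completions:
        vals = comp.frame[column].to_numpy(dtype=float)[rows]
        n = vals.size
        ests.append(vals.mean())
        wvars.append(vals.var(ddof=1) / vals.size)
    est, _, (lo, hi) = rubin_pool(
        np.array(ests), np.array(wvars), level, complete_df=(n or 2) - 1
    )
    return est, lo, hi


def _complete_case_mean(
    y: np.ndarray, driver: np.ndarray, level: float, adjusted: bool
) -> tuple[float, float, float]:
    """Observed-case estimate of mean(y) over the estimation rows; ``y`` may
    contain NaN (the amputed cells), ``driver`` is fully observed.

    ``adjusted=True`` uses the two-phase regression estimator
    y_reg = y_bar_obs + b (x_bar_all - x_bar_obs) with variance
    S_e^2 / r + (S_y^2 - S_e^2) / n, which stays valid under MAR on the
    driver; the default is the plain observed-case mean/t-interval baseline.
    """
    obs = ~np.isnan(y)
    yo, xo = y[obs], driver[obs]
    if not adjusted:
        est, _, (lo, hi) = t_interval(yo, level)
        return est, lo, hi
    from scipy import stats as sps

    r, n = yo.size, y.size
    coefs = np.polyfit(xo, yo, 1)
    est = float(yo.mean() + coefs[0] * (driver.mean() - xo.mean()))
    resid = yo - np.polyval(coefs, xo)
    s_e2 = float(resid @ resid / (r - 2))
    s_y2 = float(yo.var(ddof=1))
    var = s_e2 / r + max(s_y2 - s_e2, 0.0) / n
    crit = sps.t.ppf(1 - (1 - level) / 2, r - 2)
    half = crit * np.sqrt(var)
    return est, est - half, est + half


def aggregate_replicates(
    replicates: pd.DataFrame, theta_true: float
) -> pd.DataFrame:
    """Recompute (bias, variance, rmse, coverage) per (method, contamination)
    from the long per-replicate table."""
    rows = []
    for (method, k), grp in replicates.groupby(["method", "contamination"], sort=True):
        reps = EstimatorReplicates(
            theta_true=theta_true,
            estimates=grp["estimate"].to_numpy(),
            intervals=grp[["ci_low", "ci_high"]].to_numpy(),
        )
        bias, var, rmse_v = estimator_summary(reps)
        rows.append(
            {
                "method": method,
                "contamination": k,
                "bias": bias,
                "variance": var,
                "rmse": rmse_v,
                "coverage": coverage_rate(reps),
                "replications": len(grp),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# estimator studies
# ---------------------------------------------------------------------------

def run_outlier_study(config: StudyConfig) -> StudyResult:
    """Income setting: RMSE/coverage of the mean-INCOME estimate as leverage
    outliers are added (contamination affects only the imputation step)."""
    config.validate()
    if config.setting != "income_outliers":
        raise StudyError("config.setting must be 'income_outliers'")
    spec = config.income_spec
    rate = config.missing_rate if config.missing_rate is not None else spec.missing_rate
    theta = spec.mean_income
    if max(config.contamination_grid, default=0) > spec.n:
        raise StudyError("contamination exceeds sample size")
    rows = []
    for k in config.contamination_grid:
        for r in range(config.replications):
            ss = np.random.SeedSequence(config.base_seed, spawn_key=(1, k, r))
            s_data, s_out, s_amp, *s_methods = ss.spawn(3 + len(config.methods))
            clean = simulate_income(spec, seed=_seed_int(s_data))
            contaminated, flags = inject_leverage_outliers(
                clean, k, spec, seed=_seed_int(s_out)
            )
            amputed, mmask = ampute_mar(
                contaminated,
                target="INCOME",
                driver="AGE",
                rate=rate,
                protected=flags.outlier_rows,
                seed=_seed_int(s_amp),
            )
            regular = np.setdiff1d(np.arange(spec.n), flags.outlier_rows)
            for method, s_m in zip(config.methods, s_methods):
                if method == "complete_case":
                    est, lo, hi = _complete_case_mean(
                        amputed.frame["INCOME"].to_numpy(dtype=float)[regular],
                        amputed.frame["AGE"].to_numpy(dtype=float)[regular],
                        config.level,
                        config.mar_adjusted_complete_case,
                    )
                else:
                    comps = _impute_with(
                        method, amputed, mmask, config.m, _seed_int(s_m), config
                    )
                    est, lo, hi = _estimate_mean(comps, "INCOME", regular, config.level)
                rows.append(
                    {
                        "method": method,
                        "contamination": k,
                        "replicate": r,
                        "estimate": est,
                        "ci_low": lo,
                        "ci_high": hi,
                    }
                )
    replicates = pd.DataFrame(rows)
    return StudyResult(config, replicates, aggregate_replicates(replicates, theta), theta)


LOG_ENERGY_SCHEMA = [
    VariableSchema("type", "binary", categories=("0", "1")),
    VariableSchema("log_runtime", "continuous"),
    VariableSchema("log_energy", "continuous"),
]


def _log_transform_energy(data: MixedDataset) -> MixedDataset:
    frame = pd.DataFrame(
        {
            "type": data.frame["type"].to_numpy(dtype=object),
            "log_runtime": np.log(data.frame["runtime"].to_numpy(dtype=float)),
            "log_energy": np.log(data.frame["energy"].to_numpy(dtype=float)),
        }
    )
    return MixedDataset(list(LOG_ENERGY_SCHEMA), frame)


def run_misclassification_study(config: StudyConfig) -> StudyResult:
    """Energy setting: RMSE/coverage of the type-1 group mean of log-energy
    as recorded machine types are flipped."""
    config.validate()
    if config.setting != "energy_misclassification":
        raise StudyError("config.setting must be 'energy_misclassification'")
    spec = config.energy_spec
    rate = config.missing_rate if config.missing_rate is not None else spec.missing_rate
    theta = float(spec.true_group_mean_log_energy)
    rows = []
    for k in config.contamination_grid:
        for r in range(config.replications):
            ss = np.random.SeedSequence(config.base_seed, spawn_key=(2, k, r))
            s_data, s_mis, s_amp, *s_methods = ss.spawn(3 + len(config.methods))
            clean = simulate_energy(spec, seed=_seed_int(s_data))
            flipped, flags = inject_misclassifications(clean, k, seed=_seed_int(s_mis))
            logged = _log_transform_energy(flipped)
            amputed, mmask = ampute_mar(
                logged,
                target="log_energy",
                driver="log_runtime",
                rate=rate,
                protected=flags.misclassified_rows,
                seed=_seed_int(s_amp),
            )
            keep = np.ones(spec.n, dtype=bool)
            keep[flags.misclassified_rows] = False
            group = np.flatnonzero(
                keep & (logged.frame["type"].to_numpy(dtype=object) == "1")
            )
            for method, s_m in zip(config.methods, s_methods):
                if method == "complete_case":
                    est, lo, hi = _complete_case_mean(
                        amputed.frame["log_energy"].to_numpy(dtype=float)[group],
                        amputed.frame["log_runtime"].to_numpy(dtype=float)[group],
                        config.level,
                        config.mar_adjusted_complete_case,
                    )
                else:
                    comps = _impute_with(
                        method, amputed, mmask, config.m, _seed_int(s_m), config
                    )
                    est, lo, hi = _estimate_mean(comps, "log_energy", group, config.level)
                rows.append(
                    {
                        "method": method,
                        "contamination": k,
                        "replicate": r,
                        "estimate": est,
                        "ci_low": lo,
                        "ci_high": hi,
                    }
                )
    replicates = pd.DataFrame(rows)
    return StudyResult(config, replicates, aggregate_replicates(replicates, theta), theta)


# ---------------------------------------------------------------------------
# precision study on complete datasets
# ---------------------------------------------------------------------------

def run_precision_study(config: StudyConfig, dataset: MixedDataset) -> StudyResult:
    """Repeatedly ampute 10% MCAR per variable (outlier rows protected),
    impute, and score MAPE/NRMSE/MSECOR/FC against the known truth."""
    config.validate()
    if build_mask(dataset).n_missing > 0:
        raise StudyError("precision study needs a complete dataset")
    rate = config.missing_rate if config.missing_rate is not None else 0.10
    try:
        flagged = np.flatnonzero(flag_outliers_mcd(dataset).flagged)
    except Exception:
        flagged = np.array([], dtype=int)
    rows = []
    for r in range(config.replications):
        ss = np.random.SeedSequence(config.base_seed, spawn_key=(3, r))
        s_amp, *s_methods = ss.spawn(1 + len(config.methods))
        amputed, mmask = ampute_mcar(
            dataset, rate, protected=flagged, seed=_seed_int(s_amp)
        )
        for method, s_m in zip(config.methods, s_methods):
            if method == "oracle":
                comps = [CompletedDataset(dataset.copy(), mmask, method_tag="oracle")]
            else:
                comps = _impute_with(method, amputed, mmask, 1, _seed_int(s_m), config)
            pair = EvaluationPair(comps[0], dataset, mmask, exclude_rows=flagged)
            rec = {"method": method, "replicate": r}
            for name, fn in (("mape", mape), ("nrmse", nrmse), ("msecor", msecor),
                             ("fc", false_classification_rate)):
                try:
                    rec[name] = fn(pair)
                except Exception:
                    rec[name] = np.nan
            rows.append(rec)
    replicates = pd.DataFrame(rows)
    agg = replicates.groupby("method", sort=True)[["mape", "nrmse", "msecor", "fc"]].median()
    return StudyResult(config, replicates, agg.reset_index())


# ---------------------------------------------------------------------------
# classification study
# ---------------------------------------------------------------------------

def run_classification_study(
    config: StudyConfig,
    dataset: MixedDataset,
    label_column: str,
    positive_label: str | None = None,
) -> StudyResult:
    """Hold-out F1 of a random-forest classifier after amputing and imputing
    the training features (the test set is never touched)."""
    config.validate()
    label_var = dataset.var(label_column)
    if not label_var.is_categorical:
        raise StudyError("label column must be binary/categorical")
    labels_all = dataset.frame[label_column].to_numpy(dtype=object).astype(str)
    if len(set(labels_all)) < 2:
        raise StudyError("label column has a single class")
    pos = positive_label or str(label_var.categories[-1])  # type: ignore[index]
    feat_schema = [v for v in dataset.schema if v.name != label_column]
    feat_cols = [v.name for v in feat_schema]
    rate = config.missing_rate if config.missing_rate is not None else 0.10
    from .regression_imputers import encode_design

    rows = []
    for r in range(config.replications):
        ss = np.random.SeedSequence(config.base_seed, spawn_key=(4, r))
        s_split, s_amp, s_clf, *s_methods = ss.spawn(3 + len(config.methods))
        idx_train, idx_test = train_test_split(
            np.arange(dataset.n),
            test_size=0.30,
            stratify=labels_all,
            random_state=_seed_int(s_split),
        )
        train = MixedDataset(
            list(feat_schema), dataset.frame.iloc[idx_train][feat_cols].reset_index(drop=True)
        )
        test_X = encode_design(
            dataset.frame.iloc[idx_test][feat_cols], list(feat_schema), exclude=""
        )
        y_train_full = labels_all[idx_train]
        y_test = labels_all[idx_test]
        amputed, mmask = ampute_mcar(train, rate, seed=_seed_int(s_amp))
        clf_seed = _seed_int(s_clf)
        for method, s_m in zip(config.methods, s_methods):
            if method == "complete_case":
                keep = ~mmask.entries.any(axis=1)
                if keep.sum() < 2 or len(set(y_train_full[keep])) < 2:
                    rec_f1, rec_acc = np.nan, np.nan
                    rows.append({"method": method, "replicate": r, "f1": rec_f1,
                                 "accuracy": rec_acc})
                    continue
                frame = amputed.frame.loc[keep].reset_index(drop=True)
                fit_frame, fit_y = frame, y_train_full[keep]
            elif method == "oracle":
                fit_frame, fit_y = train.frame, y_train_full
            elif method == "none":
                fit_frame, fit_y = train.frame, y_train_full
            else:
                comps = _impute_with(method, amputed, mmask, 1, _seed_int(s_m), config)
                fit_frame, fit_y = comps[0].frame, y_train_full
            Xtr = encode_design(fit_frame, list(feat_schema), exclude="")
            clf = RandomForestClassifier(
                n_estimators=config.forest_trees, random_state=clf_seed, n_jobs=1
            )
            clf.fit(Xtr, fit_y)
            pred = clf.predict(test_X)
            counts = ConfusionCounts(
                TP=int(((pred == pos) & (y_test == pos)).sum()),
                TN=int(((pred != pos) & (y_test != pos)).sum()),
                FP=int(((pred == pos) & (y_test != pos)).sum()),
                FN=int(((pred != pos) & (y_test == pos)).sum()),
            )
            acc, f1 = f1_accuracy(counts)
            rows.append({"method": method, "replicate": r, "f1": f1, "accuracy": acc})
    replicates = pd.DataFrame(rows)
    agg = replicates.groupby("method", sort=True)[["f1", "accuracy"]].median().reset_index()
    return StudyResult(config, replicates, agg)


__all__ = [
    "StudyConfig",
    "StudyResult",
    "KNOWN_METHODS",
    "run_outlier_study",
    "run_misclassification_study",
    "run_precision_study",
    "run_classification_study",
    "aggregate_replicates",
    "StudyError",
]
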