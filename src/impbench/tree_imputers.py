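"""Non-linear imputation: iterative random-forest imputation and
bootstrap boosted-tree imputation with predictive-mean matching.

Forest imputation (missForest/missRanger family): initialise by
mean/mode, then cycle over the variables (ascending missing count),
refitting a random forest of each variable on all others and re-predicting
its missing cells, until the per-scale convergence criteria hold —
for a continuous variable sum((new - old)^2) / sum(new) < delta, for a
categorical variable the fraction of changed labels < delta — or the
iteration cap is reached.

Boosted imputation (mixgb family): per copy, each variable's model is a
gradient-boosted tree ensemble fitted on a bootstrap resample of the rows
observed in that variable; missing cells are imputed by predictive mean
matching against the donors' predictions (classes are matched on predicted
class-probability vectors), so imputed values always come from the observed
support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .core_data import (
    CompletedDataset,
    MissingMask,
    MixedDataset,
    MultipleImputationSet,
    build_mask,
)
from .donor_imputers import ImputationError, impute_mean
from .regression_imputers import encode_design


@dataclass
class ForestConfig:
    trees: int = 100
    delta: float = 1e-4
    max_iter: int = 10

    def validate(self) -> None:
        if self.trees < 1 or self.delta <= 0 or self.max_iter < 1:
            raise ImputationError("invalid forest configuration")


@dataclass
class BoostConfig:
    rounds: int = 100
    learning_rate: float = 0.1
    k_donors: int = 5
    bootstrap: bool = True

    def validate(self) -> None:
        if self.rounds < 1 or self.k_donors < 1:
            raise ImputationError("invalid boosting configuration")


@dataclass
class ForestDiagnostics:
    iterations: int
    converged: bool
    change_history: list[dict[str, float]] = field(default_factory=list)


def forest_impute(
    data: MixedDataset,
    mask: MissingMask | None = None,
    config: ForestConfig | None = None,
    seed: int = 0,
) -> CompletedDataset:
    """Iterative random-forest imputation with per-scale convergence checks."""
    config = config or ForestConfig()
    config.validate()
    mask = mask if mask is not None else build_mask(data)
    if mask.n_missing == 0:
        comp = CompletedDataset(data.copy(), mask, method_tag="forest", seed=seed)
        comp.diagnostics = ForestDiagnostics(0, True)  # type: ignore[attr-defined]
        return comp
    counts = mask.per_column_counts
    order = sorted(
        (j for j in range(data.p) if counts[j] > 0), key=lambda j: (counts[j], j)
    )
    rng = np.random.default_rng(seed)
    work = impute_mean(data, mask, statistic="mean").data.copy()
    diag = ForestDiagnostics(0, False)
    for it in range(1, config.max_iter + 1):
        changes: dict[str, float] = {}
        all_small = True
        for j in order:
            v = data.schema[j]
            X = encode_design(work.frame, data.schema, v.name)
            miss = mask.column(j)
            obs = ~miss
            rs = int(rng.integers(2**31 - 1))
            if v.is_numeric:
                y = work.frame[v.name].to_numpy(dtype=float)
                if np.ptp(y[obs]) == 0:
                    pred = np.repeat(y[obs][0], miss.sum())
                else:
                    model = RandomForestRegressor(
                        n_estimators=config.trees, random_state=rs, n_jobs=1
                    )
                    model.fit(X[obs], y[obs])
                    pred = model.predict(X[miss])
                old = y[miss]
                denom = float(np.abs(pred).sum())
                crit = float(((pred - old) ** 2).sum()) / (denom if denom > 0 else 1.0)
                y = y.copy()
                y[miss] = pred
                work.frame[v.name] = y
            else:
                y = work.frame[v.name].to_numpy(dtype=object)
                labels = y[obs].astype(str)
                if len(set(labels)) < 2:
                    pred = np.repeat(labels[0], miss.sum())
                else:
                    model = RandomForestClassifier(
                        n_estimators=config.trees, random_state=rs, n_jobs=1
                    )
                    model.fit(X[obs], labels)
                    pred = model.predict(X[miss])
                old = y[miss].astype(str)
                crit = float(np.mean(old != pred)) if miss.sum() else 0.0
                y = y.copy()
                y[miss] = pred
                work.frame[v.name] = y
            changes[v.name] = crit
            if crit >= config.delta:
                all_small = False
        diag.change_history.append(changes)
        diag.iterations = it
        if all_small:
            diag.converged = True
            break
    comp = CompletedDataset(work, mask, method_tag="forest", seed=seed)
    comp.diagnostics = diag  # type: ignore[attr-defined]
    return comp


def boosted_impute(
    data: MixedDataset,
    mask: MissingMask | None = None,
    m: int = 5,
    config: BoostConfig | None = None,
    seed: int = 0,
) -> MultipleImputationSet:
    """Bootstrap boosted-tree imputation with PMM donor matching; m copies."""
    from xgboost import XGBClassifier, XGBRegressor

    config = config or BoostConfig()
    config.validate()
    mask = mask if mask is not None else build_mask(data)
    counts = mask.per_column_counts
    order = sorted(
        (j for j in range(data.p) if counts[j] > 0), key=lambda j: (counts[j], j)
    )
    ss = np.random.SeedSequence(seed)
    completions = []
    for copy_i, child in enumerate(ss.spawn(max(m, 1))):
        rng = np.random.default_rng(child)
        work = impute_mean(data, mask, statistic="mean").data.copy()
        for j in order:
            v = data.schema[j]
            X = encode_design(work.frame, data.schema, v.name)
            miss = mask.column(j)
            obs_idx = np.flatnonzero(~miss)
            miss_idx = np.flatnonzero(miss)
            if obs_idx.size < config.k_donors:
                raise ImputationError(f"fewer than k donors for {v.name!r}")
            fit_idx = (
                rng.choice(obs_idx, size=obs_idx.size, replace=True)
                if config.bootstrap
                else obs_idx
            )
            rs = int(rng.integers(2**31 - 1))
            col = work.frame[v.name].to_numpy(dtype=object).copy()
            kk = min(config.k_donors, obs_idx.size)
            if v.is_numeric:
                y = work.frame[v.name].to_numpy(dtype=float)
                if np.ptp(y[obs_idx]) == 0:
                    col[miss] = y[obs_idx[0]]
                else:
                    model = XGBRegressor(
                        n_estimators=config.rounds,
                        learning_rate=config.learning_rate,
                        random_state=rs,
                        n_jobs=1,
                        verbosity=0,
                    )
                    model.fit(X[fit_idx], y[fit_idx])
                    pred = model.predict(X)
                    for r in miss_idx:
                        d = np.abs(pred[obs_idx] - pred[r])
                        near = np.argpartition(d, kk - 1)[:kk]
                        col[r] = y[obs_idx[rng.choice(near)]]
            else:
                y = work.frame[v.name].to_numpy(dtype=object)
                labels = y[fit_idx].astype(str)
                if len(set(labels)) < 2:
                    col[miss] = labels[0]
                else:
                    classes, codes = np.unique(labels, return_inverse=True)
                    model = XGBClassifier(
                        n_estimators=config.rounds,
                        learning_rate=config.learning_rate,
                        random_state=rs,
                        n_jobs=1,
                        verbosity=0,
                    )
                    model.fit(X[fit_idx], codes)
                    proba = model.predict_proba(X)
                    for r in miss_idx:
                        d = np.linalg.norm(proba[obs_idx] - proba[r], axis=1)
                        near = np.argpartition(d, kk - 1)[:kk]
                        col[r] = y[obs_idx[rng.choice(near)]]
            work.frame[v.name] = col
        completions.append(
            CompletedDataset(work, mask, method_tag="boost", seed=seed + copy_i)
        )
    return MultipleImputationSet(completions)


__all__ = [
    "ForestConfig",
    "BoostConfig",
    "ForestDiagnostics",
    "forest_impute",
    "boosted_impute",
]
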