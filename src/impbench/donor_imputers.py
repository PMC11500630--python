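"""Model-free donor imputation: mean/median/mode, random hotdeck, and
k-nearest-neighbour with Gower distance.

Gower dissimilarity between two mixed-type rows is the weighted mean of
per-variable dissimilarities over the variables observed in *both* rows:
|a - b| / range for continuous/semicontinuous/count variables (range =
max - min over the observed values of the whole input dataset) and simple
0/1 disagreement for binary/categorical variables.  Constant columns
contribute dissimilarity 0.  kNN imputes numeric targets by the median of
the k = 5 nearest donors and categorical targets by their most frequent
category, with deterministic tie-breaking (smallest row position at the
k-th distance, smallest label for mode ties).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import (
    CompletedDataset,
    MissingMask,
    MixedDataset,
    build_mask,
)


class ImputationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Gower distance
# ---------------------------------------------------------------------------

@dataclass
class GowerContext:
    """Precomputed ranges/weights for Gower comparisons on one dataset."""

    schema: list
    ranges: dict[str, float]  # continuous-like columns: max-min over observed
    weights: dict[str, float]

    @classmethod
    def from_dataset(
        cls, data: MixedDataset, weights: dict[str, float] | None = None
    ) -> "GowerContext":
        ranges = {}
        for v in data.schema:
            if v.is_numeric:
                col = data.frame[v.name].to_numpy(dtype=float)
                obs = col[~np.isnan(col)]
                ranges[v.name] = float(obs.max() - obs.min()) if obs.size else 0.0
        w = {v.name: 1.0 for v in data.schema}
        if weights:
            w.update(weights)
        if any(x < 0 for x in w.values()) or sum(w.values()) == 0:
            raise ImputationError("weights must be >= 0 and not all zero")
        return cls(schema=list(data.schema), ranges=ranges, weights=w)


def gower_distance(row_a: pd.Series, row_b: pd.Series, ctx: GowerContext) -> float:
    """Gower dissimilarity in [0, 1] between two rows (pandas Series indexed
    by column name); only variables observed in both rows are compared."""
    num = 0.0
    wsum = 0.0
    for v in ctx.schema:
        a, b = row_a[v.name], row_b[v.name]
        if pd.isna(a) or pd.isna(b):
            continue
        w = ctx.weights[v.name]
        if v.is_numeric:
            rng = ctx.ranges[v.name]
            d = 0.0 if rng == 0 else abs(float(a) - float(b)) / rng
        else:
            d = 0.0 if a == b else 1.0
        num += w * min(d, 1.0)
        wsum += w
    if wsum == 0:
        raise ImputationError("no commonly observed variable: Gower distance undefined")
    return num / wsum


def gower_matrix(
    recipients: pd.DataFrame,
    donors: pd.DataFrame,
    ctx: GowerContext,
    undefined: str = "raise",
) -> np.ndarray:
    """Vectorized Gower distances, shape (len(recipients), len(donors)).

    A pair with no commonly observed variable has an undefined distance:
    ``undefined="raise"`` signals an error, ``undefined="nan"`` returns NaN
    for that pair (callers treat it as "not a candidate donor").
    """
    nr, nd = len(recipients), len(donors)
    num = np.zeros((nr, nd))
    wsum = np.zeros((nr, nd))
    for v in ctx.schema:
        w = ctx.weights[v.name]
        if w == 0:
            continue
        if v.is_numeric:
            a = recipients[v.name].to_numpy(dtype=float)[:, None]
            b = donors[v.name].to_numpy(dtype=float)[None, :]
            both = ~(np.isnan(a) | np.isnan(b))
            rng = ctx.ranges[v.name]
            d = np.zeros((nr, nd)) if rng == 0 else np.minimum(np.abs(a - b) / rng, 1.0)
        else:
            a = recipients[v.name].to_numpy(dtype=object)[:, None]
            b = donors[v.name].to_numpy(dtype=object)[None, :]
            obs_a = ~pd.isna(recipients[v.name].to_numpy(dtype=object))[:, None]
            obs_b = ~pd.isna(donors[v.name].to_numpy(dtype=object))[None, :]
            both = obs_a & obs_b
            d = (a != b).astype(float)
        d = np.where(both, d, 0.0)
        num += w * d
        wsum += w * both
    bad = wsum == 0
    if bad.any():
        if undefined == "raise":
            raise ImputationError("some row pair shares no observed variable")
        wsum = np.where(bad, 1.0, wsum)
        out = num / wsum
        out[bad] = np.nan
        return out
    return num / wsum


# ---------------------------------------------------------------------------
# column statistics
# ---------------------------------------------------------------------------

def _column_mode(values: np.ndarray) -> object:
    """Most frequent value; ties broken by the smallest label."""
    labels, counts = np.unique(values.astype(str), return_counts=True)
    return labels[np.lexsort((labels, -counts))[0]]


def impute_mean(
    data: MixedDataset,
    mask: MissingMask | None = None,
    statistic: str = "mean",
) -> CompletedDataset:
    """Column-statistic imputation: numeric cells get the column mean or
    median of observed cases, categorical/binary cells the observed mode."""
    if statistic not in ("mean", "median", "mode"):
        raise ImputationError(f"unknown statistic {statistic!r}")
    mask = mask if mask is not None else build_mask(data)
    out = data.copy()
    for j, v in enumerate(data.schema):
        miss = mask.column(j)
        if not miss.any():
            continue
        col = out.frame[v.name]
        obs = col[~miss]
        if obs.dropna().empty:
            raise ImputationError(f"column {v.name!r} has no observed value")
        if v.is_numeric and statistic != "mode":
            fill = float(obs.astype(float).mean() if statistic == "mean" else obs.astype(float).median())
        elif v.is_numeric:
            fill = float(_column_mode(obs.to_numpy()))
        else:
            fill = _column_mode(obs.to_numpy())
        col = col.copy()
        col[miss] = fill
        out.frame[v.name] = col
    return CompletedDataset(out, mask, method_tag=f"{statistic}")


def impute_hotdeck(
    data: MixedDataset, mask: MissingMask | None = None, seed: int = 0
) -> CompletedDataset:
    """Random hotdeck: each missing cell receives the value of a donor row
    drawn uniformly from the rows observed in that variable."""
    mask = mask if mask is not None else build_mask(data)
    rng = np.random.default_rng(seed)
    out = data.copy()
    for j, v in enumerate(data.schema):
        miss = mask.column(j)
        if not miss.any():
            continue
        col = out.frame[v.name].to_numpy(dtype=object).copy()
        donors = col[~miss]
        if donors.size == 0:
            raise ImputationError(f"empty donor pool for {v.name!r}")
        col[miss] = rng.choice(donors, size=int(miss.sum()), replace=True)
        out.frame[v.name] = col
    return CompletedDataset(out, mask, method_tag="hotdeck", seed=seed)


def impute_knn(
    data: MixedDataset,
    mask: MissingMask | None = None,
    k: int = 5,
    seed: int = 0,
    weights: dict[str, float] | None = None,
    on_undefined: str = "error",
) -> CompletedDataset:
    """Gower-distance k-nearest-neighbour imputation (k = 5 default).

    For each row with missing cells the k rows observed in the target
    variable with the smallest Gower distance are found; numeric targets are
    imputed by the donors' median, categorical targets by their mode.  Ties
    at the k-th distance keep the smallest row positions (deterministic);
    ``seed`` is accepted for interface symmetry but unused.

    A recipient with no defined Gower distance to any donor (a fully missing
    row) signals an error by default; ``on_undefined="median"`` falls back to
    the column median/mode for such recipients.
    """
    mask = mask if mask is not None else build_mask(data)
    ctx = GowerContext.from_dataset(data, weights)
    out = data.copy()
    fills: dict[str, np.ndarray] = {}
    for j, v in enumerate(data.schema):
        miss = mask.column(j)
        if not miss.any():
            continue
        donors_idx = np.flatnonzero(~miss)
        if donors_idx.size == 0:
            raise ImputationError(f"no donors for {v.name!r}")
        recip_idx = np.flatnonzero(miss)
        dmat = gower_matrix(
            data.frame.iloc[recip_idx], data.frame.iloc[donors_idx], ctx,
            undefined="nan",
        )
        hopeless = np.isnan(dmat).all(axis=1)
        if hopeless.any() and on_undefined == "error":
            raise ImputationError(
                f"a recipient of {v.name!r} has no donor with a defined distance"
            )
        dmat = np.where(np.isnan(dmat), np.inf, dmat)
        col = out.frame[v.name].to_numpy(dtype=object).copy()
        donors_col = data.frame[v.name].iloc[donors_idx]
        if v.is_numeric:
            fallback: object = float(donors_col.astype(float).median())
        else:
            fallback = _column_mode(donors_col.to_numpy())
        kk = min(k, donors_idx.size)
        # stable sort => ties at the k-th distance resolved by row position
        order = np.argsort(dmat, axis=1, kind="stable")[:, :kk]
        for r, ri in enumerate(recip_idx):
            if hopeless[r]:
                col[ri] = fallback
                continue
            nb = donors_idx[order[r]]
            nb = nb[np.isfinite(dmat[r, order[r]])]
            vals = data.frame[v.name].iloc[nb]
            if v.is_numeric:
                col[ri] = float(vals.astype(float).median())
            else:
                col[ri] = _column_mode(vals.to_numpy())
        fills[v.name] = col
    for name, col in fills.items():
        out.frame[name] = col
    return CompletedDataset(out, mask, method_tag=f"knn(k={k})", seed=seed)


__all__ = [
    "GowerContext",
    "gower_distance",
    "gower_matrix",
    "impute_mean",
    "impute_hotdeck",
    "impute_knn",
    "ImputationError",
]
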