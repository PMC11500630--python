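"""Synthetic populations, contamination and amputation mechanisms.

Two study populations are generated here:

* **Income setting** — (AGE, INCOME) bivariate Gaussian with mean
  (40, 1500) and covariance assembled by element-wise squaring of the
  printed parameters (10, 44; 44, 300), i.e.
  Sigma = [[100, 1936], [1936, 90000]] (correlation ~0.645).  High-leverage
  outliers are placed at the four symmetric positions
  mu +/- 0.8 * diag(Sigma) with scatter Sigma / 5.
* **Energy setting** — machines with a binary ``type`` ~ Bernoulli(0.4),
  ``runtime`` ~ Exponential(rate 1/100) and
  ``energy = exp(2 + I(type = 1) - 0.1 log(runtime) + eps)`` with
  eps ~ N(0, 0.1): a lognormal energy/runtime relationship.  Contamination
  flips the recorded type of k machines (misclassification).

Amputation is exact-count: per column, round(rate * n_eligible) cells are
set missing (MCAR uniformly; MAR by rank-of-driver weighted sampling
without replacement), and rows passed as ``protected`` (outliers /
misclassified machines) are never amputed — a method must never be
rewarded for imputing an outlier with an outlier value.

Outlier flagging uses robust (MCD-based) squared Mahalanobis distances with
a chi-square cutoff at probability 0.99 and, following the source protocol,
df = (number of continuous variables) - 1 by default (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import MinCovDet

from .core_data import (
    MissingMask,
    MixedDataset,
    VariableSchema,
    build_mask,
    set_missing,
)


class ContaminationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# simulation specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IncomeSimSpec:
    """Bivariate AGE/INCOME population of the outlier study.

    The covariance parameters (age_param, cross_param; cross_param,
    income_param) admit two readings, both representable:

    * ``covariance_reading="raw"`` (default): the parameters are the
      covariance entries, Sigma = [[10, 44], [44, 300]] (correlation 0.80).
      Outlier centers mu +/- 0.8 * diag(Sigma) = (40 +/- 8, 1500 +/- 240)
      then sit ~2.5 sigma out in AGE — genuine high-leverage points that
      overlap the regular AGE range.
    * ``covariance_reading="elementwise"``: the parameters are squared
      element-wise, Sigma = [[100, 1936], [1936, 90000]] (correlation 0.645),
      with centers (40 +/- 80, 1500 +/- 72000).

    ``outlier_placement`` controls whether one of the four centers is drawn
    once per contaminated sample ("per_replicate", default — contamination
    is directional within a replicate) or independently per outlier row
    ("per_outlier" — contamination is symmetric within a replicate).
    """

    mean_age: float = 40.0
    mean_income: float = 1500.0
    age_param: float = 10.0
    income_param: float = 300.0
    cross_param: float = 44.0
    covariance_reading: str = "raw"
    n: int = 200
    missing_rate: float = 0.30
    outlier_shift_factor: float = 0.8
    outlier_variance_ratio: float = 0.2  # scatter of outlier groups: Sigma/5
    outlier_placement: str = "per_replicate"

    @property
    def mean(self) -> np.ndarray:
        return np.array([self.mean_age, self.mean_income])

    @property
    def covariance(self) -> np.ndarray:
        if self.covariance_reading == "raw":
            sigma = np.array(
                [
                    [self.age_param, self.cross_param],
                    [self.cross_param, self.income_param],
                ],
                dtype=float,
            )
        elif self.covariance_reading == "elementwise":
            sigma = np.array(
                [
                    [self.age_param**2, self.cross_param**2],
                    [self.cross_param**2, self.income_param**2],
                ],
                dtype=float,
            )
        else:
            raise ContaminationError(f"unknown reading {self.covariance_reading!r}")
        # symmetric by construction; eigenvalues must be positive
        if np.linalg.eigvalsh(sigma)[0] <= 0:
            raise ContaminationError("income covariance is not positive definite")
        return sigma

    def validate(self) -> None:
        if not (0 <= self.missing_rate < 1):
            raise ContaminationError("missing_rate must be in [0, 1)")
        if self.outlier_placement not in ("per_replicate", "per_outlier"):
            raise ContaminationError(f"unknown placement {self.outlier_placement!r}")
        self.covariance  # noqa: B018  (raises if not PD)


@dataclass(frozen=True)
class EnergySimSpec:
    """Lognormal energy-consumption population of the misclassification study."""

    intercept: float = 2.0
    type_effect: float = 1.0
    runtime_coeff: float = -0.1
    type_prob: float = 0.4
    runtime_rate: float = 1.0 / 100.0
    noise_var: float = 0.1
    n: int = 200
    missing_rate: float = 0.30

    def validate(self) -> None:
        if self.runtime_rate <= 0:
            raise ContaminationError("runtime_rate must be > 0")
        if not (0 < self.type_prob < 1):
            raise ContaminationError("type_prob must be in (0, 1)")
        if self.noise_var < 0:
            raise ContaminationError("noise_var must be >= 0")

    @property
    def true_group_mean_log_energy(self) -> float:
        """E[log energy | type = 1]: intercept + effect + coeff * E[log runtime],
        with E[log runtime] = -log(rate) - Euler gamma for an exponential."""
        e_log_runtime = -np.log(self.runtime_rate) - np.euler_gamma
        return self.intercept + self.type_effect + self.runtime_coeff * e_log_runtime


@dataclass
class ContaminationFlags:
    """Row indices (positions) altered by contamination."""

    outlier_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    misclassified_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def all_rows(self) -> np.ndarray:
        return np.union1d(self.outlier_rows, self.misclassified_rows).astype(int)


@dataclass
class RobustDistanceResult:
    distances: np.ndarray  # squared robust Mahalanobis distances
    cutoff: float
    flagged: np.ndarray
    location: np.ndarray
    scatter: np.ndarray


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

INCOME_SCHEMA = [
    VariableSchema("AGE", "continuous"),
    VariableSchema("INCOME", "continuous"),
]

ENERGY_SCHEMA = [
    VariableSchema("type", "binary", categories=("0", "1")),
    VariableSchema("runtime", "continuous"),
    VariableSchema("energy", "continuous"),
]


def simulate_income(spec: IncomeSimSpec = IncomeSimSpec(), seed: int = 0) -> MixedDataset:
    """Draw n rows of (AGE, INCOME) from the spec's bivariate normal."""
    spec.validate()
    rng = np.random.default_rng(seed)
    xy = rng.multivariate_normal(spec.mean, spec.covariance, size=spec.n,
                                 method="cholesky")
    frame = pd.DataFrame(xy, columns=["AGE", "INCOME"])
    return MixedDataset(list(INCOME_SCHEMA), frame)


def inject_leverage_outliers(
    data: MixedDataset,
    k: int,
    spec: IncomeSimSpec = IncomeSimSpec(),
    seed: int = 0,
) -> tuple[MixedDataset, ContaminationFlags]:
    """Replace k uniformly chosen rows by high-leverage outliers.

    Centers are the four sign combinations mu + (+/-f*Sigma_11, +/-f*Sigma_22)
    with f = spec.outlier_shift_factor; scatter is Sigma times
    spec.outlier_variance_ratio.  Non-selected rows are returned bit-identical.
    """
    n = data.n
    if k > n:
        raise ContaminationError(f"k={k} outliers exceed n={n} rows")
    if k == 0:
        return data.copy(), ContaminationFlags()
    rng = np.random.default_rng(seed)
    sigma = spec.covariance
    shift = spec.outlier_shift_factor * np.diag(sigma)
    rows = rng.choice(n, size=k, replace=False)
    if spec.outlier_placement == "per_replicate":
        signs = np.broadcast_to(rng.choice([-1.0, 1.0], size=2), (k, 2))
    else:
        signs = rng.choice([-1.0, 1.0], size=(k, 2))
    centers = spec.mean + signs * shift
    draws = centers + rng.multivariate_normal(
        np.zeros(2), sigma * spec.outlier_variance_ratio, size=k, method="cholesky"
    )
    out = data.copy()
    cols = ["AGE", "INCOME"]
    arr = out.frame[cols].to_numpy()
    arr[rows] = draws
    out.frame[cols] = arr
    return out, ContaminationFlags(outlier_rows=np.sort(rows))


def simulate_energy(spec: EnergySimSpec = EnergySimSpec(), seed: int = 0) -> MixedDataset:
    """Draw n machines: binary type, exponential runtime, lognormal energy."""
    spec.validate()
    rng = np.random.default_rng(seed)
    machine_type = rng.binomial(1, spec.type_prob, size=spec.n)
    runtime = rng.exponential(scale=1.0 / spec.runtime_rate, size=spec.n)
    eps = rng.normal(0.0, np.sqrt(spec.noise_var), size=spec.n) if spec.noise_var > 0 else 0.0
    log_energy = (
        spec.intercept
        + spec.type_effect * machine_type
        + spec.runtime_coeff * np.log(runtime)
        + eps
    )
    frame = pd.DataFrame(
        {
            "type": machine_type.astype(str),
            "runtime": runtime,
            "energy": np.exp(log_energy),
        }
    )
    return MixedDataset(list(ENERGY_SCHEMA), frame)


def inject_misclassifications(
    data: MixedDataset, k: int, seed: int = 0, type_column: str = "type"
) -> tuple[MixedDataset, ContaminationFlags]:
    """Flip the binary type of k distinct uniformly chosen rows."""
    var = data.var(type_column)
    if var.scale != "binary":
        raise ContaminationError(f"{type_column!r} is not binary")
    if k > data.n:
        raise ContaminationError(f"k={k} exceeds n={data.n}")
    if k == 0:
        return data.copy(), ContaminationFlags()
    rng = np.random.default_rng(seed)
    rows = rng.choice(data.n, size=k, replace=False)
    a, b = var.categories  # type: ignore[misc]
    out = data.copy()
    col = out.frame[type_column].to_numpy(dtype=object)
    col[rows] = np.where(col[rows] == a, b, a)
    out.frame[type_column] = col
    return out, ContaminationFlags(misclassified_rows=np.sort(rows))


# ---------------------------------------------------------------------------
# robust outlier flagging
# ---------------------------------------------------------------------------

def flag_outliers_mcd(
    data: MixedDataset,
    prob: float = 0.99,
    df: int | None = None,
    random_state: int = 0,
) -> RobustDistanceResult:
    """Flag rows whose squared robust Mahalanobis distance exceeds the
    chi-square quantile at ``prob``.

    Location and scatter come from the MCD estimator on the continuous
    columns (complete rows only).  ``df`` defaults to
    (number of continuous variables) - 1, the source protocol's printed
    convention; pass ``df=p`` for the textbook convention.
    """
    if not (0 < prob < 1):
        raise ContaminationError("prob must be in (0, 1)")
    cols = data.continuous_columns
    if len(cols) < 2:
        raise ContaminationError("need >= 2 continuous columns for MCD flagging")
    x = data.frame[cols].to_numpy(dtype=float)
    complete = ~np.isnan(x).any(axis=1)
    p = len(cols)
    if complete.sum() < p + 1:
        raise ContaminationError("too few complete rows for MCD")
    mcd = MinCovDet(random_state=random_state).fit(x[complete])
    d2 = np.full(data.n, np.nan)
    d2[complete] = mcd.mahalanobis(x[complete])
    dof = (p - 1) if df is None else df
    dof = max(dof, 1)
    cutoff = stats.chi2.ppf(prob, dof)
    flagged = np.zeros(data.n, dtype=bool)
    flagged[complete] = d2[complete] > cutoff
    return RobustDistanceResult(
        distances=d2,
        cutoff=float(cutoff),
        flagged=flagged,
        location=mcd.location_,
        scatter=mcd.covariance_,
    )


# ---------------------------------------------------------------------------
# amputation
# ---------------------------------------------------------------------------

def _exact_count(rate: float, n_eligible: int) -> int:
    # round half up, so the printed rates (10%, 30%) are hit exactly
    return int(np.floor(rate * n_eligible + 0.5))


def ampute_mcar(
    data: MixedDataset,
    rate: float,
    protected: np.ndarray | None = None,
    seed: int = 0,
    columns: list[str] | None = None,
) -> tuple[MixedDataset, MissingMask]:
    """Set exactly round(rate * n_eligible) cells missing per column, chosen
    uniformly without replacement among non-protected rows."""
    if not (0 <= rate < 1):
        raise ContaminationError("rate must be in [0, 1)")
    prot = np.zeros(data.n, dtype=bool)
    if protected is not None and len(protected) > 0:
        prot[np.asarray(protected, dtype=int)] = True
    eligible = np.flatnonzero(~prot)
    if rate > 0 and eligible.size == 0:
        raise ContaminationError("all rows protected with positive rate")
    rng = np.random.default_rng(seed)
    cols = columns if columns is not None else data.columns
    entries = np.zeros((data.n, data.p), dtype=bool)
    col_pos = {c: j for j, c in enumerate(data.columns)}
    for c in cols:
        k = _exact_count(rate, eligible.size)
        if k == 0:
            continue
        hit = rng.choice(eligible, size=k, replace=False)
        entries[hit, col_pos[c]] = True
    return set_missing(data, entries), MissingMask(entries)


def ampute_mar(
    data: MixedDataset,
    target: str,
    driver: str,
    rate: float,
    protected: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[MixedDataset, MissingMask]:
    """Monotone MAR amputation of ``target`` driven by ``driver``.

    Exactly round(rate * n_eligible) target cells among the non-protected
    rows are set missing, sampled without replacement with probability
    proportional to the rank of the driver value: the larger the driver,
    the likelier the target is missing.  A constant driver degrades to
    MCAR (warning semantics: weights become equal, no error).
    """
    if target == driver:
        raise ContaminationError("target and driver must differ")
    if not (0 <= rate < 1):
        raise ContaminationError("rate must be in [0, 1)")
    drv = data.frame[driver]
    if drv.isna().any():
        raise ContaminationError("driver column must be fully observed")
    prot = np.zeros(data.n, dtype=bool)
    if protected is not None and len(protected) > 0:
        prot[np.asarray(protected, dtype=int)] = True
    eligible = np.flatnonzero(~prot)
    if rate > 0 and eligible.size == 0:
        raise ContaminationError("all rows protected with positive rate")
    k = _exact_count(rate, eligible.size)
    entries = np.zeros((data.n, data.p), dtype=bool)
    if k > 0:
        drv_vals = pd.to_numeric(drv.iloc[eligible], errors="coerce")
        if drv_vals.isna().any():  # categorical driver: use codes
            drv_vals = pd.Series(
                pd.factorize(drv.iloc[eligible])[0], index=drv_vals.index, dtype=float
            )
        weights = stats.rankdata(drv_vals.to_numpy())  # ranks 1..n_eligible
        rng = np.random.default_rng(seed)
        hit = _weighted_sample_without_replacement(eligible, weights, k, rng)
        entries[hit, data.columns.index(target)] = True
    return set_missing(data, entries), MissingMask(entries)


def _weighted_sample_without_replacement(
    items: np.ndarray, weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Efraimidis-Spirakis exponential-keys sampling: draw k items without
    replacement with inclusion driven by ``weights`` (successive sampling)."""
    keys = rng.exponential(size=len(items)) / np.asarray(weights, dtype=float)
    order = np.argsort(keys)
    return items[order[:k]]


__all__ = [
    "IncomeSimSpec",
    "EnergySimSpec",
    "ContaminationFlags",
    "RobustDistanceResult",
    "INCOME_SCHEMA",
    "ENERGY_SCHEMA",
    "simulate_income",
    "inject_leverage_outliers",
    "simulate_energy",
    "inject_misclassifications",
    "flag_outliers_mcd",
    "ampute_mcar",
    "ampute_mar",
    "ContaminationError",
]
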