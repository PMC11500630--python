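"""Evaluation statistics for imputation quality.

Precision measures score only the amputed cells (the ones whose truth is
known because they were deliberately set missing):

* MAPE   = 100 * mean |x_imp - x_orig| / |x_orig| over scored continuous cells
* NRMSE  = sqrt( mean (x_imp - x_orig)^2 / s_j^2 ), the per-column variance
  s_j^2 computed over the originally-missing cells of column j
  (divisor sum(m_ij) - 1) — near 0 is good, near 1 is the mean-imputation
  regime
* MSECOR = ||R - R_tilde||_F / (D - 1): Frobenius distance between the
  correlation matrices of the continuous variables before and after
  imputation (computed on non-outlier rows)
* FC     = 100 * fraction of scored categorical cells imputed into the
  wrong category

Estimator-based evaluation: bias, variance, RMSE over simulation
replicates; coverage rate of confidence intervals; Rubin's rules for
pooling m multiply-imputed estimates (total variance
T = W_bar + (1 + 1/m) B, interval with Barnard-Rubin degrees of freedom);
and accuracy / F1 for classification studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_data import CompletedDataset, MissingMask, MixedDataset


class EvaluationError(ValueError):
    pass


@dataclass
class EvaluationPair:
    """Imputed data vs ground truth, scored on the mask's cells only."""

    imputed: CompletedDataset
    original: MixedDataset
    mask: MissingMask
    exclude_rows: np.ndarray | None = None  # outlier rows dropped from scoring

    def __post_init__(self) -> None:
        if self.imputed.data.frame.shape != self.original.frame.shape:
            raise EvaluationError("imputed and original shapes differ")
        if self.mask.entries.shape != self.original.frame.shape:
            raise EvaluationError("mask shape mismatch")

    def _scored(self, scales: tuple[str, ...]):
        """Yield (imp_values, orig_values) per scored column."""
        keep = np.ones(self.original.n, dtype=bool)
        if self.exclude_rows is not None and len(self.exclude_rows) > 0:
            keep[np.asarray(self.exclude_rows, dtype=int)] = False
        for j, v in enumerate(self.original.schema):
            if v.scale not in scales:
                continue
            cells = self.mask.column(j) & keep
            if not cells.any():
                continue
            yield (
                v,
                self.imputed.frame[v.name].to_numpy(dtype=object)[cells],
                self.original.frame[v.name].to_numpy(dtype=object)[cells],
            )


def mape(pair: EvaluationPair) -> float:
    """Mean absolute percentage error over scored continuous cells."""
    num, count = 0.0, 0
    for _, imp, orig in pair._scored(("continuous",)):
        orig = orig.astype(float)
        imp = imp.astype(float)
        if (orig == 0).any():
            raise EvaluationError("zero original cell in MAPE scope")
        num += float(np.abs((imp - orig) / orig).sum())
        count += orig.size
    if count == 0:
        raise EvaluationError("no scored continuous cells")
    return 100.0 * num / count


def nrmse(pair: EvaluationPair) -> float:
    """Variance-normalised RMSE over scored continuous cells."""
    sq, count = 0.0, 0
    for v, imp, orig in pair._scored(("continuous",)):
        orig = orig.astype(float)
        imp = imp.astype(float)
        if orig.size < 2:
            raise EvaluationError(
                f"column {v.name!r} has a single scored cell: variance undefined"
            )
        s2 = float(((orig - orig.mean()) ** 2).sum() / (orig.size - 1))
        if s2 == 0:
            raise EvaluationError(f"zero variance at scored cells of {v.name!r}")
        sq += float(((imp - orig) ** 2 / s2).sum())
        count += orig.size
    if count == 0:
        raise EvaluationError("no scored continuous cells")
    return float(np.sqrt(sq / count))


def false_classification_rate(pair: EvaluationPair) -> float:
    """Percentage of scored categorical/binary cells imputed incorrectly."""
    wrong, count = 0, 0
    for _, imp, orig in pair._scored(("binary", "categorical")):
        wrong += int((imp.astype(str) != orig.astype(str)).sum())
        count += orig.size
    if count == 0:
        raise EvaluationError("no scored categorical cells")
    return 100.0 * wrong / count


def msecor(pair: EvaluationPair, double_sum_form: bool = False) -> float:
    """Distance between original and post-imputation correlation structure.

    Default: ||R - R_tilde||_F / (D - 1) over all D continuous variables.
    ``double_sum_form=True`` reproduces the indexed double-sum variant
    (entries 1..D-1 with weight 1/(D-1)^2).  Computed on non-excluded rows.
    """
    cols = pair.original.continuous_columns
    D = len(cols)
    if D < 2:
        raise EvaluationError("need >= 2 continuous variables for MSECOR")
    keep = np.ones(pair.original.n, dtype=bool)
    if pair.exclude_rows is not None and len(pair.exclude_rows) > 0:
        keep[np.asarray(pair.exclude_rows, dtype=int)] = False
    xo = pair.original.frame.loc[keep, cols].to_numpy(dtype=float)
    xi = pair.imputed.frame.loc[keep, cols].to_numpy(dtype=float)
    if np.isnan(xo).any():
        raise EvaluationError("original data must be complete for MSECOR")
    for x in (xo, xi):
        if (x.std(axis=0) == 0).any():
            raise EvaluationError("constant column: correlation undefined")
    r = np.corrcoef(xo, rowvar=False)
    rt = np.corrcoef(xi, rowvar=False)
    if double_sum_form:
        diff = (r[: D - 1, : D - 1] - rt[: D - 1, : D - 1]) ** 2
        return float(diff.sum() / (D - 1) ** 2)
    return float(np.linalg.norm(r - rt, "fro") / (D - 1))


@dataclass
class LoadingsPair:
    """First-two principal-axis loadings before/after imputation."""

    B: np.ndarray  # (p, 2)
    B_imp: np.ndarray  # (p, 2)


def loading_rel_diff(pair: LoadingsPair) -> float:
    """100 * mean over the 2p entries of |b - b_imp| / |b|, after aligning
    each imputed column's sign with the reference (principal-axis signs are
    arbitrary).  Zero reference entries are excluded from the mean."""
    B = np.asarray(pair.B, dtype=float)
    Bi = np.asarray(pair.B_imp, dtype=float).copy()
    if B.shape != Bi.shape or B.shape[1] != 2:
        raise EvaluationError("loadings must both be p x 2")
    for c in range(2):
        if B[:, c] @ Bi[:, c] < 0:
            Bi[:, c] = -Bi[:, c]
        if not np.any(B[:, c] != 0):
            raise EvaluationError(f"loading column {c + 1} is all zero")
    nz = B != 0
    rel = np.abs(B[nz] - Bi[nz]) / np.abs(B[nz])
    return float(100.0 * rel.sum() / (2 * B.shape[0]))


@dataclass
class EstimatorReplicates:
    """Per-replicate point estimates and confidence intervals for one
    target parameter theta."""

    theta_true: float
    estimates: np.ndarray
    intervals: np.ndarray | None = None  # (R, 2) lower/upper
    level: float = 0.95

    def __post_init__(self) -> None:
        self.estimates = np.asarray(self.estimates, dtype=float)
        if self.estimates.size < 1:
            raise EvaluationError("need >= 1 replicate")
        if self.intervals is not None:
            self.intervals = np.asarray(self.intervals, dtype=float)
            if (self.intervals[:, 0] > self.intervals[:, 1]).any():
                raise EvaluationError("intervals must satisfy lower <= upper")


def estimator_summary(reps: EstimatorReplicates) -> tuple[float, float, float]:
    """(bias, variance, rmse) over replicates; variance with divisor R and
    rmse = sqrt(variance + bias^2)."""
    est = reps.estimates
    bias = float(est.mean() - reps.theta_true)
    variance = float(((est - est.mean()) ** 2).mean())
    return bias, variance, float(np.sqrt(variance + bias**2))


def coverage_rate(reps: EstimatorReplicates) -> float:
    """Fraction of confidence intervals containing theta."""
    if reps.intervals is None:
        raise EvaluationError("no intervals recorded")
    lo, hi = reps.intervals[:, 0], reps.intervals[:, 1]
    return float(np.mean((lo <= reps.theta_true) & (reps.theta_true <= hi)))


def rubin_pool(
    estimates: np.ndarray,
    within_vars: np.ndarray,
    level: float = 0.95,
    single_copy_df: float | None = None,
    complete_df: float | None = None,
) -> tuple[float, float, tuple[float, float]]:
    """Rubin's rules for m multiply-imputed estimates.

    Q_bar = mean estimate, W_bar = mean within-imputation variance,
    B = between-imputation variance (divisor m-1),
    T = W_bar + (1 + 1/m) B.  The interval uses
    nu_old = (m-1) (1 + W_bar / ((1 + 1/m) B))^2 degrees of freedom; when
    ``complete_df`` (the hypothetical complete-data df) is given, the
    Barnard-Rubin small-sample adjustment
    1/nu = 1/nu_old + 1/nu_obs is applied.  With m = 1 the single-copy t
    (or normal) interval is returned.
    """
    est = np.asarray(estimates, dtype=float)
    wv = np.asarray(within_vars, dtype=float)
    m = est.size
    if m == 0:
        raise EvaluationError("no estimates to pool")
    alpha = 1.0 - level
    q_bar = float(est.mean())
    w_bar = float(wv.mean())
    if m == 1:
        se = np.sqrt(w_bar)
        crit = (
            stats.t.ppf(1 - alpha / 2, single_copy_df)
            if single_copy_df
            else stats.norm.ppf(1 - alpha / 2)
        )
        return q_bar, w_bar, (q_bar - crit * se, q_bar + crit * se)
    b = float(((est - q_bar) ** 2).sum() / (m - 1))
    t_var = w_bar + (1.0 + 1.0 / m) * b
    if b > 0:
        nu = (m - 1) * (1.0 + w_bar / ((1.0 + 1.0 / m) * b)) ** 2
        if complete_df is not None and t_var > 0:
            gamma = (1.0 + 1.0 / m) * b / t_var
            nu_obs = (1.0 - gamma) * complete_df * (complete_df + 1) / (complete_df + 3)
            nu = 1.0 / (1.0 / nu + 1.0 / nu_obs)
    else:
        nu = np.inf
    crit = stats.t.ppf(1 - alpha / 2, nu) if np.isfinite(nu) else stats.norm.ppf(1 - alpha / 2)
    se = np.sqrt(t_var)
    return q_bar, float(t_var), (q_bar - crit * se, q_bar + crit * se)


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise EvaluationError("confusion counts must be >= 0")


def f1_accuracy(counts: ConfusionCounts) -> tuple[float, float]:
    """(accuracy, F1) = ((TP+TN)/total, 2TP/(2TP+FP+FN))."""
    total = counts.TP + counts.TN + counts.FP + counts.FN
    if total == 0:
        raise EvaluationError("empty confusion matrix")
    denom = 2 * counts.TP + counts.FP + counts.FN
    if denom == 0:
        raise EvaluationError("F1 undefined: no positives anywhere")
    return (counts.TP + counts.TN) / total, 2 * counts.TP / denom


def t_interval(values: np.ndarray, level: float = 0.95) -> tuple[float, float, tuple[float, float]]:
    """Mean, variance-of-the-mean and t confidence interval of a sample."""
    x = np.asarray(values, dtype=float)
    n = x.size
    mean = float(x.mean())
    var_mean = float(x.var(ddof=1) / n)
    crit = stats.t.ppf(1 - (1 - level) / 2, n - 1)
    half = crit * np.sqrt(var_mean)
    return mean, var_mean, (mean - half, mean + half)


__all__ = [
    "EvaluationPair",
    "LoadingsPair",
    "EstimatorReplicates",
    "ConfusionCounts",
    "mape",
    "nrmse",
    "msecor",
    "false_classification_rate",
    "loading_rel_diff",
    "estimator_summary",
    "coverage_rate",
    "rubin_pool",
    "f1_accuracy",
    "t_interval",
    "EvaluationError",
]
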