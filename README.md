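# impbench

Benchmarking missing-data imputation under outliers and misclassification.

Practitioners imputing survey, industrial or biomedical tables rarely face
clean elliptical data: real tables carry high-leverage outliers and
misrecorded categories, and a non-robust imputer fitted to such data can
produce arbitrarily distorted completions.  `impbench` bundles, behind one
mixed-type data model, the classical and robust imputers used to study this
problem, the amputation mechanisms that create benchmark missingness, the
evaluation statistics, and config-driven simulation harnesses that measure
how each method degrades as contamination grows.

## What is inside

**Imputers** (all preserve observed cells; donor methods impute only
observed values):

- mean / median / mode, random hotdeck, k-nearest-neighbour with Gower
  distance (k = 5, median/mode aggregation);
- **PMM** — Bayesian-regression predictive mean matching: β̂ by least
  squares, β* ~ N(β̂, σ*²(XᵀX)⁻¹) with σ*² from the scaled inverse-χ²
  posterior, donors matched on predicted values, m multiply-imputed copies;
- **midastouch** — all observed cases are donors; donor *i* imputes
  recipient *j* with probability ω_i·d_ij^(−κ) / Σ ω·d^(−κ), where ω are
  bootstrap frequencies, d_ij = |(x_i − x_j)β̂*| and
  κ(R²) = (50·R² / (1 + δ − R²))^(3/8);
- **IRMI** — iterative robust model-based imputation: chained regressions
  with scale-appropriate fits (high-breakdown MM regression for continuous
  responses, logistic/multinomial for binary/categorical, robustified
  Poisson for counts, two-stage spike models for semicontinuous variables),
  iterated to stabilisation, plus a final stochastic pass whose residual
  draw is inflated by √(1 + #m_l/n);
- iterative random-forest imputation and bootstrap boosted-tree imputation
  with predictive-mean matching.

**Contamination and amputation**: the bivariate AGE/INCOME population with
four-corner high-leverage outliers; the lognormal machine-energy model
energy = exp(2 + I(type=1) − 0.1·log runtime + ε) with type
misclassification; robust MCD/Mahalanobis outlier flagging; exact-count
MCAR and rank-weighted monotone MAR amputation that never touches
outlier rows.

**Evaluation**: MAPE, NRMSE (variance-normalised at the scored cells),
MSECOR (‖R − R̃‖_F/(D−1)), false-classification rate, PCA-loading relative
difference, bias/variance/RMSE of estimators, confidence-interval coverage,
Rubin's rules with Barnard–Rubin degrees of freedom, accuracy/F1.

**Studies** (`impbench.study_runner`): the outlier study, the
misclassification study, the precision study (10% MCAR per variable,
MCD-protected), and the classification study (hold-out F1 after train-set
amputation), all with common random numbers across methods and full
per-replicate output tables.

## Worked example

Simulate the income population, add 20 leverage outliers, ampute 30% of
INCOME under MAR on AGE (outliers protected), impute, and estimate the mean
income of the regular rows:

```python
import numpy as np
from impbench import (
    IncomeSimSpec, simulate_income, inject_leverage_outliers, ampute_mar,
    irmi_impute, pmm_impute, rubin_pool,
)

spec = IncomeSimSpec()                       # N((40, 1500), [[10, 44], [44, 300]])
truth = simulate_income(spec, seed=7)
data, flags = inject_leverage_outliers(truth, k=20, spec=spec, seed=7)
amputed, mask = ampute_mar(data, target="INCOME", driver="AGE", rate=0.30,
                           protected=flags.outlier_rows, seed=7)
print("missing INCOME cells:", mask.per_column_counts[1])

regular = np.setdiff1d(np.arange(spec.n), flags.outlier_rows)
for name, result in [("IRMI", irmi_impute(amputed, mask, seed=7, multiple=5)),
                     ("PMM", pmm_impute(amputed, mask, m=5, seed=7))]:
    ests = [c.frame["INCOME"].to_numpy()[regular].mean() for c in result]
    wvars = [c.frame["INCOME"].to_numpy()[regular].var(ddof=1) / regular.size
             for c in result]
    q, T, (lo, hi) = rubin_pool(np.array(ests), np.array(wvars),
                                complete_df=regular.size - 1)
    print(f"{name}: mean income {q:.1f}, 95% CI ({lo:.1f}, {hi:.1f})")
```

Output:

```
missing INCOME cells: 54
IRMI: mean income 1498.6, 95% CI (1496.0, 1501.3)
PMM: mean income 1493.3, 95% CI (1480.0, 1506.7)
```

The true mean is 1500.  With 20 outliers present, the robust IRMI
completion keeps the pooled estimate tight around the truth, while PMM —
whose regression and donor pool absorb the outliers — is already visibly
noisier; at higher contamination its RMSE grows several-fold while IRMI's
stays flat (see the study harness).

A shell interface mirrors the library:

```bash
impbench simulate --setting income --n 200 --contaminate 20 --seed 1 \
    --out data.csv --schema-out schema.yaml --flags flags.json
impbench impute --method irmi --m 5 --in data.csv --schema schema.yaml \
    --seed 1 --out-prefix imp_
impbench study --config study.yaml --out results/
```

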