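# Methods

This note records the statistical models implemented in `impbench`, the
parameter choices that matter, what the synthetic generators emulate, the
numerical details, and the open design choices we resolved.

## Data model

A dataset is a rectangular table with a per-column scale declaration:
`continuous`, `semicontinuous` (a spike at a declared constant, usually 0,
mixed with a continuous part), `binary`, `categorical`, or `count`.
Categorical values are stored as string labels, never integer codes, so no
imputer can silently treat them as ordinal.  Missingness is represented by
the indicator matrix M (m_ij = 1 where cell (i,j) is missing); every
imputer receives (data, mask) and must return completions whose observed
cells are bit-identical to the input — enforced by `check_preservation`
and asserted throughout the test suite.  In CSV form both the empty field
and the literal `NA` parse as missing; files are written with empty fields.
Row and column indices in reports are 1-based.

## Synthetic populations

**Income setting.** (AGE, INCOME) ~ N((40, 1500), Σ).  The covariance
parameters (10, 44; 44, 300) admit two readings, both constructible via
`IncomeSimSpec`:

- `raw` (default): Σ = [[10, 44], [44, 300]], correlation 0.80.  Outlier
  centers μ ± 0.8·diag(Σ) = (40 ± 8, 1500 ± 240) then sit ~2.5σ out in AGE
  — genuine high-leverage points that overlap the regular AGE range, so
  that donor methods (kNN, hotdeck, PMM) can actually pick them up.  This
  reading reproduces the qualitative degradation of every non-robust
  imputer that the study design targets.
- `elementwise`: Σ = [[100, 1936], [1936, 90000]], correlation 0.645, with
  centers (40 ± 80, 1500 ± 72000).  Under this reading the outliers are so
  remote (8σ in AGE, 240σ in INCOME) that Gower-based donor selection never
  touches them and non-robust intervals inflate instead of mis-covering;
  we keep it available but it is not the study default.

Outliers replace k uniformly chosen rows with draws centred at one of the
four sign-combination corners, with scatter Σ/5.  By default one corner is
drawn **per replicate** (`outlier_placement="per_replicate"`), making the
contamination directional within a replicate — the regime in which
non-robust imputers both inflate RMSE and lose coverage;
`"per_outlier"` draws a corner independently per row (symmetric
contamination).

**Energy setting.**  type ~ Bernoulli(0.4), runtime ~ Exponential(rate
1/100), and energy = exp(2 + I(type=1) − 0.1·log runtime + ε) with
ε ~ N(0, 0.1) *inside* the exponent: the energy/runtime relationship is
lognormal, and the study log-transforms energy and runtime before
imputation.  Misclassification flips the recorded type of k distinct rows.
The estimand is the type-1 group mean of log-energy; its closed form is
3 − 0.1·(log 100 − γ) ≈ 2.5972 (γ the Euler–Mascheroni constant).

**What the generators do not emulate:** real tables with skewed marginals,
nonlinear relations, clustered or weighted designs, MNAR mechanisms, or
more than one contaminated variable at a time.  Passing the simulation
studies therefore demonstrates behaviour under idealised elliptical data
with a single contamination mode, not performance on arbitrary real data.

## Amputation

Amputation uses exact counts — per column, round(rate·n_eligible) cells,
rounding half up — rather than independent Bernoulli draws, so a printed
rate like 30% is hit exactly in every replicate and small-sample tests
carry no extra variance.  MCAR samples uniformly without replacement; MAR
samples without replacement with selection weight proportional to the rank
of the driver (AGE for income, log-runtime for energy), giving a monotone
mechanism with exactly the requested rate.  A constant driver degrades to
MCAR.  Rows flagged as outliers or misclassified are never amputed: a
method must not look good by imputing an outlier with an outlier value.
Outlier flagging uses MCD location/scatter on the continuous columns and a
χ² cutoff at probability 0.99 with df = (number of continuous variables) −
1 by default (df configurable; the df = p convention is one flag away).

## Imputers

**PMM.**  Bayesian regression draw under the noninformative prior:
σ*² = RSS/χ²_{n−q}, β* ~ N(β̂, σ*²(XᵀX)⁻¹).  Matching: donors scored with
β̂ and recipients with β* (`matchtype=1`, the mice default used for the
reference results); `matchtype=2` scores both sides with β*.  Each missing
cell copies the observed value of one of the k = 5 closest donors, chosen
uniformly; m = 5 copies by default.  With several incomplete variables a
chained loop runs (median/mode initialisation, ascending missing count,
5 cycles).  Categorical targets use a logistic/multinomial fit on a
bootstrap resample with matching on predicted class-probability vectors.

**Midastouch.**  Per copy: bootstrap the donors (approximate Bayesian
bootstrap), take resample frequencies as ω, fit on the resample for β*,
set d_ij = |ŷ_i − ŷ_j|, κ = κ(R²) with δ = 1e−4 guarding R² = 1, and
sample one donor per recipient with probability ∝ ω_i·d_ij^(−κ).
Zero-distance donors absorb all mass, split equally.  The leave-one-out
β̂*₋ᵢ of the exact formulation is approximated by the single per-copy
bootstrap fit (donors absent from the resample have ω = 0); exact
per-donor refits are quadratic cost.  A degenerate bootstrap draw
(constant resampled response) falls back to ω-only sampling; a constant
observed response is an error.

**IRMI.**  Initialise by kNN; order variables by descending missing count;
cycle robust fits until the summed squared change of the imputed values is
below δ_conv = 1e−4 for every continuous variable (categorical: fraction
changed below δ_conv), max 10 iterations; then one stochastic pass per
copy re-runs the cycle adding a residual draw ε* with the robust residual
scale times √(1 + #m_l/n).  The inflation constant's printed form is
ambiguous; we use the reading that grows with the number of missing
responses (configurable, including off).  Per-variable fit seeds are held
fixed across iterations so that refitting unchanged data returns the
identical fit — otherwise the elemental-set randomness of the MM search
would block convergence.  Count responses are drawn Poisson(μ̂) in the
stochastic pass; binary/categorical responses are drawn from predicted
class probabilities.  Stepwise AIC model selection is a declared stub
(off); per-variable user formulas are out of scope.

**MM regression** (the continuous robust fit).  Stage 1: 50 random
elemental starts, each refined by two concentration steps, scored by the
trimmed sum of squared residuals over h = ⌊(n+q+1)/2⌋ points; the best
start supplies the coefficients and the robust scale (1.4826·MAD of its
residuals).  Stage 2: IRWLS with the Tukey bisquare ρ at c = 4.685 (~95%
Gaussian efficiency) and fixed scale, to coefficient tolerance 1e−10 or 50
iterations.  A (near-)exact fit on the majority (scale ≈ 0) short-circuits
to least squares on the zero-residual rows, so noise-free data reproduce
OLS exactly.  This estimator is written in the package because no
installed Python library provides a high-breakdown bounded-influence
linear fit; the non-robust variant (`robust=False`) is plain OLS and is
used as the contrast in robustness tests.

**Forest / boosted imputation.**  The forest imputer is the iterative
scheme (mean/mode initialisation, per-variable forest refits, per-scale
convergence criteria: relative summed squared change for continuous,
fraction changed for categorical, both against δ = 1e−4, max 10
iterations) over sklearn random forests (100 trees default).  The boosted
imputer fits an XGBoost model per variable on a bootstrap resample of the
observed rows and imputes by predictive mean matching (k = 5), so imputed
values always come from the observed support; m copies from independent
bootstraps; classes are matched on predicted class-probability vectors.

## Estimation and pooling

Studies estimate a mean (income) or a group mean (log-energy) on the
non-contaminated rows only — contamination affects the imputation step,
never the estimand.  Single completions get the t-interval of the
completed sample; multiple completions are pooled by Rubin's rules
(T = W̄ + (1 + 1/m)B) with the Barnard–Rubin small-sample degrees of
freedom when the complete-data df is known (the harness passes n − 1).
The complete-case baseline is the plain observed-case mean/t-interval; a
MAR-consistent two-phase regression estimator
(ȳ_obs + b(x̄_all − x̄_obs), variance S_e²/r + (S_y² − S_e²)/n) is
available via `mar_adjusted_complete_case=True` and is the variant that
attains nominal coverage under the rank-MAR mechanisms, since the plain
observed mean is biased when missingness follows the driver.

## Evaluation statistics

MAPE and NRMSE score only the amputed cells; NRMSE's normalising variance
s²_j is computed over the originally missing cells of column j with
divisor Σm_ij − 1.  MSECOR uses the Frobenius-norm form
‖R − R̃‖_F/(D − 1) over all D continuous variables (the indexed
double-sum variant of the same quantity is available behind a flag; the
two printed forms disagree and the norm form uses every variable), and is
computed on non-outlier rows.  Loading comparisons sign-align each column
pair before differencing (principal-axis signs are arbitrary) and exclude
zero reference entries.  Estimator summaries use divisor R for the
variance so RMSE² = variance + bias² holds exactly.

## Study harness

Per replicate, every method consumes the same simulated data and the same
mask (common random numbers), so method contrasts are paired; per-method
imputation seeds derive from (base_seed, contamination, replicate, method
position) through numpy `SeedSequence` spawn keys, and a rerun with the
same config reproduces every table bit-for-bit.  Default replications are
1000; the bundled tests run 200–500 replicates on grids {0, 20, 40} /
{0, 40}, which resolves the orderings of interest at Monte-Carlo error of
a few percent, and the acceptance script uses 1500 replicates for the
coverage estimate (MC standard error ~0.006).  Study
defaults for tree methods are scaled to 50 trees / 50 rounds.

## Known limitations

- PMM's coverage is slightly below nominal (~0.93–0.95 at 500 replicates)
  under the strong rank-MAR mechanism — the known fixed-donor-pool
  undercoverage of PMM, not an implementation artefact.
- IRMI's bisquare weight at a ±1 type-flip residual (~3.2σ in the energy
  model) is ≈ 0.29, so heavy misclassification still leaves a small
  attenuation bias; PMM's donor matching is partially self-robust in that
  specific setting and can match IRMI's coverage there.
- Under symmetric (four-corner) leverage contamination the completed-data
  variance inflates at least as fast as the estimate biases, so non-robust
  methods lose coverage gradually (to ~0.5–0.9) rather than collapsing to
  zero; directional contamination is the harsher and default regime.
- The midastouch Parzen variance correction and the deep-learning imputer
  of the wider literature are out of scope; hotdeck is the random variant
  (no ordering/domain variables); MNAR and multivariate amputation
  patterns beyond per-column MCAR / single-target MAR are not provided.
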