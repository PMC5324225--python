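# Methods

## Problem setting

Risk models for binary clinical outcomes are usually fitted by maximum
likelihood (ML) logistic regression. When the training data are small or the
outcome is rare — events-per-variable (EPV) below about 10 — two linked
pathologies appear. First, *separation*: a binary predictor level that
contains only events (or only non-events) makes the likelihood monotone in
that coefficient, so the MLE is infinite and iterative fitting either fails
or wanders off. Second, *overfitting*: even when the MLE exists, the fitted
linear predictor is too spread out, so external predictions are too extreme
(calibration slope below 1). This package implements and compares the
standard remedies — Firth's bias-reduced fit, logF(m,m) penalization, and
ridge — together with the validation metrics and simulation designs needed
to quantify the trade-offs.

## Estimators

All four fitters maximize an objective of the form `l(β) − pen(β)` with a
damped Newton method (details below).

**MLE.** `pen = 0`. Convergence is declared when the maximum absolute
coefficient update falls below `tol` within `max_iter` iterations *and* every
|β̂_j| is below the divergence guard (default 15 on the log-odds scale; a
log odds ratio of e¹⁵ ≈ 3×10⁶ has no clinical meaning, so anything beyond it
is treated as a diverging monotone likelihood). Non-convergence is reported
via a flag with the last iterate retained, never as an exception — the
failure *rate* is itself a quantity of interest in the simulations.

**Firth.** `l(β) + ½ log|I(β)|`, the Jeffreys-prior penalty, fitted with the
modified score `U*_j = Σ_i x_ij (y_i − π_i + h_i(½ − π_i))` where `h_i` are
the hat-matrix diagonals of the weighted design. Removes the O(n⁻¹) bias of
the MLE and keeps estimates finite under complete separation. The penalty
covers the **whole** coefficient vector, intercept included; this is
deliberate and is what produces the documented upward bias in the average
predicted probability (APP) at low prevalence — the Jeffreys prior shrinks
the fitted probabilities towards ½. On a saturated 2×2 design the Firth
estimate is exactly the add-½-to-every-cell log odds ratio, which the test
suite exploits as a closed-form oracle.

**logF(m,m).** `l(β) + Σ_j [m β_j/2 − m ln(1+e^{β_j})]` over non-intercept
coefficients. The penalty is the log-density of a logF(m,m) prior,
equivalent to augmenting the data with m pseudo-observations per penalized
coefficient (one half-weight success and one half-weight failure at
`x_j = 1`, all other columns 0); the tests verify this equivalence against
an independent weighted-GLM fit. `m = 0` reproduces the MLE; `m ≥ 1` keeps
estimates finite under separation; shrinkage is O(1/m). The intercept is
**unpenalized**, so the intercept score equation `Σ(y_i − π_i) = 0` holds at
the optimum and the training-set APP equals the event proportion exactly.
Default degrees of freedom in the comparison pipeline: m ∈ {1, 2}.

**Ridge.** `l(β) − λ₂ Σ_j β_j²` over non-intercept coefficients, on an
internally standardized scale: non-intercept columns are centered and scaled
to unit sample SD before penalization (this makes λ₂ comparable across
designs) and coefficients are mapped back to the original scale afterwards.
λ₂ is selected from a grid (default 25 log-spaced points in [10⁻⁴, 10³]) by
minimizing the mean out-of-fold binomial deviance over 10 outcome-stratified
folds, then refitting on the full data. A ridge fit is recorded as a
convergence failure when the final refit fails the Newton criteria or every
candidate λ₂ fails in at least one fold; single-class folds are skipped with
a warning. Ridge failure percentages are strongly implementation-dependent
(they hinge on the software's convergence test), so the package reports its
own rates without treating any published rate as a reference.

## Newton core and numerics

One shared optimizer: full Newton steps with up to 10 step-halvings per
iteration to keep the (penalized) log-likelihood non-decreasing;
`tol = 1e-8` on the maximum absolute coefficient update; `max_iter = 50`.
Log-likelihoods use `log1p`-safe forms (`y·η − logaddexp(0, η)`), so large
linear predictors do not overflow. A numerically singular information matrix
terminates the iteration with the last iterate and a non-convergence flag
(this only happens on diverging ML fits). Rank-deficient designs — including
a constant non-intercept column, which is collinear with the intercept —
raise an explicit error rather than being silently dropped.

## Separation diagnostics

Each binary predictor is cross-tabulated against the outcome. One empty
cell ⇒ quasi-complete separation; a level predicting both classes perfectly
(both discordant cells empty) ⇒ complete. Separation caused by continuous
predictors or linear combinations is out of scope (a linear-programming test
would be needed); in the simulation designs the binary covariate is the
separating one by construction.

## Validation metrics

Computed on an independent test set from the fitted coefficients, with no
recalibration step:

* **calibration slope** — ML logistic refit of the test outcome on the
  prognostic index `η = β̂ᵀx` (with intercept). 1 = perfect, <1 =
  overfitting, >1 = underfitting. Undefined (flagged, excluded from
  summaries) for a constant index, a single-class outcome, or a
  non-convergent refit.
* **AUC** — Mann–Whitney concordance with ½ credit for ties; invariant to
  strictly increasing transforms of the risk score.
* **Brier score** — mean (y − p̂)²; reported as its square root (rBS) for
  interpretability.
* **APP** — mean predicted probability; compared with the design prevalence
  to expose intercept-penalty bias.

## Simulation designs

**Coefficient recovery (design "series1").** X₁ ~ N(0,1), X₂ ~ Bern(0.5),
true slopes 0.30 and 0.9, n = 120. The intercept is calibrated by bisection
so the Monte-Carlo mean of `expit(β₀ + 0.3X₁ + 0.9X₂)` (10⁶ draws, fixed
calibration seed) hits a target prevalence in {5.5, 11.5, 20.4, 39.6,
59.9}% ; the calibrated β₀ for 5.5% is −3.421. At the low-prevalence end
roughly one replicate in seven has an empty event-by-X₂ cell (an analytic
computation gives 14.4%), so separation behaviour is exercised heavily.
Recorded per replicate: coefficient estimates, convergence, separation
status. Aggregates: mean, SD, relative bias (%) = 100·(mean − true)/true,
MSE, Monte-Carlo error.

**Predictive performance (designs "series2_weak"/"series2_strong").**
X₁..X₃ ~ N(0,1), X₄ ~ Bern(0.2), X₅ ~ Bern(0.6), all independent. Weak
model β = (−1.5, 0.2, 0.5, −0.03, 0.05, −0.6) (implied prevalence ≈ 0.152);
strong model β = (−3.5, 1.2, −0.9, 0.9, 1.2, 1.2) (≈ 0.162). Training size
from the EPV rule `n = ⌈EPV·p/prev⌉` with p = 5 predictors and prev fixed
at 0.15, reproducing n ∈ {67, 100, 167, 334} for EPV ∈ {2, 3, 5, 10}; test
sets of 1000 are drawn independently from the same true model. Metrics are
computed only for replicates where the training fit converged, each method
excluded per-method.

**Resample design ("resample").** Covariate rows are drawn with replacement
from any supplied table; outcomes are simulated from a user-supplied "true"
coefficient vector whose intercept is overridden to pin the average
prevalence; the test set is m× the table size (default m = 2). The packaged
default table is `synthetic_echo_table()`: 558 fully simulated rows with
marginals plausible for a suspected coronary-artery-disease cohort (age,
baseline/dobutamine ejection fractions, four binary history/test
indicators). It is a synthetic stand-in — no patient data — so absolute
results on it characterize the method, not any real cohort. An optional
multiplier can inflate one binary coefficient to provoke separation
(default 1 = off, since no canonical magnitude exists).

**Seed discipline.** A root seed spawns a `SeedSequence` substream per
(design, replicate, purpose ∈ {covariates, outcomes, cv-folds,
test-covariates, test-outcomes}), so every replicate is bit-reproducible,
train and test never share a stream, and the ridge CV fold shuffle has its
own stream.

## Aggregation

Summaries are computed **only over converged replicates**; a replicate-level
exception is caught, logged with its seed, and counted as a convergence
failure for that method alone. Monte-Carlo error of a summary mean is the
sample SD divided by √(number of converged replicates). Raw per-replicate
tables are written at full precision alongside the rounded summaries, and
the figure reference lines (MLE medians) are recomputed from the raw values.

## What the generators do and do not emulate

The synthetic designs use independent predictors, correctly specified
models, and Bernoulli outcomes — separation and low EPV are the only
stresses. They do not emulate correlated predictors, model misspecification,
measurement error, missing data, or case-mix differences between training
and validation populations, so passing results bound what the estimators do
under clean sparsity, not their behaviour on arbitrary real cohorts.

## Default problem sizes

Simulation comparisons default to 1000 replicates per scenario (Monte-Carlo
error on a calibration-slope mean ≈ 0.01 at EPV 2); exploratory work and the
README example use 200, with correspondingly wider Monte-Carlo bands. The
intercept calibration uses 10⁶ Monte-Carlo draws.

## Known limitations

* No standard errors or confidence intervals for the penalized fits.
* No lasso/elastic-net (variable selection is a different objective), and no
  survival-time extensions.
* Separation detection covers binary predictors only.
* The MLE non-convergence *rate* depends on the guard/update criteria; other
  software using a log-likelihood-change test will flag a somewhat smaller
  subset of quasi-separated fits (see the guard discussion above).
* Ridge CV failure rates are likewise criterion-dependent and should not be
  compared across implementations.
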