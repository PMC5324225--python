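# sparselogit

Penalized logistic regression and risk-prediction validation for **small or
sparse binary data** — the regime where events-per-variable (EPV) is low and
a binary predictor can *separate* the outcome, so plain maximum-likelihood
(ML) logistic regression diverges or produces badly overfitted risk models.

The package is aimed at biostatisticians and methodologists who develop or
evaluate clinical risk models at low EPV: it provides the estimators, the
external-validation metrics, and a Monte-Carlo simulation harness for
comparing them.

## What it implements

For the model `logit(π_i) = βᵀx_i`, four estimation schemes:

| method | objective maximized | intercept penalized? |
|---|---|---|
| MLE | `l(β)` | — |
| Firth | `l(β) + ½ log|I(β)|` | yes (full Jeffreys prior) |
| logF(m,m) | `l(β) + Σ_j [m β_j/2 − m ln(1+e^{β_j})]` | no |
| ridge | `l(β) − λ₂ Σ_j β_j²`, λ₂ by 10-fold CV deviance | no |

All share a damped-Newton core with step-halving. ML fits carry a
divergence guard (any |β̂_j| > 15 while the update criterion is unmet ⇒
flagged non-convergent, last iterate retained), which operationalizes
separation-driven failure. Firth estimates stay finite under complete
separation; logF(m,m) is equivalent to adding `m` pseudo-observations per
penalized coefficient and reduces to the MLE at `m = 0`. The logF
intercept is never penalized, so the mean fitted probability equals the
observed event proportion — the Firth fit, whose Jeffreys penalty covers
the intercept, instead biases the average predicted probability (APP)
towards 0.5.

Around the estimators:

* **separation diagnostics** — cross-tabulation of every binary predictor
  against the outcome (quasi-complete = one empty cell, complete = a level
  that perfectly predicts both classes);
* **validation metrics** — calibration slope (logistic refit of the test
  outcome on the prognostic index; 1 = perfect, <1 = overfitting), AUC
  (Mann–Whitney concordance), Brier score and its root, APP;
* **simulation designs** — (a) a coefficient-recovery design (one normal and
  one Bernoulli(0.5) predictor, slopes 0.30/0.9, n=120, intercept calibrated
  by Monte-Carlo bisection to prevalences 5.5–59.9%); (b) a predictive-
  performance design (three normal + Bernoulli(20%)/Bernoulli(60%)
  predictors, weak or strong coefficient vectors, training size from the
  EPV rule `n = ⌈EPV·p/prev⌉`, independent test sets of 1000); (c) a generic
  resample-from-covariate-table design with a packaged *synthetic* stress-
  echo-style table of 558 rows;
* **a scenario runner** aggregating per-replicate estimates/metrics into
  tables of mean, SD, relative bias (%), MSE, Monte-Carlo error and
  convergence-failure rates — always over converged replicates only — plus
  boxplot figures.

## Worked example

```python
import numpy as np
from sparselogit import *

# quasi-complete separation: level A has 10 events / 0 non-events, level B 2 / 8
x = np.array([1.0]*10 + [0.0]*10)
y = np.array([1.0]*10 + [1.0]*2 + [0.0]*8)
data = make_dataset(x[:, None], y, kinds=["binary"], names=("x",))
print(detect_separation(data).status.value)      # quasi_complete
for label, res in [("MLE", fit_mle(data)), ("Firth", fit_firth(data)),
                   ("logF(1,1)", fit_logf(data, m=1))]:
    print(f"{label:10s} slope={res.beta[1]: .3f}  converged={res.converged}")
```

```
MLE        slope= 38.589  converged=False
Firth      slope= 4.268  converged=True
logF(1,1)  slope= 4.087  converged=True
```

The ML slope is diverging towards +∞ (the guard flags it); Firth returns
exactly the half-cell-corrected log-odds ratio ln(10.5·8.5 / (0.5·2.5)) =
4.268, and logF(1,1) a slightly stronger shrinkage.

A small simulation (weak-signal model, EPV = 2, 200 replicates):

```python
cfg = ScenarioConfig(design="series2_weak", epv=2, n_reps=200, base_seed=7)
res = run_scenario(cfg, methods=["mle", "firth", "logf1"])
print(res.summary[res.summary.key == "calibration_slope"]
      [["method", "mean", "sd", "failure_rate_pct"]])
```

```
method     mean       sd  failure_rate_pct
   mle 0.328302 0.251466              11.0
 firth 0.380330 0.285361               0.0
 logf1 0.353047 0.262540               0.0
```

A mean calibration slope of 0.33 for MLE means its risk predictions are
severely overfitted at EPV 2 (a slope of 1 is ideal); the penalized fits
improve it and never fail to converge. In the same run the mean APP is
0.157 (MLE), 0.178 (Firth), 0.153 (logF(1,1)) against a design prevalence
of 0.152 — the Firth intercept penalty visibly inflates APP while logF
tracks the truth.

A command-line interface mirrors the library:

```bash
sparselogit fit train.csv --outcome y --method firth --out coef.csv
sparselogit validate coef.csv test.csv --outcome y
sparselogit simulate --design series2_weak --epv 2 --reps 1000 --seed 1 --out report/
```

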