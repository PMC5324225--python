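"""Synthetic-data generators for the simulation designs.

Three designs are provided:

* ``series1`` — coefficient-recovery design: one standard-normal and one
  Bernoulli(0.5) predictor, true slopes 0.30 and 0.9, n=120, with the
  intercept calibrated by Monte Carlo so the marginal event prevalence hits
  a target in {5.5, 11.5, 20.4, 39.6, 59.9}%. At the low-prevalence end the
  binary predictor induces quasi-complete separation in a nontrivial
  fraction of replicates, which is the phenomenon of interest.
* ``series2_weak`` / ``series2_strong`` — predictive-performance design:
  three standard-normal and two Bernoulli (20%, 60%) predictors, training
  size driven by events-per-variable (EPV), an independent test set of 1000
  drawn from the same true model.
* ``resample`` — generic resample-from-covariate-table design: covariate
  rows are drawn with replacement from any supplied table and outcomes are
  simulated from a fitted "true" model with an overridden intercept; a
  synthetic 558-row stand-in for a stress-echocardiography cohort is
  packaged as the default table.

Seed discipline: a root seed spawns independent substreams per
(design, replicate, purpose), so each replicate is bit-reproducible and the
train and test draws never share a stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import ceil
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .fit import BinaryDataset, SeparationReport, detect_separation, make_dataset

# --- study-condition constants -------------------------------------------

SERIES1_SLOPES = (0.30, 0.9)
SERIES1_N = 120
SERIES1_PREVALENCES = (0.055, 0.115, 0.204, 0.396, 0.599)
SERIES1_SPEC = (("normal",), ("bernoulli", 0.5))

WEAK_BETA = (-1.5, 0.2, 0.5, -0.03, 0.05, -0.6)
STRONG_BETA = (-3.5, 1.2, -0.9, 0.9, 1.2, 1.2)
SERIES2_SPEC = (
    ("normal",),
    ("normal",),
    ("normal",),
    ("bernoulli", 0.2),
    ("bernoulli", 0.6),
)
SERIES2_N_TEST = 1000
SERIES2_PREV = 0.15  # prevalence used in the n = EPV*p/prev sample-size rule

_DESIGN_CODES = {"series1": 1, "series2_weak": 2, "series2_strong": 3, "resample": 4}
_PURPOSES = {"covariates": 0, "outcomes": 1, "cv_folds": 2,
             "test_covariates": 3, "test_outcomes": 4}


def substream(base_seed: int, design: str, rep_id: int, purpose: str) -> np.random.Generator:
    """Independent, replayable RNG stream for one (design, rep, purpose)."""
    ss = np.random.SeedSequence(
        [int(base_seed), _DESIGN_CODES[design], int(rep_id), _PURPOSES[purpose]]
    )
    return np.random.default_rng(ss)


def cv_fold_seed(base_seed: int, design: str, rep_id: int) -> int:
    """31-bit integer seed for fold shuffling, from its own substream."""
    return int(substream(base_seed, design, rep_id, "cv_folds").integers(2**31 - 1))


@dataclass
class ScenarioConfig:
    """Declarative description of one simulation scenario."""

    design: str
    true_beta: tuple[float, ...] = ()
    prevalence_target: float | None = None
    n_train: int | None = None
    epv: float | None = None
    n_test: int = SERIES2_N_TEST
    n_reps: int = 1000
    base_seed: int = 0
    predictor_spec: tuple = ()
    sep_multiplier: float = 1.0  # optional separation-inducing coefficient inflation

    def __post_init__(self):
        if self.design not in _DESIGN_CODES:
            raise ValueError(f"unknown design {self.design!r}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if (self.n_train is None) == (self.epv is None):
            raise ValueError("exactly one of n_train / epv must be set")
        if self.design == "series1":
            if self.prevalence_target is None:
                raise ValueError("series1 needs a prevalence_target")
            if not self.true_beta:
                self.true_beta = SERIES1_SLOPES  # slopes; intercept calibrated
            if not self.predictor_spec:
                self.predictor_spec = SERIES1_SPEC
        elif self.design in ("series2_weak", "series2_strong"):
            if not self.true_beta:
                self.true_beta = (
                    WEAK_BETA if self.design == "series2_weak" else STRONG_BETA
                )
            if not self.predictor_spec:
                self.predictor_spec = SERIES2_SPEC
        if self.prevalence_target is not None and not (0 < self.prevalence_target < 1):
            raise ValueError("prevalence_target must be in (0, 1)")

    def resolve_n_train(self) -> int:
        if self.n_train is not None:
            return self.n_train
        prev = self.prevalence_target if self.prevalence_target is not None else SERIES2_PREV
        n = epv_to_n(self.epv, len(self.predictor_spec), prev)
        if n < len(self.predictor_spec) + 1:
            raise ValueError("derived n_train smaller than number of coefficients")
        return n

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("true_beta", "predictor_spec"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(
                    tuple(v) if isinstance(v, (list, tuple)) else v for v in raw[key]
                )
        return cls(**raw)


@dataclass
class ReplicatePair:
    """Train/test datasets drawn from one true model, plus bookkeeping."""

    train: BinaryDataset
    test: BinaryDataset | None
    separation: SeparationReport
    rep_id: int
    seed_used: int


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def draw_covariates(spec: Sequence, n: int, rng: np.random.Generator) -> np.ndarray:
    cols = []
    for item in spec:
        kind = item[0]
        if kind == "normal":
            cols.append(rng.standard_normal(n))
        elif kind == "bernoulli":
            cols.append(rng.binomial(1, item[1], n).astype(float))
        else:
            raise ValueError(f"unknown predictor kind {kind!r}")
    return np.column_stack(cols)


def spec_kinds(spec: Sequence) -> list[str]:
    return ["continuous" if s[0] == "normal" else "binary" for s in spec]


def epv_to_n(epv: float, n_predictors: int, prev: float) -> int:
    """Training size from the events-per-variable rule n = EPV * p / prev."""
    if prev <= 0:
        raise ValueError("prevalence must be positive")
    if epv <= 0 or n_predictors <= 0:
        raise ValueError("epv and n_predictors must be positive")
    return ceil(epv * n_predictors / prev)


def calibrate_intercept(
    slopes: Sequence[float],
    predictor_spec: Sequence,
    target_prev: float,
    mc_size: int = 1_000_000,
    seed: int = 20_170_223,
) -> float:
    """Intercept beta0 such that E[expit(beta0 + slopes.x)] = target_prev.

    The expectation is a Monte-Carlo mean over ``mc_size`` covariate draws
    and is monotone increasing in beta0, so the root is found by Brent
    bisection, widening the bracket if needed. Accurate to ~1e-10 on the MC
    surrogate (the MC error of the implied prevalence is O(mc_size^-1/2)).
    """
    if not (0 < target_prev < 1):
        raise ValueError("target_prev must be in (0, 1)")
    if mc_size < 10**5:
        raise ValueError("mc_size must be at least 1e5 for a stable calibration")
    rng = np.random.default_rng(seed)
    X = draw_covariates(predictor_spec, mc_size, rng)
    lin = X @ np.asarray(slopes, dtype=float)

    def gap(b0):
        return float(np.mean(expit(b0 + lin))) - target_prev

    lo, hi = -5.0, 5.0
    for _ in range(10):
        if gap(lo) < 0 < gap(hi):
            return float(brentq(gap, lo, hi, xtol=1e-10))
        lo, hi = lo * 2, hi * 2
    raise RuntimeError("intercept bisection failed to bracket the target prevalence")


@lru_cache(maxsize=64)
def _cached_intercept(slopes: tuple, spec: tuple, target: float) -> float:
    return calibrate_intercept(slopes, spec, target)


def implied_prevalence(
    beta: Sequence[float],
    predictor_spec: Sequence,
    mc_size: int = 1_000_000,
    seed: int = 20_170_223,
) -> float:
    """Monte-Carlo event prevalence implied by a full coefficient vector
    (intercept first) under the given predictor distribution."""
    rng = np.random.default_rng(seed)
    X = draw_covariates(predictor_spec, mc_size, rng)
    beta = np.asarray(beta, dtype=float)
    return float(np.mean(expit(beta[0] + X @ beta[1:])))


def _simulate_split(
    spec: Sequence, beta_full: np.ndarray, n: int,
    rng_x: np.random.Generator, rng_y: np.random.Generator,
    names: Sequence[str] | None = None,
) -> BinaryDataset:
    Xp = draw_covariates(spec, n, rng_x)
    pi = expit(beta_full[0] + Xp @ beta_full[1:])
    y = rng_y.binomial(1, pi)
    return make_dataset(Xp, y, kinds=spec_kinds(spec), names=names)


# ---------------------------------------------------------------------------
# the three designs
# ---------------------------------------------------------------------------

def simulate_series1(config: ScenarioConfig, rep_id: int) -> ReplicatePair:
    """One coefficient-recovery replicate: n=120 train set, no test set."""
    if config.design != "series1":
        raise ValueError("config.design must be 'series1'")
    slopes = tuple(config.true_beta)
    b0 = _cached_intercept(slopes, tuple(config.predictor_spec), config.prevalence_target)
    beta_full = np.array([b0, *slopes])
    n = config.n_train if config.n_train is not None else SERIES1_N
    train = _simulate_split(
        config.predictor_spec, beta_full, n,
        substream(config.base_seed, "series1", rep_id, "covariates"),
        substream(config.base_seed, "series1", rep_id, "outcomes"),
        names=("x1", "x2"),
    )
    return ReplicatePair(train, None, detect_separation(train), rep_id, config.base_seed)


def simulate_series2(config: ScenarioConfig, rep_id: int) -> ReplicatePair:
    """One predictive-performance replicate: EPV-sized train set plus an
    independent test set of 1000 from the same true model."""
    if config.design not in ("series2_weak", "series2_strong"):
        raise ValueError("config.design must be series2_weak or series2_strong")
    beta_full = np.asarray(config.true_beta, dtype=float)
    n_train = config.resolve_n_train()
    names = tuple(f"x{j+1}" for j in range(len(config.predictor_spec)))
    train = _simulate_split(
        config.predictor_spec, beta_full, n_train,
        substream(config.base_seed, config.design, rep_id, "covariates"),
        substream(config.base_seed, config.design, rep_id, "outcomes"),
        names=names,
    )
    test = _simulate_split(
        config.predictor_spec, beta_full, config.n_test,
        substream(config.base_seed, config.design, rep_id, "test_covariates"),
        substream(config.base_seed, config.design, rep_id, "test_outcomes"),
        names=names,
    )
    return ReplicatePair(train, test, detect_separation(train), rep_id, config.base_seed)


def simulate_resample(
    covariate_table: pd.DataFrame,
    fitted_true_beta: dict[str, float],
    intercept_override: float,
    epv: float,
    prev: float,
    m_test: int = 2,
    rep_id: int = 0,
    base_seed: int = 0,
    sep_multiplier: float = 1.0,
    sep_column: str | None = None,
) -> ReplicatePair:
    """One resample-from-covariate-table replicate.

    Train covariate rows are drawn with replacement (n from the EPV rule)
    from ``covariate_table``; outcomes are Bernoulli with probabilities from
    the supplied "true" coefficients, the intercept replaced by
    ``intercept_override`` to pin the average prevalence. The test set is
    ``m_test`` times the table size, drawn and labelled the same way.
    ``sep_multiplier`` optionally inflates one binary coefficient
    (``sep_column``) to provoke separation; the default 1 leaves the model
    untouched.
    """
    if covariate_table.empty:
        raise ValueError("covariate table is empty")
    if not (0 < prev < 1):
        raise ValueError("prev must be in (0, 1)")
    missing = [c for c in fitted_true_beta if c not in covariate_table.columns]
    if missing:
        raise ValueError(f"covariate table lacks columns {missing}")
    cols = list(fitted_true_beta)
    slopes = np.array([fitted_true_beta[c] for c in cols], dtype=float)
    if sep_multiplier != 1.0:
        if sep_column is None or sep_column not in cols:
            raise ValueError("sep_multiplier needs a valid sep_column")
        slopes[cols.index(sep_column)] *= sep_multiplier
    table = covariate_table[cols].to_numpy(float)
    n_train = epv_to_n(epv, len(cols), prev)
    n_test = m_test * len(covariate_table)
    kinds = [
        "binary" if np.isin(table[:, j], (0.0, 1.0)).all() else "continuous"
        for j in range(table.shape[1])
    ]

    def _draw(n, rng_x, rng_y):
        rows = rng_x.integers(0, len(table), size=n)
        Xp = table[rows]
        pi = expit(intercept_override + Xp @ slopes)
        y = rng_y.binomial(1, pi)
        return make_dataset(Xp, y, kinds=kinds, names=cols)

    train = _draw(
        n_train,
        substream(base_seed, "resample", rep_id, "covariates"),
        substream(base_seed, "resample", rep_id, "outcomes"),
    )
    test = _draw(
        n_test,
        substream(base_seed, "resample", rep_id, "test_covariates"),
        substream(base_seed, "resample", rep_id, "test_outcomes"),
    )
    return ReplicatePair(train, test, detect_separation(train), rep_id, base_seed)


def simulate_replicate(config: ScenarioConfig, rep_id: int, **resample_kw) -> ReplicatePair:
    if config.design == "series1":
        return simulate_series1(config, rep_id)
    if config.design in ("series2_weak", "series2_strong"):
        return simulate_series2(config, rep_id)
    return simulate_resample(rep_id=rep_id, base_seed=config.base_seed, **resample_kw)


# ---------------------------------------------------------------------------
# synthetic stand-in for the stress-echocardiography covariate table
# ---------------------------------------------------------------------------

def synthetic_echo_table(n: int = 558, seed: int = 558) -> pd.DataFrame:
    """Synthetic covariate table mimicking a dobutamine stress-echo cohort.

    558 rows with plausible marginals for a suspected coronary-artery-disease
    population: age, baseline and dobutamine ejection fractions (%), and
    binary history/test indicators. Entirely simulated — no patient data —
    and intended as the default table for the resample design.
    """
    rng = np.random.default_rng(seed)
    age = np.clip(np.round(rng.normal(67, 12, n)), 28, 93)
    basebp_ef = np.clip(np.round(rng.normal(55, 10, n), 1), 20, 83)
    dob_ef = np.clip(np.round(basebp_ef + rng.normal(8, 6, n), 1), 22, 92)
    return pd.DataFrame(
        {
            "age": age,
            "baseef": basebp_ef,
            "dobef": dob_ef,
            "ht": rng.binomial(1, 0.70, n),
            "dm": rng.binomial(1, 0.22, n),
            "wma": rng.binomial(1, 0.30, n),
            "posse": rng.binomial(1, 0.25, n),
        }
    )


def series1_intercept(prevalence: float) -> float:
    """Calibrated series-1 intercept for a target prevalence (cached)."""
    return _cached_intercept(SERIES1_SLOPES, SERIES1_SPEC, prevalence)
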