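"""Penalized logistic regression fitters for small or sparse binary data.

Implements four estimation schemes for the binary logistic model
logit(pi_i) = beta' x_i:

* plain maximum likelihood (Newton/IRLS with a divergence guard that flags
  separation-driven non-convergence),
* Firth's bias-reduced fit, maximizing l(beta) + 1/2 log|I(beta)| — the
  Jeffreys-prior penalty on the full coefficient vector, intercept included,
* logF(m, m) penalization, maximizing l(beta) + sum_j [m beta_j/2
  - m log(1 + exp(beta_j))] over the non-intercept coefficients (the
  intercept is left unpenalized so the mean fitted probability tracks the
  observed event proportion),
* ridge, maximizing l(beta) - lambda2 * sum_j beta_j^2 with lambda2 chosen
  by stratified K-fold cross-validation on out-of-fold deviance.

All fitters share one damped-Newton core with step-halving and report the
last iterate together with a convergence flag rather than raising on
monotone likelihoods.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger("sparselogit")

# Newton defaults shared by every fitter.
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 50
MAX_STEP_HALVINGS = 10
# Any |beta_j| beyond this while the update criterion is unmet is treated as a
# diverging (separated / monotone) likelihood and flagged as non-convergence.
DIVERGENCE_GUARD = 15.0

DEFAULT_LAMBDA_GRID = np.logspace(-4, 3, 25)


class ColumnKind(str, Enum):
    INTERCEPT = "intercept"
    CONTINUOUS = "continuous"
    BINARY = "binary"


class Method(str, Enum):
    MLE = "MLE"
    FIRTH = "FIRTH"
    LOGF = "LOGF"
    RIDGE = "RIDGE"


class SeparationStatus(str, Enum):
    NONE = "none"
    QUASI_COMPLETE = "quasi_complete"
    COMPLETE = "complete"


@dataclass(frozen=True)
class BinaryDataset:
    """Design matrix with an explicit intercept column plus 0/1 outcomes.

    ``X`` is n x (k+1) with exactly one all-ones intercept column;
    ``column_kinds`` marks each column as intercept, continuous or binary.
    """

    X: np.ndarray
    y: np.ndarray
    column_kinds: tuple[ColumnKind, ...]
    column_names: tuple[str, ...] = ()

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X and y have incompatible shapes")
        if X.shape[0] < 1:
            raise ValueError("empty dataset")
        if len(self.column_kinds) != X.shape[1]:
            raise ValueError("column_kinds length must match X columns")
        kinds = tuple(ColumnKind(k) for k in self.column_kinds)
        object.__setattr__(self, "column_kinds", kinds)
        n_icpt = sum(k is ColumnKind.INTERCEPT for k in kinds)
        if n_icpt != 1:
            raise ValueError("exactly one intercept column required")
        j0 = kinds.index(ColumnKind.INTERCEPT)
        if not np.all(X[:, j0] == 1.0):
            raise ValueError("intercept column must be all ones")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("y must contain only 0 and 1")
        for j, k in enumerate(kinds):
            if k is ColumnKind.BINARY and not np.isin(X[:, j], (0.0, 1.0)).all():
                raise ValueError(f"binary column {j} contains non-0/1 values")
        if not self.column_names:
            names = tuple(
                "intercept" if k is ColumnKind.INTERCEPT else f"x{j}"
                for j, k in enumerate(kinds)
            )
            object.__setattr__(self, "column_names", names)
        elif len(self.column_names) != X.shape[1]:
            raise ValueError("column_names length must match X columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]

    @property
    def intercept_index(self) -> int:
        return self.column_kinds.index(ColumnKind.INTERCEPT)


@dataclass
class FitResult:
    """One fitted model: coefficients plus convergence diagnostics.

    ``beta`` is always populated — on non-convergence it holds the last
    Newton iterate, flagged via ``converged=False``.
    """

    method: Method
    beta: np.ndarray
    converged: bool
    n_iter: int
    max_abs_step: float
    loglik_penalized: float
    m: float = 0.0
    lambda2: float = 0.0
    column_names: tuple[str, ...] = ()

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(prognostic_index(self.beta, X))


@dataclass
class SeparationReport:
    status: SeparationStatus
    culprit_columns: list[int] = field(default_factory=list)
    zero_cells: list[tuple[int, float, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# dataset construction / IO
# ---------------------------------------------------------------------------

def make_dataset(
    X_pred: np.ndarray,
    y: np.ndarray,
    kinds: Sequence[str] | None = None,
    names: Sequence[str] | None = None,
) -> BinaryDataset:
    """Prepend an intercept column to a predictor matrix and wrap it."""
    X_pred = np.atleast_2d(np.asarray(X_pred, dtype=float))
    if X_pred.shape[0] == 1 and len(np.asarray(y)) != 1:
        X_pred = X_pred.T
    n, k = X_pred.shape
    if kinds is None:
        kinds = [
            ColumnKind.BINARY
            if np.isin(X_pred[:, j], (0.0, 1.0)).all()
            else ColumnKind.CONTINUOUS
            for j in range(k)
        ]
    X = np.column_stack([np.ones(n), X_pred])
    all_kinds = (ColumnKind.INTERCEPT, *[ColumnKind(k_) for k_ in kinds])
    all_names = ()
    if names is not None:
        all_names = ("intercept", *names)
    return BinaryDataset(X, np.asarray(y), all_kinds, all_names)


def read_dataset_csv(path, outcome: str) -> BinaryDataset:
    """Load a delimited text table; the intercept is added internally."""
    df = pd.read_csv(path)
    if outcome not in df.columns:
        raise ValueError(f"outcome column {outcome!r} not in {list(df.columns)}")
    y = df[outcome].to_numpy()
    pred = df.drop(columns=[outcome])
    return make_dataset(pred.to_numpy(float), y, names=tuple(pred.columns))


def write_dataset_csv(data: BinaryDataset, path, outcome: str = "y") -> None:
    cols = {}
    for j, name in enumerate(data.column_names):
        if data.column_kinds[j] is ColumnKind.INTERCEPT:
            continue
        cols[name] = data.X[:, j]
    cols[outcome] = data.y.astype(int)
    pd.DataFrame(cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# linear predictor / likelihood machinery
# ---------------------------------------------------------------------------

def prognostic_index(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Risk score eta_i = beta' x_i for each row of the design matrix."""
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != beta.shape[0]:
        raise ValueError(
            f"dimension mismatch: X has {X.shape[1] if X.ndim == 2 else '?'} "
            f"columns, beta has length {beta.shape[0]}"
        )
    return X @ beta


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # y*eta - log(1 + e^eta), overflow-safe
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _check_rank(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient (collinear or constant column)"
        )


def _newton(
    X: np.ndarray,
    y: np.ndarray,
    objective,
    score_hess,
    tol: float,
    max_iter: int,
    guard: float | None,
    beta0: np.ndarray | None = None,
) -> tuple[np.ndarray, bool, int, float, float]:
    """Damped Newton ascent with step-halving on a penalized log-likelihood.

    ``objective(beta)`` returns the (penalized) log-likelihood;
    ``score_hess(beta)`` returns (gradient, negative-Hessian). Convergence is
    max|step| < tol; if ``guard`` is set, any final |beta_j| > guard while the
    step criterion is unmet flags non-convergence (diverging likelihood).
    """
    p = X.shape[1]
    beta = np.zeros(p) if beta0 is None else beta0.astype(float).copy()
    obj = objective(beta)
    step_norm = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g, neg_hess = score_hess(beta)
        try:
            delta = np.linalg.solve(neg_hess, g)
        except np.linalg.LinAlgError:
            break  # information matrix numerically singular: diverged
        # step-halving to keep the objective non-decreasing
        frac = 1.0
        for _ in range(MAX_STEP_HALVINGS):
            cand = beta + frac * delta
            cand_obj = objective(cand)
            if np.isfinite(cand_obj) and cand_obj >= obj - 1e-12:
                break
            frac *= 0.5
        else:
            cand = beta + frac * delta
            cand_obj = objective(cand)
        step_norm = float(np.max(np.abs(cand - beta)))
        beta, obj = cand, cand_obj
        if step_norm < tol:
            converged = True
            break
    if guard is not None and np.max(np.abs(beta)) > guard:
        converged = False
    return beta, converged, it, step_norm, obj


# ---------------------------------------------------------------------------
# fitters
# ---------------------------------------------------------------------------

def fit_mle(
    data: BinaryDataset,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    sample_weight: np.ndarray | None = None,
) -> FitResult:
    """Maximum-likelihood logistic regression via guarded Newton/IRLS.

    Separation or a single-class outcome yields ``converged=False`` with the
    last iterate retained (never an exception); a rank-deficient design
    raises.
    """
    X, y = data.X, data.y
    _check_rank(X)
    w = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, float)

    def objective(beta):
        return float(np.sum(w * (y * (X @ beta) - np.logaddexp(0.0, X @ beta))))

    def score_hess(beta):
        pi = expit(X @ beta)
        g = X.T @ (w * (y - pi))
        neg_hess = (X * (w * pi * (1 - pi))[:, None]).T @ X
        return g, neg_hess

    beta, conv, it, step, obj = _newton(
        X, y, objective, score_hess, tol, max_iter, DIVERGENCE_GUARD
    )
    return FitResult(Method.MLE, beta, conv, it, step, obj,
                     column_names=data.column_names)


def fit_firth(
    data: BinaryDataset,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FitResult:
    """Firth's bias-reduced logistic fit: argmax l(beta) + 1/2 log|I(beta)|.

    The Jeffreys penalty applies to the whole coefficient vector, intercept
    included — this is what pulls the average fitted probability towards 0.5
    and makes the method biased for the average predicted probability at low
    prevalence. Estimates stay finite under complete separation.
    """
    X, y = data.X, data.y
    _check_rank(X)

    def objective(beta):
        eta = X @ beta
        pi = expit(eta)
        W = pi * (1 - pi)
        sign, logdet = np.linalg.slogdet((X * W[:, None]).T @ X)
        if sign <= 0:
            return -np.inf
        return _loglik(eta, y) + 0.5 * logdet

    def score_hess(beta):
        pi = expit(X @ beta)
        W = pi * (1 - pi)
        XtWX = (X * W[:, None]).T @ X
        # hat diagonal h_i of W^1/2 X (X'WX)^-1 X' W^1/2
        XWhalf = X * np.sqrt(W)[:, None]
        h = np.einsum("ij,ij->i", XWhalf @ np.linalg.inv(XtWX), XWhalf)
        g = X.T @ (y - pi + h * (0.5 - pi))
        return g, XtWX

    beta, conv, it, step, obj = _newton(
        X, y, objective, score_hess, tol, max_iter, guard=None
    )
    return FitResult(Method.FIRTH, beta, conv, it, step, obj,
                     column_names=data.column_names)


def fit_logf(
    data: BinaryDataset,
    m: float,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FitResult:
    """logF(m, m) penalized fit.

    Maximizes l(beta) + sum over non-intercept j of
    [m beta_j/2 - m log(1 + e^{beta_j})]; the prior is equivalent to m
    pseudo-observations per penalized coefficient. m=0 reproduces the MLE;
    the intercept is never penalized, so at the optimum the mean fitted
    probability equals the observed event proportion.
    """
    if m < 0:
        raise ValueError("logF degrees of freedom m must be >= 0")
    X, y = data.X, data.y
    _check_rank(X)
    pen_mask = np.array(
        [k is not ColumnKind.INTERCEPT for k in data.column_kinds], dtype=float
    )

    def objective(beta):
        pen = np.sum(pen_mask * (m * beta / 2.0 - m * np.logaddexp(0.0, beta)))
        return _loglik(X @ beta, y) + pen

    def score_hess(beta):
        pi = expit(X @ beta)
        g = X.T @ (y - pi)
        sb = expit(beta)
        g = g + pen_mask * (m / 2.0 - m * sb)
        neg_hess = (X * (pi * (1 - pi))[:, None]).T @ X
        neg_hess[np.diag_indices_from(neg_hess)] += pen_mask * m * sb * (1 - sb)
        return g, neg_hess

    guard = DIVERGENCE_GUARD if m == 0 else None
    beta, conv, it, step, obj = _newton(
        X, y, objective, score_hess, tol, max_iter, guard
    )
    return FitResult(Method.LOGF, beta, conv, it, step, obj, m=m,
                     column_names=data.column_names)


def _ridge_newton(X, y, lam, pen_mask, tol, max_iter):
    """Ridge fit on an already-standardized design; returns newton tuple."""

    def objective(beta):
        return _loglik(X @ beta, y) - lam * np.sum(pen_mask * beta**2)

    def score_hess(beta):
        pi = expit(X @ beta)
        g = X.T @ (y - pi) - 2.0 * lam * pen_mask * beta
        neg_hess = (X * (pi * (1 - pi))[:, None]).T @ X
        neg_hess[np.diag_indices_from(neg_hess)] += 2.0 * lam * pen_mask
        return g, neg_hess

    guard = DIVERGENCE_GUARD if lam == 0 else None
    return _newton(X, y, objective, score_hess, tol, max_iter, guard)


def fit_ridge(
    data: BinaryDataset,
    lambda_grid: Sequence[float] | None = None,
    n_folds: int = 10,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FitResult:
    """Ridge logistic regression, argmax l(beta) - lambda2 * sum beta_j^2.

    Non-intercept columns are standardized internally (the penalty acts on
    the standardized scale; coefficients are returned on the original scale)
    and the intercept is unpenalized. lambda2 is chosen to minimize the mean
    out-of-fold binomial deviance over ``n_folds`` outcome-stratified folds,
    then the model is refit on the full data. ``converged=False`` if the
    final refit fails the Newton criteria or every candidate lambda2 fails in
    at least one fold.
    """
    if lambda_grid is None:
        lambda_grid = DEFAULT_LAMBDA_GRID
    lambda_grid = np.asarray(list(lambda_grid), dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda_grid is empty")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    X, y = data.X, data.y
    _check_rank(X)
    j0 = data.intercept_index
    pen_mask = np.ones(X.shape[1])
    pen_mask[j0] = 0.0
    # center+scale non-intercept columns; penalty acts on this scale
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    mu[j0], sd[j0] = 0.0, 1.0
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    mean_dev = np.full(lambda_grid.size, np.inf)
    any_fold_failed = np.zeros(lambda_grid.size, dtype=bool)
    folds = list(skf.split(Z, y))
    for li, lam in enumerate(lambda_grid):
        devs = []
        for tr, te in folds:
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                warnings.warn("single-class fold skipped in ridge CV")
                continue
            b, conv, *_ = _ridge_newton(Z[tr], y[tr], lam, pen_mask, tol, max_iter)
            if not conv:
                any_fold_failed[li] = True
                continue
            eta_te = Z[te] @ b
            devs.append(-2.0 * _loglik(eta_te, y[te]) / len(te))
        if devs:
            mean_dev[li] = float(np.mean(devs))
    cv_failed = bool(any_fold_failed.all())
    best = int(np.argmin(mean_dev)) if np.isfinite(mean_dev).any() else 0
    lam = float(lambda_grid[best])

    beta_z, conv, it, step, obj = _ridge_newton(Z, y, lam, pen_mask, tol, max_iter)
    # back-transform to the original scale
    beta = beta_z / sd
    beta[j0] = beta_z[j0] - np.sum(np.delete(beta_z * mu / sd, j0))
    converged = conv and not cv_failed
    return FitResult(Method.RIDGE, beta, converged, it, step, obj, lambda2=lam,
                     column_names=data.column_names)


def fit_method(data: BinaryDataset, method: str, seed: int = 0, **kw) -> FitResult:
    """Dispatch by method tag: mle, firth, logf1, logf2, ridge."""
    method = method.lower()
    if method == "mle":
        return fit_mle(data, **kw)
    if method == "firth":
        return fit_firth(data, **kw)
    if method in ("logf1", "logf(1,1)"):
        return fit_logf(data, m=1.0, **kw)
    if method in ("logf2", "logf(2,2)"):
        return fit_logf(data, m=2.0, **kw)
    if method == "ridge":
        return fit_ridge(data, seed=seed, **kw)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# separation diagnostics
# ---------------------------------------------------------------------------

def detect_separation(data: BinaryDataset) -> SeparationReport:
    """Cross-tabulate each binary predictor against the outcome.

    An empty predictor-level-by-outcome cell means quasi-complete separation
    for that column; both discordant cells empty (one level all events, the
    other all non-events) means complete separation. Continuous-predictor
    separation is out of scope.
    """
    culprits: list[int] = []
    zero_cells: list[tuple[int, float, int]] = []
    status = SeparationStatus.NONE
    for j, kind in enumerate(data.column_kinds):
        if kind is not ColumnKind.BINARY:
            continue
        col = data.X[:, j]
        empty = []
        for level in (0.0, 1.0):
            for outcome in (0, 1):
                n_cell = int(np.sum((col == level) & (data.y == outcome)))
                if n_cell == 0:
                    empty.append((j, level, outcome))
        if not empty:
            continue
        culprits.append(j)
        zero_cells.extend(empty)
        # complete: level 0 predicts one class and level 1 the other
        discordant = {(lv, oc) for _, lv, oc in empty}
        is_complete = (
            {(0.0, 0), (1.0, 1)} <= discordant or {(0.0, 1), (1.0, 0)} <= discordant
        )
        if is_complete:
            status = SeparationStatus.COMPLETE
        elif status is not SeparationStatus.COMPLETE:
            status = SeparationStatus.QUASI_COMPLETE
    return SeparationReport(status, culprits, zero_cells)
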