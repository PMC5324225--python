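"""Unit and property tests for the four logistic fitters and separation
diagnostics."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit, logit

from sparselogit import (
    SeparationStatus,
    detect_separation,
    fit_firth,
    fit_logf,
    fit_mle,
    fit_ridge,
    make_dataset,
    prognostic_index,
)
from sparselogit.fit import BinaryDataset, ColumnKind

from conftest import two_by_two


# ---------------------------------------------------------------------------
# dataset invariants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "mutate",
    [
        lambda X, y, k: (X, np.where(y == 1, 2.0, y), k),  # non-0/1 outcome
        lambda X, y, k: (np.column_stack([X, X[:, :1]]), y, k),  # kinds mismatch
        lambda X, y, k: (X * 2, y, k),  # intercept column not all ones
    ],
)
def test_dataset_validation_rejects_malformed_input(balanced_2x2, mutate):
    X, y, kinds = mutate(balanced_2x2.X, balanced_2x2.y, balanced_2x2.column_kinds)
    with pytest.raises(ValueError):
        BinaryDataset(X, y, kinds)


def test_make_dataset_infers_column_kinds(random_dataset):
    assert random_dataset.column_kinds[0] is ColumnKind.INTERCEPT
    assert random_dataset.column_kinds[3] is ColumnKind.BINARY
    assert random_dataset.X.shape[1] == 4


# ---------------------------------------------------------------------------
# MLE
# ---------------------------------------------------------------------------

def test_mle_saturated_2x2_equals_empirical_log_odds_ratio(balanced_2x2):
    res = fit_mle(balanced_2x2)
    assert res.converged
    assert res.beta[1] == pytest.approx(np.log(4), abs=1e-6)
    assert res.beta[0] == pytest.approx(np.log(5 / 10), abs=1e-6)


def test_mle_flags_complete_separation(complete_separation):
    res = fit_mle(complete_separation)
    assert not res.converged
    assert np.all(np.isfinite(res.beta))  # last iterate retained, not dropped


def test_mle_flags_monotone_likelihood_for_constant_outcome():
    rng = np.random.default_rng(0)
    data = make_dataset(rng.standard_normal((30, 1)), np.zeros(30), kinds=["continuous"])
    res = fit_mle(data)
    assert not res.converged


def test_mle_rank_deficient_design_raises():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(40)
    X = np.column_stack([x, x])  # duplicated predictor
    y = rng.binomial(1, 0.5, 40)
    with pytest.raises(np.linalg.LinAlgError):
        fit_mle(make_dataset(X, y, kinds=["continuous", "continuous"]))


def test_mle_constant_column_raises():
    rng = np.random.default_rng(2)
    X = np.ones((30, 1))  # collinear with intercept
    y = rng.binomial(1, 0.5, 30)
    with pytest.raises(np.linalg.LinAlgError):
        fit_mle(make_dataset(X, y, kinds=["binary"]))


# ---------------------------------------------------------------------------
# Firth
# ---------------------------------------------------------------------------

def _firth_objective_2x2(data):
    X, y = data.X, data.y

    def neg(beta):
        eta = X @ beta
        pi = expit(eta)
        ll = np.sum(y * eta - np.logaddexp(0, eta))
        _, ld = np.linalg.slogdet((X * (pi * (1 - pi))[:, None]).T @ X)
        return -(ll + 0.5 * ld)

    return neg


@pytest.mark.parametrize(
    "cells, expected_slope",
    [
        ((10, 0, 0, 10), np.log((10.5 * 10.5) / (0.5 * 0.5))),  # complete sep
        ((10, 0, 2, 8), np.log((10.5 * 8.5) / (0.5 * 2.5))),  # quasi-complete
        ((10, 10, 10, 10), 0.0),  # symmetric, no shrinkage needed
    ],
)
def test_firth_equals_half_cell_corrected_log_odds_ratio(cells, expected_slope):
    """On a saturated 2x2 design the Jeffreys penalty is exactly the add-1/2
    cell correction, and the estimate stays finite under separation."""
    data = two_by_two(*cells)
    res = fit_firth(data)
    assert res.converged
    assert res.beta[1] == pytest.approx(expected_slope, abs=1e-6)
    # independent oracle: direct numerical maximization of the penalized LL
    opt = minimize(_firth_objective_2x2(data), np.zeros(2), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12})
    assert res.beta == pytest.approx(opt.x, abs=1e-4)


def test_firth_finite_under_separation_fuzz():
    """Firth estimates remain finite across random sparse datasets including
    complete and quasi-complete separation."""
    rng = np.random.default_rng(7)
    datasets = [two_by_two(5, 0, 0, 5), two_by_two(8, 0, 1, 7)]
    for _ in range(15):
        n = int(rng.integers(15, 50))
        X = np.column_stack([rng.standard_normal(n), rng.binomial(1, 0.3, n)])
        y = rng.binomial(1, expit(-2 + 2.5 * X[:, 1]), n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        datasets.append(make_dataset(X, y, kinds=["continuous", "binary"]))
    for data in datasets:
        res = fit_firth(data)
        assert np.all(np.isfinite(res.beta))
        assert np.max(np.abs(res.beta)) < 50


# ---------------------------------------------------------------------------
# logF
# ---------------------------------------------------------------------------

def test_logf_m0_equals_mle(random_dataset):
    mle = fit_mle(random_dataset)
    lf = fit_logf(random_dataset, m=0)
    assert mle.converged and lf.converged
    np.testing.assert_allclose(lf.beta, mle.beta, atol=1e-7)


def test_logf_rejects_negative_m(random_dataset):
    with pytest.raises(ValueError):
        fit_logf(random_dataset, m=-1)


@pytest.mark.parametrize("m", [1.0, 2.0])
def test_logf_equals_data_augmentation_oracle(quasi_separation, m):
    """logF(m,m) equals unpenalized weighted MLE after appending, per
    penalized coefficient, two pseudo-records (x_j=1, everything else 0)
    with outcomes 1 and 0 and weight m/2 each."""
    sm = pytest.importorskip("statsmodels.api")
    data = quasi_separation
    X, y = data.X, data.y
    aug_rows, aug_y, aug_w = [], [], []
    for j, kind in enumerate(data.column_kinds):
        if kind is ColumnKind.INTERCEPT:
            continue
        row = np.zeros(X.shape[1])
        row[j] = 1.0
        for outcome in (1.0, 0.0):
            aug_rows.append(row)
            aug_y.append(outcome)
            aug_w.append(m / 2.0)
    Xa = np.vstack([X, np.array(aug_rows)])
    ya = np.concatenate([y, aug_y])
    wa = np.concatenate([np.ones_like(y), aug_w])
    glm = sm.GLM(ya, Xa, family=sm.families.Binomial(), var_weights=wa)
    oracle = glm.fit(maxiter=200, tol=1e-10).params
    res = fit_logf(data, m=m)
    assert res.converged
    np.testing.assert_allclose(res.beta, oracle, atol=1e-5)


def test_logf_huge_m_shrinks_slopes_to_zero(random_dataset):
    # shrinkage is O(1/m): slopes ~0.1 at m=1e3, ~1e-3 at m=1e5
    res = fit_logf(random_dataset, m=1000)
    assert res.converged
    assert np.max(np.abs(res.beta[1:])) < 0.15
    res = fit_logf(random_dataset, m=10**5)
    assert np.max(np.abs(res.beta[1:])) < 2e-3
    assert res.beta[0] == pytest.approx(logit(random_dataset.y.mean()), abs=0.01)


def test_logf_mean_fitted_probability_matches_event_rate_firth_does_not():
    """The unpenalized logF intercept forces mean(pi-hat) = mean(y); the
    full-vector Jeffreys penalty instead pulls the average fitted
    probability towards 0.5 — upward at low prevalence."""
    data = two_by_two(5, 0, 3, 52)  # low prevalence, quasi-separated
    for m in (1.0, 2.0):
        lf = fit_logf(data, m=m)
        assert expit(prognostic_index(lf.beta, data.X)).mean() == pytest.approx(
            data.y.mean(), abs=1e-7
        )
    fr = fit_firth(data)
    assert expit(prognostic_index(fr.beta, data.X)).mean() > data.y.mean() + 1e-5
    # richer low-prevalence separated design: the upward APP bias is material
    rng = np.random.default_rng(101)
    n = 60
    X = np.column_stack([rng.standard_normal(n), rng.binomial(1, 0.3, n)])
    y = np.zeros(n)
    y[(X[:, 1] == 1) & (X[:, 0] > 0.8)] = 1  # few events, quasi-separated
    assert 0 < y.mean() < 0.15
    rich = make_dataset(X, y, kinds=["continuous", "binary"])
    fr = fit_firth(rich)
    assert expit(prognostic_index(fr.beta, rich.X)).mean() > rich.y.mean() + 0.005
    for m in (1.0, 2.0):
        lf = fit_logf(rich, m=m)
        assert expit(prognostic_index(lf.beta, rich.X)).mean() == pytest.approx(
            rich.y.mean(), abs=1e-7
        )


# ---------------------------------------------------------------------------
# ridge
# ---------------------------------------------------------------------------

def test_ridge_lambda_zero_equals_mle(random_dataset):
    mle = fit_mle(random_dataset)
    rr = fit_ridge(random_dataset, lambda_grid=[0.0])
    assert rr.converged
    np.testing.assert_allclose(rr.beta, mle.beta, atol=1e-7)


def test_ridge_huge_lambda_shrinks_slopes_to_zero(random_dataset):
    res = fit_ridge(random_dataset, lambda_grid=[1e6])
    assert np.max(np.abs(res.beta[1:])) < 1e-3
    assert res.beta[0] == pytest.approx(logit(random_dataset.y.mean()), abs=0.01)


def test_ridge_empty_grid_raises(random_dataset):
    with pytest.raises(ValueError):
        fit_ridge(random_dataset, lambda_grid=[])


def test_ridge_cv_selection_matches_bruteforce_oracle(random_dataset):
    """The CV-selected lambda2 agrees with an exhaustive recomputation of
    every fold deviance via a generic optimizer on the ridge objective."""
    from sklearn.model_selection import StratifiedKFold

    grid = [0.01, 0.1, 1.0, 10.0]
    seed = 3
    res = fit_ridge(random_dataset, lambda_grid=grid, n_folds=5, seed=seed)

    X, y = random_dataset.X, random_dataset.y
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    mu[0], sd[0] = 0.0, 1.0
    Z = (X - mu) / sd
    pen = np.ones(X.shape[1])
    pen[0] = 0.0
    folds = list(StratifiedKFold(5, shuffle=True, random_state=seed).split(Z, y))
    mean_dev = []
    for lam in grid:
        devs = []
        for tr, te in folds:
            def neg(beta, tr=tr, lam=lam):
                eta = Z[tr] @ beta
                return -(np.sum(y[tr] * eta - np.logaddexp(0, eta))
                         - lam * np.sum(pen * beta**2))
            b = minimize(neg, np.zeros(Z.shape[1]), method="BFGS",
                         options={"gtol": 1e-10}).x
            eta_te = Z[te] @ b
            devs.append(-2 * np.sum(y[te] * eta_te - np.logaddexp(0, eta_te)) / len(te))
        mean_dev.append(np.mean(devs))
    assert res.lambda2 == grid[int(np.argmin(mean_dev))]


# ---------------------------------------------------------------------------
# cross-fitter properties
# ---------------------------------------------------------------------------

def _gradient_of_objective(data, res):
    X, y = data.X, data.y
    pi = expit(X @ res.beta)
    g = X.T @ (y - pi)
    if res.method.value == "FIRTH":
        W = pi * (1 - pi)
        XtWX = (X * W[:, None]).T @ X
        XWhalf = X * np.sqrt(W)[:, None]
        h = np.einsum("ij,ij->i", XWhalf @ np.linalg.inv(XtWX), XWhalf)
        g = X.T @ (y - pi + h * (0.5 - pi))
    elif res.method.value == "LOGF":
        pen = np.array([k is not ColumnKind.INTERCEPT for k in data.column_kinds])
        g = g + pen * (res.m / 2 - res.m * expit(res.beta))
    elif res.method.value == "RIDGE":
        # ridge objective lives on the standardized scale
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        mu[0], sd[0] = 0.0, 1.0
        Z = (X - mu) / sd
        bz = res.beta * sd
        bz[0] = res.beta[0] + np.sum(res.beta[1:] * mu[1:])
        pen = np.ones(X.shape[1])
        pen[0] = 0.0
        g = Z.T @ (y - expit(Z @ bz)) - 2 * res.lambda2 * pen * bz
    return g


def test_each_fitter_returns_stationary_point(random_dataset):
    data = random_dataset
    fits = [
        fit_mle(data),
        fit_firth(data),
        fit_logf(data, m=1),
        fit_logf(data, m=2),
        fit_ridge(data, lambda_grid=[0.5]),
    ]
    for res in fits:
        assert res.converged
        g = _gradient_of_objective(data, res)
        assert np.max(np.abs(g)) < 10 * 1e-8 * max(1.0, data.n)


def test_shrinkage_is_monotone_in_penalty_strength(random_dataset):
    """Each non-intercept |beta_j| is non-increasing along increasing logF m
    and increasing ridge lambda2."""
    ms = [0.0, 0.5, 1.0, 2.0, 4.0, 8.0]
    betas = np.array([fit_logf(random_dataset, m=m).beta for m in ms])
    assert np.all(np.diff(np.abs(betas[:, 1:]), axis=0) <= 1e-8)
    lams = [0.0, 0.1, 1.0, 10.0, 100.0]
    betas = np.array([fit_ridge(random_dataset, lambda_grid=[l]).beta for l in lams])
    assert np.all(np.diff(np.abs(betas[:, 1:]), axis=0) <= 1e-8)


# ---------------------------------------------------------------------------
# separation detection / prognostic index
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "cells, status",
    [
        ((10, 0, 0, 10), SeparationStatus.COMPLETE),
        ((10, 0, 2, 8), SeparationStatus.QUASI_COMPLETE),
        ((5, 5, 5, 5), SeparationStatus.NONE),
    ],
)
def test_separation_detection_on_2x2_tables(cells, status):
    report = detect_separation(two_by_two(*cells))
    assert report.status is status
    assert (report.status is SeparationStatus.NONE) == (not report.culprit_columns)


def test_separation_none_without_binary_columns():
    rng = np.random.default_rng(5)
    data = make_dataset(rng.standard_normal((20, 1)), rng.binomial(1, 0.5, 20),
                        kinds=["continuous"])
    report = detect_separation(data)
    assert report.status is SeparationStatus.NONE
    assert report.culprit_columns == []


def test_prognostic_index_linear_predictor_identities():
    X = np.column_stack([np.ones(4), np.eye(4)[:, :3]])
    zero = prognostic_index(np.zeros(4), X)
    np.testing.assert_array_equal(zero, 0.0)
    np.testing.assert_allclose(expit(zero), 0.5)
    beta = np.array([-1.5, 0.2, 0.5, -0.03])
    eta = prognostic_index(beta, X)
    assert eta[2] == pytest.approx(-1.5 + -0.03)
    assert eta[3] == pytest.approx(-1.5)
    assert expit(prognostic_index(beta, np.array([[1.0, 0, 0, 0]])))[0] == pytest.approx(
        1 / (1 + np.exp(1.5)), abs=1e-6
    )
    np.testing.assert_allclose(prognostic_index(3 * beta, X), 3 * eta)
    with pytest.raises(ValueError):
        prognostic_index(beta[:2], X)


def test_dataset_csv_roundtrip(tmp_path, random_dataset):
    from sparselogit import read_dataset_csv, write_dataset_csv

    p = tmp_path / "d.csv"
    write_dataset_csv(random_dataset, p)
    back = read_dataset_csv(p, outcome="y")
    np.testing.assert_allclose(back.X, random_dataset.X)
    np.testing.assert_array_equal(back.y, random_dataset.y)
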