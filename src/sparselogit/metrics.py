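"""External-validation metrics for fitted risk models.

Calibration slope (refit of the outcome on the prognostic index), AUC
(Mann-Whitney concordance), Brier score and its square root, and the
average predicted probability (APP). A metric that is undefined for a given
test set — constant prognostic index, single-class outcome, non-convergent
slope refit — is flagged rather than fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .fit import FitResult, fit_mle, make_dataset, prognostic_index


@dataclass
class PerformanceRecord:
    """Per-replicate metric set on one test set."""

    calibration_slope: float
    auc: float
    rbs: float
    app: float
    n_test: int
    bs: float = float("nan")
    defined: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "calibration_slope": self.calibration_slope,
            "auc": self.auc,
            "rbs": self.rbs,
            "app": self.app,
            "n_test": self.n_test,
        }


def calibration_slope(pi: np.ndarray, y_test: np.ndarray) -> float:
    """Slope from refitting y_test on the prognostic index by plain MLE.

    1 is perfect calibration, <1 signals overfitting, >1 underfitting.
    Returns NaN (undefined) for a constant index, a single-class outcome, or
    a non-convergent refit.
    """
    pi = np.asarray(pi, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    if np.ptp(pi) == 0 or len(np.unique(y_test)) < 2:
        return float("nan")
    refit = fit_mle(make_dataset(pi[:, None], y_test, kinds=["continuous"]))
    if not refit.converged:
        return float("nan")
    return float(refit.beta[1])


def auc(risk: np.ndarray, y_test: np.ndarray) -> float:
    """Probability that a random event subject outranks a random non-event
    subject in predicted risk; ties count 1/2. NaN if only one class."""
    y_test = np.asarray(y_test)
    if len(np.unique(y_test)) < 2:
        return float("nan")
    return float(roc_auc_score(y_test, np.asarray(risk, dtype=float)))


def brier(prob: np.ndarray, y_test: np.ndarray) -> tuple[float, float]:
    """Brier score (mean squared error of the predicted probability) and its
    square root; 0 is perfect."""
    prob = np.asarray(prob, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    if np.any((prob < 0) | (prob > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    bs = float(np.mean((y_test - prob) ** 2))
    return bs, float(np.sqrt(bs))


def app(prob: np.ndarray) -> float:
    """Average predicted probability — tracks the event proportion for a
    model whose intercept is estimated without penalty."""
    prob = np.asarray(prob, dtype=float)
    if prob.size == 0:
        raise ValueError("empty probability vector")
    if np.any((prob < 0) | (prob > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean(prob))


def evaluate(fit: FitResult, X_test: np.ndarray, y_test: np.ndarray) -> PerformanceRecord:
    """Score a fitted model on an independent test design matrix."""
    eta = prognostic_index(fit.beta, X_test)
    prob = fit.predict_proba(X_test)
    slope = calibration_slope(eta, y_test)
    a = auc(eta, y_test)
    bs, rbs = brier(prob, y_test)
    rec = PerformanceRecord(
        calibration_slope=slope,
        auc=a,
        rbs=rbs,
        app=app(prob),
        n_test=len(y_test),
        bs=bs,
    )
    rec.defined = {
        "calibration_slope": np.isfinite(slope),
        "auc": np.isfinite(a),
        "rbs": True,
        "app": True,
    }
    return rec
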