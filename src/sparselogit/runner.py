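"""Scenario orchestration and Monte-Carlo aggregation.

Runs scenarios x methods x replicates, collecting per-replicate coefficient
estimates (coefficient-recovery design) or test-set performance metrics
(predictive designs), and aggregates them into summary tables reporting
mean, SD, relative bias (%), MSE, Monte-Carlo error and convergence-failure
rates. Every aggregate uses only the replicates for which the method
converged; a method failing on a replicate is excluded for that method only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fit import fit_method
from .metrics import evaluate
from .simulate import (
    ReplicatePair,
    ScenarioConfig,
    cv_fold_seed,
    series1_intercept,
    simulate_replicate,
)

logger = logging.getLogger("sparselogit")

DEFAULT_METHODS = ("mle", "firth", "logf1", "logf2", "ridge")
METRIC_KEYS = ("calibration_slope", "auc", "rbs", "app")


def relative_bias_pct(estimates, true_value: float) -> float:
    """100 * (mean(estimates) - true) / true. Undefined for true=0."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("no estimates")
    if true_value == 0:
        raise ValueError("relative bias undefined for true value 0; report absolute bias")
    return float(100.0 * (np.mean(estimates) - true_value) / true_value)


def mse(estimates, true_value: float) -> float:
    """Mean squared estimation error around the true value."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("no estimates")
    return float(np.mean((estimates - true_value) ** 2))


def monte_carlo_error(values) -> float:
    """MC standard error of a simulation mean: sample SD / sqrt(count)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return float("nan")
    return float(np.std(values, ddof=1) / np.sqrt(values.size))


@dataclass
class ScenarioResult:
    """Raw per-replicate records plus the aggregated summary for one scenario."""

    config: ScenarioConfig
    scenario_label: str
    raw: pd.DataFrame  # one row per (rep, method): estimates or metrics + converged
    summary: pd.DataFrame  # per (key, method) aggregates
    true_beta_full: tuple[float, ...] | None = None


def _scenario_label(config: ScenarioConfig) -> str:
    if config.design == "series1":
        return f"series1_prev{config.prevalence_target:g}"
    return f"{config.design}_epv{config.epv:g}" if config.epv else f"{config.design}_n{config.n_train}"


def _fit_one(rep: ReplicatePair, method: str, config: ScenarioConfig):
    seed = cv_fold_seed(config.base_seed, config.design, rep.rep_id)
    return fit_method(rep.train, method, seed=seed)


def run_scenario(
    config: ScenarioConfig,
    methods=DEFAULT_METHODS,
    resample_kw: dict | None = None,
) -> ScenarioResult:
    """Generate, fit and score all replicates of one scenario.

    Deterministic given ``config.base_seed``. Replicate-level exceptions are
    caught, logged with the offending seed, and counted as a convergence
    failure for that method only.
    """
    methods = list(methods)
    if not methods:
        raise ValueError("empty method list")
    label = _scenario_label(config)
    is_series1 = config.design == "series1"
    true_full = None
    if is_series1:
        b0 = series1_intercept(config.prevalence_target)
        true_full = (b0, *config.true_beta)
    rows = []
    for rep_id in range(config.n_reps):
        rep = simulate_replicate(config, rep_id, **(resample_kw or {}))
        for method in methods:
            row = {
                "scenario": label,
                "rep_id": rep_id,
                "method": method,
                "separation": rep.separation.status.value,
                "converged": False,
            }
            try:
                fit = _fit_one(rep, method, config)
                row["converged"] = bool(fit.converged)
                if is_series1:
                    for j, name in enumerate(rep.train.column_names):
                        row[f"beta_{name}"] = fit.beta[j]
                elif fit.converged:
                    perf = evaluate(fit, rep.test.X, rep.test.y)
                    row.update(perf.as_dict())
            except Exception:
                logger.exception(
                    "replicate %d (seed %d) failed for %s", rep_id, config.base_seed, method
                )
            rows.append(row)
    raw = pd.DataFrame(rows)
    summary = _aggregate(raw, label, config, true_full)
    return ScenarioResult(config, label, raw, summary, true_full)


def _aggregate(raw, label, config, true_full) -> pd.DataFrame:
    out = []
    n_reps = config.n_reps
    is_series1 = config.design == "series1"
    for method, grp in raw.groupby("method", sort=False):
        conv = grp[grp["converged"]]
        n_conv = len(conv)
        base = {
            "scenario": label,
            "method": method,
            "n_reps": n_reps,
            "n_converged": n_conv,
            "failure_rate_pct": 100.0 * (1 - n_conv / n_reps),
        }
        if is_series1:
            coef_cols = [c for c in raw.columns if c.startswith("beta_")]
            for j, col in enumerate(coef_cols):
                vals = conv[col].dropna().to_numpy()
                true = true_full[j]
                row = dict(base, key=col.removeprefix("beta_"))
                if vals.size:
                    row.update(
                        mean=float(np.mean(vals)),
                        sd=float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan"),
                        relative_bias_pct=relative_bias_pct(vals, true) if true != 0 else float("nan"),
                        mse=mse(vals, true),
                        mce=monte_carlo_error(vals),
                    )
                out.append(row)
        else:
            for key in METRIC_KEYS:
                vals = conv[key].dropna().to_numpy() if key in conv else np.array([])
                row = dict(base, key=key)
                if vals.size:
                    row.update(
                        mean=float(np.mean(vals)),
                        sd=float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan"),
                        mce=monte_carlo_error(vals),
                        n_defined=int(vals.size),
                    )
                out.append(row)
    cols = ["scenario", "key", "method", "mean", "sd", "relative_bias_pct",
            "mse", "mce", "n_defined", "n_converged", "n_reps", "failure_rate_pct"]
    df = pd.DataFrame(out)
    return df[[c for c in cols if c in df.columns]]


def summary_cell(result: ScenarioResult, key: str, method: str, field: str = "mean") -> float:
    """Convenience accessor for one aggregated number."""
    sel = result.summary[
        (result.summary["key"] == key) & (result.summary["method"] == method)
    ]
    if sel.empty:
        raise KeyError(f"no summary row for ({key}, {method})")
    return float(sel.iloc[0][field])


def render_report(results: list[ScenarioResult], out_dir) -> list[Path]:
    """Write summary/raw CSVs, a JSON run manifest, and per-metric boxplots.

    Boxplots show per-replicate metric distributions by method, one panel
    per scenario, with a dashed reference line at the MLE median.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not results:
        raise ValueError("no scenario results to render")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    summary = pd.concat([r.summary for r in results], ignore_index=True)
    p = out_dir / "summary.csv"
    summary.round(6).to_csv(p, index=False)
    written.append(p)
    for r in results:
        p = out_dir / f"raw_{r.scenario_label}.csv"
        r.raw.to_csv(p, index=False)
        written.append(p)

    manifest = {
        "scenarios": [
            {
                "label": r.scenario_label,
                "design": r.config.design,
                "n_reps": r.config.n_reps,
                "base_seed": r.config.base_seed,
                "true_beta_full": list(r.true_beta_full) if r.true_beta_full else None,
            }
            for r in results
        ]
    }
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2))
    written.append(p)

    metric_results = [r for r in results if r.config.design != "series1"]
    for key in METRIC_KEYS:
        if not metric_results:
            break
        fig, axes = plt.subplots(
            1, len(metric_results), figsize=(4 * len(metric_results), 4),
            squeeze=False,
        )
        for ax, r in zip(axes[0], metric_results):
            conv = r.raw[r.raw["converged"]]
            methods = list(dict.fromkeys(conv["method"]))
            series = [conv.loc[conv["method"] == m, key].dropna() for m in methods]
            ax.boxplot(series, tick_labels=[m.upper() for m in methods])
            if "mle" in methods:
                med = conv.loc[conv["method"] == "mle", key].dropna().median()
                ax.axhline(med, ls="--", color="grey", lw=1)
            ax.set_title(r.scenario_label)
            ax.set_ylabel(key)
            ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        p = out_dir / f"boxplot_{key}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
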