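"""Evaluation metrics: MAE/RMSE, the PERMA metric family, and paired tests.

Besides the standard regression errors, three theory-grounded metrics are
computed on [0, 1]-scaled labels and predictions:

* PDA (PERMA Dimension Accuracy): ``1 - MAE`` averaged over the five
  dimensions — per-dimension prediction accuracy.
* PCI (PERMA Consistency Index): ``1 - mean |y_hat - rowmean(Y_hat)|`` —
  internal consistency between the overall prediction and the mean of its
  own dimension predictions (labels play no role).
* PCE (PERMA Comprehensive Evaluation): ``alpha*PDA + beta*PCI +
  gamma*(1 - RMSE_norm)`` with default weights (0.4, 0.3, 0.3), where
  ``RMSE_norm`` is RMSE divided by the label range and capped at 1.

Model comparison uses the paired t-test on per-sample absolute errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .perma_transformer import PredictionBundle

DEFAULT_PCE_WEIGHTS = (0.4, 0.3, 0.3)
DEFAULT_EPSILON = 0.1


class MetricError(ValueError):
    pass


@dataclass
class MetricReport:
    mae: float
    rmse: float
    pda: float
    pci: float
    pce: float
    rmse_norm: float
    consistency_violation_rate: float
    epsilon: float
    pce_weights: tuple[float, float, float]
    n: int
    strata: dict[str, "MetricReport"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "mae": self.mae, "rmse": self.rmse, "pda": self.pda, "pci": self.pci,
            "pce": self.pce, "rmse_norm": self.rmse_norm,
            "consistency_violation_rate": self.consistency_violation_rate,
            "epsilon": self.epsilon, "pce_weights": list(self.pce_weights), "n": self.n,
        }
        if self.strata:
            out["strata"] = {k: v.to_dict() for k, v in self.strata.items()}
        return out


@dataclass(frozen=True)
class PairedTestResult:
    t_stat: float
    df: int
    p_value: float
    mean_diff: float
    sd_diff: float
    degenerate: bool = False


def error_metrics(y, y_hat) -> tuple[float, float]:
    """(MAE, RMSE); RMSE >= MAE always."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size == 0:
        raise MetricError("inputs must be equal-length and non-empty")
    err = y - y_hat
    return float(np.mean(np.abs(err))), float(np.sqrt(np.mean(err**2)))


def _check01(arr: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise MetricError(f"{what} must lie in [0, 1]")
    return arr


def pda(perma_labels, perma_pred) -> float:
    """PERMA Dimension Accuracy: mean over dimensions of 1 - MAE."""
    labels = _check01(perma_labels, "perma labels")
    preds = _check01(perma_pred, "perma predictions")
    if labels.shape != preds.shape or labels.ndim != 2 or labels.shape[1] != 5:
        raise MetricError("expected matching (n, 5) matrices")
    per_dim_mae = np.abs(labels - preds).mean(axis=0)
    return float(np.mean(1.0 - per_dim_mae))


def pci(wellbeing_pred, perma_pred) -> float:
    """PERMA Consistency Index; depends only on the predictions."""
    y_hat = _check01(wellbeing_pred, "wellbeing predictions")
    perma = _check01(perma_pred, "perma predictions")
    if perma.shape != (len(y_hat), 5):
        raise MetricError("perma predictions must be (n, 5)")
    return float(1.0 - np.mean(np.abs(y_hat - perma.mean(axis=1))))


def pce(
    pda_value: float,
    pci_value: float,
    rmse: float,
    label_range: float = 1.0,
    weights: tuple[float, float, float] = DEFAULT_PCE_WEIGHTS,
) -> tuple[float, float]:
    """(PCE, RMSE_norm) with RMSE_norm = min(1, rmse / label_range)."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise MetricError("pce weights must be nonnegative and sum to 1")
    if label_range <= 0:
        raise MetricError("label_range must be positive")
    rmse_norm = min(1.0, rmse / label_range)
    alpha, beta, gamma = w
    return float(alpha * pda_value + beta * pci_value + gamma * (1.0 - rmse_norm)), rmse_norm


def consistency_violation_rate(bundle: PredictionBundle, epsilon: float = DEFAULT_EPSILON) -> float:
    """Fraction of students with |y_hat - rowmean(Y_hat)| > epsilon."""
    if epsilon < 0:
        raise MetricError("epsilon must be nonnegative")
    return float(np.mean(bundle.consistency_gap() > epsilon))


def paired_ttest(errors_a, errors_b) -> PairedTestResult:
    """Two-sided paired t-test on aligned per-sample error vectors.

    ``d_i = e_a,i - e_b,i``; ``t = dbar / (s_d / sqrt(n))`` with the n-1
    denominator in ``s_d``. Degenerate zero-variance cases are flagged:
    p = 1 when the mean difference is also 0, else p = 0.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise MetricError("error vectors must be aligned 1-d arrays")
    n = a.size
    if n < 2:
        raise MetricError("need n >= 2 paired samples")
    d = a - b
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    df = n - 1
    if sd_diff == 0.0:
        if mean_diff == 0.0:
            return PairedTestResult(0.0, df, 1.0, mean_diff, sd_diff, degenerate=True)
        sign = 1.0 if mean_diff > 0 else -1.0
        return PairedTestResult(sign * np.inf, df, 0.0, mean_diff, sd_diff, degenerate=True)
    t = mean_diff / (sd_diff / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return PairedTestResult(float(t), df, p, mean_diff, sd_diff)


def evaluate(
    bundle: PredictionBundle,
    wellbeing_labels,
    perma_labels,
    epsilon: float = DEFAULT_EPSILON,
    pce_weights: tuple[float, float, float] = DEFAULT_PCE_WEIGHTS,
    strata: Mapping[str, Sequence] | None = None,
    label_range: float = 1.0,
) -> MetricReport:
    """Full metric report, optionally stratified (e.g. per culture).

    ``strata`` maps a stratum label per student (one key per stratification,
    e.g. ``{"culture": cultures}``); a sub-report is computed per level.
    """
    y = np.asarray(wellbeing_labels, dtype=float)
    perma = np.asarray(perma_labels, dtype=float)
    if y.shape != (bundle.n,) or perma.shape != (bundle.n, 5):
        raise MetricError("labels must cover every student")
    mae, rmse = error_metrics(y, bundle.wellbeing_pred)
    pda_value = pda(perma, bundle.perma_pred)
    pci_value = pci(bundle.wellbeing_pred, bundle.perma_pred)
    pce_value, rmse_norm = pce(pda_value, pci_value, rmse, label_range, pce_weights)
    report = MetricReport(
        mae=mae, rmse=rmse, pda=pda_value, pci=pci_value, pce=pce_value,
        rmse_norm=rmse_norm,
        consistency_violation_rate=consistency_violation_rate(bundle, epsilon),
        epsilon=epsilon, pce_weights=tuple(pce_weights), n=bundle.n,
    )
    if strata:
        for key, values in strata.items():
            values = np.asarray(values)
            for level in np.unique(values):
                mask = values == level
                sub = PredictionBundle(
                    wellbeing_pred=bundle.wellbeing_pred[mask],
                    perma_pred=bundle.perma_pred[mask],
                )
                report.strata[f"{key}={level}"] = evaluate(
                    sub, y[mask], perma[mask], epsilon, pce_weights,
                    strata=None, label_range=label_range,
                )
    return report


def compare_models(
    model_errors: Mapping[str, Sequence[float]],
    holm: bool = False,
) -> pd.DataFrame:
    """All-pairs paired t-tests on per-sample absolute error vectors.

    Returns a table with per-model MAE and the pairwise test results,
    sorted by MAE of ``model_a`` then ``model_b``. Raw p-values by default;
    ``holm=True`` adds Holm-adjusted p-values.
    """
    names = list(model_errors)
    if len(names) < 2:
        raise MetricError("need at least two models")
    arrays = {k: np.asarray(v, dtype=float) for k, v in model_errors.items()}
    lengths = {a.size for a in arrays.values()}
    if len(lengths) != 1:
        raise MetricError("per-sample error vectors must be aligned")
    maes = {k: float(np.mean(np.abs(a))) for k, a in arrays.items()}
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = paired_ttest(arrays[a], arrays[b])
            rows.append({
                "model_a": a, "model_b": b,
                "mae_a": maes[a], "mae_b": maes[b],
                "t_stat": res.t_stat, "df": res.df, "p_value": res.p_value,
                "mean_diff": res.mean_diff, "sd_diff": res.sd_diff,
                "degenerate": res.degenerate,
            })
    table = pd.DataFrame(rows).sort_values(["mae_a", "mae_b"]).reset_index(drop=True)
    if holm and len(table):
        order = np.argsort(table["p_value"].to_numpy())
        m = len(table)
        adjusted = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * table["p_value"].iloc[idx])
            adjusted[idx] = min(1.0, running)
        table["p_holm"] = adjusted
    return table
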