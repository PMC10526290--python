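"""Evaluation: MSE, multiclass precision/recall/F1, per-step reports.

Classification metrics are one-vs-rest counts from the confusion matrix,
macro-averaged (unweighted mean over classes with nonzero support) and
reported in percent.  F1 is the harmonic mean 2PR/(P+R).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .multitask import CLASS_NAMES, N_CLASSES

logger = logging.getLogger(__name__)


def mse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean squared error over all elements."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise ValueError("empty arrays")
    return float(np.mean((y_true - y_pred) ** 2))


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (C, C), rows = true, columns = predicted
    class_names: tuple[str, ...] = CLASS_NAMES

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())


def confusion(
    true_labels, pred_labels, n_classes: int = N_CLASSES
) -> ConfusionMatrix:
    """counts[i, j] = number of samples with true class i predicted as j."""
    t = np.asarray(true_labels, dtype=int).ravel()
    p = np.asarray(pred_labels, dtype=int).ravel()
    if t.shape != p.shape:
        raise ValueError("label arrays differ in length")
    if t.size and (t.min() < 0 or t.max() >= n_classes
                   or p.min() < 0 or p.max() >= n_classes):
        raise ValueError(f"labels out of range 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (t, p), 1)
    names = CLASS_NAMES if n_classes == N_CLASSES else tuple(
        f"class_{i}" for i in range(n_classes)
    )
    return ConfusionMatrix(counts=counts, class_names=names)


def precision_recall_f1(
    cm: ConfusionMatrix, averaging: str = "macro"
) -> dict:
    """One-vs-rest precision/recall/F1 from a confusion matrix, in percent.

    ``macro`` returns the unweighted mean over classes with support > 0
    plus plain accuracy; ``per_class`` returns per-class vectors.  A class
    with a zero denominator contributes 0 (logged as a warning).
    """
    counts = cm.counts
    if counts.sum() == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts).astype(float)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    support = counts.sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        rec = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec
                      / np.maximum(prec + rec, 1e-300), 0.0)
    if np.any((tp + fp == 0) & (support > 0)):
        logger.warning("class with no predicted samples; precision set to 0")

    if averaging == "per_class":
        return {
            "precision": 100 * prec,
            "recall": 100 * rec,
            "f1": 100 * f1,
            "support": support,
        }
    if averaging != "macro":
        raise ValueError(f"unknown averaging {averaging!r}")
    mask = support > 0
    return {
        "precision": round(float(100 * prec[mask].mean()), 2),
        "recall": round(float(100 * rec[mask].mean()), 2),
        "f1": round(float(100 * f1[mask].mean()), 2),
        "accuracy": round(float(100 * tp.sum() / counts.sum()), 2),
    }


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of aggregate precision and recall (same units)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class MetricsReport:
    """Per-rollout-step evaluation in the shape of a step-columned table."""

    per_step: list[dict]
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, step in enumerate(self.per_step, start=1):
            rows.append(
                {
                    "step": k,
                    "mse": step["mse"],
                    "precision_pct": step["precision"],
                    "recall_pct": step["recall"],
                    "f1_pct": step["f1"],
                    "accuracy_pct": step["accuracy"],
                    "n_windows": step["n_windows"],
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "metadata": self.metadata,
            "per_step": [
                {**{k: v for k, v in s.items() if k != "confusion"},
                 "confusion": s["confusion"].counts.tolist()}
                for s in self.per_step
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def per_step_report(
    model_params,
    windows: np.ndarray,
    future_frames: np.ndarray,
    future_labels: np.ndarray,
    horizon: int = 5,
    input_scale: float = 60.0,
    metadata: dict | None = None,
) -> MetricsReport:
    """Evaluate an autoregressive rollout step by step.

    ``windows`` is (N, n, 40, 3) newtons; ``future_frames`` (N, horizon,
    40, 3) the true next frames; ``future_labels`` (N, horizon) the true
    per-frame walking states.  For each step k the rollout's frame k is
    scored by MSE (on the normalized force scale, forces / input_scale)
    and its class decision by precision/recall/F1 against the true label
    at t + k.
    """
    from .model import rollout_batch

    windows = np.asarray(windows, dtype=float)
    future_frames = np.asarray(future_frames, dtype=float)
    future_labels = np.asarray(future_labels, dtype=int)
    if future_frames.shape[1] < horizon:
        raise ValueError(
            f"future frames cover {future_frames.shape[1]} steps, "
            f"need {horizon}"
        )
    frames, _probs, labels = rollout_batch(
        windows, model_params, horizon, input_scale
    )
    per_step = []
    for k in range(horizon):
        cm = confusion(future_labels[:, k], labels[:, k])
        stats = precision_recall_f1(cm)
        per_step.append(
            {
                "mse": mse(future_frames[:, k] / input_scale,
                           frames[:, k] / input_scale),
                **stats,
                "confusion": cm,
                "n_windows": windows.shape[0],
            }
        )
    return MetricsReport(per_step=per_step, metadata=metadata or {})
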