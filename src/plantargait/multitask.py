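"""Shared-parameter multi-task head.

One sigmoid hidden layer consumes the final LSTM state; two linear task
heads read from it: next-frame force regression (40 units x 3 axes = 120
outputs) and 5-class walking-state classification (normal, fall forward,
backward, left, right).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gcn import ShapeError, sigmoid

N_CLASSES = 5
CLASS_NAMES = ("normal", "forward", "backward", "left", "right")
FRAME_OUTPUTS = 120  # 40 units x 3 force axes


@dataclass
class SharedLayer:
    w: np.ndarray  # (d, S)
    b: np.ndarray  # (S,)

    @property
    def s(self) -> int:
        return self.w.shape[1]


@dataclass
class TaskHeads:
    beta_reg: np.ndarray  # (S, 120)
    beta_cls: np.ndarray  # (S, 5)


@dataclass(frozen=True)
class ClassLabel:
    index: int

    def __post_init__(self) -> None:
        if not 0 <= self.index < N_CLASSES:
            raise ValueError(f"class index {self.index} out of range 0..4")

    @property
    def onehot(self) -> np.ndarray:
        v = np.zeros(N_CLASSES)
        v[self.index] = 1.0
        return v

    @property
    def name(self) -> str:
        return CLASS_NAMES[self.index]


def shared_forward(h: np.ndarray, layer: SharedLayer) -> np.ndarray:
    """g(h^T W + b) with logistic g; accepts (d,) or (B, d)."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != layer.w.shape[0]:
        raise ShapeError(
            f"input width {h.shape[-1]} != shared layer d {layer.w.shape[0]}"
        )
    return sigmoid(h @ layer.w + layer.b)


def task_outputs(
    shared: np.ndarray, heads: TaskHeads
) -> tuple[np.ndarray, np.ndarray]:
    """Project the shared representation to both task outputs.

    Returns (frame_pred, class_scores): frame_pred is (..., 40, 3), class
    scores are raw (unsoftmaxed) per-class values.
    """
    shared = np.asarray(shared, dtype=float)
    if shared.shape[-1] != heads.beta_reg.shape[0]:
        raise ShapeError(
            f"shared width {shared.shape[-1]} != heads S "
            f"{heads.beta_reg.shape[0]}"
        )
    frame_flat = shared @ heads.beta_reg
    frame_pred = frame_flat.reshape(*shared.shape[:-1], 40, 3)
    class_scores = shared @ heads.beta_cls
    return frame_pred, class_scores


def softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - np.max(scores, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def joint_loss(
    frame_pred: np.ndarray,
    frame_true: np.ndarray,
    class_scores: np.ndarray,
    label: ClassLabel,
    alpha: float = 1.0,
    mode: str = "l2_both",
) -> float:
    """Joint objective: frame MSE plus weighted class term.

    ``l2_both`` (default) uses the squared error between the raw class
    scores and the one-hot label, so both tasks are L2 norms of the same
    kind; ``l2_plus_xent`` substitutes softmax cross-entropy.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    frame_pred = np.asarray(frame_pred, dtype=float)
    frame_true = np.asarray(frame_true, dtype=float)
    if frame_pred.shape != frame_true.shape:
        raise ShapeError(
            f"frame shapes differ: {frame_pred.shape} vs {frame_true.shape}"
        )
    scores = np.asarray(class_scores, dtype=float)
    reg = float(np.mean((frame_pred - frame_true) ** 2))
    if mode == "l2_both":
        cls = float(np.mean((scores - label.onehot) ** 2))
    elif mode == "l2_plus_xent":
        logp = np.log(softmax(scores))
        cls = float(-logp[..., label.index].mean())
    else:
        raise ValueError(f"unknown loss mode {mode!r}")
    return reg + alpha * cls


def predict_class(class_scores: np.ndarray) -> ClassLabel:
    """Argmax decision; ties break toward the lowest class index."""
    scores = np.asarray(class_scores, dtype=float)
    if np.any(np.isnan(scores)):
        raise ValueError("class scores contain NaN")
    return ClassLabel(index=int(np.argmax(scores)))
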