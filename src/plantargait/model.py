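"""End-to-end GCN-LSTM multi-task fall-detection model.

Per frame, a (shared-weight) graph convolution stack turns the 40 x 3
force matrix into per-node spatial features; the flattened features form
the input sequence of a gate-level LSTM; the final hidden state feeds a
sigmoid shared layer with two linear task heads (next-frame regression,
5-class walking-state scores).  Multi-step prediction is an
autoregressive rollout: each predicted frame is appended to the history
window before the next step is predicted.

Training is plain reverse-mode differentiation written out by hand
(sigmoid/tanh gate algebra, truncated-at-window BPTT) with an Adam
optimizer; gradients are validated against finite differences in the
test suite.  Forces are scaled by ``input_scale`` (the 60 N sensor
range) on the way in so activations live in a well-conditioned range;
the regression head predicts on the same normalized scale and public
APIs convert back to newtons.
"""

from __future__ import annotations

import io
import json
import logging
import zlib
from dataclasses import asdict, dataclass, replace

import numpy as np

from .gcn import GCNParams, ShapeError, sigmoid
from .graph import NormalizedAdjacency, TactileGraph, normalize_adjacency
from .lstm import LSTMParams
from .multitask import N_CLASSES, SharedLayer, TaskHeads, softmax

logger = logging.getLogger(__name__)

PUBLISHED_LR = 1e-8  # the printed learning rate; selectable, not the default


class CheckpointError(RuntimeError):
    pass


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


@dataclass
class ModelConfig:
    history_len: int = 10          # n frames of history (0.2 s at 50 Hz)
    horizon: int = 5               # T_out future steps
    step_interval: float = 0.2     # seconds between predicted steps
    gcn_widths: tuple[int, ...] = (8,)
    gcn_activation: str = "sigmoid"
    lstm_hidden: int = 64
    shared_nodes: int = 64
    alpha: float = 1.0
    loss_mode: str = "l2_both"
    learning_rate: float = 1e-3
    weight_decay: float = 1e-6
    epochs: int = 15
    batch_size: int = 128
    seed: int = 0
    input_scale: float = 60.0      # N; the sensor's force range

    def __post_init__(self) -> None:
        if self.history_len < 1 or self.horizon < 1:
            raise ValueError("history_len and horizon must be >= 1")
        if self.step_interval <= 0:
            raise ValueError("step_interval must be > 0")

    @property
    def lstm_input(self) -> int:
        width = self.gcn_widths[-1] if self.gcn_widths else 3
        return 40 * width


@dataclass
class ModelParams:
    graph: TactileGraph
    norm: NormalizedAdjacency
    gcn: list[GCNParams]
    lstm: LSTMParams
    shared: SharedLayer
    heads: TaskHeads
    layout_hash: str = ""


@dataclass
class PredictionBundle:
    """Autoregressive multi-step prediction over the rollout horizon."""

    frames: np.ndarray        # (T_out, 40, 3) newtons
    class_probs: np.ndarray   # (T_out, 5) softmax probabilities
    labels: np.ndarray        # (T_out,) argmax class indices
    per_step_time: np.ndarray  # (T_out,) seconds offsets


def init_params(
    config: ModelConfig,
    graph: TactileGraph,
    layout_hash: str = "",
    rng: np.random.Generator | None = None,
) -> ModelParams:
    """Glorot-uniform initialization, reproducible from config.seed."""
    if rng is None:
        rng = substream(config.seed, "init")

    def glorot(fan_in: int, fan_out: int) -> np.ndarray:
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=(fan_in, fan_out))

    gcn_layers = []
    d_in = 3
    for idx, d_out in enumerate(config.gcn_widths):
        gcn_layers.append(
            GCNParams(
                weight=glorot(d_in, d_out),
                layer_index=idx,
                activation=config.gcn_activation,
            )
        )
        d_in = d_out

    h, m = config.lstm_hidden, config.lstm_input
    lstm = LSTMParams(
        w_f=glorot(h + m, h).T,
        w_i=glorot(h + m, h).T,
        w_c=glorot(h + m, h).T,
        w_o=glorot(h + m, h).T,
        b_f=np.ones(h),  # positive forget bias: remember by default
        b_i=np.zeros(h),
        b_c=np.zeros(h),
        b_o=np.zeros(h),
    )
    s = config.shared_nodes
    shared = SharedLayer(w=glorot(h, s), b=np.zeros(s))
    heads = TaskHeads(beta_reg=glorot(s, 120), beta_cls=glorot(s, 5))
    return ModelParams(
        graph=graph,
        norm=normalize_adjacency(graph),
        gcn=gcn_layers,
        lstm=lstm,
        shared=shared,
        heads=heads,
        layout_hash=layout_hash,
    )


# ---------------------------------------------------------------------------
# Batched forward / backward
# ---------------------------------------------------------------------------


def _forward_batch(
    windows_scaled: np.ndarray, params: ModelParams, want_cache: bool = False
):
    """Forward pass on (B, n, 40, 3) scaled windows.

    Returns (yreg (B, 120) on the normalized scale, ycls (B, 5), cache).
    """
    x = np.asarray(windows_scaled, dtype=float)
    if x.ndim != 4 or x.shape[2:] != (40, 3):
        raise ShapeError(f"expected (B, n, 40, 3) windows, got {x.shape}")
    l_sym = params.norm.l_sym

    gcn_acts = [x]
    for layer in params.gcn:
        z = l_sym @ gcn_acts[-1] @ layer.weight
        if layer.activation == "sigmoid":
            gcn_acts.append(sigmoid(z))
        else:
            gcn_acts.append(np.maximum(z, 0.0))
    b, n = x.shape[0], x.shape[1]
    seq = gcn_acts[-1].reshape(b, n, -1)  # (B, n, M)

    p = params.lstm
    hdim = p.hidden_size
    h = np.zeros((b, hdim))
    c = np.zeros((b, hdim))
    steps = []
    for t in range(n):
        z = np.concatenate([h, seq[:, t, :]], axis=1)
        f = sigmoid(z @ p.w_f.T + p.b_f)
        i = sigmoid(z @ p.w_i.T + p.b_i)
        g = np.tanh(z @ p.w_c.T + p.b_c)
        o = sigmoid(z @ p.w_o.T + p.b_o)
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        if want_cache:
            steps.append((z, f, i, g, o, c, c_new, tc))
        h, c = h_new, c_new

    s_pre = h @ params.shared.w + params.shared.b
    s = sigmoid(s_pre)
    yreg = s @ params.heads.beta_reg
    ycls = s @ params.heads.beta_cls
    cache = None
    if want_cache:
        cache = {"gcn_acts": gcn_acts, "seq": seq, "steps": steps,
                 "h_final": h, "s": s}
    return yreg, ycls, cache


def _loss_and_grads(
    windows_scaled: np.ndarray,
    frames_true_scaled: np.ndarray,
    labels: np.ndarray,
    params: ModelParams,
    alpha: float,
    loss_mode: str,
) -> tuple[float, dict[str, np.ndarray]]:
    """Joint loss and gradients for a batch (hand-derived reverse mode)."""
    b = windows_scaled.shape[0]
    yreg, ycls, cache = _forward_batch(windows_scaled, params, want_cache=True)
    ytrue = frames_true_scaled.reshape(b, -1)
    onehot = np.eye(N_CLASSES)[labels]

    reg_loss = float(np.mean((yreg - ytrue) ** 2))
    dyreg = 2.0 * (yreg - ytrue) / yreg.size
    if loss_mode == "l2_both":
        cls_loss = float(np.mean((ycls - onehot) ** 2))
        dycls = 2.0 * alpha * (ycls - onehot) / ycls.size
    elif loss_mode == "l2_plus_xent":
        p = softmax(ycls)
        cls_loss = float(-np.log(p[np.arange(b), labels] + 1e-300).mean())
        dycls = alpha * (p - onehot) / b
    else:
        raise ValueError(f"unknown loss mode {loss_mode!r}")
    loss = reg_loss + alpha * cls_loss

    grads: dict[str, np.ndarray] = {}
    s = cache["s"]
    grads["beta_reg"] = s.T @ dyreg
    grads["beta_cls"] = s.T @ dycls
    ds = dyreg @ params.heads.beta_reg.T + dycls @ params.heads.beta_cls.T
    dpre = ds * s * (1.0 - s)
    grads["shared_w"] = cache["h_final"].T @ dpre
    grads["shared_b"] = dpre.sum(axis=0)
    dh = dpre @ params.shared.w.T

    p = params.lstm
    hdim = p.hidden_size
    dc = np.zeros_like(dh)
    for name in ("w_f", "w_i", "w_c", "w_o"):
        grads[name] = np.zeros_like(getattr(p, name))
    for name in ("b_f", "b_i", "b_c", "b_o"):
        grads[name] = np.zeros_like(getattr(p, name))
    dseq = np.zeros_like(cache["seq"])
    for t in range(len(cache["steps"]) - 1, -1, -1):
        z, f, i, g, o, c_prev, c_new, tc = cache["steps"][t]
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc ** 2)
        da_f = (dc * c_prev) * f * (1.0 - f)
        da_i = (dc * g) * i * (1.0 - i)
        da_c = (dc * i) * (1.0 - g ** 2)
        da_o = do * o * (1.0 - o)
        grads["w_f"] += da_f.T @ z
        grads["w_i"] += da_i.T @ z
        grads["w_c"] += da_c.T @ z
        grads["w_o"] += da_o.T @ z
        grads["b_f"] += da_f.sum(axis=0)
        grads["b_i"] += da_i.sum(axis=0)
        grads["b_c"] += da_c.sum(axis=0)
        grads["b_o"] += da_o.sum(axis=0)
        dz = da_f @ p.w_f + da_i @ p.w_i + da_c @ p.w_c + da_o @ p.w_o
        dh = dz[:, :hdim]
        dseq[:, t, :] = dz[:, hdim:]
        dc = dc * f

    l_sym = params.norm.l_sym
    d_top = dseq.reshape(cache["gcn_acts"][-1].shape)
    for li in range(len(params.gcn) - 1, -1, -1):
        layer = params.gcn[li]
        act = cache["gcn_acts"][li + 1]
        prev = cache["gcn_acts"][li]
        if layer.activation == "sigmoid":
            dz = d_top * act * (1.0 - act)
        else:
            dz = d_top * (act > 0)
        lx = l_sym @ prev  # (B, n, 40, d_in)
        grads[f"gcn_{li}"] = np.einsum("btnd,btne->de", lx, dz)
        if li > 0:
            d_top = l_sym @ dz @ layer.weight.T  # l_sym symmetric
    return loss, grads


def _param_arrays(params: ModelParams) -> dict[str, np.ndarray]:
    out = {f"gcn_{i}": layer.weight for i, layer in enumerate(params.gcn)}
    for name in ("w_f", "w_i", "w_c", "w_o", "b_f", "b_i", "b_c", "b_o"):
        out[name] = getattr(params.lstm, name)
    out["shared_w"] = params.shared.w
    out["shared_b"] = params.shared.b
    out["beta_reg"] = params.heads.beta_reg
    out["beta_cls"] = params.heads.beta_cls
    return out


class Adam:
    """Adam with decoupled-from-biases L2 weight decay."""

    def __init__(self, arrays: dict[str, np.ndarray], lr: float,
                 weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.v = {k: np.zeros_like(v) for k, v in arrays.items()}

    def step(self, arrays: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, w in arrays.items():
            g = grads[k]
            if self.wd and w.ndim > 1:  # no decay on bias vectors
                g = g + self.wd * w
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            w -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Public inference API
# ---------------------------------------------------------------------------


def forward_window(
    window: np.ndarray, params: ModelParams, input_scale: float = 60.0
) -> tuple[np.ndarray, np.ndarray]:
    """Predict the next frame and class scores from one history window.

    ``window`` is (n, 40, 3) in newtons; returns (frame_pred (40, 3)
    newtons, class_scores (5,) raw).
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 3 or window.shape[1:] != (40, 3):
        raise ShapeError(f"expected (n, 40, 3) window, got {window.shape}")
    yreg, ycls, _ = _forward_batch(window[None] / input_scale, params)
    return yreg[0].reshape(40, 3) * input_scale, ycls[0]


def rollout(
    window: np.ndarray,
    params: ModelParams,
    t_out: int = 5,
    step_interval: float = 0.2,
    input_scale: float = 60.0,
) -> PredictionBundle:
    """Autoregressive multi-step prediction (single window)."""
    frames, probs, labels = rollout_batch(
        np.asarray(window, dtype=float)[None], params, t_out, input_scale
    )
    return PredictionBundle(
        frames=frames[0],
        class_probs=probs[0],
        labels=labels[0],
        per_step_time=step_interval * np.arange(1, t_out + 1),
    )


def rollout_batch(
    windows: np.ndarray,
    params: ModelParams,
    t_out: int,
    input_scale: float = 60.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized rollout over (B, n, 40, 3) windows.

    Returns (frames (B, T_out, 40, 3) newtons, class_probs (B, T_out, 5),
    labels (B, T_out)).
    """
    if t_out < 1:
        raise ValueError("t_out must be >= 1")
    current = np.asarray(windows, dtype=float) / input_scale
    b = current.shape[0]
    frames = np.empty((b, t_out, 40, 3))
    probs = np.empty((b, t_out, N_CLASSES))
    for k in range(t_out):
        yreg, ycls, _ = _forward_batch(current, params)
        pred = yreg.reshape(b, 40, 3)
        frames[:, k] = pred * input_scale
        probs[:, k] = softmax(ycls)
        current = np.concatenate([current[:, 1:], pred[:, None]], axis=1)
    labels = probs.argmax(axis=2)
    return frames, probs, labels


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def train_model(
    dataset,
    config: ModelConfig,
    graph: TactileGraph,
    layout_hash: str = "",
    params: ModelParams | None = None,
) -> tuple[ModelParams, list[float]]:
    """Fit the model on (window, next-frame, label) triples.

    ``dataset`` must expose arrays ``windows`` (N, n, 40, 3) newtons,
    ``next_frames`` (N, 40, 3) newtons and ``labels`` (N,) int.  Returns
    the trained parameters and the per-epoch mean training loss.
    """
    windows = np.asarray(dataset.windows, dtype=float)
    if windows.shape[0] == 0:
        raise ValueError("empty dataset")
    targets = np.asarray(dataset.next_frames, dtype=float)
    labels = np.asarray(dataset.labels, dtype=int)
    xs = windows / config.input_scale
    ys = targets / config.input_scale

    if params is None:
        params = init_params(config, graph, layout_hash)
    arrays = _param_arrays(params)
    opt = Adam(arrays, lr=config.learning_rate,
               weight_decay=config.weight_decay)
    shuffle_rng = substream(config.seed, "shuffle")

    n = xs.shape[0]
    history: list[float] = []
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        total, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            loss, grads = _loss_and_grads(
                xs[idx], ys[idx], labels[idx], params,
                config.alpha, config.loss_mode,
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}; aborting"
                )
            opt.step(arrays, grads)
            total += loss * len(idx)
            seen += len(idx)
        history.append(total / seen)
        logger.info("epoch %d/%d loss %.6f", epoch + 1, config.epochs,
                    history[-1])
    return params, history


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(params: ModelParams, config: ModelConfig, path) -> None:
    """Single binary container: arrays + config JSON + layout hash."""
    arrays = dict(_param_arrays(params))
    arrays["adjacency"] = params.graph.adjacency
    cfg = asdict(config)
    cfg["gcn_widths"] = list(config.gcn_widths)
    meta = {
        "config": cfg,
        "layout_hash": params.layout_hash,
        "n_gcn_layers": len(params.gcn),
        "gcn_activation": params.gcn[0].activation if params.gcn else "sigmoid",
        "format_version": 1,
    }
    buf = io.BytesIO()
    np.savez(buf, meta=np.array(json.dumps(meta)), **arrays)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def load_checkpoint(
    path, expected_layout_hash: str | None = None
) -> tuple[ModelParams, ModelConfig]:
    with np.load(path) as npz:
        meta = json.loads(str(npz["meta"][()]))
        arrays = {k: npz[k] for k in npz.files if k != "meta"}
    if (
        expected_layout_hash is not None
        and meta["layout_hash"]
        and meta["layout_hash"] != expected_layout_hash
    ):
        raise CheckpointError(
            f"checkpoint was trained on layout {meta['layout_hash']}, "
            f"got layout {expected_layout_hash}; refusing to load"
        )
    cfg_dict = dict(meta["config"])
    cfg_dict["gcn_widths"] = tuple(cfg_dict["gcn_widths"])
    config = ModelConfig(**cfg_dict)
    graph = TactileGraph(adjacency=arrays["adjacency"])
    gcn_layers = [
        GCNParams(weight=arrays[f"gcn_{i}"], layer_index=i,
                  activation=meta["gcn_activation"])
        for i in range(meta["n_gcn_layers"])
    ]
    lstm = LSTMParams(
        w_f=arrays["w_f"], w_i=arrays["w_i"], w_c=arrays["w_c"],
        w_o=arrays["w_o"], b_f=arrays["b_f"], b_i=arrays["b_i"],
        b_c=arrays["b_c"], b_o=arrays["b_o"],
    )
    params = ModelParams(
        graph=graph,
        norm=normalize_adjacency(graph),
        gcn=gcn_layers,
        lstm=lstm,
        shared=SharedLayer(w=arrays["shared_w"], b=arrays["shared_b"]),
        heads=TaskHeads(beta_reg=arrays["beta_reg"],
                        beta_cls=arrays["beta_cls"]),
        layout_hash=meta["layout_hash"],
    )
    return params, config


# ---------------------------------------------------------------------------
# Structural transforms
# ---------------------------------------------------------------------------


def permute_units(params: ModelParams, perm: np.ndarray) -> ModelParams:
    """Relabel the 40 units by ``perm`` consistently across all parameters.

    Node ``i`` of the permuted model corresponds to node ``perm[i]`` of
    the original; the adjacency, the node-blocked LSTM input columns and
    the node-blocked regression-head columns are permuted together, so
    predictions on permuted data equal permuted predictions.
    """
    perm = np.asarray(perm, dtype=int)
    n = params.graph.n_nodes
    a = params.graph.adjacency[np.ix_(perm, perm)]
    d_out = params.gcn[-1].d_out if params.gcn else 3
    hdim = params.lstm.hidden_size

    node_block = np.arange(n * d_out).reshape(n, d_out)[perm].ravel()
    col_perm = np.concatenate([np.arange(hdim), hdim + node_block])
    lstm = LSTMParams(
        w_f=params.lstm.w_f[:, col_perm],
        w_i=params.lstm.w_i[:, col_perm],
        w_c=params.lstm.w_c[:, col_perm],
        w_o=params.lstm.w_o[:, col_perm],
        b_f=params.lstm.b_f.copy(), b_i=params.lstm.b_i.copy(),
        b_c=params.lstm.b_c.copy(), b_o=params.lstm.b_o.copy(),
    )
    reg_block = np.arange(n * 3).reshape(n, 3)[perm].ravel()
    heads = TaskHeads(
        beta_reg=params.heads.beta_reg[:, reg_block],
        beta_cls=params.heads.beta_cls.copy(),
    )
    graph = TactileGraph(adjacency=a)
    return ModelParams(
        graph=graph,
        norm=normalize_adjacency(graph),
        gcn=[replace(layer, weight=layer.weight.copy())
             for layer in params.gcn],
        lstm=lstm,
        shared=SharedLayer(w=params.shared.w.copy(),
                           b=params.shared.b.copy()),
        heads=heads,
        layout_hash="",
    )
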