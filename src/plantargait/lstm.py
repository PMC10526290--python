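"""Gate-level LSTM over per-frame graph-convolution features.

The cell follows the classic formulation: with z_t = [h_{t-1}, x_t],

    f_t = sigma(W_f z_t + b_f)        forget gate
    i_t = sigma(W_i z_t + b_i)        input gate
    c~_t = tanh(W_c z_t + b_c)        candidate cell state
    C_t = f_t * C_{t-1} + i_t * c~_t
    o_t = sigma(W_o z_t + b_o)        output gate
    h_t = o_t * tanh(C_t)

Gate weights are H x (H + M): they act on the concatenation of the
previous hidden state (H) and the flattened GCN features (M).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gcn import ShapeError, sigmoid


@dataclass
class LSTMParams:
    w_f: np.ndarray
    w_i: np.ndarray
    w_c: np.ndarray
    w_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.w_f, self.w_i, self.w_c, self.w_o)}
        if len(shapes) != 1:
            raise ShapeError(f"gate matrices must share shape, got {shapes}")
        h = self.w_f.shape[0]
        for b in (self.b_f, self.b_i, self.b_c, self.b_o):
            if b.shape != (h,):
                raise ShapeError(f"bias shape {b.shape} != ({h},)")

    @property
    def hidden_size(self) -> int:
        return self.w_f.shape[0]

    @property
    def input_size(self) -> int:
        return self.w_f.shape[1] - self.w_f.shape[0]


@dataclass
class LSTMState:
    h: np.ndarray
    c: np.ndarray


def lstm_step(
    x_t: np.ndarray, state: LSTMState, params: LSTMParams
) -> LSTMState:
    """One cell update.  ``x_t`` is (M,) or (B, M) batched."""
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape[-1] != params.input_size:
        raise ShapeError(
            f"input width {x_t.shape[-1]} != params input_size "
            f"{params.input_size}"
        )
    if state.h.shape[-1] != params.hidden_size:
        raise ShapeError(
            f"hidden width {state.h.shape[-1]} != params hidden_size "
            f"{params.hidden_size}"
        )
    z = np.concatenate([state.h, x_t], axis=-1)
    f = sigmoid(z @ params.w_f.T + params.b_f)
    i = sigmoid(z @ params.w_i.T + params.b_i)
    c_tilde = np.tanh(z @ params.w_c.T + params.b_c)
    c = f * state.c + i * c_tilde
    o = sigmoid(z @ params.w_o.T + params.b_o)
    h = o * np.tanh(c)
    return LSTMState(h=h, c=c)


def zero_state(params: LSTMParams, batch: int | None = None) -> LSTMState:
    shape = (params.hidden_size,) if batch is None else (batch, params.hidden_size)
    return LSTMState(h=np.zeros(shape), c=np.zeros(shape))


def lstm_sequence(
    xs: np.ndarray, init: LSTMState, params: LSTMParams
) -> tuple[np.ndarray, LSTMState]:
    """Run the cell over a (T, M) or (T, B, M) sequence.

    Returns the stacked hidden states (T, ...) and the final state.
    """
    xs = np.asarray(xs, dtype=float)
    if xs.ndim < 2 or xs.shape[0] < 1:
        raise ValueError("sequence must have at least one time step")
    state = init
    hs = []
    for t in range(xs.shape[0]):
        state = lstm_step(xs[t], state, params)
        hs.append(state.h)
    return np.stack(hs, axis=0), state
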