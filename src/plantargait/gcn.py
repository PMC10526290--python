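"""Graph convolution layer: X' = sigma(L_sym X W) with logistic sigmoid.

One layer mixes each node's 3-axis force vector with its graph
neighbours through the symmetric normalized adjacency, then projects to
the layer width.  Outputs are therefore elementwise in (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import NormalizedAdjacency


class ShapeError(ValueError):
    pass


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic sigmoid."""
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class GCNParams:
    weight: np.ndarray  # (D_in, D_out)
    layer_index: int = 0
    activation: str = "sigmoid"  # "sigmoid" (default) or "relu"

    @property
    def d_in(self) -> int:
        return self.weight.shape[0]

    @property
    def d_out(self) -> int:
        return self.weight.shape[1]


def _activate(z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "sigmoid":
        return sigmoid(z)
    if activation == "relu":
        return np.maximum(z, 0.0)
    raise ValueError(f"unknown activation {activation!r}")


def gcn_forward(
    x: np.ndarray, l_sym: NormalizedAdjacency, params: GCNParams
) -> np.ndarray:
    """Apply one graph convolution: sigma(L_sym @ x @ W).

    ``x`` is (N, D_in) for one frame or (..., N, D_in) batched; the graph
    operator acts on the second-to-last axis.
    """
    x = np.asarray(x, dtype=float)
    n = l_sym.n_nodes
    if x.shape[-2] != n:
        raise ShapeError(
            f"node axis of x {x.shape} does not match l_sym ({n}, {n})"
        )
    if x.shape[-1] != params.d_in:
        raise ShapeError(
            f"feature axis of x {x.shape} does not match weight "
            f"{params.weight.shape}"
        )
    z = l_sym.l_sym @ x @ params.weight
    return _activate(z, params.activation)


def gcn_stack(
    x0: np.ndarray, l_sym: NormalizedAdjacency, layers: list[GCNParams]
) -> np.ndarray:
    """Sequentially apply graph convolutions; empty list is the identity."""
    x = np.asarray(x0, dtype=float)
    for idx, layer in enumerate(layers):
        if x.shape[-1] != layer.d_in:
            raise ShapeError(
                f"layer {idx}: input width {x.shape[-1]} does not match "
                f"weight {layer.weight.shape}"
            )
        x = gcn_forward(x, l_sym, layer)
    return x
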