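"""Static tactile graph over the sensor layout and its normalized form.

The propagation operator of the graph convolution is the symmetric
normalized adjacency with self-loops,

    L_sym = D^(-1/2) (A + I) D^(-1/2),

where D is the degree matrix of A + I.  Its eigenvalues lie in [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .layout import SensorUnit, positions, sensor_ids


class GraphConfigError(ValueError):
    pass


@dataclass
class TactileGraph:
    """Fixed undirected graph whose vertices are tactile units."""

    adjacency: np.ndarray  # (N, N) symmetric, nonnegative, zero diagonal
    edge_index: list[tuple[int, int]] = field(default_factory=list)
    weights_trainable: bool = False

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise GraphConfigError(f"adjacency must be square, got {a.shape}")
        if not np.allclose(a, a.T):
            raise GraphConfigError("adjacency must be symmetric")
        if np.any(a < 0):
            raise GraphConfigError("adjacency entries must be nonnegative")
        if np.any(np.diag(a) != 0):
            raise GraphConfigError("adjacency diagonal must be zero")
        self.adjacency = a
        if not self.edge_index:
            iu, ju = np.nonzero(np.triu(a))
            self.edge_index = list(zip(iu.tolist(), ju.tolist()))


@dataclass(frozen=True)
class NormalizedAdjacency:
    """L_sym = D^(-1/2)(A + I)D^(-1/2) and the degrees of A + I."""

    l_sym: np.ndarray
    degree: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.l_sym.shape[0]


def build_graph(
    units: list[SensorUnit],
    intra_policy: str = "full",
    inter_policy: dict | None = None,
) -> TactileGraph:
    """Construct the static tactile graph from the unit layout.

    Within each 8-unit sensor, ``intra_policy`` is either ``"full"``
    (complete subgraph) or ``"ring_center"`` (units chained in a ring by
    local index plus spokes from unit 0).  Between sensors, units of
    distinct sensors are linked by Euclidean distance: ``{"k_nearest": k}``
    joins each unit to its k nearest units in every other sensor (so the
    sensor-level graph is complete and the result is connected),
    ``{"radius": r_mm}`` joins all foreign pairs closer than r.  Default:
    full intra blocks with 1-nearest inter edges per unit per sensor.
    """
    if inter_policy is None:
        inter_policy = {"k_nearest": 1}
    xy = positions(units)
    sid = sensor_ids(units)
    n = len(units)
    a = np.zeros((n, n))

    for s in np.unique(sid):
        members = np.flatnonzero(sid == s)
        if intra_policy == "full":
            for i_, u in enumerate(members):
                for v in members[i_ + 1:]:
                    a[u, v] = a[v, u] = 1.0
        elif intra_policy == "ring_center":
            m = len(members)
            for i_ in range(m):
                u, v = members[i_], members[(i_ + 1) % m]
                a[u, v] = a[v, u] = 1.0
            for v in members[1:]:
                a[members[0], v] = a[v, members[0]] = 1.0
        else:
            raise GraphConfigError(f"unknown intra_policy {intra_policy!r}")

    dist = cdist(xy, xy)
    foreign = sid[:, None] != sid[None, :]
    if "k_nearest" in inter_policy:
        k = int(inter_policy["k_nearest"])
        if k < 1:
            raise GraphConfigError("k_nearest must be >= 1")
        for u in range(n):
            for s in np.unique(sid):
                if s == sid[u]:
                    continue
                members = np.flatnonzero(sid == s)
                nearest = members[np.argsort(dist[u, members])[:k]]
                for v in nearest:
                    a[u, v] = a[v, u] = 1.0
    elif "radius" in inter_policy:
        r = float(inter_policy["radius"])
        if r <= 0:
            raise GraphConfigError("radius must be > 0")
        close = foreign & (dist <= r)
        a[close] = 1.0
        a = np.maximum(a, a.T)
    else:
        raise GraphConfigError(f"unknown inter_policy {inter_policy!r}")

    np.fill_diagonal(a, 0.0)
    graph = TactileGraph(adjacency=a)
    if n_components(graph) > 1:
        warnings.warn(
            "tactile graph is disconnected under the chosen policies",
            stacklevel=2,
        )
    return graph


def n_components(graph: TactileGraph) -> int:
    """Connected-component count by breadth-first flood fill."""
    n = graph.n_nodes
    seen = np.zeros(n, dtype=bool)
    comps = 0
    for start in range(n):
        if seen[start]:
            continue
        comps += 1
        stack = [start]
        seen[start] = True
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(graph.adjacency[u] > 0):
                if not seen[v]:
                    seen[v] = True
                    stack.append(int(v))
    return comps


def normalize_adjacency(graph: TactileGraph) -> NormalizedAdjacency:
    """Symmetric normalization with self-loops.

    Returns L_sym = D^(-1/2)(A + I)D^(-1/2); D is the degree matrix of
    A + I, so every degree is >= 1 and the operator is well defined.
    """
    a = graph.adjacency
    a_hat = a + np.eye(graph.n_nodes)
    degree = a_hat.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(degree)
    l_sym = (d_inv_sqrt[:, None] * a_hat) * d_inv_sqrt[None, :]
    return NormalizedAdjacency(l_sym=l_sym, degree=degree)


def export_edge_list(graph: TactileGraph, path) -> None:
    rows = [
        {"u": u, "v": v, "weight": float(graph.adjacency[u, v])}
        for u, v in graph.edge_index
    ]
    pd.DataFrame(rows, columns=["u", "v", "weight"]).to_csv(path, index=False)
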