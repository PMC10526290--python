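"""Dataset containers, HDF5/CSV readers and writers, and windowing.

The on-disk container is an HDF5 file with groups ``/train`` and
``/test`` (or a single unnamed group for an unsplit set), each holding
``forces`` (float32, N x T x 40 x 3 newtons) and ``labels`` (int8,
N x T per-frame walking states), plus file-level attributes (seed,
sampling rate, condition, layout hash).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .layout import N_UNITS


class SchemaError(ValueError):
    pass


@dataclass
class TactileDataset:
    forces: np.ndarray   # (N, T, 40, 3) newtons
    labels: np.ndarray   # (N, T) int class indices
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f, y = np.asarray(self.forces), np.asarray(self.labels)
        if f.ndim != 4 or f.shape[2] != N_UNITS or f.shape[3] != 3:
            raise SchemaError(f"forces must be (N, T, 40, 3), got {f.shape}")
        if y.shape != f.shape[:2]:
            raise SchemaError(
                f"labels shape {y.shape} does not match forces {f.shape[:2]}"
            )

    @property
    def n_sequences(self) -> int:
        return self.forces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.forces.shape[1]


def _write_group(grp: h5py.Group, ds: TactileDataset) -> None:
    grp.create_dataset("forces", data=ds.forces.astype(np.float32),
                       compression="gzip", compression_opts=1)
    grp.create_dataset("labels", data=ds.labels.astype(np.int8),
                       compression="gzip", compression_opts=1)


def _read_group(grp: h5py.Group, meta: dict) -> TactileDataset:
    for name in ("forces", "labels"):
        if name not in grp:
            raise SchemaError(f"container missing array {name!r}")
    forces = grp["forces"][...]
    labels = grp["labels"][...]
    if forces.dtype != np.float32:
        raise SchemaError(f"forces dtype {forces.dtype}, expected float32")
    return TactileDataset(forces=forces, labels=labels, meta=meta)


def write_dataset(path, train: TactileDataset,
                  test: TactileDataset | None = None,
                  attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as fh:
        merged = {**(train.meta or {}), **(attrs or {})}
        for k, v in merged.items():
            if v is not None:
                fh.attrs[k] = v
        _write_group(fh.create_group("train"), train)
        if test is not None:
            _write_group(fh.create_group("test"), test)


def read_dataset(path) -> tuple[TactileDataset, TactileDataset | None]:
    with h5py.File(path, "r") as fh:
        meta = {k: (v.item() if hasattr(v, "item") else v)
                for k, v in fh.attrs.items()}
        if "train" not in fh:
            raise SchemaError("container missing group 'train'")
        train = _read_group(fh["train"], dict(meta, split="train"))
        test = None
        if "test" in fh:
            test = _read_group(fh["test"], dict(meta, split="test"))
    return train, test


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)


# ---------------------------------------------------------------------------
# Plain-CSV interoperability export (one row per frame)
# ---------------------------------------------------------------------------


def export_csv(ds: TactileDataset, path) -> None:
    """Flat CSV: sequence, frame, label, then fx/fy/fz per unit."""
    n, t = ds.n_sequences, ds.n_frames
    cols = {}
    cols["sequence"] = np.repeat(np.arange(n), t)
    cols["frame"] = np.tile(np.arange(t), n)
    cols["label"] = ds.labels.reshape(-1)
    flat = ds.forces.reshape(n * t, N_UNITS, 3)
    for u in range(N_UNITS):
        for a, axis in enumerate(("fx", "fy", "fz")):
            cols[f"u{u:02d}_{axis}"] = flat[:, u, a]
    pd.DataFrame(cols).to_csv(path, index=False)


def import_csv(path) -> TactileDataset:
    df = pd.read_csv(path)
    n = df["sequence"].nunique()
    t = df["frame"].nunique()
    force_cols = [f"u{u:02d}_{a}" for u in range(N_UNITS)
                  for a in ("fx", "fy", "fz")]
    missing = [c for c in force_cols if c not in df.columns]
    if missing:
        raise SchemaError(f"CSV missing force columns, e.g. {missing[0]}")
    df = df.sort_values(["sequence", "frame"])
    forces = df[force_cols].to_numpy(np.float32).reshape(n, t, N_UNITS, 3)
    labels = df["label"].to_numpy(np.int8).reshape(n, t)
    return TactileDataset(forces=forces, labels=labels, meta={"source": "csv"})


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------


@dataclass
class WindowSet:
    """Supervised (window, next-frame, next-label) triples for training."""

    windows: np.ndarray      # (K, n, 40, 3)
    next_frames: np.ndarray  # (K, 40, 3)
    labels: np.ndarray       # (K,)


@dataclass
class EvalWindows:
    """Windows paired with the full future horizon for per-step scoring."""

    windows: np.ndarray        # (K, n, 40, 3)
    future_frames: np.ndarray  # (K, horizon, 40, 3)
    future_labels: np.ndarray  # (K, horizon)


def training_windows(
    ds: TactileDataset,
    history_len: int,
    per_sequence: int = 3,
    rng: np.random.Generator | None = None,
) -> WindowSet:
    """Sample random anchors per sequence; target is frame/label at t+1."""
    rng = rng or np.random.default_rng(0)
    n_seq, t_frames = ds.n_sequences, ds.n_frames
    lo, hi = history_len - 1, t_frames - 2
    if hi < lo:
        raise ValueError("sequences shorter than history_len + 1")
    anchors = rng.integers(lo, hi + 1, size=(n_seq, per_sequence))
    windows, targets, labels = [], [], []
    for i in range(n_seq):
        for t in anchors[i]:
            windows.append(ds.forces[i, t - history_len + 1: t + 1])
            targets.append(ds.forces[i, t + 1])
            labels.append(ds.labels[i, t + 1])
    return WindowSet(
        windows=np.asarray(windows, dtype=float),
        next_frames=np.asarray(targets, dtype=float),
        labels=np.asarray(labels, dtype=int),
    )


def eval_windows(
    ds: TactileDataset,
    history_len: int,
    horizon: int,
    stride: int = 4,
) -> EvalWindows:
    """Deterministic anchors every ``stride`` frames with a full horizon.

    Sequences too short to carry a full horizon after the history window
    are skipped.
    """
    n_seq, t_frames = ds.n_sequences, ds.n_frames
    lo, hi = history_len - 1, t_frames - 1 - horizon
    if hi < lo:
        raise ValueError(
            f"sequences of {t_frames} frames cannot host history "
            f"{history_len} + horizon {horizon}"
        )
    anchor_ts = np.arange(lo, hi + 1, stride)
    windows, futures, flabels = [], [], []
    for i in range(n_seq):
        for t in anchor_ts:
            windows.append(ds.forces[i, t - history_len + 1: t + 1])
            futures.append(ds.forces[i, t + 1: t + 1 + horizon])
            flabels.append(ds.labels[i, t + 1: t + 1 + horizon])
    return EvalWindows(
        windows=np.asarray(windows, dtype=float),
        future_frames=np.asarray(futures, dtype=float),
        future_labels=np.asarray(flabels, dtype=int),
    )
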