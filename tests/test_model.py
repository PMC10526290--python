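import numpy as np
import pytest

from plantargait.datasets import WindowSet
from plantargait.gcn import gcn_stack
from plantargait.graph import TactileGraph, normalize_adjacency
from plantargait.lstm import LSTMState, lstm_sequence
from plantargait.model import (
    CheckpointError,
    ModelConfig,
    _loss_and_grads,
    _param_arrays,
    forward_window,
    init_params,
    load_checkpoint,
    permute_units,
    rollout,
    save_checkpoint,
    substream,
    train_model,
)
from plantargait.multitask import shared_forward, softmax, task_outputs


@pytest.fixture(scope="module")
def tiny_cfg():
    return ModelConfig(history_len=3, horizon=5, gcn_widths=(2,),
                       lstm_hidden=4, shared_nodes=3, epochs=1, seed=7)


@pytest.fixture(scope="module")
def tiny_params(tiny_cfg, graph):
    return init_params(tiny_cfg, graph, layout_hash="testlayout")


def test_zero_params_constant_output(graph, tiny_cfg):
    params = init_params(tiny_cfg, graph)
    for arr in _param_arrays(params).values():
        arr[:] = 0.0
    frame, scores = forward_window(np.zeros((3, 40, 3)), params)
    assert np.allclose(frame, 0)
    assert np.allclose(scores, 0)


def test_forward_is_pure(tiny_params, rng):
    win = rng.uniform(0, 60, (3, 40, 3))
    f1, s1 = forward_window(win, tiny_params)
    f2, s2 = forward_window(win.copy(), tiny_params)
    assert np.array_equal(f1, f2) and np.array_equal(s1, s2)


def test_matches_composition_of_public_ops(tiny_params, rng):
    """The assembled forward equals GCN stack -> flatten -> LSTM ->
    shared layer -> task heads built from the standalone operations."""
    win = rng.uniform(0, 60, (3, 40, 3))
    scaled = win / 60.0
    feats = gcn_stack(scaled, tiny_params.norm, tiny_params.gcn)
    seq = feats.reshape(3, -1)
    init = LSTMState(h=np.zeros(4), c=np.zeros(4))
    _, final = lstm_sequence(seq, init, tiny_params.lstm)
    shared = shared_forward(final.h, tiny_params.shared)
    exp_frame, exp_scores = task_outputs(shared, tiny_params.heads)
    got_frame, got_scores = forward_window(win, tiny_params)
    assert np.allclose(got_frame, exp_frame * 60.0, atol=1e-10)
    assert np.allclose(got_scores, exp_scores, atol=1e-10)


class TestRollout:
    def test_single_step_equals_forward_plus_softmax(self, tiny_params, rng):
        win = rng.uniform(0, 60, (3, 40, 3))
        bundle = rollout(win, tiny_params, t_out=1)
        frame, scores = forward_window(win, tiny_params)
        assert np.allclose(bundle.frames[0], frame, atol=1e-12)
        assert np.allclose(bundle.class_probs[0], softmax(scores), atol=1e-12)

    def test_unrolled_manual_loop(self, tiny_params, rng):
        win = rng.uniform(0, 60, (3, 40, 3))
        bundle = rollout(win, tiny_params, t_out=5)
        cur = win.copy()
        for k in range(5):
            frame, scores = forward_window(cur, tiny_params)
            assert np.allclose(bundle.frames[k], frame, atol=1e-9)
            cur = np.concatenate([cur[1:], frame[None]], axis=0)

    def test_prefix_consistency(self, tiny_params, rng):
        win = rng.uniform(0, 60, (3, 40, 3))
        b5 = rollout(win, tiny_params, t_out=5)
        b2 = rollout(win, tiny_params, t_out=2)
        assert np.array_equal(b5.frames[:2], b2.frames)
        assert np.array_equal(b5.class_probs[:2], b2.class_probs)

    def test_deterministic(self, tiny_params, rng):
        win = rng.uniform(0, 60, (3, 40, 3))
        a = rollout(win, tiny_params, t_out=4)
        b = rollout(win, tiny_params, t_out=4)
        assert np.array_equal(a.frames, b.frames)

    def test_labels_are_argmax_and_times_spaced(self, tiny_params, rng):
        win = rng.uniform(0, 60, (3, 40, 3))
        b = rollout(win, tiny_params, t_out=5, step_interval=0.2)
        assert np.array_equal(b.labels, b.class_probs.argmax(axis=1))
        assert np.allclose(b.per_step_time, [0.2, 0.4, 0.6, 0.8, 1.0])

    def test_bad_horizon(self, tiny_params):
        with pytest.raises(ValueError):
            rollout(np.zeros((3, 40, 3)), tiny_params, t_out=0)


def test_gradients_match_finite_differences(graph, rng):
    """Hand-derived reverse-mode gradients vs central differences for
    every parameter array, both loss modes."""
    cfg = ModelConfig(history_len=3, gcn_widths=(3, 2), lstm_hidden=4,
                      shared_nodes=3, seed=11)
    params = init_params(cfg, graph)
    xs = rng.uniform(0, 1, (3, 3, 40, 3))
    ys = rng.uniform(0, 1, (3, 40, 3))
    labels = rng.integers(0, 5, 3)
    for mode in ("l2_both", "l2_plus_xent"):
        _, grads = _loss_and_grads(xs, ys, labels, params, 0.8, mode)
        for name, arr in _param_arrays(params).items():
            flat_idx = rng.integers(0, arr.size, size=3)
            for fi in flat_idx:
                idx = np.unravel_index(fi, arr.shape)
                eps, orig = 1e-6, arr[idx]
                arr[idx] = orig + eps
                lp, _ = _loss_and_grads(xs, ys, labels, params, 0.8, mode)
                arr[idx] = orig - eps
                lm, _ = _loss_and_grads(xs, ys, labels, params, 0.8, mode)
                arr[idx] = orig
                fd = (lp - lm) / (2 * eps)
                g = grads[name][idx]
                assert abs(fd - g) <= 1e-4 * max(abs(fd), abs(g), 1e-3), (
                    f"{mode}/{name}{idx}: fd={fd} grad={g}"
                )


class TestTraining:
    def make_dataset(self, rng, n=10):
        return WindowSet(
            windows=rng.uniform(0, 60, (n, 3, 40, 3)),
            next_frames=rng.uniform(0, 60, (n, 40, 3)),
            labels=rng.integers(0, 5, n),
        )

    def test_zero_lr_leaves_params_unchanged(self, graph, rng):
        cfg = ModelConfig(history_len=3, gcn_widths=(2,), lstm_hidden=4,
                          shared_nodes=3, epochs=1, learning_rate=0.0,
                          seed=5)
        ds = self.make_dataset(rng)
        before = init_params(cfg, graph)
        snapshot = {k: v.copy() for k, v in _param_arrays(before).items()}
        after, history = train_model(ds, cfg, graph, params=before)
        for k, v in _param_arrays(after).items():
            assert np.array_equal(v, snapshot[k])
        assert len(history) == 1 and np.isfinite(history[0])

    def test_empty_dataset_rejected(self, graph):
        cfg = ModelConfig(history_len=3, gcn_widths=(2,), lstm_hidden=4,
                          shared_nodes=3, epochs=1)
        ds = WindowSet(windows=np.zeros((0, 3, 40, 3)),
                       next_frames=np.zeros((0, 40, 3)),
                       labels=np.zeros(0, dtype=int))
        with pytest.raises(ValueError, match="empty"):
            train_model(ds, cfg, graph)

    def test_seeded_init_is_reproducible(self, graph):
        cfg = ModelConfig(gcn_widths=(2,), lstm_hidden=4, shared_nodes=3,
                          seed=42)
        a = _param_arrays(init_params(cfg, graph))
        b = _param_arrays(init_params(cfg, graph))
        for k in a:
            assert np.array_equal(a[k], b[k])

    def test_substreams_are_independent(self):
        a = substream(3, "init").normal(size=4)
        b = substream(3, "shuffle").normal(size=4)
        assert not np.allclose(a, b)
        assert np.allclose(a, substream(3, "init").normal(size=4))


class TestCheckpoint:
    def test_round_trip_bitwise(self, tiny_params, tiny_cfg, tmp_path):
        p1 = tmp_path / "model.npz"
        p2 = tmp_path / "model2.npz"
        save_checkpoint(tiny_params, tiny_cfg, p1)
        loaded, cfg = load_checkpoint(p1, expected_layout_hash="testlayout")
        assert cfg == tiny_cfg
        orig, back = _param_arrays(tiny_params), _param_arrays(loaded)
        for k in orig:
            assert np.array_equal(orig[k], back[k])
        save_checkpoint(loaded, cfg, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_layout_mismatch_refused(self, tiny_params, tiny_cfg, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_params, tiny_cfg, path)
        with pytest.raises(CheckpointError, match="layout"):
            load_checkpoint(path, expected_layout_hash="otherlayout")


def test_unit_permutation_consistency(tiny_params, rng):
    """Relabeling the 40 units in data and parameters together permutes
    frame predictions and leaves class scores unchanged."""
    perm = rng.permutation(40)
    permuted = permute_units(tiny_params, perm)
    win = rng.uniform(0, 60, (3, 40, 3))
    f, s = forward_window(win, tiny_params)
    fp, sp = forward_window(win[:, perm, :], permuted)
    assert np.allclose(fp, f[perm], atol=1e-10)
    assert np.allclose(sp, s, atol=1e-10)
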