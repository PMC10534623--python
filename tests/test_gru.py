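"""GRU motion models: normalization, forward pass, gradients, training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from birdtrack.gru import (
    BiGruNet,
    GruConfig,
    GruMotionModel,
    NormScale,
    denormalize_state,
    load_checkpoint,
    normalize_window,
    save_checkpoint,
)
from birdtrack.linear import cv_matrix
from birdtrack.sim import SegmentSpec, SimConfig, downsample, generate_trajectory, observe
from birdtrack.train import (
    TrainConfig,
    make_training_set,
    partition_bins,
    train_model,
    save_dataset,
    load_dataset,
)

SCALE = NormScale(pos_scale=210.0, vel_scale=30.0)


class TestNormalization:
    def test_all_ref_zero_velocity_gives_zero_window(self):
        ref = np.array([100.0, 0.0, -50.0, 0.0])
        est = np.tile(ref, (7, 1))
        w = normalize_window(est, est, ref, SCALE)
        np.testing.assert_array_equal(w.rows, np.zeros((7, 8)))

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        est = rng.normal(0, 100, (7, 4))
        meas = rng.normal(0, 100, (7, 4))
        ref = est[-1]
        w = normalize_window(est, meas, ref, SCALE)
        back_est = denormalize_state(w.rows[:, :4], ref, SCALE)
        back_meas = denormalize_state(w.rows[:, 4:], ref, SCALE)
        np.testing.assert_allclose(back_est, est, atol=1e-9)
        np.testing.assert_allclose(back_meas, meas, atol=1e-9)

    def test_cv_track_bounded(self):
        # pos_scale = v_max * L * dt bounds any window cut from a track at v <= v_max
        L, dt, v = 7, 1.0, 15.0
        scale = NormScale(pos_scale=30.0 * L * dt, vel_scale=30.0)
        traj = downsample(generate_trajectory([SegmentSpec("CV", 20.0, v)], 0.1), dt)
        for i in range(1, len(traj) - L):
            w = normalize_window(traj.states[i:i + L], traj.states[i:i + L],
                                 traj.states[i + L - 1], scale)
            assert np.all(np.abs(w.rows) <= 1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            normalize_window(np.zeros((7, 4)), np.zeros((6, 4)), np.zeros(4), SCALE)


class TestForward:
    def test_deterministic_in_inference(self):
        cfg = GruConfig()
        net = BiGruNet(cfg, np.random.default_rng(0))
        x = np.random.default_rng(1).normal(0, 0.1, (3, 7, 8))
        np.testing.assert_array_equal(net.forward(x), net.forward(x))

    def test_output_inside_tanh_range(self):
        cfg = GruConfig()
        net = BiGruNet(cfg, np.random.default_rng(0))
        x = np.random.default_rng(2).normal(0, 5, (16, 7, 8))
        y = net.forward(x)
        assert np.all(np.abs(y) < 1.0)

    def test_shape_mismatch_rejected(self):
        net = BiGruNet(GruConfig(), np.random.default_rng(0))
        with pytest.raises(ValueError):
            net.forward(np.zeros((2, 5, 8)))


def test_gradients_match_finite_differences():
    """Backprop through the stacked bidirectional GRU against central differences."""
    cfg = GruConfig(num_layers=2, hidden_dim=4, window_len=3, dropout=0.0, input_dim=5, output_dim=2)
    rng = np.random.default_rng(0)
    net = BiGruNet(cfg, rng)
    X = rng.normal(0, 0.5, (4, 3, 5))
    Y = rng.normal(0, 0.5, (4, 2))

    def loss():
        d = net.forward(X, train=False) - Y
        return float(np.sum(d * d))

    pred = net.forward(X, train=True)
    grads = net.backward(2.0 * (pred - Y))
    eps = 1e-6
    check_rng = np.random.default_rng(1)
    for name, p in net.params.items():
        flat = p.reshape(-1)
        for idx in check_rng.choice(flat.size, size=min(4, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            lp = loss()
            flat[idx] = orig - eps
            lm = loss()
            flat[idx] = orig
            num = (lp - lm) / (2 * eps)
            ana = grads[name].reshape(-1)[idx]
            assert ana == pytest.approx(num, abs=1e-6, rel=1e-4), name


class TestMakeTrainingSet:
    def _track(self, n_samples=101):
        return generate_trajectory([SegmentSpec("CV", (n_samples - 1) * 0.1, 12.0)], 0.1)

    def test_window_count(self):
        ds = make_training_set([self._track()], (1.0, 1.0), SimConfig(seed=0))
        # 101 base samples -> 11 at 1 s; sliding from the second sample: 3 windows
        assert len(ds) == 3

    def test_noiseless_measurement_equals_truth_channel(self):
        ds = make_training_set([self._track()], (1.0, 1.0), SimConfig(delta_l=0.0, seed=0))
        np.testing.assert_allclose(ds.X[:, 1:, :4], ds.X[:, 1:, 4:], atol=1e-12)

    def test_bin_spans_ten_intervals(self):
        ds_narrow = make_training_set([self._track()], (1.0, 1.0), SimConfig(seed=0))
        ds_wide = make_training_set([self._track(201)], (0.1, 1.0), SimConfig(seed=0))
        # ten distinct scan intervals contribute windows in the wide bin
        assert len(ds_wide) > len(ds_narrow)
        from birdtrack.train import dt_values_in_bin

        assert len(dt_values_in_bin(0.1, 1.0)) == 10

    def test_short_trajectory_skipped(self):
        short = generate_trajectory([SegmentSpec("CV", 2.0, 12.0)], 0.1)
        with pytest.raises(ValueError):
            make_training_set([short], (5.0, 5.0), SimConfig(seed=0))


class TestPartitionBins:
    def test_five_reproduces_canonical_bins(self):
        assert partition_bins(5) == [(0.1, 1.0), (1.1, 2.0), (2.1, 3.0), (3.1, 4.0), (4.1, 5.0)]

    def test_single_bin_covers_full_range(self):
        assert partition_bins(1) == [(0.1, 5.0)]

    @pytest.mark.parametrize("n", [2, 3, 4, 7])
    def test_partition_tiles_grid(self, n):
        bins = partition_bins(n)
        grid = np.round(np.arange(0.1, 5.01, 0.1), 10)
        covered = []
        for lo, hi in bins:
            covered.extend(g for g in grid if lo - 1e-9 <= g <= hi + 1e-9)
        assert sorted(covered) == list(grid)
        assert len(covered) == len(set(covered))  # disjoint


@pytest.fixture(scope="module")
def toy_dataset():
    traj = generate_trajectory([SegmentSpec("CT", 60.0, 14.0, turn_rate=0.2)], 0.1)
    return make_training_set([traj], (1.0, 1.0), SimConfig(delta_l=0.5, seed=0), max_windows=32)


class TestTraining:
    def test_overfits_toy_dataset(self, toy_dataset):
        from birdtrack.train import _mse

        cfg = GruConfig(hidden_dim=16)
        tcfg = TrainConfig(batch_size=32, max_epochs=200, patience=200, weight_decay=0.0, seed=0)
        init_net = BiGruNet(cfg, np.random.default_rng(tcfg.seed))
        initial = _mse(init_net, toy_dataset.X, toy_dataset.Y)
        model = train_model(toy_dataset, gru_cfg=cfg, train_cfg=tcfg)
        final = _mse(model.net, toy_dataset.X, toy_dataset.Y)
        assert final < 1e-3 * initial

    def test_same_seed_identical_weights(self, toy_dataset):
        tcfg = TrainConfig(batch_size=32, max_epochs=10, seed=5)
        a = train_model(toy_dataset, train_cfg=tcfg)
        b = train_model(toy_dataset, train_cfg=tcfg)
        for k in a.net.params:
            np.testing.assert_array_equal(a.net.params[k], b.net.params[k])

    def test_checkpoint_validation_no_worse_than_init(self, toy_dataset):
        from birdtrack.train import _mse

        tcfg = TrainConfig(batch_size=32, max_epochs=15, seed=0)
        n_val = max(1, len(toy_dataset) // 10)
        vX, vY = toy_dataset.X[-n_val:], toy_dataset.Y[-n_val:]
        init_net = BiGruNet(GruConfig(), np.random.default_rng(tcfg.seed))
        model = train_model(toy_dataset, train_cfg=tcfg)
        assert _mse(model.net, vX, vY) <= _mse(init_net, vX, vY) + 1e-12


def test_training_recovery_on_single_regime_cv():
    """A model trained on one regime approaches the matched analytic predictor.

    Both predictors consume the same noisy measurement history of held-out
    constant-velocity tracks; the trained network's one-step position RMSE must
    come within a factor 2 of extrapolating the last measurement with the CV
    transition.
    """
    dt = 1.0
    cv_trajs = [
        generate_trajectory([SegmentSpec("CV", 120.0, s)], 0.1, heading=h)
        for s, h in [(10.0, 0.3), (14.0, 2.1), (18.0, 4.0), (12.0, 5.5)]
    ]
    ds = make_training_set(cv_trajs, (dt, dt), SimConfig(delta_l=1.0, seed=0), max_windows=4000)
    model = train_model(ds, train_cfg=TrainConfig(max_epochs=120, seed=0))

    test_traj = downsample(generate_trajectory([SegmentSpec("CV", 120.0, 16.0)], 0.1, heading=1.0), dt)
    frames = observe(test_traj, SimConfig(delta_t=dt, delta_l=1.0, seed=99))
    meas = np.stack([f.points[f.truth_index] for f in frames])
    L = model.config.window_len
    e_net, e_cv = [], []
    for i in range(1, len(test_traj) - L):
        target = test_traj.states[i + L]
        pred_net = model.predict(test_traj.states[i:i + L], meas[i:i + L])
        pred_cv = cv_matrix(dt) @ meas[i + L - 1]
        e_net.append(np.hypot(*(pred_net - target)[[0, 2]]))
        e_cv.append(np.hypot(*(pred_cv - target)[[0, 2]]))
    rmse_net = np.sqrt(np.mean(np.square(e_net)))
    rmse_cv = np.sqrt(np.mean(np.square(e_cv)))
    assert rmse_net <= 2.0 * rmse_cv


def test_checkpoint_round_trip(tmp_path):
    traj = generate_trajectory([SegmentSpec("CV", 30.0, 12.0)], 0.1)
    ds = make_training_set([traj], (1.0, 1.0), SimConfig(seed=0))
    model = train_model(ds, train_cfg=TrainConfig(batch_size=16, max_epochs=3, seed=0))
    save_checkpoint(model, tmp_path / "model_1")
    back = load_checkpoint(tmp_path / "model_1")
    assert back.delta_t_bin == model.delta_t_bin
    rng = np.random.default_rng(0)
    est, meas = rng.normal(0, 10, (7, 4)), rng.normal(0, 10, (7, 4))
    np.testing.assert_array_equal(back.predict(est, meas), model.predict(est, meas))


def test_dataset_hdf5_round_trip(tmp_path):
    traj = generate_trajectory([SegmentSpec("CV", 30.0, 12.0)], 0.1)
    ds = make_training_set([traj], (1.0, 1.0), SimConfig(seed=0))
    save_dataset(ds, tmp_path / "cache.h5")
    back = load_dataset(tmp_path / "cache.h5")
    np.testing.assert_array_equal(back.X, ds.X)
    np.testing.assert_array_equal(back.Y, ds.Y)
    assert back.delta_t_bin == ds.delta_t_bin
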