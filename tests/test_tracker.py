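"""IMM tracking loop: gating, Kalman update, Bayes weights, invariants."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from birdtrack.linear import cv_matrix
from birdtrack.sim import ScanFrame, SegmentSpec, SimConfig, downsample, generate_trajectory, observe
from birdtrack.tracker import (
    AnalyticCtModel,
    AnalyticCvModel,
    ModelBankState,
    TrackerConfig,
    combine_predictions,
    init_track,
    kalman_update,
    mixture_density,
    run_tracker,
    select_measurement,
    step,
    update_weights,
)

from conftest import textbook_cv_kalman


def cv_frames(duration=60.0, dt=1.0, delta_l=0.0, seed=0, speed=12.0, p_fa=0.0):
    traj = downsample(generate_trajectory([SegmentSpec("CV", duration, speed)], 0.1), dt)
    return traj, observe(traj, SimConfig(delta_t=dt, delta_l=delta_l, p_fa=p_fa, seed=seed))


class TestInitTrack:
    def test_noiseless_cv_warmup_matches_truth(self):
        traj, frames = cv_frames()
        state = init_track(frames, TrackerConfig(), n_models=3)
        np.testing.assert_allclose(state.est[0], traj.states[7], atol=1e-6)
        np.testing.assert_allclose(state.est_hist[0, -1], traj.states[7], atol=1e-6)

    def test_uniform_initial_weights(self):
        _, frames = cv_frames()
        state = init_track(frames, TrackerConfig(), n_models=5)
        np.testing.assert_allclose(state.mu, 0.2)

    def test_too_few_frames_rejected(self):
        _, frames = cv_frames()
        with pytest.raises(ValueError):
            init_track(frames[:5], TrackerConfig(), n_models=1)

    def test_warmup_filters_noise(self):
        # KF averaging: warm-up estimate beats the raw measurement, MC over 100 seeds
        err_est, err_meas = [], []
        for seed in range(100):
            traj, frames = cv_frames(delta_l=1.5, seed=seed)
            state = init_track(frames, TrackerConfig(), n_models=1)
            truth = traj.states[7, [0, 2]]
            err_est.append(np.sum((state.est[0][[0, 2]] - truth) ** 2))
            err_meas.append(np.sum((frames[7].points[0][[0, 2]] - truth) ** 2))
        assert np.sqrt(np.mean(err_est)) <= np.sqrt(np.mean(err_meas))


class TestMixtureDensity:
    CFG = TrackerConfig(R=np.zeros((4, 4)))

    def test_single_component_mode_height(self):
        pred = np.array([10.0, 1.0, -5.0, 0.0])
        S = np.diag([2.0, 1.0, 3.0, 1.0])
        d = mixture_density(pred, pred[None], S[None], np.array([1.0]), self.CFG)
        assert d == pytest.approx(1.0 / (2 * np.pi * np.sqrt(6.0)))

    def test_mirror_symmetry(self):
        preds = np.array([[5.0, 0, 0, 0], [-5.0, 0, 0, 0]])
        S = np.stack([np.eye(4)] * 2)
        mu = np.array([0.5, 0.5])
        da = mixture_density(np.array([3.0, 0, 0, 0]), preds, S, mu, self.CFG)
        db = mixture_density(np.array([-3.0, 0, 0, 0]), preds, S, mu, self.CFG)
        assert da == pytest.approx(db)

    def test_matches_scipy_mixture(self):
        rng = np.random.default_rng(0)
        cfg = TrackerConfig()
        for _ in range(20):
            preds = rng.normal(0, 10, (3, 4))
            covs = np.stack([np.diag(rng.uniform(1, 5, 4)) for _ in range(3)])
            mu = rng.dirichlet(np.ones(3))
            z = rng.normal(0, 10, 4)
            expected = sum(
                w * multivariate_normal.pdf(z[[0, 2]], mean=p[[0, 2]],
                                            cov=(S + cfg.R)[np.ix_([0, 2], [0, 2])])
                for w, p, S in zip(mu, preds, covs)
            )
            assert mixture_density(z, preds, covs, mu, cfg) == pytest.approx(expected)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            mixture_density(np.zeros(4), np.zeros((2, 4)), np.stack([np.eye(4)] * 2),
                            np.array([0.7, 0.7]), TrackerConfig())


class TestSelectMeasurement:
    def _phase(self):
        preds = np.array([[0.0, 10.0, 0.0, 0.0]])
        covs = np.stack([4.0 * np.eye(4)])
        return preds, covs, np.array([1.0])

    def test_single_point(self):
        preds, covs, mu = self._phase()
        frame = ScanFrame(0.0, np.array([[1.0, 10.0, 1.0, 0.0]]), 0)
        idx, _ = select_measurement(frame, preds, covs, mu, TrackerConfig())
        assert idx == 0

    def test_density_dominance(self):
        preds, covs, mu = self._phase()
        frame = ScanFrame(0.0, np.array([[500.0, 0.0, 500.0, 0.0], [0.0, 10.0, 0.0, 0.0]]), 1)
        idx, dens = select_measurement(frame, preds, covs, mu, TrackerConfig())
        assert idx == 1 and dens > 0

    def test_tie_breaks_to_lowest_index(self):
        preds, covs, mu = self._phase()
        pt = np.array([1.0, 10.0, 1.0, 0.0])
        frame = ScanFrame(0.0, np.stack([pt, pt]), 0)
        idx, _ = select_measurement(frame, preds, covs, mu, TrackerConfig())
        assert idx == 0


class TestKalmanUpdate:
    def test_perfect_measurement(self):
        cfg = TrackerConfig(R=1e-14 * np.eye(4))
        z = np.array([1.0, 2.0, 3.0, 4.0])
        est, _ = kalman_update(np.zeros(4), np.eye(4), z, cfg)
        np.testing.assert_allclose(est, z, atol=1e-9)

    def test_perfect_prior(self):
        cfg = TrackerConfig()
        pred = np.array([1.0, 2.0, 3.0, 4.0])
        est, S = kalman_update(pred, np.zeros((4, 4)), np.ones(4), cfg)
        np.testing.assert_allclose(est, pred, atol=1e-12)
        np.testing.assert_allclose(S, 0.0, atol=1e-12)

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(4)
        cfg = TrackerConfig()
        for _ in range(50):
            A = rng.normal(size=(4, 4))
            S = A @ A.T + 0.1 * np.eye(4)
            pred = rng.normal(0, 10, 4)
            z = rng.normal(0, 10, 4)
            est, S_est = kalman_update(pred, S, z, cfg)
            K = S @ np.linalg.inv(S + cfg.R)
            est_o = pred + K @ (z - pred)
            S_o = (np.eye(4) - K) @ S
            np.testing.assert_allclose(est, est_o, atol=1e-9)
            np.testing.assert_allclose(S_est, 0.5 * (S_o + S_o.T), atol=1e-9)
            assert np.linalg.eigvalsh(S_est).min() > -1e-9


class TestUpdateWeights:
    def test_equal_likelihoods_leave_weights(self):
        mu = np.array([0.3, 0.7])
        np.testing.assert_allclose(update_weights(mu, np.array([2.0, 2.0]), 0.0), mu)

    def test_single_model(self):
        np.testing.assert_array_equal(update_weights(np.array([1.0]), np.array([0.1]), 0.0), [1.0])

    def test_bayes_arithmetic(self):
        out = update_weights(np.array([0.5, 0.5]), np.array([3.0, 1.0]), 0.0)
        np.testing.assert_allclose(out, [0.75, 0.25])

    def test_zero_likelihoods_leave_weights(self):
        mu = np.array([0.4, 0.6])
        np.testing.assert_array_equal(update_weights(mu, np.zeros(2), 0.01), mu)

    def test_floor_prevents_lockout(self):
        out = update_weights(np.array([0.5, 0.5]), np.array([1.0, 0.0]), 0.05)
        assert out[1] >= 0.04 and abs(out.sum() - 1.0) < 1e-12


class TestCombinePredictions:
    def test_selects_first(self):
        preds = np.array([[1.0, 1, 1, 1], [9.0, 9, 9, 9]])
        np.testing.assert_array_equal(combine_predictions(preds, np.array([1.0, 0.0])), preds[0])

    def test_identical_predictions(self):
        preds = np.tile([2.0, 3, 4, 5], (3, 1))
        np.testing.assert_allclose(combine_predictions(preds, np.full(3, 1 / 3)), preds[0])

    def test_midpoint(self):
        preds = np.array([[0.0, 0, 0, 0], [2.0, 2, 2, 2]])
        np.testing.assert_allclose(combine_predictions(preds, np.array([0.5, 0.5])), np.ones(4))


class TestStepInvariants:
    def test_weights_stay_on_simplex(self):
        _, frames = cv_frames(delta_l=1.0, seed=3)
        bank = [AnalyticCvModel(), AnalyticCtModel(0.2), AnalyticCtModel(-0.2)]
        res = run_tracker(frames, bank, TrackerConfig())
        np.testing.assert_allclose(res.weights.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(res.weights >= 0)

    def test_single_model_weight_trace_constant(self):
        _, frames = cv_frames(delta_l=1.0, seed=5)
        res = run_tracker(frames, [AnalyticCvModel()], TrackerConfig())
        np.testing.assert_array_equal(res.weights, np.ones((len(res), 1)))

    def test_covariances_stay_psd(self):
        _, frames = cv_frames(delta_l=1.0, seed=6)
        cfg = TrackerConfig()
        bank = [AnalyticCvModel(), AnalyticCtModel(0.3)]
        state = init_track(frames, cfg, n_models=2)
        for frame in frames[8:]:
            state, _ = step(state, frame, bank, cfg)
            for S in state.S:
                np.testing.assert_allclose(S, S.T, atol=1e-9)
                assert np.linalg.eigvalsh(S).min() > -1e-9

    def test_noiseless_cv_tracks_exactly(self):
        traj, frames = cv_frames(delta_l=0.0)
        res = run_tracker(frames, [AnalyticCvModel()], TrackerConfig())
        np.testing.assert_allclose(res.estimates, traj.states[8:], atol=1e-6)


class TestMixing:
    def test_identity_mixing_changes_nothing(self):
        _, frames = cv_frames(delta_l=1.0, seed=12)
        bank = [AnalyticCvModel(), AnalyticCtModel(0.2)]
        plain = run_tracker(frames, bank, TrackerConfig())
        mixed = run_tracker(frames, bank, TrackerConfig(mixing=np.eye(2)))
        np.testing.assert_array_equal(plain.weights, mixed.weights)
        np.testing.assert_array_equal(plain.estimates, mixed.estimates)

    def test_uniform_mixing_pulls_weights_together(self):
        _, frames = cv_frames(delta_l=1.0, seed=13)
        bank = [AnalyticCvModel(), AnalyticCtModel(0.4)]
        plain = run_tracker(frames, bank, TrackerConfig(mu_floor=0.0))
        mixed = run_tracker(frames, bank, TrackerConfig(mu_floor=0.0, mixing=np.full((2, 2), 0.5)))
        # full mixing resets the prior each step, so the posterior gap between
        # the matched and mismatched model shrinks on average
        assert np.mean(np.abs(mixed.weights[:, 0] - 0.5)) <= np.mean(np.abs(plain.weights[:, 0] - 0.5))

    def test_invalid_mixing_rejected(self):
        with pytest.raises(ValueError):
            TrackerConfig(mixing=np.array([[0.5, 0.2], [0.1, 0.9]]))


def test_reduces_to_cv_kalman_filter():
    """With one exact CV predictor the whole loop is algebraically a CV KF."""
    _, frames = cv_frames(duration=210.0, delta_l=1.0, seed=9)
    cfg = TrackerConfig()
    res = run_tracker(frames, [AnalyticCvModel()], cfg)
    times, oracle = textbook_cv_kalman(frames, cfg.Q, cfg.R)
    keep = np.isin(times, res.times)
    np.testing.assert_allclose(res.estimates, oracle[keep], atol=1e-9)


def test_regime_identification(bank5):
    """On a long single-regime run the bin-matched model gets the top weight."""
    from birdtrack.experiments import circular_trajectory
    from birdtrack.metrics import weight_statistics

    truth = downsample(circular_trajectory(duration=300.0), 1.0)
    frames = observe(truth, SimConfig(delta_t=1.0, delta_l=1.0, seed=21))
    res = run_tracker(frames, bank5, TrackerConfig())
    mw = weight_statistics(res)
    assert int(np.argmax(mw)) == 0


def test_track_result_csv(tmp_path):
    _, frames = cv_frames(delta_l=1.0, seed=1)
    res = run_tracker(frames, [AnalyticCvModel()], TrackerConfig())
    res.to_csv(tmp_path / "track.csv")
    import pandas as pd

    df = pd.read_csv(tmp_path / "track.csv")
    assert list(df.columns) == ["t", "x_pred", "y_pred", "x_est", "y_est",
                                "mu_1", "chosen_point_id", "gate_density"]
    assert len(df) == len(res)
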