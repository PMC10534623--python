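import numpy as np
import pytest

from birdtrack.experiments import piecewise_trajectory
from birdtrack.sim import SimConfig
from birdtrack.train import TrainConfig, build_bank


@pytest.fixture(scope="session")
def training_trajectories():
    """Bird-like synthetic trajectories shared by every training fixture."""
    rng = np.random.default_rng(123)
    return [piecewise_trajectory(rng, duration=240.0) for _ in range(8)]


@pytest.fixture(scope="session")
def bank5(training_trajectories):
    """A five-model bank at reduced problem size (fewer windows, capped epochs)
    so the whole suite stays fast; the acceptance script trains at full scale."""
    return build_bank(
        training_trajectories,
        n_models=5,
        train_cfg=TrainConfig(max_epochs=120, seed=0),
        sim_cfg=SimConfig(seed=0),
        max_windows=1200,
    )


def textbook_cv_kalman(frames, Q, R):
    """Independent oracle: a plain constant-velocity Kalman filter over scans,
    initialised from the first frame's first point with covariance R.
    Returns (times, estimates) for every frame after the first."""
    from birdtrack.linear import cv_matrix

    x = frames[0].points[0].astype(float).copy()
    S = R.copy()
    times, ests = [], []
    t_prev = frames[0].time
    for f in frames[1:]:
        T = f.time - t_prev
        t_prev = f.time
        F = cv_matrix(T)
        x = F @ x
        S = F @ S @ F.T + Q
        z = f.points[0]
        K = S @ np.linalg.inv(S + R)
        x = x + K @ (z - x)
        S = (np.eye(4) - K) @ S
        times.append(f.time)
        ests.append(x.copy())
    return np.array(times), np.stack(ests)
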