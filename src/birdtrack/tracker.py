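"""The interacting-multiple-model tracking loop over a motion-model bank.

Per scan, the cycle is: (1) every model in the bank predicts the next state
from its own recent estimates and the shared measurements; (2) each prediction
is given a linear stand-in transition (the fitted CV/CT blend) so a covariance
can be propagated; (3) the scan's candidate points are scored under the
predictive mixture-Gaussian density and the most probable one is taken as the
target measurement (false-alarm gating); (4) each model's state is corrected by
a Kalman update; (5) model probabilities are re-weighted by Bayes' rule from
the per-model predictive likelihood of the chosen measurement; (6) the
combined estimate and prediction are probability-weighted sums.

Measurements are 4-vectors [x, vx, y, vy] with velocity obtained by position
differencing, so the measurement matrix H is the identity by default.  Gating
and weighting densities are evaluated on the 2-D position marginal by default
(differenced velocities are strongly correlated with positions and would
double-count the noise); the full 4-D density is a configuration switch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linear import approx_transfer, cv_matrix, ct_matrix, estimate_turn_rate, propagate_covariance

logger = logging.getLogger(__name__)

__all__ = [
    "TrackerConfig",
    "ModelBankState",
    "TrackResult",
    "AnalyticCvModel",
    "AnalyticCtModel",
    "init_track",
    "mixture_density",
    "select_measurement",
    "kalman_update",
    "update_weights",
    "combine_predictions",
    "predict_phase",
    "step",
    "run_tracker",
]

_POS = np.array([0, 2])  # indices of x, y in the state vector
_TINY = 1e-300


@dataclass
class TrackerConfig:
    """Filter parameters.

    Q (process) and R (measurement) noise covariances default to 16*I and 4*I:
    a deliberately distrustful process model so the filter re-converges fast
    after unmodelled manoeuvres, and a measurement covariance matching ~2 m
    position noise.  mu_floor keeps every model's probability recoverable;
    floor 0 lets Bayes updates saturate completely.  mixing, if given, is a
    Markov model-transition matrix applied to the weights before each
    prediction (off by default: the weight update is pure Bayes).
    """

    Q: np.ndarray = field(default_factory=lambda: 16.0 * np.eye(4))
    R: np.ndarray = field(default_factory=lambda: 4.0 * np.eye(4))
    H: np.ndarray = field(default_factory=lambda: np.eye(4))
    mu_floor: float = 1e-3
    window_len: int = 7
    gate_4d: bool = False
    pseudo_r_inflation: float = 10.0
    mixing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        for M in (self.Q, self.R):
            if not np.allclose(M, M.T, atol=1e-9) or np.linalg.eigvalsh(M).min() < -1e-9:
                raise ValueError("Q and R must be symmetric PSD")
        if not 0.0 <= self.mu_floor <= 0.1:
            raise ValueError("mu_floor must lie in [0, 0.1]")
        if self.mixing is not None:
            self.mixing = np.asarray(self.mixing, dtype=float)
            if not np.allclose(self.mixing.sum(axis=1), 1.0, atol=1e-9) or (self.mixing < 0).any():
                raise ValueError("mixing rows must be probabilities summing to 1")


class AnalyticCvModel:
    """Exact constant-velocity predictor (diagnostics and degenerate banks)."""

    def predict(self, est_hist: np.ndarray, meas_hist: np.ndarray, T: float) -> np.ndarray:
        del meas_hist
        return cv_matrix(T) @ np.asarray(est_hist)[-1]


class AnalyticCtModel:
    """Exact coordinated-turn predictor at a fixed turn rate."""

    def __init__(self, omega: float):
        self.omega = omega

    def predict(self, est_hist: np.ndarray, meas_hist: np.ndarray, T: float) -> np.ndarray:
        del meas_hist
        return ct_matrix(T, self.omega) @ np.asarray(est_hist)[-1]


@dataclass
class ModelBankState:
    """Joint state of the bank: per-model beliefs plus shared history.

    Models keep their own estimates (each one's input window reflects its own
    past predictions) but share the selected measurements.
    """

    t: float
    est: np.ndarray        # (n, 4) per-model estimates
    S: np.ndarray          # (n, 4, 4) per-model covariances
    mu: np.ndarray         # (n,) model probabilities, simplex
    est_hist: np.ndarray   # (n, L, 4)
    meas_hist: np.ndarray  # (L, 4)

    @property
    def n_models(self) -> int:
        return len(self.mu)

    def copy(self) -> "ModelBankState":
        return ModelBankState(
            t=self.t, est=self.est.copy(), S=self.S.copy(), mu=self.mu.copy(),
            est_hist=self.est_hist.copy(), meas_hist=self.meas_hist.copy(),
        )


@dataclass
class TrackResult:
    """Per-step tracking output (one row per scan after warm-up)."""

    times: np.ndarray
    predictions: np.ndarray   # combined predictions X_{k/k-1}, (N, 4)
    estimates: np.ndarray     # combined estimates, (N, 4)
    weights: np.ndarray       # (N, n_models)
    chosen_index: np.ndarray  # selected point id per frame
    gate_density: np.ndarray  # mixture density of the selected point

    def __len__(self) -> int:
        return len(self.times)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"t": self.times, "x_pred": self.predictions[:, 0], "y_pred": self.predictions[:, 2],
             "x_est": self.estimates[:, 0], "y_est": self.estimates[:, 2]}
        )
        for j in range(self.weights.shape[1]):
            df[f"mu_{j + 1}"] = self.weights[:, j]
        df["chosen_point_id"] = self.chosen_index
        df["gate_density"] = self.gate_density
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_records(cls, records: list[dict]) -> "TrackResult":
        return cls(
            times=np.array([r["time"] for r in records]),
            predictions=np.stack([r["pred"] for r in records]),
            estimates=np.stack([r["est"] for r in records]),
            weights=np.stack([r["mu"] for r in records]),
            chosen_index=np.array([r["chosen"] for r in records], dtype=int),
            gate_density=np.array([r["density"] for r in records]),
        )


# ----------------------------------------------------------------------------
# densities

def _gauss_pdf(z: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Multivariate normal pdf with defensive regularisation."""
    d = len(mean)
    diff = z - mean
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        logger.warning("singular component covariance; regularising with 1e-9*I")
        L = np.linalg.cholesky(cov + 1e-9 * np.eye(d))
    sol = np.linalg.solve(L, diff)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return float(np.exp(-0.5 * (sol @ sol) - 0.5 * (d * np.log(2.0 * np.pi) + logdet)))


def _component_density(z: np.ndarray, pred: np.ndarray, S_pred: np.ndarray, cfg: TrackerConfig) -> float:
    """Predictive density of measurement z under one model's prediction."""
    H, R = cfg.H, cfg.R
    mean = H @ pred
    cov = H @ S_pred @ H.T + R
    if cfg.gate_4d:
        return _gauss_pdf(z, mean, cov)
    idx = np.ix_(_POS, _POS)
    return _gauss_pdf(z[_POS], mean[_POS], cov[idx])


def mixture_density(
    z: np.ndarray, predictions: np.ndarray, covs: np.ndarray, weights: np.ndarray,
    cfg: TrackerConfig,
) -> float:
    """Probability-weighted mixture of per-model predictive densities at z."""
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError("model weights must sum to 1")
    return float(sum(
        w * _component_density(np.asarray(z, float), p, S, cfg)
        for w, p, S in zip(weights, predictions, covs)
    ))


def select_measurement(frame, predictions, covs, weights, cfg: TrackerConfig):
    """Most probable candidate point under the predictive mixture.

    Returns (index, density); ties break toward the lowest point index.
    """
    densities = np.array([mixture_density(p, predictions, covs, weights, cfg) for p in frame.points])
    idx = int(np.argmax(densities))  # argmax returns the first maximiser
    return idx, float(densities[idx])


# ----------------------------------------------------------------------------
# Kalman machinery

def kalman_update(pred: np.ndarray, S_pred: np.ndarray, z: np.ndarray, cfg: TrackerConfig,
                  R: np.ndarray | None = None):
    """Standard Kalman correction of one model's prediction by measurement z."""
    H = cfg.H
    R = cfg.R if R is None else R
    innov_cov = H @ S_pred @ H.T + R
    try:
        gain = np.linalg.solve(innov_cov.T, (S_pred @ H.T).T).T
    except np.linalg.LinAlgError:
        logger.warning("singular innovation covariance; regularising")
        gain = np.linalg.solve((innov_cov + 1e-9 * np.eye(len(innov_cov))).T, (S_pred @ H.T).T).T
    est = pred + gain @ (z - H @ pred)
    S_est = (np.eye(len(pred)) - gain @ H) @ S_pred
    return est, 0.5 * (S_est + S_est.T)


def update_weights(mu: np.ndarray, likelihoods: np.ndarray, floor: float) -> np.ndarray:
    """Bayes re-weighting mu' ~ likelihood * mu, with an optional floor.

    The floor is applied after normalisation and followed by renormalisation,
    preventing irrecoverable lock-out of a model.  If every likelihood is zero
    the weights are returned unchanged.
    """
    mu = np.asarray(mu, dtype=float)
    lik = np.asarray(likelihoods, dtype=float)
    w = mu * lik
    total = w.sum()
    if total <= 0.0:
        return mu.copy()
    w = w / total
    if floor > 0.0:
        w = np.maximum(w, floor)
        w = w / w.sum()
    return w


def combine_predictions(preds: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Probability-weighted mean of the per-model predictions."""
    mu = np.asarray(mu, dtype=float)
    if abs(mu.sum() - 1.0) > 1e-6:
        raise ValueError("model weights must sum to 1")
    return np.einsum("j,jk->k", mu, np.asarray(preds, dtype=float))


# ----------------------------------------------------------------------------
# the tracking loop, split into a predict phase and an update phase so the
# back-tracking beam can score candidate measurements between the two.

@dataclass
class PredictPhase:
    T: float
    time: float
    preds: np.ndarray    # (n, 4)
    S_pred: np.ndarray   # (n, 4, 4)
    mu: np.ndarray       # prior weights for this step (after optional mixing)
    combined_pred: np.ndarray


def predict_phase(state: ModelBankState, frame_time: float, bank, cfg: TrackerConfig) -> PredictPhase:
    """Per-model prediction and covariance propagation up to frame_time."""
    T = frame_time - state.t
    if T <= 0:
        raise ValueError("frames must be strictly increasing in time")
    n = state.n_models
    preds = np.empty((n, 4))
    S_pred = np.empty((n, 4, 4))
    for j in range(n):
        preds[j] = bank[j].predict(state.est_hist[j], state.meas_hist, T)
        omega = estimate_turn_rate(state.est_hist[j][-2], state.est_hist[j][-1], T)
        F = approx_transfer(state.est[j], preds[j], T, omega)
        S_pred[j] = propagate_covariance(F.entries, state.S[j], cfg.Q)
    mu = state.mu if cfg.mixing is None else cfg.mixing.T @ state.mu
    combined = combine_predictions(preds, mu)
    return PredictPhase(T=T, time=frame_time, preds=preds, S_pred=S_pred, mu=mu, combined_pred=combined)


def update_phase(
    state: ModelBankState, phase: PredictPhase, z: np.ndarray | None,
    chosen: int, density: float, cfg: TrackerConfig,
) -> tuple[ModelBankState, dict]:
    """Correct every model with measurement z and re-weight the bank.

    z=None carries the combined prediction forward as a pseudo-measurement
    with inflated measurement covariance (degenerate frame handling).
    """
    n = state.n_models
    R = cfg.R
    if z is None:
        z = cfg.H @ phase.combined_pred
        R = cfg.R * cfg.pseudo_r_inflation
        logger.warning("no measurement at t=%.3f; carrying prediction forward", phase.time)
    new_est = np.empty_like(state.est)
    new_S = np.empty_like(state.S)
    lik = np.empty(n)
    for j in range(n):
        lik[j] = _component_density(z, phase.preds[j], phase.S_pred[j], cfg)
        new_est[j], new_S[j] = kalman_update(phase.preds[j], phase.S_pred[j], z, cfg, R=R)
    mu = update_weights(phase.mu, lik, cfg.mu_floor)
    combined_est = np.einsum("j,jk->k", mu, new_est)
    new_state = ModelBankState(
        t=phase.time, est=new_est, S=new_S, mu=mu,
        est_hist=np.concatenate([state.est_hist[:, 1:], new_est[:, None, :]], axis=1),
        meas_hist=np.vstack([state.meas_hist[1:], z]),
    )
    record = {
        "time": phase.time, "pred": phase.combined_pred, "est": combined_est,
        "mu": mu, "chosen": chosen, "density": density,
    }
    return new_state, record


def step(state: ModelBankState, frame, bank, cfg: TrackerConfig) -> tuple[ModelBankState, dict]:
    """One full cycle: predict, gate, update, re-weight, combine."""
    phase = predict_phase(state, frame.time, bank, cfg)
    chosen, density = select_measurement(frame, phase.preds, phase.S_pred, phase.mu, cfg)
    return update_phase(state, phase, frame.points[chosen], chosen, density, cfg)


def init_track(frames, cfg: TrackerConfig, n_models: int) -> ModelBankState:
    """Warm start: a CV Kalman filter over the first L+1 frames.

    Warm-up frames are consumed single-point (first point per frame; no gating
    yet).  The filter's estimates fill the length-L history every motion model
    needs, model weights start uniform, and the warm-up posterior covariance
    seeds every model.
    """
    L = cfg.window_len
    if len(frames) < L + 1:
        raise ValueError(f"warm start needs at least {L + 1} frames")
    frames = frames[:L + 1]
    x = frames[0].points[0].astype(float).copy()
    S = cfg.R.copy()
    est_list, meas_list = [], []
    for prev, cur in zip(frames[:-1], frames[1:]):
        T = cur.time - prev.time
        F = cv_matrix(T)
        x = F @ x
        S = propagate_covariance(F, S, cfg.Q)
        z = cur.points[0]
        x, S = kalman_update(x, S, z, cfg)
        est_list.append(x.copy())
        meas_list.append(z.copy())
    est_hist = np.broadcast_to(np.stack(est_list), (n_models, L, 4)).copy()
    return ModelBankState(
        t=frames[-1].time,
        est=np.broadcast_to(x, (n_models, 4)).copy(),
        S=np.broadcast_to(S, (n_models, 4, 4)).copy(),
        mu=np.full(n_models, 1.0 / n_models),
        est_hist=est_hist,
        meas_hist=np.stack(meas_list),
    )


def run_tracker(frames, bank, cfg: TrackerConfig | None = None) -> TrackResult:
    """Track a full scan sequence: warm start, then the cycle per frame."""
    cfg = cfg or TrackerConfig()
    L = cfg.window_len
    state = init_track(frames, cfg, n_models=len(bank))
    records = []
    for frame in frames[L + 1:]:
        state, rec = step(state, frame, bank, cfg)
        records.append(rec)
    if not records:
        raise ValueError("no frames left after warm-up")
    return TrackResult.from_records(records)
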