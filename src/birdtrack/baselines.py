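"""Reference trackers: UKF, IMM-UKF, bootstrap particle filter, GRU-EKF.

These are the conventional methods the GRU-bank tracker is compared against.
They share the scan-frame input, the warm-up convention (metrics start after
the first L+1 frames) and a simple nearest-to-prediction gate; the
back-tracking correction is deliberately not applied to them.

The UKF runs, by default, on a coordinated-turn model with the turn rate
augmented into the state ([x, vx, y, vy, w]); a plain linear CV configuration
is available (the unscented transform is exact there, so it coincides with a
Kalman filter).  The IMM-UKF mixes a CV model and two fixed-rate CT models
under a Markov model-transition matrix.  The particle filter propagates CT
dynamics with a random-walk turn rate and resamples systematically.  GRU-EKF
is structurally the bank tracker with a single (larger) learned motion model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .linear import cv_matrix, ct_matrix
from .tracker import TrackerConfig, TrackResult, run_tracker

__all__ = [
    "BaselineConfig",
    "run_ukf",
    "run_imm_ukf",
    "run_pf",
    "run_gru_ekf",
]


@dataclass
class BaselineConfig:
    """Knobs of the comparison methods.

    ukf_params: Merwe sigma-point spread (alpha_s, beta_s, kappa).
    dynamics: "ct_aug" (augmented turn rate, nonlinear) or "cv" (linear).
    imm_omegas / imm_self_transition: the IMM-UKF model set {CV, CT(+w),
    CT(-w)} and its Markov self-transition probability -- free parameters of
    the comparison, not prescribed anywhere.
    q_omega: turn-rate random-walk intensity (rad^2/s^3) for augmented models.
    """

    n_particles: int = 1000
    ukf_params: tuple[float, float, float] = (1e-3, 2.0, 0.0)
    dynamics: str = "ct_aug"
    imm_omegas: tuple[float, float] = (0.2, -0.2)
    imm_self_transition: float = 0.9
    q_omega: float = 1e-2
    omega_init_std: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.dynamics not in ("ct_aug", "cv"):
            raise ValueError("dynamics must be 'ct_aug' or 'cv'")
        if not 0.0 < self.imm_self_transition <= 1.0:
            raise ValueError("imm_self_transition must lie in (0, 1]")


def _nearest_point(frame, pred_pos: np.ndarray) -> tuple[int, np.ndarray]:
    d2 = np.sum((frame.points[:, [0, 2]] - pred_pos) ** 2, axis=1)
    idx = int(np.argmin(d2))
    return idx, frame.points[idx]


# ----------------------------------------------------------------------------
# Unscented machinery (Merwe scaled sigma points)

def _sigma_points(x: np.ndarray, P: np.ndarray, alpha: float, beta: float, kappa: float):
    n = len(x)
    lam = alpha**2 * (n + kappa) - n
    try:
        U = np.linalg.cholesky((n + lam) * P)
    except np.linalg.LinAlgError:
        U = np.linalg.cholesky((n + lam) * (P + 1e-9 * np.eye(n)))
    pts = np.vstack([x, x + U.T, x - U.T])
    Wm = np.full(2 * n + 1, 0.5 / (n + lam))
    Wc = Wm.copy()
    Wm[0] = lam / (n + lam)
    Wc[0] = lam / (n + lam) + (1.0 - alpha**2 + beta)
    return pts, Wm, Wc


def _unscented_transform(pts: np.ndarray, Wm: np.ndarray, Wc: np.ndarray, noise: np.ndarray):
    mean = Wm @ pts
    diff = pts - mean
    cov = (Wc[:, None] * diff).T @ diff + noise
    return mean, 0.5 * (cov + cov.T)


class _Ukf:
    """Generic UKF over a configurable transition x -> f(x, T)."""

    def __init__(self, x0, P0, fx, h_dim, Q_fn, R, params):
        self.x = np.asarray(x0, dtype=float)
        self.P = np.asarray(P0, dtype=float)
        self.fx = fx
        self.h_dim = h_dim
        self.Q_fn = Q_fn
        self.R = R
        self.alpha, self.beta, self.kappa = params

    def predict(self, T: float):
        pts, Wm, Wc = _sigma_points(self.x, self.P, self.alpha, self.beta, self.kappa)
        prop = np.stack([self.fx(p, T) for p in pts])
        self.x, self.P = _unscented_transform(prop, Wm, Wc, self.Q_fn(T))
        self._pts_pred = prop
        self._Wm, self._Wc = Wm, Wc
        return self.x.copy()

    def update(self, z: np.ndarray) -> float:
        """Measurement update; returns the innovation likelihood."""
        pts, Wm, Wc = _sigma_points(self.x, self.P, self.alpha, self.beta, self.kappa)
        zs = pts[:, : self.h_dim]  # measurement picks the first h_dim components
        z_mean, S = _unscented_transform(zs, Wm, Wc, self.R)
        diff_x = pts - self.x
        diff_z = zs - z_mean
        Pxz = (Wc[:, None] * diff_x).T @ diff_z
        K = np.linalg.solve(S.T, Pxz.T).T
        innov = z - z_mean
        self.x = self.x + K @ innov
        P = self.P - K @ S @ K.T
        self.P = 0.5 * (P + P.T)
        sign, logdet = np.linalg.slogdet(S)
        quad = innov @ np.linalg.solve(S, innov)
        return float(np.exp(-0.5 * (quad + logdet + self.h_dim * np.log(2 * np.pi))))


def _init_from_frame(frame, tracker_cfg: TrackerConfig, extra_dim: int = 0, extra_var: float = 0.1):
    z0 = frame.points[0][:4]
    x0 = np.concatenate([z0, np.zeros(extra_dim)])
    P0 = np.zeros((4 + extra_dim, 4 + extra_dim))
    P0[:4, :4] = tracker_cfg.R
    for i in range(extra_dim):
        P0[4 + i, 4 + i] = extra_var
    return x0, P0


def _collect(frames, L, step_fn) -> TrackResult:
    """Drive a per-frame (pred, est, extra) step function, recording post warm-up."""
    records = []
    for k, frame in enumerate(frames[1:], start=1):
        pred, est, mu, chosen, dens = step_fn(frame)
        if k >= L + 1:
            records.append({"time": frame.time, "pred": pred[:4], "est": est[:4],
                            "mu": mu, "chosen": chosen, "density": dens})
    return TrackResult.from_records(records)


def run_ukf(frames, cfg: BaselineConfig | None = None,
            tracker_cfg: TrackerConfig | None = None) -> TrackResult:
    """Unscented Kalman filter over the scan sequence."""
    cfg = cfg or BaselineConfig()
    tracker_cfg = tracker_cfg or TrackerConfig()
    Q4, R = tracker_cfg.Q, tracker_cfg.R

    if cfg.dynamics == "ct_aug":
        def fx(x, T):
            out = np.empty(5)
            out[:4] = ct_matrix(T, x[4]) @ x[:4]
            out[4] = x[4]
            return out

        def Q_fn(T):
            Q = np.zeros((5, 5))
            Q[:4, :4] = Q4
            Q[4, 4] = cfg.q_omega * T
            return Q

        x0, P0 = _init_from_frame(frames[0], tracker_cfg, extra_dim=1)
    else:
        def fx(x, T):
            return cv_matrix(T) @ x

        def Q_fn(T):
            return Q4

        x0, P0 = _init_from_frame(frames[0], tracker_cfg)

    ukf = _Ukf(x0, P0, fx, h_dim=4, Q_fn=Q_fn, R=R, params=cfg.ukf_params)
    t_prev = frames[0].time

    def step_fn(frame):
        nonlocal t_prev
        pred = ukf.predict(frame.time - t_prev)
        t_prev = frame.time
        chosen, z = _nearest_point(frame, pred[[0, 2]])
        ukf.update(z)
        return pred, ukf.x.copy(), np.array([1.0]), chosen, np.nan

    return _collect(frames, tracker_cfg.window_len, step_fn)


def run_imm_ukf(frames, cfg: BaselineConfig | None = None,
                tracker_cfg: TrackerConfig | None = None) -> TrackResult:
    """Classical IMM over {CV, CT(+w), CT(-w)} with per-model UKF steps."""
    cfg = cfg or BaselineConfig()
    tracker_cfg = tracker_cfg or TrackerConfig()
    Q4, R = tracker_cfg.Q, tracker_cfg.R
    omegas = [0.0, *cfg.imm_omegas]
    n = len(omegas)
    p_self = cfg.imm_self_transition
    trans = np.full((n, n), (1.0 - p_self) / (n - 1)) if n > 1 else np.ones((1, 1))
    np.fill_diagonal(trans, p_self)

    x0, P0 = _init_from_frame(frames[0], tracker_cfg)
    filters = []
    for w in omegas:
        def fx(x, T, w=w):
            return (cv_matrix(T) if w == 0.0 else ct_matrix(T, w)) @ x
        filters.append(_Ukf(x0.copy(), P0.copy(), fx, 4, lambda T: Q4, R, cfg.ukf_params))
    mu = np.full(n, 1.0 / n)
    t_prev = frames[0].time

    def step_fn(frame):
        nonlocal t_prev, mu
        T = frame.time - t_prev
        t_prev = frame.time
        # interaction: mix the model-conditioned estimates
        c = trans.T @ mu  # predicted model probabilities
        xs = np.stack([f.x for f in filters])
        Ps = np.stack([f.P for f in filters])
        mix_w = trans * mu[:, None] / np.maximum(c[None, :], 1e-300)  # [i, j]
        for j, f in enumerate(filters):
            x0j = mix_w[:, j] @ xs
            P0j = np.zeros_like(Ps[0])
            for i in range(n):
                d = xs[i] - x0j
                P0j += mix_w[i, j] * (Ps[i] + np.outer(d, d))
            f.x, f.P = x0j, 0.5 * (P0j + P0j.T)
        preds = np.stack([f.predict(T) for f in filters])
        pred_comb = c @ preds
        chosen, z = _nearest_point(frame, pred_comb[[0, 2]])
        lik = np.array([f.update(z) for f in filters])
        mu_new = c * lik
        mu = mu_new / mu_new.sum() if mu_new.sum() > 0 else c
        est = mu @ np.stack([f.x for f in filters])
        return pred_comb, est, mu.copy(), chosen, np.nan

    return _collect(frames, tracker_cfg.window_len, step_fn)


def run_pf(frames, cfg: BaselineConfig | None = None,
           tracker_cfg: TrackerConfig | None = None,
           rng: np.random.Generator | None = None) -> TrackResult:
    """Bootstrap particle filter with CT dynamics and random-walk turn rate."""
    cfg = cfg or BaselineConfig()
    tracker_cfg = tracker_cfg or TrackerConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    Q4, R = tracker_cfg.Q, tracker_cfg.R
    N = cfg.n_particles
    Rinv = np.linalg.inv(R)
    _, logdetR = np.linalg.slogdet(R)
    chol_Q = np.linalg.cholesky(Q4 + 1e-12 * np.eye(4))

    z0 = frames[0].points[0][:4]
    parts = np.zeros((N, 5))
    parts[:, :4] = z0 + rng.multivariate_normal(np.zeros(4), R, size=N)
    parts[:, 4] = rng.normal(0.0, cfg.omega_init_std, size=N) if cfg.omega_init_std > 0 else 0.0
    w = np.full(N, 1.0 / N)
    t_prev = frames[0].time

    def propagate(T):
        om = parts[:, 4]
        swt, cwt = np.sin(om * T), np.cos(om * T)
        sw = np.where(np.abs(om) < 1e-8, T, swt / np.where(np.abs(om) < 1e-8, 1.0, om))
        cw = np.where(np.abs(om) < 1e-8, 0.0, (1.0 - cwt) / np.where(np.abs(om) < 1e-8, 1.0, om))
        x, vx, y, vy = parts[:, 0], parts[:, 1], parts[:, 2], parts[:, 3]
        new = np.empty_like(parts)
        new[:, 0] = x + sw * vx - cw * vy
        new[:, 1] = cwt * vx - swt * vy
        new[:, 2] = y + cw * vx + sw * vy
        new[:, 3] = swt * vx + cwt * vy
        new[:, :4] += rng.standard_normal((N, 4)) @ chol_Q.T
        new[:, 4] = om + rng.normal(0.0, np.sqrt(cfg.q_omega * T), size=N)
        return new

    def step_fn(frame):
        nonlocal parts, w, t_prev
        T = frame.time - t_prev
        t_prev = frame.time
        parts = propagate(T)
        pred = np.append(w @ parts[:, :4], 0.0)
        chosen, z = _nearest_point(frame, pred[[0, 2]])
        diff = parts[:, :4] - z
        loglik = -0.5 * (np.einsum("ni,ij,nj->n", diff, Rinv, diff) + logdetR + 4 * np.log(2 * np.pi))
        logw = np.log(np.maximum(w, 1e-300)) + loglik
        logw -= logw.max()
        w_new = np.exp(logw)
        total = w_new.sum()
        if not np.isfinite(total) or total <= 0:
            # weight degeneracy: reinitialise around the last estimate
            parts[:, :4] = z + rng.multivariate_normal(np.zeros(4), R, size=N)
            w_new = np.full(N, 1.0)
            total = float(N)
        w = w_new / total
        ess = 1.0 / np.sum(w**2)
        if ess < N / 2:
            # systematic resampling
            positions = (rng.random() + np.arange(N)) / N
            idx = np.searchsorted(np.cumsum(w), positions)
            parts = parts[np.minimum(idx, N - 1)]
            w = np.full(N, 1.0 / N)
        est = np.append(w @ parts[:, :4], 0.0)
        return pred, est, np.array([1.0]), chosen, np.nan

    return _collect(frames, tracker_cfg.window_len, step_fn)


def run_gru_ekf(frames, big_model, cfg: TrackerConfig | None = None) -> TrackResult:
    """Single large learned motion model + Kalman correction.

    Structurally identical to the bank tracker with one model (the weight
    trace is constant at 1); the model is trained on the full 0.1-5 s range.
    """
    return run_tracker(frames, [big_model], cfg)
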