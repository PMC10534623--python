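"""Classical linear kinematics and the approximate state-transfer matrix.

A neural one-step predictor emits a point prediction with no explicit
transition model, so nothing exists to push a covariance through.  The fix
implemented here: approximate the unknown transition as a convex blend of the
two classical planar models,

    F = alpha * F_CV(T) + (1 - alpha) * F_CT(T, omega),   alpha in [0, 1],

with alpha chosen to minimise || F x_est - x_pred ||^2.  The blend then serves
as an ordinary linear transition for covariance propagation and likelihood
evaluation.  State ordering is fixed as [x, vx, y, vy].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "cv_matrix",
    "ct_matrix",
    "estimate_turn_rate",
    "fit_alpha",
    "approx_transfer",
    "propagate_covariance",
    "TransferMatrix",
    "GaussianBelief",
]

_OMEGA_EPS = 1e-8


@dataclass(frozen=True)
class TransferMatrix:
    """A fitted blend alpha*F_CV + (1-alpha)*F_CT over interval T."""

    entries: np.ndarray
    T: float
    alpha: float
    omega: float


@dataclass
class GaussianBelief:
    """Gaussian state belief: mean [x, vx, y, vy] and 4x4 covariance."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(4)
        self.cov = np.asarray(self.cov, dtype=float).reshape(4, 4)
        if not np.allclose(self.cov, self.cov.T, atol=1e-9):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.cov).min() < -1e-9:
            raise ValueError("covariance must be positive semidefinite")


def cv_matrix(T: float) -> np.ndarray:
    """Constant-velocity transition over T seconds."""
    if T <= 0:
        raise ValueError("T must be positive")
    return np.array(
        [
            [1.0, T, 0.0, 0.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, T],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def ct_matrix(T: float, omega: float) -> np.ndarray:
    """Coordinated-turn transition at constant turn rate omega (rad/s).

    For |omega| below 1e-8 the analytic limit sin(wT)/w -> T applies and the
    CV matrix is returned, keeping the family continuous in omega.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if abs(omega) < _OMEGA_EPS:
        return cv_matrix(T)
    swt = np.sin(omega * T)
    cwt = np.cos(omega * T)
    return np.array(
        [
            [1.0, swt / omega, 0.0, -(1.0 - cwt) / omega],
            [0.0, cwt, 0.0, -swt],
            [0.0, (1.0 - cwt) / omega, 1.0, swt / omega],
            [0.0, swt, 0.0, cwt],
        ]
    )


def estimate_turn_rate(prev: np.ndarray, cur: np.ndarray, T: float) -> float:
    """Turn rate implied by the heading change between two state estimates.

    Wrapped heading change of the velocity vector divided by T, in
    (-pi/T, pi/T].  Near-zero speeds carry no heading information: returns 0.
    """
    prev = np.asarray(prev, dtype=float)
    cur = np.asarray(cur, dtype=float)
    if np.hypot(prev[1], prev[3]) <= 1e-6 or np.hypot(cur[1], cur[3]) <= 1e-6:
        return 0.0
    dh = np.arctan2(cur[3], cur[1]) - np.arctan2(prev[3], prev[1])
    dh = (dh + np.pi) % (2.0 * np.pi) - np.pi  # wrap to (-pi, pi]
    if dh == -np.pi:
        dh = np.pi
    return dh / T


def fit_alpha(x_est: np.ndarray, x_pred: np.ndarray, T: float, omega: float) -> float:
    """Closed-form minimiser of ||(a F_CV + (1-a) F_CT) x_est - x_pred||^2.

    The objective is quadratic in a: with u = F_CV x_est, v = F_CT x_est and
    t = x_pred, the unconstrained optimum is (u-v).(t-v)/||u-v||^2, clipped to
    [0, 1].  When u == v (stationary target or omega == 0) every alpha is
    optimal and 1 (pure CV, the simpler model) is returned.
    """
    x_est = np.asarray(x_est, dtype=float)
    t = np.asarray(x_pred, dtype=float)
    u = cv_matrix(T) @ x_est
    v = ct_matrix(T, omega) @ x_est
    d = u - v
    nd2 = float(d @ d)
    if nd2 < 1e-24:  # ||u - v|| < 1e-12
        return 1.0
    alpha = float(d @ (t - v)) / nd2
    return float(np.clip(alpha, 0.0, 1.0))


def approx_transfer(x_est: np.ndarray, x_pred: np.ndarray, T: float, omega: float) -> TransferMatrix:
    """Fit the blended transition that best explains x_est -> x_pred."""
    alpha = fit_alpha(x_est, x_pred, T, omega)
    F = alpha * cv_matrix(T) + (1.0 - alpha) * ct_matrix(T, omega)
    return TransferMatrix(entries=F, T=T, alpha=alpha, omega=omega)


def propagate_covariance(F: np.ndarray, S: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """F S F^T + Q, symmetrised to suppress round-off."""
    F = np.asarray(F, dtype=float)
    S = np.asarray(S, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if F.shape != S.shape or S.shape != Q.shape or F.shape[0] != F.shape[1]:
        raise ValueError("F, S, Q must be square matrices of equal shape")
    out = F @ S @ F.T + Q
    return 0.5 * (out + out.T)
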