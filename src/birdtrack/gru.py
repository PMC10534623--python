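"""GRU-based motion models: architecture, normalization, checkpoints.

Each motion model is a small stacked *bidirectional* GRU regressor that maps a
length-L window of (state estimate, measurement) pairs to the next state.  At
every stack level the forward-time and backward-time hidden features are
combined by element-wise sum, the next level consumes the combined per-step
features, and the last time-step's top-level feature passes through an affine
+ tanh head.  A bank of such models, each trained on a different band of scan
intervals, supplies the motion hypotheses of the interacting-multiple-model
tracker.

The network is implemented directly on NumPy arrays (float64) with hand-written
backpropagation through time; gradients are validated against finite
differences in the test suite.  Everything is seeded and deterministic.

Normalization: the network never sees absolute coordinates.  Window positions
are expressed as displacements from the newest estimated position, divided by
``pos_scale``; velocities are divided by ``vel_scale``.  With
``pos_scale = v_max * L * dt_max`` (v_max a generous speed bound, dt_max the
model's scan-interval bin ceiling) all inputs and targets stay inside the tanh
head's (-1, 1) range, and the model is translation invariant.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

__all__ = [
    "GruConfig",
    "NormScale",
    "InputWindow",
    "normalize_window",
    "denormalize_state",
    "BiGruNet",
    "GruMotionModel",
    "save_checkpoint",
    "load_checkpoint",
]

V_MAX_DEFAULT = 30.0  # m/s, generous bound on bird speed for normalization


@dataclass(frozen=True)
class GruConfig:
    """Architecture hyper-parameters.

    Defaults follow the small-model configuration used throughout: 2 stacked
    bidirectional layers of 32 hidden units, window length 7, dropout 0.1
    between the stacked layers, 8 inputs (estimate and measurement 4-vectors
    spliced) and 4 outputs.
    """

    num_layers: int = 2
    hidden_dim: int = 32
    window_len: int = 7
    dropout: float = 0.1
    input_dim: int = 8
    output_dim: int = 4

    def __post_init__(self) -> None:
        if self.num_layers < 1 or self.window_len < 2:
            raise ValueError("need num_layers >= 1 and window_len >= 2")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


@dataclass(frozen=True)
class NormScale:
    """Units used to map metres and m/s into the network's (-1, 1) world."""

    pos_scale: float
    vel_scale: float

    def __post_init__(self) -> None:
        if self.pos_scale <= 0 or self.vel_scale <= 0:
            raise ValueError("normalization scales must be positive")

    @classmethod
    def for_bin(cls, dt_hi: float, window_len: int, v_max: float = V_MAX_DEFAULT) -> "NormScale":
        return cls(pos_scale=v_max * window_len * dt_hi, vel_scale=v_max)


@dataclass
class InputWindow:
    """Normalized L x 8 input, plus the reference state that anchors it."""

    rows: np.ndarray
    ref_state: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        self.ref_state = np.asarray(self.ref_state, dtype=float).reshape(4)
        if self.rows.ndim != 2 or self.rows.shape[1] != 8:
            raise ValueError("window rows must form an (L, 8) array")
        if not np.all(np.isfinite(self.rows)):
            raise ValueError("window contains non-finite entries")


def _norm4(states: np.ndarray, ref: np.ndarray, scale: NormScale) -> np.ndarray:
    out = np.array(states, dtype=float, copy=True)
    out[..., 0] = (out[..., 0] - ref[0]) / scale.pos_scale
    out[..., 2] = (out[..., 2] - ref[2]) / scale.pos_scale
    out[..., 1] /= scale.vel_scale
    out[..., 3] /= scale.vel_scale
    return out


def normalize_window(
    estimates: np.ndarray, measurements: np.ndarray, ref: np.ndarray, scale: NormScale
) -> InputWindow:
    """Build the network input from L estimates and L measurements.

    Rows run oldest to newest; each row is concat(normalized estimate,
    normalized measurement).  Invertible given (ref, scale).
    """
    estimates = np.asarray(estimates, dtype=float)
    measurements = np.asarray(measurements, dtype=float)
    if estimates.shape != measurements.shape or estimates.ndim != 2 or estimates.shape[1] != 4:
        raise ValueError("estimates and measurements must both be (L, 4) arrays")
    ref = np.asarray(ref, dtype=float).reshape(4)
    rows = np.concatenate([_norm4(estimates, ref, scale), _norm4(measurements, ref, scale)], axis=1)
    return InputWindow(rows=rows, ref_state=ref)


def denormalize_state(y: np.ndarray, ref: np.ndarray, scale: NormScale) -> np.ndarray:
    """Map a normalized state (network output) back to absolute units."""
    y = np.asarray(y, dtype=float)
    out = np.array(y, copy=True)
    out[..., 0] = y[..., 0] * scale.pos_scale + ref[0]
    out[..., 2] = y[..., 2] * scale.pos_scale + ref[2]
    out[..., 1] = y[..., 1] * scale.vel_scale
    out[..., 3] = y[..., 3] * scale.vel_scale
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class BiGruNet:
    """Stacked bidirectional GRU + tanh head, on raw NumPy (float64).

    Parameters live in a flat dict name -> array so the optimiser, the
    checkpoint writer and the gradient checker can treat them uniformly.
    Gate layout follows the common convention: reset, update, candidate.
    """

    def __init__(self, cfg: GruConfig, rng: np.random.Generator):
        self.cfg = cfg
        H = cfg.hidden_dim
        self.params: dict[str, np.ndarray] = {}
        for layer in range(cfg.num_layers):
            d_in = cfg.input_dim if layer == 0 else H
            k = 1.0 / np.sqrt(H)
            for dirn in ("f", "b"):
                p = f"l{layer}{dirn}"
                self.params[f"{p}_Wx"] = rng.uniform(-k, k, size=(3 * H, d_in))
                self.params[f"{p}_Wh"] = rng.uniform(-k, k, size=(3 * H, H))
                self.params[f"{p}_bx"] = rng.uniform(-k, k, size=3 * H)
                self.params[f"{p}_bh"] = rng.uniform(-k, k, size=3 * H)
        k = 1.0 / np.sqrt(H)
        self.params["head_W"] = rng.uniform(-k, k, size=(cfg.output_dim, H))
        self.params["head_b"] = rng.uniform(-k, k, size=cfg.output_dim)
        self._cache = None

    # -- forward -------------------------------------------------------------

    def _dir_forward(self, prefix: str, X: np.ndarray, order: range):
        """One direction of one layer over the whole window; returns (out, cache)."""
        Wx, Wh = self.params[f"{prefix}_Wx"], self.params[f"{prefix}_Wh"]
        bx, bh = self.params[f"{prefix}_bx"], self.params[f"{prefix}_bh"]
        B, L, _ = X.shape
        H = self.cfg.hidden_dim
        h = np.zeros((B, H))
        out = np.zeros((B, L, H))
        steps = []
        for t in order:
            x_t = X[:, t]
            gx = x_t @ Wx.T + bx
            gh = h @ Wh.T + bh
            r = _sigmoid(gx[:, :H] + gh[:, :H])
            z = _sigmoid(gx[:, H:2 * H] + gh[:, H:2 * H])
            ghn = gh[:, 2 * H:]
            n = np.tanh(gx[:, 2 * H:] + r * ghn)
            h_new = (1.0 - z) * n + z * h
            steps.append((t, x_t, h, r, z, n, ghn))
            h = h_new
            out[:, t] = h
        return out, steps

    def forward(self, X: np.ndarray, train: bool = False, drop_rng: np.random.Generator | None = None) -> np.ndarray:
        """Batch forward pass: X (B, L, input_dim) -> (B, output_dim).

        In inference mode (train=False) dropout is off and the pass is
        deterministic.  In training mode, inverted dropout is applied between
        stacked layers and caches are retained for `backward`.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1] != self.cfg.window_len or X.shape[2] != self.cfg.input_dim:
            raise ValueError(
                f"expected (B, {self.cfg.window_len}, {self.cfg.input_dim}) input, got {X.shape}"
            )
        L = self.cfg.window_len
        layer_caches = []
        inp = X
        for layer in range(self.cfg.num_layers):
            out_f, steps_f = self._dir_forward(f"l{layer}f", inp, range(L))
            out_b, steps_b = self._dir_forward(f"l{layer}b", inp, range(L - 1, -1, -1))
            out = out_f + out_b  # element-wise combination of the two directions
            mask = None
            if train and self.cfg.dropout > 0 and layer < self.cfg.num_layers - 1:
                if drop_rng is None:
                    raise ValueError("training forward pass needs drop_rng for dropout")
                mask = (drop_rng.random(out.shape) >= self.cfg.dropout) / (1.0 - self.cfg.dropout)
                out = out * mask
            layer_caches.append({"inp": inp, "steps_f": steps_f, "steps_b": steps_b, "mask": mask})
            inp = out
        h_last = inp[:, -1]
        pre = h_last @ self.params["head_W"].T + self.params["head_b"]
        y = np.tanh(pre)
        if train:
            self._cache = {"layers": layer_caches, "h_last": h_last, "y": y}
        return y

    # -- backward ------------------------------------------------------------

    def _dir_backward(self, prefix: str, steps, dOut: np.ndarray, grads: dict):
        Wx, Wh = self.params[f"{prefix}_Wx"], self.params[f"{prefix}_Wh"]
        B, L, H = dOut.shape
        dX = np.zeros((B, L, Wx.shape[1]))
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        dbx = np.zeros(3 * H)
        dbh = np.zeros(3 * H)
        dh_carry = np.zeros((B, H))
        for t, x_t, h_prev, r, z, n, ghn in reversed(steps):
            dh = dOut[:, t] + dh_carry
            dn = dh * (1.0 - z)
            dz = dh * (h_prev - n)
            dh_carry = dh * z
            dgn = dn * (1.0 - n * n)
            dr = dgn * ghn
            dghn = dgn * r
            dgr = dr * r * (1.0 - r)
            dgz = dz * z * (1.0 - z)
            dgx = np.concatenate([dgr, dgz, dgn], axis=1)
            dgh = np.concatenate([dgr, dgz, dghn], axis=1)
            dWx += dgx.T @ x_t
            dbx += dgx.sum(axis=0)
            dWh += dgh.T @ h_prev
            dbh += dgh.sum(axis=0)
            dX[:, t] += dgx @ Wx
            dh_carry = dh_carry + dgh @ Wh
        grads[f"{prefix}_Wx"] = dWx
        grads[f"{prefix}_Wh"] = dWh
        grads[f"{prefix}_bx"] = dbx
        grads[f"{prefix}_bh"] = dbh
        return dX

    def backward(self, dY: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss wrt all parameters, given dLoss/dY."""
        if self._cache is None:
            raise RuntimeError("backward requires a prior forward(train=True)")
        cache = self._cache
        grads: dict[str, np.ndarray] = {}
        dpre = np.asarray(dY, dtype=float) * (1.0 - cache["y"] ** 2)
        grads["head_W"] = dpre.T @ cache["h_last"]
        grads["head_b"] = dpre.sum(axis=0)
        dh_last = dpre @ self.params["head_W"]
        B = dh_last.shape[0]
        L, H = self.cfg.window_len, self.cfg.hidden_dim
        dOut = np.zeros((B, L, H))
        dOut[:, -1] = dh_last
        for layer in range(self.cfg.num_layers - 1, -1, -1):
            lc = cache["layers"][layer]
            if lc["mask"] is not None:
                dOut = dOut * lc["mask"]
            dX_f = self._dir_backward(f"l{layer}f", lc["steps_f"], dOut, grads)
            dX_b = self._dir_backward(f"l{layer}b", lc["steps_b"], dOut, grads)
            dOut = dX_f + dX_b
        self._cache = None
        return grads

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()


@dataclass
class GruMotionModel:
    """A trained motion model: network + normalization + its scan-interval bin.

    `predict` is the interface the tracker consumes: given the model's own L
    most recent state estimates and the L shared measurements, return the
    absolute predicted next state.
    """

    net: BiGruNet
    norm_scale: NormScale
    delta_t_bin: tuple[float, float]
    train_seed: int | None = None

    @property
    def config(self) -> GruConfig:
        return self.net.cfg

    def make_window(self, est_hist: np.ndarray, meas_hist: np.ndarray) -> InputWindow:
        est_hist = np.asarray(est_hist, dtype=float)
        return normalize_window(est_hist, meas_hist, ref=est_hist[-1], scale=self.norm_scale)

    def forward(self, window: InputWindow) -> np.ndarray:
        """Absolute predicted next state from a prepared window (inference)."""
        if window.rows.shape[0] != self.config.window_len:
            raise ValueError("window length does not match model configuration")
        y = self.net.forward(window.rows[None, :, :], train=False)[0]
        return denormalize_state(y, window.ref_state, self.norm_scale)

    def predict(self, est_hist: np.ndarray, meas_hist: np.ndarray, T: float | None = None) -> np.ndarray:
        del T  # interval specialisation is baked in through the training bin
        return self.forward(self.make_window(est_hist, meas_hist))


# ----------------------------------------------------------------------------
# Checkpoints: .npz weight archive + JSON sidecar with config and provenance.

def save_checkpoint(model: GruMotionModel, path) -> None:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.net.params)
    digest = hashlib.sha256(path.with_suffix(".npz").read_bytes()).hexdigest()
    sidecar = {
        "config": asdict(model.config),
        "norm_scale": {"pos_scale": model.norm_scale.pos_scale, "vel_scale": model.norm_scale.vel_scale},
        "delta_t_bin": list(model.delta_t_bin),
        "train_seed": model.train_seed,
        "weights_sha256": digest,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> GruMotionModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = GruConfig(**sidecar["config"])
    net = BiGruNet(cfg, rng=np.random.default_rng(0))
    with np.load(path.with_suffix(".npz")) as archive:
        net.set_params({k: archive[k] for k in archive.files})
    scale = NormScale(**sidecar["norm_scale"])
    return GruMotionModel(
        net=net,
        norm_scale=scale,
        delta_t_bin=tuple(sidecar["delta_t_bin"]),
        train_seed=sidecar["train_seed"],
    )
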