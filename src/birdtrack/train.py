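"""Training protocol for the GRU motion-model bank.

The scan-interval range [0.1, 5] s is partitioned into contiguous bins (five
by default: [0.1,1], [1.1,2], [2.1,3], [3.1,4], [4.1,5]) and one motion model
is trained per bin, on windows cut from trajectories downsampled to every
interval inside that bin.  A model therefore specialises in a band of motion
change per step purely through its training data -- the interval itself is
never an input feature.

Teacher forcing: during training the estimate channel of each window holds the
ground-truth states (at scan scale, i.e. with differenced velocities), and the
target is the true next state.  Closed-loop estimates appear only at tracking
time.

Optimisation: MSE loss, Adam with decoupled weight decay, cosine-annealed
learning rate restarting every `epochs_per_cycle` epochs, early stopping when
the validation loss has not improved for `patience` epochs, returning the
best-validation checkpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .gru import BiGruNet, GruConfig, GruMotionModel, NormScale, V_MAX_DEFAULT, normalize_window
from .sim import SimConfig, Trajectory, downsample, observe

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "WindowDataset",
    "make_training_set",
    "split_dataset",
    "train_model",
    "build_bank",
    "partition_bins",
    "save_dataset",
    "load_dataset",
    "TrainingDivergedError",
]

DT_GRID_STEP = 0.1
DT_RANGE = (0.1, 5.0)


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Optimiser settings.

    weight_decay is the decoupled (AdamW-style) coefficient.  Note the
    interaction with normalization: targets live on a ~0.1 scale, so MSE
    gradients are small and an aggressive decay (0.1+) pins the weights near
    the origin and training stalls; 1e-2 is a safe default for these small
    networks.
    """

    batch_size: int = 256
    learning_rate: float = 0.01
    weight_decay: float = 1e-2
    epochs_per_cycle: int = 5
    patience: int = 20
    max_epochs: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs_per_cycle, self.max_epochs) < 1 or self.patience < 1:
            raise ValueError("batch_size, epochs_per_cycle, max_epochs, patience must be >= 1")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning_rate must be > 0 and weight_decay >= 0")


@dataclass
class WindowDataset:
    """Normalized training windows X (N, L, 8) and targets Y (N, 4)."""

    X: np.ndarray
    Y: np.ndarray
    scale: NormScale
    delta_t_bin: tuple[float, float]

    def __len__(self) -> int:
        return len(self.X)


def dt_values_in_bin(bin_lo: float, bin_hi: float) -> np.ndarray:
    """All scan intervals on the 0.1 s grid inside [bin_lo, bin_hi]."""
    grid = np.round(np.arange(DT_RANGE[0], DT_RANGE[1] + 1e-9, DT_GRID_STEP), 10)
    return grid[(grid >= bin_lo - 1e-9) & (grid <= bin_hi + 1e-9)]


def partition_bins(n_models: int) -> list[tuple[float, float]]:
    """Split the 0.1-5 s interval grid into n contiguous, gap-free bins.

    n=5 reproduces the canonical bins {[0.1,1], [1.1,2], [2.1,3], [3.1,4],
    [4.1,5]}; other n partition the same 0.1 s grid as evenly as possible.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    grid = np.round(np.arange(DT_RANGE[0], DT_RANGE[1] + 1e-9, DT_GRID_STEP), 10)
    chunks = np.array_split(grid, n_models)
    return [(float(c[0]), float(c[-1])) for c in chunks]


def make_training_set(
    trajectories: list[Trajectory],
    delta_t_bin: tuple[float, float],
    cfg: SimConfig,
    gru_cfg: GruConfig | None = None,
    max_windows: int | None = None,
    v_max: float = V_MAX_DEFAULT,
) -> WindowDataset:
    """Cut (window, next-state) pairs from trajectories across a Δt bin.

    For every trajectory and every interval in the bin (0.1 s grid): downsample,
    observe with position noise (no false alarms during training), slide a
    length-L window whose estimate channel is the ground truth and whose
    measurement channel is the noisy observation; the target is the next true
    state.  Windows start at the second resampled sample because the first
    sample's differenced velocity is fabricated.  Windows are shuffled (and
    optionally subsampled to `max_windows`) with cfg.seed.
    """
    gru_cfg = gru_cfg or GruConfig()
    lo, hi = delta_t_bin
    if lo < DT_RANGE[0] - 1e-9 or hi > DT_RANGE[1] + 1e-9:
        raise ValueError("delta_t_bin must lie within [0.1, 5] s")
    L = gru_cfg.window_len
    scale = NormScale.for_bin(hi, L, v_max=v_max)
    rng = np.random.default_rng(cfg.seed)
    xs, ys = [], []
    for ti, traj in enumerate(trajectories):
        for dt in dt_values_in_bin(lo, hi):
            if traj.times[-1] - traj.times[0] < (L + 1) * dt:
                logger.warning("trajectory %d shorter than (L+1)*%.1fs; skipped", ti, dt)
                continue
            tr = downsample(traj, dt)
            obs_cfg = SimConfig(
                delta_t=dt, delta_l=cfg.delta_l, p_fa=0.0, fa_radius=cfg.fa_radius,
                seed=int(rng.integers(2**31 - 1)),
            )
            frames = observe(tr, obs_cfg)
            meas = np.stack([f.points[f.truth_index] for f in frames])
            truth = tr.states
            for i in range(1, len(tr) - L):
                ref = truth[i + L - 1]
                w = normalize_window(truth[i:i + L], meas[i:i + L], ref=ref, scale=scale)
                target = truth[i + L]
                ty = np.array(
                    [
                        (target[0] - ref[0]) / scale.pos_scale,
                        target[1] / scale.vel_scale,
                        (target[2] - ref[2]) / scale.pos_scale,
                        target[3] / scale.vel_scale,
                    ]
                )
                xs.append(w.rows)
                ys.append(ty)
    if not xs:
        raise ValueError("no training windows could be produced")
    X = np.stack(xs)
    Y = np.stack(ys)
    perm = rng.permutation(len(X))
    if max_windows is not None and len(perm) > max_windows:
        perm = perm[:max_windows]
    return WindowDataset(X=X[perm], Y=Y[perm], scale=scale, delta_t_bin=(float(lo), float(hi)))


def split_dataset(ds: WindowDataset, fractions=(0.8, 0.1, 0.1)) -> tuple[WindowDataset, ...]:
    """Deterministic train/val/test split (the dataset is already shuffled)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(ds)
    cuts = np.cumsum([int(round(f * n)) for f in fractions[:-1]])
    parts = np.split(np.arange(n), cuts)
    return tuple(
        WindowDataset(X=ds.X[idx], Y=ds.Y[idx], scale=ds.scale, delta_t_bin=ds.delta_t_bin)
        for idx in parts
    )


def _cosine_lr(base_lr: float, epoch: int, cycle: int) -> float:
    return 0.5 * base_lr * (1.0 + np.cos(np.pi * (epoch % cycle) / cycle))


def _mse(net: BiGruNet, X: np.ndarray, Y: np.ndarray, batch: int = 4096) -> float:
    total = 0.0
    for i in range(0, len(X), batch):
        pred = net.forward(X[i:i + batch], train=False)
        total += float(np.sum((pred - Y[i:i + batch]) ** 2))
    return total / Y.size


def train_model(
    dataset: WindowDataset,
    gru_cfg: GruConfig | None = None,
    train_cfg: TrainConfig | None = None,
    val_dataset: WindowDataset | None = None,
) -> GruMotionModel:
    """Fit one motion model on a window dataset.

    If no validation set is supplied, the last 10% of the (pre-shuffled)
    dataset is held out.  Returns the model at its best validation loss.
    """
    gru_cfg = gru_cfg or GruConfig()
    train_cfg = train_cfg or TrainConfig()
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    if val_dataset is None:
        n_val = max(1, len(dataset) // 10)
        val_X, val_Y = dataset.X[-n_val:], dataset.Y[-n_val:]
        X, Y = dataset.X[:-n_val], dataset.Y[:-n_val]
        if len(X) == 0:
            X, Y = val_X, val_Y
    else:
        X, Y = dataset.X, dataset.Y
        val_X, val_Y = val_dataset.X, val_dataset.Y

    rng = np.random.default_rng(train_cfg.seed)
    net = BiGruNet(gru_cfg, rng)
    m = {k: np.zeros_like(v) for k, v in net.params.items()}
    v = {k: np.zeros_like(p) for k, p in net.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    best_val = _mse(net, val_X, val_Y)
    best_params = net.copy_params()
    epochs_since_best = 0

    for epoch in range(train_cfg.max_epochs):
        lr = _cosine_lr(train_cfg.learning_rate, epoch, train_cfg.epochs_per_cycle)
        order = rng.permutation(len(X))
        for start in range(0, len(X), train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            xb, yb = X[idx], Y[idx]
            pred = net.forward(xb, train=True, drop_rng=rng)
            diff = pred - yb
            loss = float(np.mean(diff**2))
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, step {step} (lr={lr:.3g})"
                )
            grads = net.backward(2.0 * diff / diff.size)
            step += 1
            for key, p in net.params.items():
                g = grads[key]
                m[key] = beta1 * m[key] + (1.0 - beta1) * g
                v[key] = beta2 * v[key] + (1.0 - beta2) * g * g
                mhat = m[key] / (1.0 - beta1**step)
                vhat = v[key] / (1.0 - beta2**step)
                p -= lr * (mhat / (np.sqrt(vhat) + eps) + train_cfg.weight_decay * p)
        val_loss = _mse(net, val_X, val_Y)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = net.copy_params()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= train_cfg.patience:
                break

    net.set_params(best_params)
    return GruMotionModel(
        net=net, norm_scale=dataset.scale, delta_t_bin=dataset.delta_t_bin,
        train_seed=train_cfg.seed,
    )


def build_bank(
    trajectories: list[Trajectory],
    n_models: int = 5,
    gru_cfg: GruConfig | None = None,
    train_cfg: TrainConfig | None = None,
    sim_cfg: SimConfig | None = None,
    max_windows: int | None = None,
) -> list[GruMotionModel]:
    """Train one motion model per scan-interval bin, slowest bin first."""
    gru_cfg = gru_cfg or GruConfig()
    train_cfg = train_cfg or TrainConfig()
    sim_cfg = sim_cfg or SimConfig()
    bank = []
    for i, dt_bin in enumerate(partition_bins(n_models)):
        ds = make_training_set(
            trajectories, dt_bin,
            SimConfig(delta_t=sim_cfg.delta_t, delta_l=sim_cfg.delta_l, p_fa=0.0,
                      fa_radius=sim_cfg.fa_radius, seed=sim_cfg.seed + i),
            gru_cfg=gru_cfg, max_windows=max_windows,
        )
        cfg_i = TrainConfig(
            batch_size=train_cfg.batch_size, learning_rate=train_cfg.learning_rate,
            weight_decay=train_cfg.weight_decay, epochs_per_cycle=train_cfg.epochs_per_cycle,
            patience=train_cfg.patience, max_epochs=train_cfg.max_epochs,
            seed=train_cfg.seed + i,
        )
        bank.append(train_model(ds, gru_cfg=gru_cfg, train_cfg=cfg_i))
    return bank


# ----------------------------------------------------------------------------
# HDF5 dataset cache

def save_dataset(ds: WindowDataset, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=ds.X)
        f.create_dataset("Y", data=ds.Y)
        f.attrs["pos_scale"] = ds.scale.pos_scale
        f.attrs["vel_scale"] = ds.scale.vel_scale
        f.attrs["bin_lo"] = ds.delta_t_bin[0]
        f.attrs["bin_hi"] = ds.delta_t_bin[1]


def load_dataset(path) -> WindowDataset:
    import h5py

    with h5py.File(path, "r") as f:
        return WindowDataset(
            X=f["X"][:], Y=f["Y"][:],
            scale=NormScale(pos_scale=float(f.attrs["pos_scale"]), vel_scale=float(f.attrs["vel_scale"])),
            delta_t_bin=(float(f.attrs["bin_lo"]), float(f.attrs["bin_hi"])),
        )
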