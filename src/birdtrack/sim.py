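"""Synthetic bird-like trajectories and Lidar-style scan observations.

Generates planar, piecewise-manoeuvring trajectories (constant velocity,
coordinated turn, constant acceleration segments) sampled on a uniform base
grid, then emulates a low-refresh-rate scanning sensor: downsampling to a
coarser interval, additive Gaussian position noise of variance ``4*delta_l**2``
per axis (``delta_l`` being the sensor's range resolution in metres), observed
velocities formed by backward-differencing observed positions, and occasional
false-alarm points injected near the target.

State convention throughout the package: ``[x, vx, y, vy]`` in metres and
metres per second, ENU-like planar coordinates, time in seconds from 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SegmentSpec",
    "Trajectory",
    "ScanFrame",
    "SimConfig",
    "generate_trajectory",
    "random_segments",
    "downsample",
    "observe",
    "save_trajectory_csv",
    "load_trajectory_csv",
    "save_scans_csv",
    "load_scans_csv",
]

SEGMENT_KINDS = ("CV", "CT", "CA")


class UnknownSegmentKindError(ValueError):
    """Raised for a segment kind outside {CV, CT, CA}."""


@dataclass(frozen=True)
class SegmentSpec:
    """One manoeuvre segment of a piecewise trajectory.

    kind
        ``CV`` straight flight at constant speed, ``CT`` coordinated turn at
        constant turn rate, ``CA`` straight flight at constant tangential
        acceleration.
    duration
        Segment length in seconds (> 0).
    speed
        Speed at segment entry, m/s.
    turn_rate
        Signed turn rate in rad/s (CT only; positive = counter-clockwise).
    accel
        Tangential acceleration in m/s^2 (CA only).
    """

    kind: str
    duration: float
    speed: float
    turn_rate: float = 0.0
    accel: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise UnknownSegmentKindError(f"unknown segment kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        if self.speed < 0:
            raise ValueError("segment speed must be non-negative")


@dataclass
class Trajectory:
    """Uniformly sampled planar trajectory: times (s) and [x, vx, y, vy] rows."""

    times: np.ndarray
    states: np.ndarray
    base_dt: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")
        if self.states.ndim != 2 or self.states.shape[1] != 4:
            raise ValueError("states must be an (N, 4) array")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, self.base_dt, atol=1e-9, rtol=0):
                raise ValueError("times must be uniformly spaced at base_dt")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def positions(self) -> np.ndarray:
        return self.states[:, [0, 2]]

    @property
    def velocities(self) -> np.ndarray:
        return self.states[:, [1, 3]]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.times,
                "x": self.states[:, 0],
                "y": self.states[:, 2],
                "vx": self.states[:, 1],
                "vy": self.states[:, 3],
            }
        )


@dataclass
class ScanFrame:
    """One sensor scan: candidate measurement points at a single instant.

    Each point is a 4-vector ``[x, vx, y, vy]`` (observed velocity comes from
    position differencing).  ``truth_index`` locates the true-target point and
    exists only for simulation bookkeeping; a tracker never reads it.
    """

    time: float
    points: np.ndarray  # (D, 4)
    truth_index: int

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if len(self.points) < 1:
            raise ValueError("a scan frame needs at least one point")
        if self.truth_index >= len(self.points):
            raise ValueError("truth_index out of range")


@dataclass
class SimConfig:
    """Observation model configuration.

    delta_t
        Scan interval in seconds (the trajectory must already be resampled to
        it, or `downsample` is applied first); integer multiple of base_dt.
    delta_l
        Sensor range resolution in metres; position noise per axis is
        N(0, 4*delta_l**2).  Held constant per run (no target-sensor geometry
        is modelled).
    p_fa
        Probability that a frame contains one additional false-alarm point.
    fa_radius
        False points land uniformly in a disc of this radius (m) around the
        true position: near enough to confuse association.
    """

    delta_t: float = 1.0
    delta_l: float = 1.0
    p_fa: float = 0.0
    fa_radius: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_fa <= 1.0:
            raise ValueError("p_fa must lie in [0, 1]")
        if self.delta_t <= 0 or self.delta_l < 0 or self.fa_radius <= 0:
            raise ValueError("delta_t, fa_radius must be positive; delta_l >= 0")


def _segment_state(seg: SegmentSpec, pos: np.ndarray, heading: float, tau: np.ndarray):
    """Closed-form kinematics of one segment at local times tau (vectorised).

    Returns (positions (n,2), velocities (n,2)). `pos`/`heading` are the exact
    entry position and heading, guaranteeing continuity across joins.
    """
    s = seg.speed
    tau = np.asarray(tau, dtype=float)
    if seg.kind == "CV":
        v = s * np.array([np.cos(heading), np.sin(heading)])
        p = pos[None, :] + tau[:, None] * v[None, :]
        vel = np.broadcast_to(v, (len(tau), 2)).copy()
    elif seg.kind == "CT":
        w = seg.turn_rate
        th = heading + w * tau
        vel = s * np.stack([np.cos(th), np.sin(th)], axis=1)
        if abs(w) < 1e-12:
            p = pos[None, :] + tau[:, None] * vel
        else:
            p = pos[None, :] + (s / w) * np.stack(
                [np.sin(th) - np.sin(heading), -np.cos(th) + np.cos(heading)], axis=1
            )
    else:  # CA
        a = seg.accel
        d = np.array([np.cos(heading), np.sin(heading)])
        dist = s * tau + 0.5 * a * tau**2
        p = pos[None, :] + dist[:, None] * d[None, :]
        vel = (s + a * tau)[:, None] * d[None, :]
    return p, vel


def _segment_exit(seg: SegmentSpec, pos: np.ndarray, heading: float):
    """Exact (position, heading, speed) at the end of a segment."""
    p, v = _segment_state(seg, pos, heading, np.array([seg.duration]))
    if seg.kind == "CT":
        heading_out = heading + seg.turn_rate * seg.duration
        speed_out = seg.speed
    elif seg.kind == "CA":
        heading_out = heading
        speed_out = seg.speed + seg.accel * seg.duration
    else:
        heading_out = heading
        speed_out = seg.speed
    return p[0], heading_out, speed_out


def generate_trajectory(
    segments: list[SegmentSpec],
    base_dt: float = 0.1,
    seed: int | None = None,
    start: np.ndarray | None = None,
    heading: float = 0.0,
) -> Trajectory:
    """Sample a piecewise CV/CT/CA trajectory on a uniform grid.

    The kinematics are evaluated in closed form per segment, so positions and
    velocities are exact (no numerical integration).  Generation is
    deterministic; ``seed`` is accepted for interface symmetry with the
    stochastic operations and ignored.
    """
    del seed
    if not segments:
        raise ValueError("segments must be non-empty")
    if base_dt <= 0:
        raise ValueError("base_dt must be positive")
    # speed continuity: each segment's entry speed is taken from its spec, but
    # the entry position and heading chain exactly from the previous segment.
    pos = np.zeros(2) if start is None else np.asarray(start, dtype=float)
    starts = []  # (t_start, seg, pos, heading)
    t0 = 0.0
    hd = heading
    for seg in segments:
        starts.append((t0, seg, pos.copy(), hd))
        pos, hd, _ = _segment_exit(seg, pos, hd)
        t0 += seg.duration
    total = t0
    n = int(np.floor(total / base_dt + 1e-9)) + 1
    times = np.arange(n) * base_dt

    states = np.empty((n, 4))
    bounds = np.array([s[0] for s in starts] + [total])
    for i, (ts, seg, p0, h0) in enumerate(starts):
        # half-open [ts, ts+dur); the final grid point belongs to the last segment
        lo, hi = bounds[i], bounds[i + 1]
        mask = (times >= lo - 1e-9) & (times < hi - 1e-9)
        if i == len(starts) - 1:
            mask |= np.abs(times - total) < 1e-9
        tau = times[mask] - ts
        p, v = _segment_state(seg, p0, h0, tau)
        states[mask, 0] = p[:, 0]
        states[mask, 2] = p[:, 1]
        states[mask, 1] = v[:, 0]
        states[mask, 3] = v[:, 1]
    return Trajectory(times=times, states=states, base_dt=base_dt)


def random_segments(
    rng: np.random.Generator,
    n_segments: int = 5,
    speed_range: tuple[float, float] = (10.0, 20.0),
    turn_rate_max: float = 0.5,
    duration_range: tuple[float, float] = (5.0, 60.0),
) -> list[SegmentSpec]:
    """Pigeon-like random manoeuvre programme: alternating CV and CT segments.

    Defaults mimic small-bird flight: speeds 10-20 m/s, |turn rate| <= 0.5
    rad/s, segment durations 5-60 s.
    """
    segs = []
    speed = rng.uniform(*speed_range)
    for _ in range(n_segments):
        dur = rng.uniform(*duration_range)
        if rng.random() < 0.5:
            segs.append(SegmentSpec("CV", duration=dur, speed=speed))
        else:
            w = rng.uniform(0.05, turn_rate_max) * rng.choice([-1.0, 1.0])
            segs.append(SegmentSpec("CT", duration=dur, speed=speed, turn_rate=w))
    return segs


def downsample(traj: Trajectory, delta_t: float) -> Trajectory:
    """Resample to a coarser scan interval, re-deriving observed velocities.

    Keeps every k-th sample (k = delta_t / base_dt, which must be an integer)
    starting at index 0.  Velocities are recomputed as backward position
    differences divided by delta_t -- the only velocity a scanning sensor can
    report -- with the first sample copying the second (its backward
    difference does not exist).
    """
    ratio = delta_t / traj.base_dt
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-6:
        raise ValueError(
            f"delta_t={delta_t} is not an integer multiple of base_dt={traj.base_dt}"
        )
    times = traj.times[::k]
    pos = traj.positions[::k]
    n = len(times)
    if n < 2:
        raise ValueError("trajectory too short to downsample at this interval")
    vel = np.empty_like(pos)
    vel[1:] = (pos[1:] - pos[:-1]) / delta_t
    vel[0] = vel[1]
    states = np.empty((n, 4))
    states[:, 0] = pos[:, 0]
    states[:, 2] = pos[:, 1]
    states[:, 1] = vel[:, 0]
    states[:, 3] = vel[:, 1]
    return Trajectory(times=times.copy(), states=states, base_dt=delta_t)


def observe(traj: Trajectory, cfg: SimConfig) -> list[ScanFrame]:
    """Turn a trajectory (already at cfg.delta_t spacing) into scan frames.

    Per frame: the true point with i.i.d. N(0, 4*delta_l**2) noise added to x
    and y independently; observed velocity = backward difference of the noisy
    positions (first frame copies the second); with probability ``p_fa`` one
    false point, uniform in a disc of radius ``fa_radius`` around the true
    position, whose velocity channel is differenced against the previous
    frame's noisy true position.  Point order is shuffled and the true point's
    index recorded.  Fully reproducible from cfg.seed.
    """
    if abs(traj.base_dt - cfg.delta_t) > 1e-9:
        raise ValueError("trajectory spacing does not match cfg.delta_t")
    rng = np.random.default_rng(cfg.seed)
    n = len(traj)
    sigma = 2.0 * cfg.delta_l  # std of N(0, 4*delta_l^2)
    noisy = traj.positions + rng.normal(0.0, sigma, size=(n, 2)) if sigma > 0 else traj.positions.copy()
    ovel = np.empty_like(noisy)
    ovel[1:] = (noisy[1:] - noisy[:-1]) / cfg.delta_t
    ovel[0] = ovel[1]

    # pre-draw false-alarm randomness in frame order for reproducibility
    fa_mask = rng.random(n) < cfg.p_fa
    fa_mask[0] = False  # no backward difference exists at frame 0
    frames: list[ScanFrame] = []
    for i in range(n):
        true_pt = np.array([noisy[i, 0], ovel[i, 0], noisy[i, 1], ovel[i, 1]])
        pts = [true_pt]
        if fa_mask[i]:
            r = cfg.fa_radius * np.sqrt(rng.random())
            th = rng.uniform(0.0, 2.0 * np.pi)
            fpos = traj.positions[i] + r * np.array([np.cos(th), np.sin(th)])
            fvel = (fpos - noisy[i - 1]) / cfg.delta_t
            pts.append(np.array([fpos[0], fvel[0], fpos[1], fvel[1]]))
        pts_arr = np.stack(pts)
        order = rng.permutation(len(pts_arr))
        truth_index = int(np.where(order == 0)[0][0])
        frames.append(ScanFrame(time=float(traj.times[i]), points=pts_arr[order], truth_index=truth_index))
    return frames


# ----------------------------------------------------------------------------
# CSV interfaces (trajectory: t,x,y,vx,vy ; scans: t,point_id,x,y,vx,vy,is_truth)

def save_trajectory_csv(traj: Trajectory, path) -> None:
    traj.to_dataframe().to_csv(path, index=False)


def load_trajectory_csv(path) -> Trajectory:
    """Load a trajectory (or a real GPS track in the same dialect)."""
    df = pd.read_csv(path)
    times = df["t"].to_numpy(dtype=float)
    states = np.stack(
        [df["x"].to_numpy(float), df["vx"].to_numpy(float), df["y"].to_numpy(float), df["vy"].to_numpy(float)],
        axis=1,
    )
    base_dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
    return Trajectory(times=times, states=states, base_dt=base_dt)


def save_scans_csv(frames: list[ScanFrame], path) -> None:
    rows = []
    for f in frames:
        for i, p in enumerate(f.points):
            rows.append(
                {"t": f.time, "point_id": i, "x": p[0], "y": p[2], "vx": p[1], "vy": p[3],
                 "is_truth": int(i == f.truth_index)}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_scans_csv(path) -> list[ScanFrame]:
    df = pd.read_csv(path)
    frames = []
    for t, grp in df.groupby("t", sort=True):
        grp = grp.sort_values("point_id")
        pts = np.stack(
            [grp["x"].to_numpy(float), grp["vx"].to_numpy(float), grp["y"].to_numpy(float), grp["vy"].to_numpy(float)],
            axis=1,
        )
        truth = grp["is_truth"].to_numpy()
        idx = int(np.argmax(truth)) if truth.any() else -1
        frames.append(ScanFrame(time=float(t), points=pts, truth_index=idx))
    return frames
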