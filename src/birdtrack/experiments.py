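"""Monte-Carlo experiment harness.

Builds seeded scenarios (a circular constant-turn trajectory, random piecewise
manoeuvre programmes, or a loaded track), runs any of the implemented trackers
over a grid of scan intervals and false-alarm rates, and aggregates RMSE /
false-detection / model-weight statistics with standard errors.  Every run is
fully reproducible from (spec, base_seed): replicate seeds are spawned from a
single SeedSequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .backtrack import BacktrackConfig, run_backtrack_tracker
from .baselines import BaselineConfig, run_imm_ukf, run_pf, run_ukf
from .metrics import count_false_selections, false_detection_ratio, rmse, weight_statistics
from .sim import SegmentSpec, SimConfig, Trajectory, downsample, generate_trajectory, observe, random_segments
from .tracker import TrackerConfig, run_tracker

__all__ = [
    "ExperimentSpec",
    "circular_trajectory",
    "piecewise_trajectory",
    "make_scenario",
    "run_method",
    "run_experiment",
    "summarize",
]

METHODS = ("imm_gru", "imm_gru_bt", "gru_ekf", "ukf", "imm_ukf", "pf")


@dataclass
class ExperimentSpec:
    """One experiment grid: scenario x delta_t x p_fa x methods x replicates."""

    scenario: str = "piecewise"  # "circular" | "piecewise" | "loaded"
    delta_t_grid: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    p_fa_grid: tuple[float, ...] = (0.0,)
    methods: tuple[str, ...] = ("imm_gru",)
    n_monte_carlo: int = 50
    base_seed: int = 0
    delta_l: float = 1.0
    fa_radius: float = 100.0
    duration: float = 150.0
    loaded_trajectory: Trajectory | None = None

    def __post_init__(self) -> None:
        if not self.delta_t_grid or not self.p_fa_grid or not self.methods:
            raise ValueError("grids and method list must be non-empty")
        if self.n_monte_carlo < 1:
            raise ValueError("n_monte_carlo must be >= 1")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


def circular_trajectory(radius: float = 200.0, speed: float = 15.0,
                        duration: float = 400.0, base_dt: float = 0.1) -> Trajectory:
    """Constant-turn-rate circle: a single-motion scenario (w = speed/radius)."""
    seg = SegmentSpec("CT", duration=duration, speed=speed, turn_rate=speed / radius)
    return generate_trajectory([seg], base_dt=base_dt)


def piecewise_trajectory(rng: np.random.Generator, duration: float = 150.0,
                         base_dt: float = 0.1) -> Trajectory:
    """Random bird-like manoeuvre programme of roughly `duration` seconds."""
    segs, total = [], 0.0
    for seg in random_segments(rng, n_segments=64):
        segs.append(seg)
        total += seg.duration
        if total >= duration:
            break
    return generate_trajectory(segs, base_dt=base_dt, heading=rng.uniform(0, 2 * np.pi))


def make_scenario(spec: ExperimentSpec, delta_t: float, p_fa: float, seed: int):
    """Seeded (downsampled truth, scan frames) pair for one replicate."""
    rng = np.random.default_rng(seed)
    if spec.scenario == "circular":
        traj = circular_trajectory(duration=spec.duration)
    elif spec.scenario == "piecewise":
        traj = piecewise_trajectory(rng, duration=spec.duration)
    elif spec.scenario == "loaded":
        if spec.loaded_trajectory is None:
            raise ValueError("scenario 'loaded' requires loaded_trajectory")
        traj = spec.loaded_trajectory
    else:
        raise ValueError(f"unknown scenario {spec.scenario!r}")
    truth = downsample(traj, delta_t)
    cfg = SimConfig(delta_t=delta_t, delta_l=spec.delta_l, p_fa=p_fa,
                    fa_radius=spec.fa_radius, seed=int(rng.integers(2**31 - 1)))
    return truth, observe(truth, cfg)


def run_method(method: str, frames, bank=None, big_model=None,
               tracker_cfg: TrackerConfig | None = None,
               baseline_cfg: BaselineConfig | None = None,
               bt_cfg: BacktrackConfig | None = None,
               seed: int = 0):
    """Dispatch one tracking run; returns a TrackResult."""
    tracker_cfg = tracker_cfg or TrackerConfig()
    baseline_cfg = baseline_cfg or BaselineConfig()
    if method == "imm_gru":
        if bank is None:
            raise ValueError("imm_gru requires a trained model bank")
        return run_tracker(frames, bank, tracker_cfg)
    if method == "imm_gru_bt":
        if bank is None:
            raise ValueError("imm_gru_bt requires a trained model bank")
        return run_backtrack_tracker(frames, bank, tracker_cfg, bt_cfg or BacktrackConfig())
    if method == "gru_ekf":
        if big_model is None:
            raise ValueError("gru_ekf requires a trained full-range model")
        return run_tracker(frames, [big_model], tracker_cfg)
    if method == "ukf":
        return run_ukf(frames, baseline_cfg, tracker_cfg)
    if method == "imm_ukf":
        return run_imm_ukf(frames, baseline_cfg, tracker_cfg)
    if method == "pf":
        return run_pf(frames, baseline_cfg, tracker_cfg, rng=np.random.default_rng(seed))
    raise ValueError(f"unknown method {method!r}")


def evaluate_run(result, truth: Trajectory, frames) -> dict:
    """Metrics for one run: warm-up rows are excluded identically everywhere."""
    idx = {round(t, 9): i for i, t in enumerate(truth.times)}
    rows = [idx[round(t, 9)] for t in result.times]
    truth_states = truth.states[rows]
    nf, nt, n_consec = count_false_selections(result, frames)
    return {
        "est_rmse": rmse(result.estimates, truth_states),
        "pred_rmse": rmse(result.predictions, truth_states),
        "fdr": false_detection_ratio(nf, nt),
        "n_false_present": nt,
        "n_false_selected": nf,
        "n_consecutive_false": n_consec,
        "n_steps": len(result),
        "mean_weights": weight_statistics(result),
    }


def run_experiment(spec: ExperimentSpec, bank=None, big_model=None,
                   tracker_cfg: TrackerConfig | None = None,
                   baseline_cfg: BaselineConfig | None = None,
                   bt_cfg: BacktrackConfig | None = None) -> pd.DataFrame:
    """Full grid of Monte-Carlo runs; one row per (method, dt, p_fa, replicate).

    Matched seeds: every method sees the identical scenario and scans within a
    replicate, so method comparisons are paired.
    """
    tracker_cfg = tracker_cfg or TrackerConfig()
    rows = []
    ss = np.random.SeedSequence(spec.base_seed)
    for delta_t in spec.delta_t_grid:
        for p_fa in spec.p_fa_grid:
            child_seeds = ss.spawn(spec.n_monte_carlo)
            for rep, child in enumerate(child_seeds):
                seed = int(child.generate_state(1)[0] % (2**31 - 1))
                truth, frames = make_scenario(spec, delta_t, p_fa, seed)
                for method in spec.methods:
                    result = run_method(
                        method, frames, bank=bank, big_model=big_model,
                        tracker_cfg=tracker_cfg, baseline_cfg=baseline_cfg,
                        bt_cfg=bt_cfg, seed=seed,
                    )
                    m = evaluate_run(result, truth, frames)
                    weights = m.pop("mean_weights")
                    row = {"method": method, "delta_t": delta_t, "p_fa": p_fa,
                           "rep": rep, "seed": seed, **m}
                    for j, w in enumerate(weights):
                        row[f"mean_mu_{j + 1}"] = w
                    rows.append(row)
    return pd.DataFrame(rows)


def summarize(raw: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of the metrics per (method, delta_t, p_fa)."""
    grp = raw.groupby(["method", "delta_t", "p_fa"])
    out = grp[["est_rmse", "pred_rmse", "fdr"]].agg(["mean", "sem"])
    out.columns = ["_".join(c) for c in out.columns]
    out["n_runs"] = grp.size()
    return out.reset_index()
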