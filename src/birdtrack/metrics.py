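"""Tracking performance metrics.

RMSE is the root of the mean squared Euclidean *position* error in metres
(velocity components can be included behind a flag, but differenced velocities
have mixed units and would dominate the sum at small scan intervals).  The
false-detection ratio is the fraction of false-alarm occurrences in which the
tracker actually selected the false point.
"""

from __future__ import annotations

import numpy as np

from .tracker import TrackResult

__all__ = ["rmse", "false_detection_ratio", "weight_statistics", "count_false_selections"]


def rmse(values: np.ndarray, truth: np.ndarray, full_state: bool = False) -> float:
    """Root mean squared error between aligned state sequences.

    `values` holds either estimates X_hat_k or one-step predictions X_{k/k-1},
    both already aligned to the truth at the same time stamps (warm-up rows
    excluded identically across methods by the harness).
    """
    values = np.asarray(values, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if values.shape != truth.shape:
        raise ValueError(f"shape mismatch: {values.shape} vs {truth.shape}")
    cols = slice(None) if full_state else [0, 2]
    diff = values[:, cols] - truth[:, cols]
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def false_detection_ratio(n_false_selected: int, n_false_present: int) -> float:
    """Nf / Nt; 0 when no false alarm ever occurred."""
    if n_false_present < 0 or n_false_selected < 0:
        raise ValueError("counts must be non-negative")
    if n_false_selected > n_false_present:
        raise ValueError("selected more false points than were present (bookkeeping bug)")
    if n_false_present == 0:
        return 0.0
    return n_false_selected / n_false_present


def count_false_selections(result: TrackResult, frames) -> tuple[int, int, int]:
    """(Nf, Nt, consecutive false pairs) over the tracked portion of a run.

    `frames` must be the same scan list the tracker consumed; the tracked
    portion is matched by time stamp.
    """
    by_time = {f.time: f for f in frames}
    nf = nt = n_consec = 0
    prev_false = False
    for t, chosen in zip(result.times, result.chosen_index):
        f = by_time[t]
        has_false = len(f.points) > 1
        is_false = has_false and int(chosen) != f.truth_index
        nt += int(has_false)
        nf += int(is_false)
        n_consec += int(is_false and prev_false)
        prev_false = is_false
    return nf, nt, n_consec


def weight_statistics(track: TrackResult) -> np.ndarray:
    """Time-averaged model probability per motion model (sums to 1)."""
    if len(track) == 0:
        raise ValueError("empty track")
    return track.weights.mean(axis=0)
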