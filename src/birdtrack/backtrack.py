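"""Back-tracking correction: revising yesterday's measurement association.

A false-alarm point occasionally wins the gate.  Because the motion models
consume an L-step history, one wrong association contaminates the next L-1
predictions.  The correction keeps up to D' alternative associations alive for
exactly one scan: at the next scan every (hypothesis x gated candidate) pair is
advanced one tracker step, the best-scoring child becomes the new primary --
possibly descending from an alternative, which silently revises the previous
association -- and the beam is refilled with that child's siblings.  Look-back
depth is one step: with false-alarm rate p, two consecutive wrong associations
occur with probability < p**2 and are ignored.

Hypotheses are scored by the sum of log gate densities over the last two steps
(older terms are shared by every live hypothesis, so they cancel in any
comparison and would only drift the scale on long tracks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracker import (
    ModelBankState,
    TrackerConfig,
    TrackResult,
    init_track,
    mixture_density,
    predict_phase,
    update_phase,
)

__all__ = [
    "BacktrackConfig",
    "Hypothesis",
    "gate_candidates",
    "expand_and_prune",
    "finalize",
    "run_backtrack_tracker",
]

_LOG_TINY = 1e-300


@dataclass(frozen=True)
class BacktrackConfig:
    """beam_width D': hypotheses kept alive; eta: gate density threshold
    (same units as the tracker's gating density, m^-2 for the 2-D marginal);
    relax_if_empty: when no point clears eta, keep the single best point.

    eta must sit well below the typical true-point gate density (median
    2e-4..3e-3 m^-2 at 1-3 s scans under the default Q, R), otherwise the
    relaxation rule fires every step, only one point is ever kept and the
    correction is effectively disabled.  The default 1e-6 keeps alternatives
    within roughly 3-5 innovation sigma of the prediction and drops remote
    false alarms."""

    beam_width: int = 2
    eta: float = 1e-6
    relax_if_empty: bool = True

    def __post_init__(self) -> None:
        if self.beam_width < 1 or self.eta < 0:
            raise ValueError("beam_width must be >= 1 and eta >= 0")


@dataclass
class Hypothesis:
    """One candidate association history with its tracker state."""

    state: ModelBankState
    records: list = field(default_factory=list)
    assoc: list = field(default_factory=list)
    last_log_density: float = 0.0
    log_prob: float = 0.0


def _rank_candidates(densities: np.ndarray, cfg: BacktrackConfig) -> list[tuple[int, float]]:
    """Sort points by density (desc, ties to the lower index), apply the eta
    gate, truncate at D'; relax to the single argmax if nothing passes."""
    order = sorted(range(len(densities)), key=lambda i: (-densities[i], i))
    kept = [(i, float(densities[i])) for i in order if densities[i] >= cfg.eta]
    kept = kept[: cfg.beam_width]
    if not kept and cfg.relax_if_empty:
        i = order[0]
        kept = [(i, float(densities[i]))]
    return kept


def gate_candidates(frame, hyp: Hypothesis, bank, cfg: BacktrackConfig,
                    tracker_cfg: TrackerConfig) -> list[tuple[int, float]]:
    """Ranked admissible (point index, density) pairs for one hypothesis."""
    phase = predict_phase(hyp.state, frame.time, bank, tracker_cfg)
    densities = np.array(
        [mixture_density(p, phase.preds, phase.S_pred, phase.mu, tracker_cfg) for p in frame.points]
    )
    return _rank_candidates(densities, cfg)


def expand_and_prune(
    hyps: list[Hypothesis], frame, bank,
    tracker_cfg: TrackerConfig, cfg: BacktrackConfig,
) -> list[Hypothesis]:
    """Advance every (hypothesis x gated candidate) pair and keep D' children.

    The best child by two-step score becomes the primary; the beam is refilled
    with the primary's *siblings* (same parent, different current point), so
    all surviving hypotheses agree on every association older than one step --
    committing to the primary's revision of the previous scan.
    """
    if not hyps:
        raise ValueError("hypothesis beam is empty")
    children: list[tuple[float, int, int, Hypothesis]] = []
    for pi, hyp in enumerate(hyps):
        phase = predict_phase(hyp.state, frame.time, bank, tracker_cfg)
        densities = np.array(
            [mixture_density(p, phase.preds, phase.S_pred, phase.mu, tracker_cfg)
             for p in frame.points]
        )
        for idx, dens in _rank_candidates(densities, cfg):
            new_state, rec = update_phase(hyp.state, phase, frame.points[idx], idx, dens, tracker_cfg)
            logd = float(np.log(max(dens, _LOG_TINY)))
            child = Hypothesis(
                state=new_state,
                records=hyp.records + [rec],
                assoc=hyp.assoc + [idx],
                last_log_density=logd,
                log_prob=hyp.log_prob + logd,
            )
            score = hyp.last_log_density + logd
            children.append((score, pi, idx, child))
    if not children:
        raise ValueError("no admissible candidates (relax_if_empty disabled?)")
    children.sort(key=lambda c: (-c[0], c[1], c[2]))
    best_score, best_parent, _, primary = children[0]
    beam = [primary]
    for score, pi, idx, child in children[1:]:
        if len(beam) >= cfg.beam_width:
            break
        if pi == best_parent:  # siblings only: shared history older than 1 step
            beam.append(child)
    return beam


def finalize(hyps: list[Hypothesis]) -> TrackResult:
    """TrackResult of the most probable hypothesis (revisions included)."""
    if not hyps:
        raise ValueError("no hypotheses to finalize")
    best = max(hyps, key=lambda h: h.log_prob)
    return TrackResult.from_records(best.records)


def run_backtrack_tracker(
    frames, bank, cfg: TrackerConfig | None = None,
    bt_cfg: BacktrackConfig | None = None,
    diagnostics: bool = False,
):
    """Full tracking run with the back-tracking correction enabled.

    With diagnostics=True also returns a per-step DataFrame (number of gated
    candidates, beam occupancy, whether the primary revised the previous
    association).
    """
    cfg = cfg or TrackerConfig()
    bt_cfg = bt_cfg or BacktrackConfig()
    L = cfg.window_len
    state = init_track(frames, cfg, n_models=len(bank))
    beam = [Hypothesis(state=state)]
    diag_rows = []
    for frame in frames[L + 1:]:
        prev_primary_assoc = list(beam[0].assoc)
        beam = expand_and_prune(beam, frame, bank, cfg, bt_cfg)
        if diagnostics:
            revised = (
                len(prev_primary_assoc) > 0
                and beam[0].assoc[:-1][-1:] != prev_primary_assoc[-1:]
            )
            diag_rows.append(
                {"t": frame.time, "n_candidates": len(frame.points),
                 "beam": len(beam), "revised": bool(revised)}
            )
    result = finalize(beam)
    if diagnostics:
        return result, pd.DataFrame(diag_rows)
    return result
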