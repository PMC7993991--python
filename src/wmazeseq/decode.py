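"""Memoryless Poisson Bayesian decoding over (linear position x trajectory).

The posterior for a spike-count vector observed in a window of length tau,
with per-unit templates f_i(x, tr), is

    P(x, tr | spikes)  proportional to  (prod_i f_i(x,tr)^{n_i}) * exp(-tau * sum_i f_i(x,tr))

with a uniform prior over the joint (position, trajectory) state space and
a single normalization across both trajectories.  All computation is done
in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .behavior import LOCO_SPEED_CM_S, in_intervals
from .config import traj_of
from .ratemaps import BIN_CM, RateMap

RATE_FLOOR_HZ = 0.01
BEHAV_TAU_S = 0.120
BEHAV_STEP_S = 0.060
WELL_EXCLUSION_CM = 15.0


@dataclass
class EncodingModel:
    """Templates on a common 2-cm grid for the two trajectories of one travel."""

    travel: str                      # 'outbound' | 'inbound'
    region: str
    unit_ids: List[int]
    bin_edges: np.ndarray            # shared grid, cm from center well
    rates: np.ndarray                # (n_units, 2, D), floor-applied, Hz
    sides: Tuple[str, str] = ("L", "R")

    @property
    def n_bins(self) -> int:
        return self.rates.shape[2]

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def log_rates(self) -> np.ndarray:
        return np.log(self.rates)

    def traj_types(self) -> Tuple[str, str]:
        return tuple(traj_of(self.travel, s) for s in self.sides)


def build_templates(
    maps: Dict[Tuple[int, str], RateMap],
    travel: str,
    region: str,
    unit_ids: Sequence[int],
    rate_floor_hz: float = RATE_FLOOR_HZ,
    min_units: int = 5,
) -> EncodingModel:
    """Assemble an encoding model from per-trajectory rate maps.

    A unit missing a map on one trajectory contributes the floor there.
    Units with no map on either trajectory are dropped.
    """
    tt_l, tt_r = traj_of(travel, "L"), traj_of(travel, "R")
    edges = None
    rates = []
    kept = []
    for uid in unit_ids:
        per_side = []
        found = False
        for tt in (tt_l, tt_r):
            rm = maps.get((uid, tt))
            if rm is None:
                per_side.append(None)
                continue
            if edges is None:
                edges = rm.bin_edges
            elif len(rm.bin_edges) != len(edges) or not np.allclose(
                rm.bin_edges, edges
            ):
                raise ValueError("mismatched bin grids across rate maps")
            per_side.append(np.nan_to_num(rm.rate_hz, nan=0.0))
            found = True
        if not found:
            continue
        D = len(edges) - 1
        f = np.stack(
            [p if p is not None else np.zeros(D) for p in per_side]
        )
        rates.append(np.maximum(f, rate_floor_hz))
        kept.append(uid)
    if edges is None or len(kept) < min_units:
        raise ValueError(
            f"need >= {min_units} units with defined maps, got {len(kept)}"
        )
    return EncodingModel(
        travel=travel,
        region=region,
        unit_ids=kept,
        bin_edges=edges,
        rates=np.stack(rates),
    )


def count_spikes_in_windows(
    trains: Dict[int, np.ndarray],
    unit_ids: Sequence[int],
    window_starts: np.ndarray,
    tau: float,
) -> np.ndarray:
    """(T, n_units) spike counts for half-open windows [t, t + tau)."""
    T = len(window_starts)
    counts = np.zeros((T, len(unit_ids)), dtype=float)
    ends = window_starts + tau
    for j, uid in enumerate(unit_ids):
        st = trains[uid]
        counts[:, j] = np.searchsorted(st, ends, side="left") - np.searchsorted(
            st, window_starts, side="left"
        )
    return counts


def log_posterior(model: EncodingModel, counts: np.ndarray, tau: float) -> np.ndarray:
    """Log posterior, normalized jointly across trajectories.

    counts: (T, n_units) -> returns (T, 2, D) with logsumexp over (2, D)
    equal to 0 for every window.
    """
    counts = np.atleast_2d(np.asarray(counts, float))
    logf = model.log_rates.reshape(len(model.unit_ids), -1)  # (n, 2D)
    sumf = model.rates.reshape(len(model.unit_ids), -1).sum(axis=0)
    ll = counts @ logf - tau * sumf  # (T, 2D)
    ll -= logsumexp(ll, axis=1, keepdims=True)
    return ll.reshape(counts.shape[0], 2, model.n_bins)


def posterior(model: EncodingModel, counts: np.ndarray, tau: float) -> np.ndarray:
    """Posterior probabilities (T, 2, D); each window sums to 1."""
    return np.exp(log_posterior(model, counts, tau))


@dataclass
class BehavioralDecode:
    window_centers: np.ndarray
    map_position_cm: np.ndarray
    map_side: np.ndarray            # 'L' / 'R'
    actual_position_cm: np.ndarray
    actual_side: np.ndarray
    decode_error_cm: np.ndarray
    choice_correct: np.ndarray      # bool per window
    n_excluded_zero_spike: int = 0

    @property
    def session_accuracy(self) -> float:
        return float(np.mean(self.choice_correct)) if len(self.choice_correct) else np.nan

    @property
    def median_error_cm(self) -> float:
        return float(np.median(self.decode_error_cm)) if len(self.decode_error_cm) else np.nan

    def accuracy_by_position(self, bin_cm: float = 10.0) -> pd.DataFrame:
        if not len(self.choice_correct):
            return pd.DataFrame(columns=["bin_left_cm", "accuracy", "n"])
        bins = np.floor(self.actual_position_cm / bin_cm) * bin_cm
        df = pd.DataFrame({"bin_left_cm": bins, "correct": self.choice_correct})
        g = df.groupby("bin_left_cm")["correct"]
        return pd.DataFrame(
            {"bin_left_cm": g.mean().index, "accuracy": g.mean().values,
             "n": g.size().values}
        )


def decode_behavioral(
    model: EncodingModel,
    trains: Dict[int, np.ndarray],
    linearized: pd.DataFrame,
    path_length_cm: float,
    swr_ivals: Optional[np.ndarray] = None,
    tau: float = BEHAV_TAU_S,
    step: float = BEHAV_STEP_S,
) -> BehavioralDecode:
    """Behavioral-timescale decode: 120 ms windows stepped 60 ms.

    Windows are retained when their center falls in locomotion (> 5 cm/s)
    on a trial of the model's travel class, at least 15 cm from a reward
    well, outside SWRs.  Zero-spike windows are excluded and counted.
    """
    t = linearized.time_s.to_numpy(float)
    lin = linearized.linear_cm.to_numpy(float)
    speed = linearized.speed_cm_s.to_numpy(float)
    tts = linearized.traj_type.to_numpy()
    tt_l, tt_r = model.traj_types()

    starts = np.arange(t[0], t[-1] - tau, step)
    centers = starts + tau / 2.0
    idx = np.clip(np.searchsorted(t, centers), 0, len(t) - 1)
    ok = (
        (speed[idx] > LOCO_SPEED_CM_S)
        & ((tts[idx] == tt_l) | (tts[idx] == tt_r))
        & np.isfinite(lin[idx])
    )
    with np.errstate(invalid="ignore"):
        dist_c = lin[idx]
        dist_w = path_length_cm - lin[idx]
        ok &= (dist_c >= WELL_EXCLUSION_CM) & (dist_w >= WELL_EXCLUSION_CM)
    if swr_ivals is not None and len(swr_ivals):
        ok &= ~in_intervals(centers, swr_ivals)

    starts, centers, idx = starts[ok], centers[ok], idx[ok]
    counts = count_spikes_in_windows(trains, model.unit_ids, starts, tau)
    nz = counts.sum(axis=1) > 0
    n_zero = int((~nz).sum())
    counts, centers, idx = counts[nz], centers[nz], idx[nz]
    if len(centers) == 0:
        return BehavioralDecode(
            *(np.empty(0) for _ in range(6)),
            choice_correct=np.empty(0, bool),
            n_excluded_zero_spike=n_zero,
        )

    lp = log_posterior(model, counts, tau)
    flat = lp.reshape(len(centers), -1)
    amax = flat.argmax(axis=1)
    k = amax // model.n_bins
    j = amax % model.n_bins
    map_pos = model.bin_centers[j]
    map_side = np.array(model.sides)[k]
    actual_pos = lin[idx]
    actual_side = np.array(
        ["L" if tt == tt_l else "R" for tt in tts[idx]]
    )
    return BehavioralDecode(
        window_centers=centers,
        map_position_cm=map_pos,
        map_side=map_side,
        actual_position_cm=actual_pos,
        actual_side=actual_side,
        decode_error_cm=np.abs(map_pos - actual_pos),
        choice_correct=map_side == actual_side,
        n_excluded_zero_spike=n_zero,
    )
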