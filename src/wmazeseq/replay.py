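"""Replay detection inside SWRs and CA1-PFC reactivation strength.

Replay: each candidate SWR (>= 5 place cells active, >= 50 ms, during
immobility at a well) is decoded in 10 ms non-overlapping bins; the
R-squared of an ordinary linear regression of MAP position on bin index
is compared against a circular time-bin shuffle of the posterior.

Reactivation: C_RUN holds Pearson correlations of CA1 x PFC linearized
rate maps per trajectory; C_SWR holds correlations of the pair's 10 ms
z-scored event spike trains; the reactivation strength R of the event
for that trajectory is the correlation of the two matrices, with a 95%
CI from cell-identity permutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .decode import EncodingModel, count_spikes_in_windows, posterior
from .lfp import SWREvent
from .ratemaps import RateMap

REPLAY_TAU_S = 0.010
MIN_REPLAY_CELLS = 5
MIN_REPLAY_BINS = 3
N_REPLAY_SHUFFLES = 1000
N_REACT_SHUFFLES = 1000


@dataclass
class ReplayResult:
    swr: SWREvent
    candidate: bool
    n_active: int
    r2: Dict[str, float]
    p: Dict[str, float]
    decoded_side: Optional[str]
    significant: bool
    direction: Optional[str]   # 'forward' | 'reverse' along travel


def _regress_r2(y: np.ndarray) -> Tuple[float, float]:
    """(R^2, slope) of ordinary least squares of y on its index."""
    k = np.arange(len(y), dtype=float)
    if len(y) < 2 or np.ptp(y) == 0:
        return 0.0, 0.0
    slope, intercept = np.polyfit(k, y, 1)
    pred = slope * k + intercept
    ss_res = np.sum((y - pred) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return float(1.0 - ss_res / ss_tot), float(slope)


def detect_replay(
    model: EncodingModel,
    swr_events: Sequence[SWREvent],
    trains: Dict[int, np.ndarray],
    n_shuffles: int = N_REPLAY_SHUFFLES,
    rng: Optional[np.random.Generator] = None,
    position_estimator: str = "map",
) -> List[ReplayResult]:
    """Score every eligible SWR for replay content on both trajectories.

    ``position_estimator``: 'map' regresses the per-bin MAP position
    (default); 'centroid' uses the posterior-weighted mean position.
    """
    rng = np.random.default_rng() if rng is None else rng
    if position_estimator not in ("map", "centroid"):
        raise ValueError("position_estimator must be 'map' or 'centroid'")
    out = []
    for ev in swr_events:
        if ev.duration_s < 0.05:
            continue
        n_active = sum(
            1
            for uid in model.unit_ids
            if np.searchsorted(trains[uid], ev.end_s)
            > np.searchsorted(trains[uid], ev.start_s)
        )
        if n_active < MIN_REPLAY_CELLS:
            out.append(
                ReplayResult(ev, False, n_active, {}, {}, None, False, None)
            )
            continue
        starts = np.arange(ev.start_s, ev.end_s - REPLAY_TAU_S + 1e-9, REPLAY_TAU_S)
        counts = count_spikes_in_windows(trains, model.unit_ids, starts, REPLAY_TAU_S)
        nz = counts.sum(axis=1) > 0
        if nz.sum() < MIN_REPLAY_BINS:
            continue
        P = posterior(model, counts[nz], REPLAY_TAU_S)  # (T, 2, D)
        centers = model.bin_centers

        def _positions(pm):
            if position_estimator == "centroid":
                w = pm / pm.sum(axis=1, keepdims=True)
                return w @ centers
            return centers[pm.argmax(axis=1)]

        r2 = {}
        pvals = {}
        slopes = {}
        for k, side in enumerate(model.sides):
            pm = P[:, k, :]  # (T, D)
            r2_obs, slope = _regress_r2(_positions(pm))
            sh = np.empty(n_shuffles)
            T = pm.shape[0]
            for i in range(n_shuffles):
                shift = rng.integers(1, T) if T > 1 else 0
                rolled = np.roll(pm, shift, axis=0)
                sh[i], _ = _regress_r2(_positions(rolled))
            r2[side] = r2_obs
            pvals[side] = float((np.sum(sh >= r2_obs) + 1) / (n_shuffles + 1))
            slopes[side] = slope
        sig_sides = [s for s in r2 if pvals[s] < 0.05]
        if sig_sides:
            decoded = max(sig_sides, key=lambda s: r2[s])
            travel_sign = 1.0 if model.travel == "outbound" else -1.0
            direction = "forward" if slopes[decoded] * travel_sign > 0 else "reverse"
            out.append(
                ReplayResult(ev, True, n_active, r2, pvals, decoded, True, direction)
            )
        else:
            out.append(
                ReplayResult(ev, True, n_active, r2, pvals, None, False, None)
            )
    return out


@dataclass
class ReactivationResult:
    swr: SWREvent
    ca1_ids: List[int]
    pfc_ids: List[int]
    strength: Dict[str, float]          # trajectory side -> R
    shuffle_ci: Dict[str, Tuple[float, float]]


def run_correlation_matrix(
    maps: Dict[Tuple[int, str], RateMap],
    ca1_ids: Sequence[int],
    pfc_ids: Sequence[int],
    traj_type: str,
) -> np.ndarray:
    """C_RUN: (N_CA1, M_PFC) Pearson correlations of linearized rate maps."""
    def _vec(uid):
        rm = maps.get((uid, traj_type))
        return None if rm is None else np.nan_to_num(rm.rate_hz, nan=0.0)

    C = np.full((len(ca1_ids), len(pfc_ids)), np.nan)
    for i, ci in enumerate(ca1_ids):
        vi = _vec(ci)
        if vi is None or np.std(vi) == 0:
            continue
        for j, pj in enumerate(pfc_ids):
            vj = _vec(pj)
            if vj is None or np.std(vj) == 0:
                continue
            C[i, j] = np.corrcoef(vi, vj)[0, 1]
    return C


def swr_correlation_matrix(
    trains: Dict[int, np.ndarray],
    ca1_ids: Sequence[int],
    pfc_ids: Sequence[int],
    start_s: float,
    end_s: float,
    bin_s: float = 0.010,
) -> np.ndarray:
    """C_SWR: correlations of z-scored 10 ms binned event spike trains."""
    edges = np.arange(start_s, end_s + bin_s / 2, bin_s)
    if len(edges) < 3:
        return np.full((len(ca1_ids), len(pfc_ids)), np.nan)

    def _z(uid):
        h, _ = np.histogram(trains[uid], bins=edges)
        sd = h.std()
        if sd == 0:
            return None
        return (h - h.mean()) / sd

    zc = [_z(u) for u in ca1_ids]
    zp = [_z(u) for u in pfc_ids]
    n = len(edges) - 1
    C = np.full((len(ca1_ids), len(pfc_ids)), np.nan)
    for i, vi in enumerate(zc):
        if vi is None:
            continue
        for j, vj in enumerate(zp):
            if vj is None:
                continue
            C[i, j] = float((vi * vj).mean())
    return C


def matrix_correlation(c_run: np.ndarray, c_swr: np.ndarray) -> float:
    """Correlation of the vectorized matrices over jointly finite entries."""
    a = c_run.ravel()
    b = c_swr.ravel()
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
        return np.nan
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


def reactivation_strength(
    event: SWREvent,
    trains: Dict[int, np.ndarray],
    maps: Dict[Tuple[int, str], RateMap],
    ca1_ids: Sequence[int],
    pfc_ids: Sequence[int],
    traj_types: Sequence[str],
    n_shuffles: int = N_REACT_SHUFFLES,
    rng: Optional[np.random.Generator] = None,
) -> Optional[ReactivationResult]:
    """Reactivation strength R per trajectory for one SWR.

    Requires >= 5 CA1 and >= 5 PFC cells with spikes in the event.
    The null CI comes from permuting PFC cell identity in C_SWR.
    """
    rng = np.random.default_rng() if rng is None else rng

    def _active(ids):
        return [
            u
            for u in ids
            if np.searchsorted(trains[u], event.end_s)
            > np.searchsorted(trains[u], event.start_s)
        ]

    ca1 = _active(ca1_ids)
    pfc = _active(pfc_ids)
    if len(ca1) < 5 or len(pfc) < 5:
        return None
    c_swr = swr_correlation_matrix(trains, ca1, pfc, event.start_s, event.end_s)
    strength = {}
    cis = {}
    for tt in traj_types:
        c_run = run_correlation_matrix(maps, ca1, pfc, tt)
        strength[tt] = matrix_correlation(c_run, c_swr)
        sh = np.empty(n_shuffles)
        for i in range(n_shuffles):
            perm = rng.permutation(c_swr.shape[1])
            sh[i] = matrix_correlation(c_run, c_swr[:, perm])
        ok = np.isfinite(sh)
        if ok.any():
            lo, hi = np.percentile(sh[ok], [2.5, 97.5])
        else:
            lo = hi = np.nan
        cis[tt] = (float(lo), float(hi))
    return ReactivationResult(
        swr=event, ca1_ids=ca1, pfc_ids=pfc, strength=strength, shuffle_ci=cis
    )
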