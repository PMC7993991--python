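"""Theta-sequence detection and scoring.

Candidate events are theta cycles with >= 5 active units at running speed
> 10 cm/s lasting 100-200 ms.  Each candidate is decoded at 20 ms / 10 ms
resolution; each trajectory's posterior is scored with (a) the weighted
space-time correlation r and (b) the best-fit constant-velocity line
goodness-of-fit R_max, and tested against space-circular shuffles.

Position axes are oriented along the direction of travel, so a forward
sequence always has r > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .decode import EncodingModel, count_spikes_in_windows, posterior
from .lfp import ThetaCycle, ThetaPhaseSeries

EVENT_TAU_S = 0.020
EVENT_STEP_S = 0.010
MIN_ACTIVE_UNITS = 5
MIN_EVENT_SPEED = 10.0
EVENT_MIN_S, EVENT_MAX_S = 0.100, 0.200
MIN_DECODED_WINDOWS = 3
VICINITY_CM = 8.0
V_MIN_MPS, V_MAX_MPS, V_STEP_MPS = 1.0, 15.0, 0.25
N_SHUFFLES = 1000
DISTANCE_WINDOW_CM = 60.0


# --------------------------------------------------------------------------
# candidate events
# --------------------------------------------------------------------------
@dataclass
class CandidateEvent:
    event_id: int
    region: str
    start_s: float
    end_s: float
    n_active: int
    speed_cm_s: float
    position_cm: float      # animal linear position (from center well)
    trial_id: int
    travel: str
    choice: str             # trial's choice side

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def find_candidates(
    cycles: Sequence[ThetaCycle],
    trains: Dict[int, np.ndarray],
    unit_ids: Sequence[int],
    linearized: pd.DataFrame,
    trials: pd.DataFrame,
    region: str,
    min_active: int = MIN_ACTIVE_UNITS,
) -> List[CandidateEvent]:
    """Gate theta cycles into candidate events for one region."""
    t = linearized.time_s.to_numpy(float)
    speed = linearized.speed_cm_s.to_numpy(float)
    lin = linearized.linear_cm.to_numpy(float)
    trial_of = linearized.trial_id.to_numpy()
    tr_idx = trials.set_index("trial_id")
    out = []
    eid = 0
    for cyc in cycles:
        if not EVENT_MIN_S <= cyc.duration_s <= EVENT_MAX_S:
            continue
        mid = 0.5 * (cyc.start_s + cyc.end_s)
        i = min(int(np.searchsorted(t, mid)), len(t) - 1)
        if speed[i] <= MIN_EVENT_SPEED or trial_of[i] < 0 or not np.isfinite(lin[i]):
            continue
        n_active = sum(
            1
            for uid in unit_ids
            if np.searchsorted(trains[uid], cyc.end_s)
            > np.searchsorted(trains[uid], cyc.start_s)
        )
        if n_active < min_active:
            continue
        trial = tr_idx.loc[int(trial_of[i])]
        out.append(
            CandidateEvent(
                event_id=eid,
                region=region,
                start_s=cyc.start_s,
                end_s=cyc.end_s,
                n_active=n_active,
                speed_cm_s=float(speed[i]),
                position_cm=float(lin[i]),
                trial_id=int(trial_of[i]),
                travel=str(trial.travel),
                choice=str(trial.choice),
            )
        )
        eid += 1
    return out


# --------------------------------------------------------------------------
# event decoding
# --------------------------------------------------------------------------
@dataclass
class EventPosterior:
    """Oriented per-trajectory posteriors for one candidate event.

    pmats[side] has shape (D, T); the position axis increases along the
    direction of travel (flipped for inbound trajectories).
    """

    pmats: Dict[str, np.ndarray]
    window_centers: np.ndarray
    window_idx: np.ndarray        # surviving window indices on the step grid
    bin_cm: float
    animal_pos_oriented_cm: float
    travel: str


def orient_positions(lin_cm, path_length_cm: float, travel: str):
    """Map center-well-referenced positions to travel-oriented positions."""
    return lin_cm if travel == "outbound" else path_length_cm - lin_cm


def decode_event(
    model: EncodingModel,
    trains: Dict[int, np.ndarray],
    cand: CandidateEvent,
    tau: float = EVENT_TAU_S,
    step: float = EVENT_STEP_S,
) -> Optional[EventPosterior]:
    """Decode one candidate at theta timescale; None if < 3 usable windows."""
    starts = np.arange(cand.start_s, cand.end_s - tau + 1e-9, step)
    if len(starts) < MIN_DECODED_WINDOWS:
        return None
    counts = count_spikes_in_windows(trains, model.unit_ids, starts, tau)
    nz = counts.sum(axis=1) > 0
    if nz.sum() < MIN_DECODED_WINDOWS:
        return None
    window_idx = np.flatnonzero(nz)
    starts, counts = starts[nz], counts[nz]
    P = posterior(model, counts, tau)  # (T, 2, D)
    bin_cm = float(model.bin_edges[1] - model.bin_edges[0])
    path_len = float(model.bin_edges[-1])
    pmats = {}
    for k, side in enumerate(model.sides):
        pm = P[:, k, :].T  # (D, T)
        if cand.travel == "inbound":
            pm = pm[::-1]
        pmats[side] = pm
    return EventPosterior(
        pmats=pmats,
        window_centers=starts + tau / 2.0,
        window_idx=window_idx,
        bin_cm=bin_cm,
        animal_pos_oriented_cm=float(
            orient_positions(cand.position_cm, path_len, cand.travel)
        ),
        travel=cand.travel,
    )


# --------------------------------------------------------------------------
# scoring
# --------------------------------------------------------------------------
def weighted_correlation(
    pmat: np.ndarray,
    x: Optional[np.ndarray] = None,
    t: Optional[np.ndarray] = None,
) -> float:
    """Posterior-mass-weighted correlation between position and time.

    pmat is (D, T): rows are position bins x_j, columns time bins t_i.
    """
    P = np.asarray(pmat, float)
    D, T = P.shape
    x = np.arange(D, dtype=float) if x is None else np.asarray(x, float)
    t = np.arange(T, dtype=float) if t is None else np.asarray(t, float)
    W = P.sum()
    if W <= 0:
        return np.nan
    ex = (P * x[:, None]).sum() / W
    et = (P * t[None, :]).sum() / W
    dx = x - ex
    dt_ = t - et
    cov_xt = (P * dx[:, None] * dt_[None, :]).sum() / W
    cov_xx = (P * dx[:, None] ** 2).sum() / W
    cov_tt = (P * dt_[None, :] ** 2).sum() / W
    denom = np.sqrt(cov_xx * cov_tt)
    if denom == 0:
        return np.nan
    return float(cov_xt / denom)


@dataclass
class BestFitLine:
    v_mps: float        # signed slope
    rho_cm: float       # position at the first time bin
    r_max: float


_LINE_GRID_CACHE: Dict[tuple, tuple] = {}


def _line_grid(D: int, T: int, bin_cm: float, dt_s: float, d_cm: float,
               v_min: float, v_max: float, v_step: float,
               t_idx: Optional[np.ndarray] = None):
    """Cached (slopes cm/s, intercepts cm, j_lo, j_hi) index grids for the
    line search; they depend only on the posterior shape, the (possibly
    non-contiguous) window indices, and the parameters."""
    k = np.arange(T, dtype=float) if t_idx is None else np.asarray(t_idx, float)
    key = (D, T, bin_cm, dt_s, d_cm, v_min, v_max, v_step, tuple(k))
    hit = _LINE_GRID_CACHE.get(key)
    if hit is not None:
        return hit
    v_abs = np.arange(v_min, v_max + 1e-9, v_step)
    vs = np.concatenate([v_abs, -v_abs]) * 100.0  # cm/s
    vs = vs[np.argsort(np.abs(vs), kind="stable")]
    rhos = (np.arange(D) + 0.5) * bin_cm
    pos = rhos[None, :, None] + vs[:, None, None] * (k[None, None, :] * dt_s)
    # 1e-9 cm tolerance keeps exact-boundary bins in deterministically
    j_lo = np.clip(
        np.ceil((pos - d_cm) / bin_cm - 0.5 - 1e-9).astype(np.int32), 0, D
    )
    j_hi = np.clip(
        np.floor((pos + d_cm) / bin_cm - 0.5 + 1e-9).astype(np.int32) + 1, 0, D
    )
    out = (vs, rhos, j_lo, j_hi)
    _LINE_GRID_CACHE[key] = out
    return out


def _norm_columns(pmat: np.ndarray) -> np.ndarray:
    # normalize columns so R is an average probability even if the input
    # is a single-trajectory slice of a jointly normalized posterior
    P = np.asarray(pmat, float)
    csum = P.sum(axis=0, keepdims=True)
    csum = np.where(csum == 0, 1.0, csum)
    return P / csum


def best_fit_line(
    pmat: np.ndarray,
    bin_cm: float,
    dt_s: float = EVENT_STEP_S,
    d_cm: float = VICINITY_CM,
    v_min: float = V_MIN_MPS,
    v_max: float = V_MAX_MPS,
    v_step: float = V_STEP_MPS,
    t_idx: Optional[np.ndarray] = None,
) -> BestFitLine:
    """Dense grid search for the constant-velocity line maximizing the
    average posterior mass within ``d_cm`` of the line.

    Slopes span +-[v_min, v_max] m/s in v_step increments; intercepts sit
    at every position-bin center; ``t_idx`` supplies the window indices
    when interior windows were dropped.  Ties resolve to the line with
    the most mass in a tight half-bin vicinity, then to the smallest |v|
    and intercept.
    """
    Pn = _norm_columns(pmat)
    D, T = Pn.shape
    vs, rhos, j_lo, j_hi = _line_grid(
        D, T, bin_cm, dt_s, d_cm, v_min, v_max, v_step, t_idx
    )
    C = np.vstack([np.zeros((1, T)), np.cumsum(Pn, axis=0)])  # (D+1, T)
    karr = np.broadcast_to(np.arange(T), j_lo.shape)
    mass = C[j_hi, karr] - C[j_lo, karr]
    R = mass.mean(axis=2)  # (nv, nrho)
    best = R.max()
    ties = np.argwhere(R >= best - 1e-12)
    if len(ties) > 1:
        # refine ties (e.g. a saturated delta ridge) by the mass in a
        # tight half-bin vicinity, then smallest |v| / intercept
        _, _, tl, th = _line_grid(
            D, T, bin_cm, dt_s, bin_cm / 2, v_min, v_max, v_step, t_idx
        )
        k1 = np.arange(T)
        tight = np.array(
            [(C[th[i, j], k1] - C[tl[i, j], k1]).mean() for i, j in ties]
        )
        ties = ties[tight >= tight.max() - 1e-12]
    iv, ir = ties[0]
    return BestFitLine(
        v_mps=float(vs[iv] / 100.0), rho_cm=float(rhos[ir]), r_max=float(best)
    )


def space_circular_shuffle(pmat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently circularly shift the position bins of each column."""
    D, T = pmat.shape
    shifts = rng.integers(0, D, size=T)
    rows = (np.arange(D)[:, None] - shifts[None, :]) % D
    return pmat[rows, np.arange(T)[None, :]]


def _shuffle_scores_batch(
    pmat: np.ndarray,
    n_shuffles: int,
    rng: np.random.Generator,
    bin_cm: float,
    dt_s: float,
    d_cm: float = VICINITY_CM,
    v_chunk: int = 16,
    t_idx: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """(r, R_max) for ``n_shuffles`` space-circular shuffles, vectorized.

    Equivalent to calling weighted_correlation / best_fit_line on each
    shuffle of ``space_circular_shuffle`` draws from the same rng stream.
    """
    Pn = _norm_columns(pmat)
    D, T = Pn.shape
    shifts = rng.integers(0, D, size=(n_shuffles, T))  # (S, T)
    rows = (np.arange(D)[None, :, None] - shifts[:, None, :]) % D  # (S, D, T)
    stack = Pn[rows, np.arange(T)[None, None, :]]  # (S, D, T)

    # weighted correlation, vectorized over shuffles
    x = np.arange(D, dtype=float)
    t = np.arange(T, dtype=float) if t_idx is None else np.asarray(t_idx, float)
    W = stack.sum(axis=(1, 2))
    ex = np.einsum("sdt,d->s", stack, x) / W
    et = np.einsum("sdt,t->s", stack, t) / W
    dx = x[None, :] - ex[:, None]           # (S, D)
    dt_ = t[None, :] - et[:, None]          # (S, T)
    cov_xt = np.einsum("sdt,sd,st->s", stack, dx, dt_) / W
    cov_xx = np.einsum("sdt,sd->s", stack, dx**2) / W
    cov_tt = np.einsum("sdt,st->s", stack, dt_**2) / W
    with np.errstate(invalid="ignore", divide="ignore"):
        r_sh = cov_xt / np.sqrt(cov_xx * cov_tt)

    # best-fit-line goodness of fit
    vs, _rhos, j_lo, j_hi = _line_grid(
        D, T, bin_cm, dt_s, d_cm, V_MIN_MPS, V_MAX_MPS, V_STEP_MPS, t_idx
    )
    C = np.concatenate(
        [np.zeros((n_shuffles, 1, T)), np.cumsum(stack, axis=1)], axis=1
    )  # (S, D+1, T)
    karr = np.arange(T)
    rmax_sh = np.full(n_shuffles, -np.inf)
    for i0 in range(0, len(vs), v_chunk):
        lo = j_lo[i0 : i0 + v_chunk]  # (c, nrho, T)
        hi = j_hi[i0 : i0 + v_chunk]
        mass = C[:, hi, karr] - C[:, lo, karr]  # (S, c, nrho, T)
        R = mass.mean(axis=3).reshape(n_shuffles, -1).max(axis=1)
        rmax_sh = np.maximum(rmax_sh, R)
    return r_sh, rmax_sh


@dataclass
class SequenceScore:
    r: float
    line: BestFitLine
    r_lo: float = np.nan        # 2.5th percentile of shuffled r
    r_hi: float = np.nan        # 97.5th percentile of shuffled r
    rmax_thr: float = np.nan    # 95th percentile of shuffled R_max
    p_r: float = np.nan
    p_rmax: float = np.nan
    significant: bool = False


def shuffle_significance(
    pmat: np.ndarray,
    bin_cm: float,
    n_shuffles: int = N_SHUFFLES,
    rng: Optional[np.random.Generator] = None,
    dt_s: float = EVENT_STEP_S,
    t_idx: Optional[np.ndarray] = None,
) -> SequenceScore:
    """Score one trajectory's posterior against space-circular shuffles.

    Significant iff r is outside the [2.5, 97.5] shuffle percentiles AND
    R_max exceeds the 95th shuffle percentile.
    """
    rng = np.random.default_rng() if rng is None else rng
    if n_shuffles < 100:
        import warnings

        warnings.warn("fewer than 100 shuffles: percentile resolution is low")
    r_obs = weighted_correlation(pmat, t=t_idx)
    line_obs = best_fit_line(pmat, bin_cm, dt_s=dt_s, t_idx=t_idx)
    r_sh, rmax_sh = _shuffle_scores_batch(
        pmat, n_shuffles, rng, bin_cm, dt_s, t_idx=t_idx
    )
    r_lo, r_hi = np.nanpercentile(r_sh, [2.5, 97.5])
    rmax_thr = np.nanpercentile(rmax_sh, 95.0)
    p_r = 2 * min(
        (np.sum(r_sh >= r_obs) + 1) / (n_shuffles + 1),
        (np.sum(r_sh <= r_obs) + 1) / (n_shuffles + 1),
    )
    p_rmax = (np.sum(rmax_sh >= line_obs.r_max) + 1) / (n_shuffles + 1)
    sig = (
        np.isfinite(r_obs)
        and (r_obs > r_hi or r_obs < r_lo)
        and line_obs.r_max > rmax_thr
    )
    return SequenceScore(
        r=r_obs, line=line_obs, r_lo=float(r_lo), r_hi=float(r_hi),
        rmax_thr=float(rmax_thr), p_r=float(min(p_r, 1.0)),
        p_rmax=float(p_rmax), significant=bool(sig),
    )


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------
@dataclass
class SequenceResult:
    event: CandidateEvent
    scores: Dict[str, SequenceScore]
    decoded_side: Optional[str]
    significant: bool
    direction: Optional[str]        # 'forward' | 'reverse'
    slope_mps: float
    start_rel_cm: float             # fitted line start minus animal position
    end_rel_cm: float
    represents: Optional[str]       # 'actual' | 'alternative'
    segment: str = "neither"        # before_cp | after_cp | neither


def classify_sequence(
    ep: EventPosterior,
    scores: Dict[str, SequenceScore],
    cand: CandidateEvent,
) -> SequenceResult:
    """Pick the decoded trajectory and derive direction/slope/extent."""
    sig_sides = [s for s, sc in scores.items() if sc.significant]
    if not sig_sides:
        return SequenceResult(
            event=cand, scores=scores, decoded_side=None, significant=False,
            direction=None, slope_mps=np.nan, start_rel_cm=np.nan,
            end_rel_cm=np.nan, represents=None,
        )
    decoded = max(sig_sides, key=lambda s: abs(scores[s].r))
    sc = scores[decoded]
    v_cm = sc.line.v_mps * 100.0
    k0, k1 = ep.window_idx[0], ep.window_idx[-1]
    start = sc.line.rho_cm + v_cm * k0 * EVENT_STEP_S
    end = sc.line.rho_cm + v_cm * k1 * EVENT_STEP_S
    return SequenceResult(
        event=cand,
        scores=scores,
        decoded_side=decoded,
        significant=True,
        direction="forward" if sc.r > 0 else "reverse",
        slope_mps=abs(sc.line.v_mps),
        start_rel_cm=float(start - ep.animal_pos_oriented_cm),
        end_rel_cm=float(end - ep.animal_pos_oriented_cm),
        represents="actual" if decoded == cand.choice else "alternative",
    )


def score_event(
    model: EncodingModel,
    trains: Dict[int, np.ndarray],
    cand: CandidateEvent,
    n_shuffles: int = N_SHUFFLES,
    rng: Optional[np.random.Generator] = None,
) -> Optional[SequenceResult]:
    """Decode + score + classify one candidate (None if undecodable)."""
    ep = decode_event(model, trains, cand)
    if ep is None:
        return None
    rng = np.random.default_rng() if rng is None else rng
    scores = {
        side: shuffle_significance(pm, ep.bin_cm, n_shuffles, rng,
                                   t_idx=ep.window_idx)
        for side, pm in ep.pmats.items()
    }
    return classify_sequence(ep, scores, cand)


# --------------------------------------------------------------------------
# distance index
# --------------------------------------------------------------------------
@dataclass
class DistanceIndex:
    first_half: float    # (III - II)/(III + II)
    second_half: float   # (IV - I)/(IV + I)
    quadrants: Tuple[float, float, float, float]  # I, II, III, IV masses


def distance_index(
    eps: Sequence[EventPosterior],
    results: Sequence[SequenceResult],
    phase_series: ThetaPhaseSeries,
    window_cm: float = DISTANCE_WINDOW_CM,
) -> Optional[DistanceIndex]:
    """Quadrant-mass distance index over forward candidates (r > 0).

    Posterior mass within +-60 cm of the animal is split by relative
    position (behind/ahead) and theta-phase half (-pi..0 first, 0..pi
    second).  Quadrants: II = first/behind, III = first/ahead,
    I = second/behind, IV = second/ahead.
    """
    q = np.zeros(4)  # I, II, III, IV
    for ep, res in zip(eps, results):
        side = res.decoded_side or max(
            res.scores, key=lambda s: res.scores[s].r
        )
        if not np.isfinite(res.scores[side].r) or res.scores[side].r <= 0:
            continue
        pm = ep.pmats[side]
        D, T = pm.shape
        xs = (np.arange(D) + 0.5) * ep.bin_cm - ep.animal_pos_oriented_cm
        ph = phase_series.at(ep.window_centers)
        first = ph < 0
        behind = (xs >= -window_cm) & (xs < 0)
        ahead = (xs > 0) & (xs <= window_cm)
        pm_n = pm / max(pm.sum(), 1e-300)
        q[1] += pm_n[np.ix_(behind, first)].sum()   # II
        q[2] += pm_n[np.ix_(ahead, first)].sum()    # III
        q[0] += pm_n[np.ix_(behind, ~first)].sum()  # I
        q[3] += pm_n[np.ix_(ahead, ~first)].sum()   # IV
    if q[1] + q[2] == 0 or q[0] + q[3] == 0:
        return None
    return DistanceIndex(
        first_half=float((q[2] - q[1]) / (q[2] + q[1])),
        second_half=float((q[3] - q[0]) / (q[3] + q[0])),
        quadrants=tuple(q),
    )


# --------------------------------------------------------------------------
# choice representation and CA1-PFC coherence
# --------------------------------------------------------------------------
def results_to_frame(results: Sequence[SequenceResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        ev = res.event
        row = dict(
            event_id=ev.event_id, region=ev.region, trial_id=ev.trial_id,
            start_s=ev.start_s, end_s=ev.end_s, travel=ev.travel,
            choice=ev.choice, position_cm=ev.position_cm, segment=res.segment,
            significant=res.significant, decoded_side=res.decoded_side,
            direction=res.direction, slope_mps=res.slope_mps,
            start_rel_cm=res.start_rel_cm, end_rel_cm=res.end_rel_cm,
            represents=res.represents,
        )
        for side, sc in res.scores.items():
            row[f"r_{side}"] = sc.r
            row[f"rmax_{side}"] = sc.line.r_max
            row[f"p_r_{side}"] = sc.p_r
        rows.append(row)
    return pd.DataFrame(rows)


def label_segments(
    results: Sequence[SequenceResult], cp_arclength_cm: float
) -> None:
    """Assign before/after-CP segment labels in place (10-cm gap excluded)."""
    for res in results:
        pos = res.event.position_cm
        if pos < cp_arclength_cm:
            res.segment = "before_cp"
        elif pos >= cp_arclength_cm + 10.0:
            res.segment = "after_cp"
        else:
            res.segment = "neither"


def choice_representation(
    results: Sequence[SequenceResult], segment: Optional[str] = None
) -> Tuple[float, float, pd.DataFrame]:
    """(% actual, % alternative, per-trial counts) of significant sequences."""
    sel = [
        r for r in results
        if r.significant and (segment is None or r.segment == segment)
    ]
    if not sel:
        return np.nan, np.nan, pd.DataFrame(
            columns=["trial_id", "n_actual", "n_alternative"]
        )
    n_act = sum(r.represents == "actual" for r in sel)
    n_alt = len(sel) - n_act
    per_trial = (
        pd.DataFrame(
            [
                dict(trial_id=r.event.trial_id, actual=r.represents == "actual")
                for r in sel
            ]
        )
        .groupby("trial_id")["actual"]
        .agg(n_actual="sum", n_total="count")
        .reset_index()
    )
    per_trial["n_alternative"] = per_trial.n_total - per_trial.n_actual
    per_trial = per_trial[["trial_id", "n_actual", "n_alternative"]]
    return 100.0 * n_act / len(sel), 100.0 * n_alt / len(sel), per_trial


def coherent_pairs(
    ca1_results: Sequence[SequenceResult],
    pfc_results: Sequence[SequenceResult],
    min_events: int = 5,
) -> Optional[pd.DataFrame]:
    """Conditional PFC representation given CA1, on shared theta cycles.

    Events are matched when their cycle intervals coincide.  Returns a
    one-row table with the conditionals and the independence-null
    marginal, or None with fewer than ``min_events`` matches.
    """
    ca1 = {
        (round(r.event.start_s, 4), round(r.event.end_s, 4)): r
        for r in ca1_results
        if r.significant
    }
    matched = []
    for r in pfc_results:
        if not r.significant:
            continue
        key = (round(r.event.start_s, 4), round(r.event.end_s, 4))
        if key in ca1:
            matched.append((ca1[key], r))
    if len(matched) < min_events:
        return None
    df = pd.DataFrame(
        [
            dict(ca1=c.represents, pfc=p.represents)
            for c, p in matched
        ]
    )
    p_pfc_actual = float((df.pfc == "actual").mean())
    ca1_act = df[df.ca1 == "actual"]
    ca1_alt = df[df.ca1 == "alternative"]
    return pd.DataFrame(
        [
            dict(
                n_matched=len(df),
                p_pfc_actual=p_pfc_actual,
                p_pfc_actual_given_ca1_actual=(
                    float((ca1_act.pfc == "actual").mean()) if len(ca1_act) else np.nan
                ),
                p_pfc_alt_given_ca1_alt=(
                    float((ca1_alt.pfc == "alternative").mean())
                    if len(ca1_alt)
                    else np.nan
                ),
            )
        ]
    )
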