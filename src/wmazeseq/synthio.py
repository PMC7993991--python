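"""Synthetic W-maze sessions with known ground truth.

Generates continuous alternation behavior (four trajectory types),
trajectory-selective place/PFC cells as inhomogeneous Poisson processes
(1 ms thinning) with theta phase precession and optional cycle skipping,
a theta/ripple LFP reference channel, and immobility SWRs carrying
planted replay content.  All randomness flows through generators derived
from ``SimConfig.seed``, so identical configs produce identical sessions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import erf

from .config import MazeGeometry, SimConfig, traj_of, traj_side, traj_travel
from .io import Session, SpikeSet

RUN_RAMP_S = 0.6          # accel/decel ramp of the trapezoidal speed profile
POS_NOISE_SD_CM = 0.10    # tracking jitter on x/y
SPIKE_DT_S = 0.001        # thinning resolution


# --------------------------------------------------------------------------
# ground truth bookkeeping
# --------------------------------------------------------------------------
@dataclass
class GroundTruth:
    """Planted parameters of a synthetic session, one record per entity."""

    units: pd.DataFrame       # per-unit true tuning parameters
    trials: pd.DataFrame      # true choice / correctness (copy of trial table)
    swrs: pd.DataFrame        # planted SWR times and replay content
    behavior: pd.DataFrame    # per position sample: true linear pos, traj, speed
    run_intervals: pd.DataFrame  # start_s, end_s, traj_type, trial_id

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("units", "trials", "swrs", "behavior", "run_intervals"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)

    @classmethod
    def load(cls, in_dir) -> "GroundTruth":
        src = Path(in_dir)
        return cls(
            **{
                name: pd.read_csv(src / f"{name}.csv")
                for name in ("units", "trials", "swrs", "behavior", "run_intervals")
            }
        )


# --------------------------------------------------------------------------
# behavior
# --------------------------------------------------------------------------
def _trapezoid_arclength(total_len: float, speed: float, fs: float):
    """Arclength-vs-time samples of a trapezoidal speed profile.

    Ramps of RUN_RAMP_S at both ends; the cruise phase covers the rest.
    Returns (t, s, v) arrays sampled at fs, starting at t=0, s=0.
    """
    tr = RUN_RAMP_S
    ramp_dist = speed * tr / 2.0
    if 2 * ramp_dist >= total_len:
        # short path: triangular profile reaching a lower peak speed
        tr = np.sqrt(total_len / speed * tr)
        cruise_t = 0.0
        peak = total_len / tr
    else:
        cruise_t = (total_len - 2 * ramp_dist) / speed
        peak = speed
    total_t = 2 * tr + cruise_t
    t = np.arange(0.0, total_t, 1.0 / fs)
    v = np.where(
        t < tr,
        peak * t / tr,
        np.where(t < tr + cruise_t, peak, np.clip(peak * (total_t - t) / tr, 0, peak)),
    )
    s = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) / fs)])
    s = np.clip(s, 0.0, total_len)
    return t, s, v


def gen_behavior(cfg: SimConfig, rng: Optional[np.random.Generator] = None):
    """Simulate alternation behavior.

    Returns (position, trials, gt_behavior, run_intervals): the position
    trace at ``cfg.fs_pos``, the trial table, per-sample ground-truth
    linear position / trajectory / speed, and run intervals.
    """
    if cfg.n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    rng = np.random.default_rng([cfg.seed, 1]) if rng is None else rng
    maze = cfg.maze
    fs = cfg.fs_pos
    plen = maze.path_length_cm

    t_cursor = 0.0
    times: List[np.ndarray] = []
    xs: List[np.ndarray] = []
    ys: List[np.ndarray] = []
    lin: List[np.ndarray] = []
    spd: List[np.ndarray] = []
    traj: List[np.ndarray] = []
    trial_rows = []
    run_rows = []

    def _dwell(well: str, dur: float):
        nonlocal t_cursor
        n = max(int(round(dur * fs)), 1)
        t = t_cursor + np.arange(n) / fs
        wx, wy = maze.well_xy(well)
        # slow AR(1) wander, small enough to stay below the immobility gate
        steps = rng.normal(0, 0.02, size=(n, 2))
        wander = np.empty((n, 2))
        acc = np.zeros(2)
        for i in range(n):
            acc = 0.98 * acc + steps[i]
            wander[i] = acc
        times.append(t)
        xs.append(wx + wander[:, 0])
        ys.append(wy + wander[:, 1])
        lin.append(np.full(n, plen if well in ("L", "R") else 0.0))
        spd.append(np.zeros(n))
        traj.append(np.full(n, "none", dtype=object))
        t_cursor = float(t[-1] + 1.0 / fs)

    def _run(traj_type: str, trial_id: int):
        nonlocal t_cursor
        side = traj_side(traj_type)
        outbound = traj_travel(traj_type) == "outbound"
        t_rel, s, v = _trapezoid_arclength(plen, cfg.run_speed_cm_s, fs)
        arclen = s if outbound else plen - s
        pts = maze.point_at_arclength(side, arclen)
        t = t_cursor + t_rel
        times.append(t)
        xs.append(pts[:, 0] + rng.normal(0, POS_NOISE_SD_CM, len(t)))
        ys.append(pts[:, 1] + rng.normal(0, POS_NOISE_SD_CM, len(t)))
        lin.append(arclen)
        spd.append(v)
        traj.append(np.full(len(t), traj_type, dtype=object))
        run_rows.append(
            dict(start_s=t[0], end_s=t[-1], traj_type=traj_type, trial_id=trial_id)
        )
        t_cursor = float(t[-1] + 1.0 / fs)
        return t[0], t[-1]

    # initial dwell at center well before the first outbound run
    _dwell("C", 3.0)

    current_well = "C"
    last_side: Optional[str] = None
    for trial_id in range(cfg.n_trials):
        if current_well == "C":
            travel = "outbound"
            if last_side is None:
                choice = "L" if rng.random() < 0.5 else "R"
                correct = True
            else:
                correct_choice = "L" if last_side == "R" else "R"
                if rng.random() < cfg.error_rate:
                    choice = last_side
                    correct = False
                else:
                    choice = correct_choice
                    correct = True
            traj_type = traj_of("outbound", choice)
            target = choice
        else:
            travel = "inbound"
            choice = current_well
            correct = True
            traj_type = traj_of("inbound", choice)
            target = "C"

        run_start, run_end = _run(traj_type, trial_id)
        arrival_trigger = run_end + 0.1
        dwell_dur = rng.uniform(*cfg.dwell_range_s)
        _dwell(target, dwell_dur)
        departure_trigger = t_cursor + 0.05  # beam crossed just after leaving
        trial_rows.append(
            dict(
                trial_id=trial_id,
                travel=travel,
                traj_type=traj_type,
                choice=choice,
                correct=correct,
                start_s=run_start,
                arrival_trigger_s=arrival_trigger,
                departure_trigger_s=departure_trigger,
                origin_well=current_well,
                target_well=target,
            )
        )
        if travel == "outbound":
            last_side = choice
        current_well = target

    position = pd.DataFrame(
        {
            "time_s": np.concatenate(times),
            "x_cm": np.concatenate(xs),
            "y_cm": np.concatenate(ys),
        }
    )
    trials = pd.DataFrame(trial_rows)
    gt_behavior = pd.DataFrame(
        {
            "time_s": position.time_s.to_numpy(),
            "linear_cm": np.concatenate(lin),
            "traj_type": np.concatenate(traj),
            "speed_cm_s": np.concatenate(spd),
        }
    )
    run_intervals = pd.DataFrame(run_rows)
    return position, trials, gt_behavior, run_intervals


# --------------------------------------------------------------------------
# ensemble
# --------------------------------------------------------------------------
def _field_shape(x: np.ndarray, center: float, width: float, skew: float) -> np.ndarray:
    """Peak-normalized, optionally skewed Gaussian bump."""
    d = (x - center) / width
    g = np.exp(-0.5 * d * d)
    if skew != 0.0:
        g = g * (1.0 + erf(2.5 * skew * d / np.sqrt(2.0)))
        m = g.max() if g.size else 1.0
        if m > 0:
            g = g / m
    return g


def draw_unit_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sample true tuning parameters for all units."""
    maze = cfg.maze
    plen = maze.path_length_cm
    rows = []
    uid = 0
    slope = cfg.precession_slope_deg_per_cm
    for region, n, peak, wscale in (
        ("CA1", cfg.n_ca1, cfg.ca1_peak_hz, 1.0),
        ("PFC", cfg.n_pfc, cfg.pfc_peak_hz, cfg.pfc_field_scale),
    ):
        n_sel = int(round(cfg.selectivity_frac * n))
        n_skip = int(round(cfg.skip_frac * n)) if region == "CA1" else 0
        for j in range(n):
            width = cfg.field_width_cm * wscale * rng.uniform(0.8, 1.25)
            selective = j < n_sel
            gain = cfg.selective_gain if selective else 1.0
            rows.append(
                dict(
                    unit_id=uid,
                    region=region,
                    travel_class="outbound" if j % 2 == 0 else "inbound",
                    field_center_cm=rng.uniform(8.0, plen - 8.0),
                    field_width_cm=width,
                    peak_hz=peak * rng.uniform(0.7, 1.4),
                    pref_side="L" if rng.random() < 0.5 else "R",
                    selective=selective,
                    gain_nonpref=gain,
                    si_true=(1 - gain) / (1 + gain),
                    skip=j < n_skip,
                    precession_slope_deg_per_cm=slope,
                    phase0_rad=np.pi,
                )
            )
            uid += 1
    return pd.DataFrame(rows)


def gen_ensemble(
    cfg: SimConfig,
    gt_behavior: pd.DataFrame,
    run_intervals: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
    unit_table: Optional[pd.DataFrame] = None,
) -> Tuple[SpikeSet, pd.DataFrame]:
    """Inhomogeneous-Poisson spikes for the whole ensemble.

    rate = field tuning x side gain x theta modulation (with precession,
    and per-cycle skipping gain for flagged units) + uniform baseline.
    """
    rng = np.random.default_rng([cfg.seed, 2]) if rng is None else rng
    if unit_table is None:
        unit_table = draw_unit_table(cfg, rng)

    t_end = float(gt_behavior.time_s.iloc[-1])
    tg = np.arange(0.0, t_end, SPIKE_DT_S)
    lin = np.interp(tg, gt_behavior.time_s, gt_behavior.linear_cm)
    speed = np.interp(tg, gt_behavior.time_s, gt_behavior.speed_cm_s)

    # per-sample trajectory code from run intervals
    traj_code = np.full(len(tg), -1, dtype=np.int8)
    codes = {"C-to-L": 0, "C-to-R": 1, "L-to-C": 2, "R-to-C": 3}
    for r in run_intervals.itertuples():
        i0, i1 = np.searchsorted(tg, [r.start_s, r.end_s])
        traj_code[i0:i1] = codes[r.traj_type]

    loco = speed > 5.0
    phase = 2 * np.pi * cfg.theta_hz * tg  # global theta clock (unwrapped)
    cos_ph = np.cos
    cycle_odd = (np.floor(cfg.theta_hz * tg).astype(np.int64) % 2) == 1
    side_of_code = np.array(["L", "R", "L", "R"])
    travel_of_code = np.array(["outbound", "outbound", "inbound", "inbound"])

    trains: Dict[int, np.ndarray] = {}
    m = cfg.theta_mod_depth
    for u in unit_table.itertuples():
        mask = loco & (traj_code >= 0)
        mask &= travel_of_code[np.clip(traj_code, 0, 3)] == u.travel_class
        idx = np.flatnonzero(mask)
        rate = np.zeros(len(idx))
        if len(idx):
            x = lin[idx]
            shape = _field_shape(x, u.field_center_cm, u.field_width_cm, cfg.asymmetry)
            gain = np.where(
                side_of_code[traj_code[idx]] == u.pref_side, 1.0, u.gain_nonpref
            )
            # preferred phase advances linearly with distance traveled in field
            trav_sign = 1.0 if u.travel_class == "outbound" else -1.0
            dist = (x - u.field_center_cm) * trav_sign
            psi = u.phase0_rad + np.deg2rad(u.precession_slope_deg_per_cm) * dist
            mod = 1.0 + m * cos_ph(phase[idx] - psi)
            rate = u.peak_hz * shape * gain * mod
            if u.skip:
                rate = rate * np.where(cycle_odd[idx], cfg.skip_gain, 1.0)
        p = rate * SPIKE_DT_S
        fire = rng.random(len(idx)) < p
        spk = tg[idx[fire]]
        # uniform baseline over the whole session
        n_base = rng.poisson(cfg.baseline_hz * t_end)
        base = np.sort(rng.uniform(0.0, t_end, n_base))
        spk = np.unique(np.concatenate([spk, base]))
        trains[int(u.unit_id)] = spk

    units = unit_table[["unit_id", "region"]].copy()
    return SpikeSet(units=units, trains=trains), unit_table


# --------------------------------------------------------------------------
# LFP + SWRs
# --------------------------------------------------------------------------
def _dwell_intervals(trials: pd.DataFrame, t_end: float) -> pd.DataFrame:
    rows = []
    for tr in trials.itertuples():
        start = tr.arrival_trigger_s
        end = min(tr.departure_trigger_s, t_end)
        nxt = tr.trial_id + 1
        rows.append(
            dict(start_s=start, end_s=end, well=tr.target_well, next_trial=nxt)
        )
    return pd.DataFrame(rows)


def gen_lfp(
    cfg: SimConfig,
    gt_behavior: pd.DataFrame,
    trials: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Dict[str, np.ndarray], pd.DataFrame]:
    """Reference LFP channel and the planted-SWR table.

    Theta sinusoid gated by locomotion plus white noise; ripple-band
    bursts (Gaussian-enveloped sinusoid at ``ripple_hz``) at SWR times
    drawn as a Poisson process over well-dwell intervals.
    """
    rng = np.random.default_rng([cfg.seed, 3]) if rng is None else rng
    fs = cfg.fs_lfp
    t_end = float(gt_behavior.time_s.iloc[-1])
    t = np.arange(0.0, t_end, 1.0 / fs)
    speed = np.interp(t, gt_behavior.time_s, gt_behavior.speed_cm_s)
    env = np.clip((speed - 4.0) / 2.0, 0.0, 1.0)  # fades in above immobility
    lfp = cfg.theta_amp * env * np.cos(2 * np.pi * cfg.theta_hz * t)
    lfp = lfp + rng.normal(0.0, cfg.lfp_noise_sd, len(t))

    swr_rows = []
    if cfg.swr_rate_hz > 0:
        dwells = _dwell_intervals(trials, t_end)
        sid = 0
        for d in dwells.itertuples():
            lo, hi = d.start_s + 0.3, d.end_s - 0.3
            if hi <= lo:
                continue
            n_ev = rng.poisson(cfg.swr_rate_hz * (hi - lo))
            starts = np.sort(rng.uniform(lo, hi, n_ev))
            last_end = -np.inf
            for s0 in starts:
                dur = rng.uniform(0.07, 0.12)
                if s0 < last_end + 0.25 or s0 + dur > hi:
                    continue
                mid = s0 + dur / 2
                i0, i1 = np.searchsorted(t, [s0 - 0.02, s0 + dur + 0.02])
                tt = t[i0:i1]
                envlp = np.exp(-0.5 * ((tt - mid) / (dur / 4)) ** 2)
                lfp[i0:i1] += cfg.ripple_amp * envlp * np.sin(
                    2 * np.pi * cfg.ripple_hz * (tt - s0)
                )
                swr_rows.append(
                    dict(
                        swr_id=sid,
                        start_s=s0,
                        end_s=s0 + dur,
                        well=d.well,
                        next_trial=d.next_trial,
                    )
                )
                sid += 1
                last_end = s0 + dur
    swrs = pd.DataFrame(
        swr_rows, columns=["swr_id", "start_s", "end_s", "well", "next_trial"]
    )
    return {"ca1_ref": lfp}, swrs


# --------------------------------------------------------------------------
# replay content
# --------------------------------------------------------------------------
def gen_replay_content(
    cfg: SimConfig,
    swrs: pd.DataFrame,
    trials: pd.DataFrame,
    unit_table: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Dict[int, np.ndarray], pd.DataFrame]:
    """Plant ordered spikes inside center-well SWRs.

    Within each SWR, >=5 CA1 units (and PFC units) fire in field-center
    order along the planted trajectory, time-compressed into the event.
    With probability ``replay_fidelity`` the planted side equals the
    upcoming outbound choice.  Returns (extra spikes per unit, swr table
    augmented with content columns).
    """
    rng = np.random.default_rng([cfg.seed, 4]) if rng is None else rng
    extra: Dict[int, np.ndarray] = {int(u): [] for u in unit_table.unit_id}
    rows = []
    trials_idx = trials.set_index("trial_id")
    out_units = unit_table[unit_table.travel_class == "outbound"]

    for ev in swrs.itertuples():
        rec = dict(
            swr_id=ev.swr_id, start_s=ev.start_s, end_s=ev.end_s, well=ev.well,
            next_trial=ev.next_trial, content_side="", direction="",
            upcoming_side="", matches_upcoming=False, has_content=False,
        )
        dur = ev.end_s - ev.start_s
        if ev.well != "C" or dur < 0.05 or ev.next_trial not in trials_idx.index:
            rows.append(rec)
            continue
        nxt = trials_idx.loc[ev.next_trial]
        if nxt.travel != "outbound":
            rows.append(rec)
            continue
        upcoming = str(nxt.choice)
        if rng.random() < cfg.replay_fidelity:
            side = upcoming
        else:
            side = "R" if upcoming == "L" else "L"
        direction = "reverse" if rng.random() < cfg.replay_reverse_frac else "forward"

        cand = out_units[
            (out_units.pref_side == side) | (~out_units.selective.astype(bool))
        ]
        ca1 = cand[cand.region == "CA1"].sort_values("field_center_cm")
        pfc = cand[cand.region == "PFC"].sort_values("field_center_cm")
        if len(ca1) < 5:
            rows.append(rec)
            continue
        t0, t1 = ev.start_s + 0.005, ev.end_s - 0.005
        plen = cfg.maze.path_length_cm
        for group in (ca1, pfc):
            for u in group.itertuples():
                frac = np.clip(u.field_center_cm / plen, 0.0, 1.0)
                if direction == "reverse":
                    frac = 1.0 - frac
                t_spk = t0 + frac * (t1 - t0)
                n_spk = 1 + int(rng.random() < 0.5)
                ts = t_spk + rng.normal(0.0, 0.003, n_spk)
                extra[int(u.unit_id)].append(np.clip(ts, ev.start_s, ev.end_s))
        rec.update(
            content_side=side,
            direction=direction,
            upcoming_side=upcoming,
            matches_upcoming=side == upcoming,
            has_content=True,
        )
        rows.append(rec)

    extra_arr = {
        uid: (np.sort(np.concatenate(v)) if v else np.empty(0))
        for uid, v in extra.items()
    }
    return extra_arr, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# top level
# --------------------------------------------------------------------------
def simulate_session(cfg: SimConfig) -> Session:
    """Run all generators and assemble a :class:`Session` with ground truth."""
    position, trials, gt_behavior, run_intervals = gen_behavior(cfg)
    spikes, unit_table = gen_ensemble(cfg, gt_behavior, run_intervals)
    lfp, swrs = gen_lfp(cfg, gt_behavior, trials)
    extra, swrs = gen_replay_content(cfg, swrs, trials, unit_table)
    for uid, ts in extra.items():
        if len(ts):
            spikes.trains[uid] = np.unique(
                np.concatenate([spikes.trains[uid], ts])
            )
    gt = GroundTruth(
        units=unit_table,
        trials=trials.copy(),
        swrs=swrs,
        behavior=gt_behavior,
        run_intervals=run_intervals,
    )
    return Session(
        spikes=spikes,
        position=position,
        trials=trials,
        lfp=lfp,
        fs_lfp=cfg.fs_lfp,
        config=cfg,
        ground_truth=gt,
    )
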