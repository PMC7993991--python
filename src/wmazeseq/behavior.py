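"""Position processing: speed, linearization, well events, masks.

Turns the raw (time, x, y) trace into a linearized, trajectory-labeled,
trial-segmented table with locomotion/immobility masks and before/after
choice-point intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .config import MazeGeometry, traj_side

LOCO_SPEED_CM_S = 5.0     # locomotion gate: speed strictly above this
IMMOBILE_SPEED_CM_S = 4.0  # immobility gate: speed at or below this
MAX_PATH_DIST_CM = 20.0   # samples farther than this from every path -> 'none'
AFTER_CP_OFFSET_CM = 10.0
SPEED_SMOOTH_S = 0.25


def compute_speed(position: pd.DataFrame, smooth_s: float = SPEED_SMOOTH_S) -> np.ndarray:
    """Speed (cm/s) from a Gaussian-smoothed position trace.

    Position is smoothed with a ``smooth_s``-SD Gaussian before a centered
    finite difference, suppressing frame-rate tracking jitter.
    """
    t = position.time_s.to_numpy(float)
    if len(t) < 3:
        return np.zeros(len(t))
    dt = np.median(np.diff(t))
    sigma = max(smooth_s / dt, 1e-9)
    x = gaussian_filter1d(position.x_cm.to_numpy(float), sigma)
    y = gaussian_filter1d(position.y_cm.to_numpy(float), sigma)
    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    return np.hypot(vx, vy)


def project_to_path(xy: np.ndarray, polyline: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Project points onto a polyline.

    Returns (arclength along polyline, distance to polyline), both in cm.
    """
    seg = np.diff(polyline, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    best_d = np.full(len(xy), np.inf)
    best_s = np.zeros(len(xy))
    for i in range(len(seg)):
        p0 = polyline[i]
        d = seg[i]
        L2 = seg_len[i] ** 2
        tproj = np.clip(((xy - p0) @ d) / L2, 0.0, 1.0)
        proj = p0 + tproj[:, None] * d
        dist = np.hypot(*(xy - proj).T)
        closer = dist < best_d
        best_d[closer] = dist[closer]
        best_s[closer] = cum[i] + tproj[closer] * seg_len[i]
    return best_s, best_d


def linearize(
    position: pd.DataFrame,
    maze: MazeGeometry,
    trials: pd.DataFrame,
    run_intervals: Optional[pd.DataFrame] = None,
    speed: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Assign each sample a linear position and trajectory type.

    Samples during a trial's run interval are projected onto the idealized
    path of that trial's trajectory type; linear position is arclength
    from the center well.  Samples outside runs, or farther than 20 cm
    from every path, get trajectory_type 'none' and trial_id -1.
    """
    t = position.time_s.to_numpy(float)
    xy = position[["x_cm", "y_cm"]].to_numpy(float)
    if speed is None:
        speed = compute_speed(position)

    traj_type = np.full(len(t), "none", dtype=object)
    trial_id = np.full(len(t), -1, dtype=int)
    linear = np.full(len(t), np.nan)

    if run_intervals is None:
        run_intervals = trials.rename(
            columns={"start_s": "start_s", "arrival_trigger_s": "end_s"}
        )[["start_s", "end_s", "traj_type", "trial_id"]]

    # cache projections onto the two side paths
    proj = {s: project_to_path(xy, maze.path_polyline(s)) for s in ("L", "R")}

    for r in run_intervals.itertuples():
        sel = (t >= r.start_s) & (t <= r.end_s)
        if not sel.any():
            continue
        side = traj_side(r.traj_type)
        s_arc, dist = proj[side]
        ok = sel & (dist <= MAX_PATH_DIST_CM)
        linear[ok] = s_arc[ok]
        traj_type[ok] = r.traj_type
        trial_id[ok] = r.trial_id

    return pd.DataFrame(
        {
            "time_s": t,
            "linear_cm": linear,
            "traj_type": traj_type,
            "speed_cm_s": speed,
            "trial_id": trial_id,
        }
    )


def detect_well_events(
    time: np.ndarray,
    speed: np.ndarray,
    arrival_trigger_s: float,
    departure_trigger_s: float,
    search_window_s: float = 5.0,
) -> Tuple[Optional[float], Optional[float]]:
    """Refine well entry/exit around the beam triggers.

    Entry: first time speed drops to <= 4 cm/s in the immobility bout
    preceding (or containing) the arrival trigger.  Exit: first time
    speed rises above 4 cm/s after the departure trigger.  Returns
    (entry, exit); either may be None if no qualifying sample exists
    within ``search_window_s`` of its trigger (event dropped upstream).
    """
    slow = speed <= IMMOBILE_SPEED_CM_S
    i_arr = int(np.searchsorted(time, arrival_trigger_s))
    entry = None
    lo = int(np.searchsorted(time, arrival_trigger_s - search_window_s))
    hi = min(int(np.searchsorted(time, arrival_trigger_s + search_window_s)), len(time))
    # walk back from the trigger to the start of the slow bout
    i = min(i_arr, len(time) - 1)
    if i >= 0 and slow[i]:
        j = i
        while j > lo and slow[j - 1]:
            j -= 1
        entry = float(time[j])
    else:
        # speed still above 4 at trigger time: first slow sample after it
        after = np.flatnonzero(slow[i_arr:hi])
        if len(after):
            entry = float(time[i_arr + after[0]])

    exit_ = None
    i_dep = int(np.searchsorted(time, departure_trigger_s))
    hi2 = min(int(np.searchsorted(time, departure_trigger_s + search_window_s)), len(time))
    fast = np.flatnonzero(speed[i_dep:hi2] > IMMOBILE_SPEED_CM_S)
    if len(fast):
        exit_ = float(time[i_dep + fast[0]])
    return entry, exit_


def add_well_events(
    trials: pd.DataFrame, position: pd.DataFrame, speed: Optional[np.ndarray] = None
) -> pd.DataFrame:
    """Augment the trial table with refined well_entry_s / well_exit_s."""
    if speed is None:
        speed = compute_speed(position)
    t = position.time_s.to_numpy(float)
    t_end = float(t[-1])
    entries, exits = [], []
    for tr in trials.itertuples():
        entry, exit_ = detect_well_events(
            t, speed, tr.arrival_trigger_s, tr.departure_trigger_s
        )
        entries.append(entry if entry is not None else np.nan)
        exits.append(exit_ if exit_ is not None else t_end)
    out = trials.copy()
    out["well_entry_s"] = entries
    out["well_exit_s"] = exits
    return out


def locomotor_mask(speed: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """(locomotion, immobility) boolean masks.

    Locomotion is speed > 5 cm/s, immobility speed <= 4 cm/s; the
    4-5 cm/s hysteresis band belongs to neither.
    """
    speed = np.asarray(speed, float)
    return speed > LOCO_SPEED_CM_S, speed <= IMMOBILE_SPEED_CM_S


def mask_to_intervals(time: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Contiguous True runs of a sample mask as an (n, 2) interval array."""
    m = np.asarray(mask, bool)
    if not m.any():
        return np.empty((0, 2))
    edges = np.diff(m.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if m[0]:
        starts = np.concatenate([[0], starts])
    if m[-1]:
        ends = np.concatenate([ends, [len(m)]])
    return np.column_stack([time[starts], time[ends - 1]])


def in_intervals(times: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Boolean mask of which times fall inside any [start, end] interval."""
    times = np.asarray(times, float)
    out = np.zeros(len(times), dtype=bool)
    for s, e in np.asarray(intervals).reshape(-1, 2):
        out |= (times >= s) & (times <= e)
    return out


@dataclass
class CpSegments:
    """Before/after choice-point segment label per linearized sample."""

    segment: np.ndarray  # 'before_cp' | 'after_cp' | 'neither'


def cp_segment(linearized: pd.DataFrame, maze: MazeGeometry) -> np.ndarray:
    """Label each trial sample before-CP (center stem) or after-CP.

    Before-CP: linear position on the stem (< CP arclength).  After-CP:
    at least 10 cm beyond the stem.  The gap in between, well vicinity
    and non-trial samples are 'neither'.
    """
    lin = linearized.linear_cm.to_numpy(float)
    on_trial = (linearized.traj_type != "none").to_numpy()
    seg = np.full(len(lin), "neither", dtype=object)
    cp = maze.cp_arclength_cm
    with np.errstate(invalid="ignore"):
        seg[on_trial & (lin < cp)] = "before_cp"
        seg[on_trial & (lin >= cp + AFTER_CP_OFFSET_CM)] = "after_cp"
    return seg
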