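"""Linearized firing-rate maps, place-cell criterion, trajectory
selectivity, spatial-field detection and field asymmetry."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .behavior import LOCO_SPEED_CM_S, in_intervals

BIN_CM = 2.0
SMOOTH_SD_CM = 4.0
MIN_OCCUPANCY_S = 0.020
PLACE_CELL_PEAK_HZ = 3.0
MIN_SESSION_SPIKES = 100
SI_THRESHOLD = {"CA1": 0.4, "PFC": 0.2}
FIELD_MIN_SEP_CM = 20.0
FIELD_MIN_LEN_CM = 8.0
FIELD_RATE_FRAC = 0.10


@dataclass
class RateMap:
    unit_id: int
    traj_type: str
    bin_edges: np.ndarray   # cm, half-open [left, right) bins
    rate_hz: np.ndarray     # NaN where occupancy below the gate
    occupancy_s: np.ndarray
    n_spikes: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def peak_rate_hz(self) -> float:
        r = self.rate_hz[np.isfinite(self.rate_hz)]
        return float(r.max()) if r.size else np.nan


@dataclass
class SelectivityResult:
    unit_id: int
    travel: str
    fr_l: float
    fr_r: float
    si: float
    selective: bool
    preferred: str


@dataclass
class FieldAsymmetry:
    field_lo_cm: float
    field_hi_cm: float
    center_cm: float
    a_l: float
    a_r: float
    ai: float


def compute_rate_map(
    spike_times: np.ndarray,
    linearized: pd.DataFrame,
    traj_type: str,
    path_length_cm: float,
    swr_intervals: Optional[np.ndarray] = None,
    bin_cm: float = BIN_CM,
) -> Optional[RateMap]:
    """Occupancy-normalized linearized rate map on one trajectory type.

    Only locomotor samples (> 5 cm/s) with SWR times excluded enter the
    occupancy; spike counts and occupancy are smoothed separately with a
    4-cm-SD Gaussian before division.  Bins whose *raw* occupancy is at
    or below 20 ms carry no rate estimate (NaN).
    """
    t = linearized.time_s.to_numpy(float)
    dt = float(np.median(np.diff(t)))
    sel = (
        (linearized.traj_type == traj_type).to_numpy()
        & (linearized.speed_cm_s > LOCO_SPEED_CM_S).to_numpy()
        & np.isfinite(linearized.linear_cm.to_numpy(float))
    )
    if swr_intervals is not None and len(swr_intervals):
        sel &= ~in_intervals(t, swr_intervals)
    if not sel.any():
        return None

    edges = np.arange(0.0, path_length_cm + bin_cm, bin_cm)
    occ, _ = np.histogram(linearized.linear_cm.to_numpy(float)[sel], bins=edges)
    occ = occ * dt

    spike_times = np.asarray(spike_times, float)
    # spike -> nearest position sample; keep spikes landing on retained samples
    idx = np.clip(np.searchsorted(t, spike_times), 0, len(t) - 1)
    left = np.clip(idx - 1, 0, len(t) - 1)
    use_left = np.abs(t[left] - spike_times) < np.abs(t[idx] - spike_times)
    idx = np.where(use_left, left, idx)
    keep = sel[idx]
    spk_pos = linearized.linear_cm.to_numpy(float)[idx[keep]]
    counts, _ = np.histogram(spk_pos, bins=edges)

    sigma = SMOOTH_SD_CM / bin_cm
    sm_counts = gaussian_filter1d(counts.astype(float), sigma, mode="constant")
    sm_occ = gaussian_filter1d(occ, sigma, mode="constant")
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = sm_counts / sm_occ
    rate[occ <= MIN_OCCUPANCY_S] = np.nan
    return RateMap(
        unit_id=-1,
        traj_type=traj_type,
        bin_edges=edges,
        rate_hz=rate,
        occupancy_s=occ,
        n_spikes=int(counts.sum()),
    )


def mean_rate(rm: Optional[RateMap]) -> float:
    """Occupancy-weighted mean rate of a map (NaN if undefined)."""
    if rm is None:
        return np.nan
    ok = np.isfinite(rm.rate_hz) & (rm.occupancy_s > 0)
    if not ok.any():
        return np.nan
    w = rm.occupancy_s[ok]
    return float(np.sum(rm.rate_hz[ok] * w) / np.sum(w))


def selectivity_index(
    rm_l: Optional[RateMap],
    rm_r: Optional[RateMap],
    unit_id: int,
    region: str,
    travel: str,
) -> Optional[SelectivityResult]:
    """SI = (FR_L - FR_R) / (FR_L + FR_R); thresholds 0.4 (CA1), 0.2 (PFC)."""
    peaks = [rm.peak_rate_hz for rm in (rm_l, rm_r) if rm is not None]
    if not peaks or np.nanmax(peaks) < PLACE_CELL_PEAK_HZ:
        return None
    fr_l, fr_r = mean_rate(rm_l), mean_rate(rm_r)
    fr_l = 0.0 if not np.isfinite(fr_l) else fr_l
    fr_r = 0.0 if not np.isfinite(fr_r) else fr_r
    if fr_l + fr_r == 0:
        return None
    si = (fr_l - fr_r) / (fr_l + fr_r)
    return SelectivityResult(
        unit_id=unit_id,
        travel=travel,
        fr_l=fr_l,
        fr_r=fr_r,
        si=si,
        selective=abs(si) > SI_THRESHOLD[region],
        preferred="L" if fr_l >= fr_r else "R",
    )


def detect_fields(rm: RateMap) -> List[Tuple[float, float, float]]:
    """Spatial fields of one map: list of (lo_cm, hi_cm, peak_cm).

    Peaks require >= 3 Hz and 20-cm minimum separation; a field is the
    maximal contiguous run around its peak with rate > 10% of that peak,
    at least 8 cm long.
    """
    rate = np.nan_to_num(rm.rate_hz, nan=0.0)
    centers = rm.bin_centers
    bin_cm = rm.bin_edges[1] - rm.bin_edges[0]
    min_sep_bins = max(int(round(FIELD_MIN_SEP_CM / bin_cm)), 1)
    peaks, _ = find_peaks(rate, height=PLACE_CELL_PEAK_HZ, distance=min_sep_bins)
    # an interior-maximum plateau or an edge peak can be missed by find_peaks
    if rate.max() >= PLACE_CELL_PEAK_HZ and len(peaks) == 0:
        peaks = np.array([int(np.argmax(rate))])
    fields = []
    for p in peaks:
        thr = FIELD_RATE_FRAC * rate[p]
        lo = p
        while lo > 0 and rate[lo - 1] > thr:
            lo -= 1
        hi = p
        while hi < len(rate) - 1 and rate[hi + 1] > thr:
            hi += 1
        lo_cm = rm.bin_edges[lo]
        hi_cm = rm.bin_edges[hi + 1]
        if hi_cm - lo_cm >= FIELD_MIN_LEN_CM:
            fields.append((float(lo_cm), float(hi_cm), float(centers[p])))
    return fields


def asymmetry_index(
    rm: RateMap,
    field: Tuple[float, float, float],
    center: Optional[float] = None,
    n_bins: int = 10,
) -> Optional[FieldAsymmetry]:
    """AI = (A_R - A_L)/(A_R + A_L) over a 10-bin resampled field profile.

    The profile is resampled into ``n_bins`` bins of 10% field length
    relative to the field center (extent midpoint by default); A_L / A_R
    are trapezoidal areas left/right of the center.
    """
    lo, hi, _peak = field
    if hi - lo < 20.0:
        return None
    if center is None:
        center = 0.5 * (lo + hi)
    xq = np.linspace(lo, hi, n_bins + 1)
    rate = np.nan_to_num(rm.rate_hz, nan=0.0)
    prof = np.interp(xq, rm.bin_centers, rate)
    # relative coordinate in units of field length
    rel = (xq - center) / (hi - lo)
    left = rel <= 0
    right = rel >= 0
    a_l = float(np.trapezoid(prof[left], rel[left])) if left.sum() > 1 else 0.0
    a_r = float(np.trapezoid(prof[right], rel[right])) if right.sum() > 1 else 0.0
    if a_l + a_r == 0:
        return None
    return FieldAsymmetry(
        field_lo_cm=lo,
        field_hi_cm=hi,
        center_cm=float(center),
        a_l=a_l,
        a_r=a_r,
        ai=(a_r - a_l) / (a_r + a_l),
    )


def compute_all_rate_maps(
    spikes,
    linearized: pd.DataFrame,
    path_length_cm: float,
    swr_intervals: Optional[np.ndarray] = None,
    traj_types: Tuple[str, ...] = ("C-to-L", "C-to-R", "L-to-C", "R-to-C"),
    min_session_spikes: int = MIN_SESSION_SPIKES,
) -> Dict[Tuple[int, str], RateMap]:
    """Rate maps for every (unit, trajectory type) with enough spikes.

    Units with fewer than 100 spikes in the session are skipped.
    """
    maps: Dict[Tuple[int, str], RateMap] = {}
    for uid in spikes.unit_ids():
        st = spikes.trains[uid]
        if len(st) < min_session_spikes:
            continue
        for tt in traj_types:
            rm = compute_rate_map(st, linearized, tt, path_length_cm, swr_intervals)
            if rm is not None:
                rm.unit_id = uid
                maps[(uid, tt)] = rm
    return maps


def maps_to_frame(maps: Dict[Tuple[int, str], RateMap]) -> pd.DataFrame:
    rows = []
    for (uid, tt), rm in maps.items():
        for left, r, o in zip(rm.bin_edges[:-1], rm.rate_hz, rm.occupancy_s):
            rows.append(
                dict(unit_id=uid, traj_type=tt, bin_left_cm=left, rate_hz=r,
                     occupancy_s=o)
            )
    return pd.DataFrame(rows)
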