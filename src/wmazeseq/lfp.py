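"""LFP analyses: theta phase, population-defined theta cycles, SWR
detection, spike phase locking, and band power/coherence summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, coherence as _coherence, filtfilt, hilbert, welch

from .behavior import in_intervals

THETA_BAND = (6.0, 12.0)
RIPPLE_BAND = (150.0, 250.0)
RIPPLE_ENV_SMOOTH_S = 0.004
SWR_THRESHOLD_SD = 3.0
SWR_MIN_DURATION_S = 0.050
SWR_MIN_ABOVE_S = 0.015   # supra-threshold persistence; rejects noise blips
CYCLE_MIN_S, CYCLE_MAX_S = 0.05, 0.3
MIN_PHASE_LOCK_SPIKES = 30


def bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 3) -> np.ndarray:
    b, a = butter(order, [lo, hi], btype="bandpass", fs=fs)
    return filtfilt(b, a, x)


@dataclass
class ThetaPhaseSeries:
    time: np.ndarray
    phase: np.ndarray       # radians in (-pi, pi]
    amplitude: np.ndarray   # analytic-signal magnitude

    def at(self, times: np.ndarray) -> np.ndarray:
        """Phase at arbitrary times via unwrapped linear interpolation."""
        unwrapped = np.unwrap(self.phase)
        ph = np.interp(times, self.time, unwrapped)
        return np.angle(np.exp(1j * ph))


def theta_phase(lfp: np.ndarray, fs: float) -> ThetaPhaseSeries:
    """Theta phase via 6-12 Hz zero-phase band-pass + analytic signal."""
    lfp = np.asarray(lfp, float)
    if np.ptp(lfp) == 0:
        raise ValueError("constant LFP: theta phase undefined")
    filt = bandpass(lfp, fs, *THETA_BAND)
    analytic = hilbert(filt)
    t = np.arange(len(lfp)) / fs
    return ThetaPhaseSeries(
        time=t, phase=np.angle(analytic), amplitude=np.abs(analytic)
    )


def rayleigh_test(phases: np.ndarray) -> Tuple[float, float, float]:
    """(mean angle, resultant length, Rayleigh p) for circular data."""
    phases = np.asarray(phases, float)
    n = len(phases)
    if n == 0:
        return np.nan, np.nan, np.nan
    C = np.cos(phases).sum()
    S = np.sin(phases).sum()
    R = np.hypot(C, S) / n
    z = n * R * R
    # Zar's approximation to the Rayleigh p-value
    p = np.exp(-z) * (1 + (2 * z - z * z) / (4 * n)
                      - (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4) / (288 * n * n))
    return float(np.arctan2(S, C)), float(R), float(np.clip(p, 0.0, 1.0))


def phase_locking(
    spike_times: np.ndarray,
    phase_series: ThetaPhaseSeries,
    mask_intervals: Optional[np.ndarray] = None,
) -> Optional[Tuple[float, float, float]]:
    """Circular mean, resultant and Rayleigh p of spike theta phases.

    Returns None when fewer than 30 spikes fall inside the mask.
    """
    st = np.asarray(spike_times, float)
    if mask_intervals is not None:
        st = st[in_intervals(st, mask_intervals)]
    if len(st) < MIN_PHASE_LOCK_SPIKES:
        return None
    return rayleigh_test(phase_series.at(st))


@dataclass
class ThetaCycle:
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def population_boundary_phase(
    spike_trains: Dict[int, np.ndarray],
    phase_series: ThetaPhaseSeries,
    loco_intervals: np.ndarray,
    n_bins: int = 36,
) -> Tuple[float, int]:
    """Session boundary phase: minimum of the mean spike-phase histogram
    over Rayleigh-significant (p < 0.05) units during locomotion.

    Returns (boundary phase, number of phase-locked units).
    """
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    hists = []
    for st in spike_trains.values():
        st = np.asarray(st, float)
        st = st[in_intervals(st, loco_intervals)]
        if len(st) < MIN_PHASE_LOCK_SPIKES:
            continue
        ph = phase_series.at(st)
        _, _, p = rayleigh_test(ph)
        if p < 0.05:
            h, _ = np.histogram(ph, bins=edges)
            hists.append(h / max(h.sum(), 1))
    if not hists:
        return np.pi, 0  # trough-to-trough fallback
    mean_hist = np.mean(hists, axis=0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(centers[int(np.argmin(mean_hist))]), len(hists)


def segment_theta_cycles(
    phase_series: ThetaPhaseSeries,
    spike_trains: Dict[int, np.ndarray],
    loco_intervals: np.ndarray,
) -> Tuple[List[ThetaCycle], float]:
    """Cut theta cycles at successive crossings of the boundary phase.

    Only cycles 50-300 ms long and entirely within locomotion are kept.
    """
    boundary, n_locked = population_boundary_phase(
        spike_trains, phase_series, loco_intervals
    )
    if n_locked == 0:
        warnings.warn("no phase-locked units; using trough-to-trough boundaries")
    # shift phases so boundary maps to -pi: crossings are wraps of shifted phase
    shifted = np.angle(np.exp(1j * (phase_series.phase - boundary - np.pi)))
    wraps = np.flatnonzero(np.diff(shifted) < -np.pi)
    t_cross = phase_series.time[wraps + 1]
    cycles = []
    for s, e in zip(t_cross[:-1], t_cross[1:]):
        if not CYCLE_MIN_S <= e - s <= CYCLE_MAX_S:
            continue
        if not in_intervals(np.array([s, e]), loco_intervals).all():
            continue
        cycles.append(ThetaCycle(float(s), float(e)))
    return cycles, boundary


@dataclass
class SWREvent:
    swr_id: int
    start_s: float
    end_s: float
    peak_z: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def detect_swrs(
    lfp_channels: Dict[str, np.ndarray],
    fs: float,
    immobility_intervals: np.ndarray,
    threshold_sd: float = SWR_THRESHOLD_SD,
    min_above_s: float = SWR_MIN_ABOVE_S,
) -> List[SWREvent]:
    """Ripple-band envelope SWR detection during immobility.

    Per channel: 150-250 Hz band-pass, Hilbert envelope smoothed with a
    4 ms Gaussian; mean/SD estimated over immobility.  Initial events =
    contiguous supra-threshold periods lasting >= ``min_above_s`` on >= 1
    channel during immobility, extended to where the (max-over-channels)
    z-scored envelope crosses 0.
    """
    n = len(next(iter(lfp_channels.values())))
    t = np.arange(n) / fs
    immob = in_intervals(t, immobility_intervals)
    if immob.sum() / fs < 10.0:
        raise ValueError("need >= 10 s of immobility to estimate envelope stats")

    zs = []
    for x in lfp_channels.values():
        env = np.abs(hilbert(bandpass(np.asarray(x, float), fs, *RIPPLE_BAND)))
        env = gaussian_filter1d(env, RIPPLE_ENV_SMOOTH_S * fs)
        mu = env[immob].mean()
        sd = env[immob].std()
        zs.append((env - mu) / sd)
    z = np.max(zs, axis=0)

    above = (z > threshold_sd) & immob
    events: List[SWREvent] = []
    eid = 0
    idx = np.flatnonzero(above)
    if len(idx) == 0:
        return events
    # group contiguous supra-threshold samples
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    min_samples = int(round(min_above_s * fs))
    last_end = -1
    for s0, e0 in zip(starts, ends):
        if e0 - s0 + 1 < min_samples:
            continue
        # extend to mean crossings (z = 0)
        s = s0
        while s > 0 and z[s - 1] > 0 and immob[s - 1]:
            s -= 1
        e = e0
        while e < n - 1 and z[e + 1] > 0 and immob[e + 1]:
            e += 1
        if s <= last_end:  # merged with the previous event
            continue
        last_end = e
        events.append(
            SWREvent(
                swr_id=eid,
                start_s=float(t[s]),
                end_s=float(t[e]),
                peak_z=float(z[s : e + 1].max()),
            )
        )
        eid += 1
    return events


def swr_intervals(events: List[SWREvent]) -> np.ndarray:
    if not events:
        return np.empty((0, 2))
    return np.array([[ev.start_s, ev.end_s] for ev in events])


def band_power_coherence(
    lfp_a: np.ndarray,
    lfp_b: np.ndarray,
    fs: float,
    mask_intervals: Optional[np.ndarray] = None,
    band: Tuple[float, float] = THETA_BAND,
    nperseg: int = 1024,
) -> Tuple[float, float, float]:
    """(z-scored band power of a, of b, mean band coherence).

    Welch spectra over >= 2 s mask segments; power z-scored per frequency
    across segments, then averaged over the band.
    """
    n = len(lfp_a)
    t = np.arange(n) / fs
    if mask_intervals is None:
        mask_intervals = np.array([[0.0, t[-1]]])
    segs = []
    for s, e in np.asarray(mask_intervals).reshape(-1, 2):
        i0, i1 = np.searchsorted(t, [s, e])
        if (i1 - i0) / fs >= 2.0:
            segs.append((i0, i1))
    if not segs:
        raise ValueError("no mask segment of at least 2 s")

    pows_a, pows_b, cohs = [], [], []
    for i0, i1 in segs:
        f, pa = welch(lfp_a[i0:i1], fs=fs, nperseg=min(nperseg, i1 - i0))
        _, pb = welch(lfp_b[i0:i1], fs=fs, nperseg=min(nperseg, i1 - i0))
        _, c = _coherence(lfp_a[i0:i1], lfp_b[i0:i1], fs=fs,
                          nperseg=min(nperseg, i1 - i0))
        band_sel = (f >= band[0]) & (f <= band[1])
        pows_a.append(pa)
        pows_b.append(pb)
        cohs.append(float(c[band_sel].mean()))

    def _z_band(pows):
        P = np.array([p for p in pows if len(p) == len(pows[0])])
        mu = P.mean(axis=0)
        sd = P.std(axis=0)
        sd[sd == 0] = 1.0
        z = (P - mu) / sd
        return float(z.mean(axis=0)[band_sel].mean())

    f, _ = welch(lfp_a[segs[0][0]:segs[0][1]], fs=fs,
                 nperseg=min(nperseg, segs[0][1] - segs[0][0]))
    band_sel = (f >= band[0]) & (f <= band[1])
    return _z_band(pows_a), _z_band(pows_b), float(np.mean(cohs))


def cycles_to_frame(cycles: List[ThetaCycle]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(start_s=c.start_s, end_s=c.end_s, duration_s=c.duration_s)
         for c in cycles]
    )


def swrs_to_frame(events: List[SWREvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(swr_id=ev.swr_id, start_s=ev.start_s, end_s=ev.end_s,
              duration_s=ev.duration_s, peak_z=ev.peak_z) for ev in events]
    )
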