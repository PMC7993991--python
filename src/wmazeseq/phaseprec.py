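"""Circular-linear regression of spike theta phase on within-field position.

The slope is found by maximizing the mean resultant length of the
residuals (phase - 2*pi*a*x) over a bounded slope range; the
circular-linear correlation and its asymptotic p-value follow the
standard circular-statistics formulation (Kempter-style).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import erfc

from .behavior import LOCO_SPEED_CM_S
from .lfp import ThetaPhaseSeries

SLOPE_BOUND_CYC_PER_CM = 0.05   # search range +-0.05 cycles/cm (+-18 deg/cm)
MIN_FIELD_SPIKES = 10


@dataclass
class PrecessionResult:
    unit_id: int
    traj_type: str
    field_lo_cm: float
    field_hi_cm: float
    slope_rad_per_cm: float
    slope_deg_per_cm: float
    r: float
    p: float
    n_spikes: int

    @property
    def significant(self) -> bool:
        return bool(self.p < 0.05)


def _resultant(a: float, x: np.ndarray, ph: np.ndarray) -> float:
    z = np.exp(1j * (ph - 2 * np.pi * a * x))
    return float(np.abs(z.mean()))


def circular_linear_fit(
    positions_cm: np.ndarray,
    phases_rad: np.ndarray,
    slope_bound: float = SLOPE_BOUND_CYC_PER_CM,
) -> Tuple[float, float, float]:
    """(slope rad/cm, circular-linear r, p-value).

    Slope maximizes the mean resultant length of (phase - 2*pi*a*x) on a
    dense grid with local refinement; r and p come from the correlation
    between the measured phases and the fitted circular variable.
    """
    x = np.asarray(positions_cm, float)
    ph = np.asarray(phases_rad, float)
    n = len(x)
    if n < 2 or np.ptp(x) == 0:
        raise ValueError("need >= 2 spikes at distinct positions")

    grid = np.linspace(-slope_bound, slope_bound, 401)
    res = np.array([_resultant(a, x, ph) for a in grid])
    a0 = grid[int(np.argmax(res))]
    da = grid[1] - grid[0]
    opt = minimize_scalar(
        lambda a: -_resultant(a, x, ph),
        bounds=(max(a0 - 2 * da, -slope_bound), min(a0 + 2 * da, slope_bound)),
        method="bounded",
    )
    a_hat = float(opt.x)

    theta = np.mod(2 * np.pi * a_hat * x, 2 * np.pi)
    phi_bar = np.arctan2(np.sin(ph).sum(), np.cos(ph).sum())
    theta_bar = np.arctan2(np.sin(theta).sum(), np.cos(theta).sum())
    sp = np.sin(ph - phi_bar)
    st = np.sin(theta - theta_bar)
    denom = np.sqrt((sp**2).sum() * (st**2).sum())
    r = float((sp * st).sum() / denom) if denom > 0 else 0.0

    lam20 = (sp**2).mean()
    lam02 = (st**2).mean()
    lam22 = (sp**2 * st**2).mean()
    if lam22 > 0:
        z = r * np.sqrt(n * lam20 * lam02 / lam22)
        p = float(erfc(abs(z) / np.sqrt(2)))
    else:
        p = 1.0
    return 2 * np.pi * a_hat, r, p


def field_precession(
    unit_id: int,
    spike_times: np.ndarray,
    phase_series: ThetaPhaseSeries,
    field: Tuple[float, float, float],
    traj_type: str,
    linearized: pd.DataFrame,
) -> Optional[PrecessionResult]:
    """Fit precession for one unit's spatial field on one trajectory.

    Spikes are restricted to locomotor traversals of the field; fields
    with fewer than 10 such spikes are skipped (None).
    """
    lo, hi, _ = field
    t = linearized.time_s.to_numpy(float)
    lin = linearized.linear_cm.to_numpy(float)
    speed = linearized.speed_cm_s.to_numpy(float)
    tts = linearized.traj_type.to_numpy()

    st = np.asarray(spike_times, float)
    idx = np.clip(np.searchsorted(t, st), 0, len(t) - 1)
    with np.errstate(invalid="ignore"):
        ok = (
            (tts[idx] == traj_type)
            & (speed[idx] > LOCO_SPEED_CM_S)
            & (lin[idx] >= lo)
            & (lin[idx] <= hi)
        )
    if ok.sum() < MIN_FIELD_SPIKES:
        return None
    pos = lin[idx[ok]]
    ph = phase_series.at(st[ok])
    slope_rad, r, p = circular_linear_fit(pos, ph)
    return PrecessionResult(
        unit_id=unit_id,
        traj_type=traj_type,
        field_lo_cm=lo,
        field_hi_cm=hi,
        slope_rad_per_cm=slope_rad,
        slope_deg_per_cm=np.rad2deg(slope_rad),
        r=r,
        p=p,
        n_spikes=int(ok.sum()),
    )
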