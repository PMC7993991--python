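"""Constructed inputs with known ground truth for tests and validation.

Lighter-weight than a full :mod:`wmazeseq.synthio` session: a toy
encoding model with Gaussian tuning curves, planted theta-timescale and
replay events generated straight from those templates, and simple
modulated Poisson trains.  Everything is seeded explicitly.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np

from .decode import EncodingModel, RATE_FLOOR_HZ
from .thetaseq import CandidateEvent


def toy_encoding_model(
    n_units: int = 30,
    n_bins: int = 60,
    bin_cm: float = 2.0,
    peak_hz: float = 25.0,
    width_cm: float = 10.0,
    travel: str = "outbound",
    selective: bool = True,
    rng: Optional[np.random.Generator] = None,
) -> EncodingModel:
    """Encoding model with evenly spread Gaussian tuning curves.

    With ``selective=True``, units alternate between L- and R-preferring
    (floor rate on the other side); otherwise both sides share tuning.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    edges = np.arange(0.0, (n_bins + 1) * bin_cm, bin_cm)
    centers = 0.5 * (edges[:-1] + edges[1:])
    track = n_bins * bin_cm
    field_centers = np.linspace(0.05 * track, 0.95 * track, n_units)
    field_centers = field_centers + rng.normal(0, bin_cm / 2, n_units)
    rates = np.full((n_units, 2, n_bins), RATE_FLOOR_HZ)
    for i, c in enumerate(field_centers):
        f = peak_hz * np.exp(-0.5 * ((centers - c) / width_cm) ** 2)
        if selective:
            rates[i, i % 2, :] = np.maximum(f, RATE_FLOOR_HZ)
        else:
            rates[i, 0, :] = rates[i, 1, :] = np.maximum(f, RATE_FLOOR_HZ)
    return EncodingModel(
        travel=travel,
        region="CA1",
        unit_ids=list(range(n_units)),
        bin_edges=edges,
        rates=rates,
    )


def planted_sweep_spikes(
    model: EncodingModel,
    side: str,
    start_pos_cm: float,
    v_mps: float,
    start_s: float,
    duration_s: float,
    rng: np.random.Generator,
    rate_gain: float = 1.0,
    dt_s: float = 0.001,
) -> Dict[int, np.ndarray]:
    """Poisson spikes depicting a constant-velocity position sweep.

    The represented position moves from ``start_pos_cm`` at ``v_mps``
    (signed, m/s) for ``duration_s``; each unit fires from its template
    on ``side`` evaluated at the swept position.
    """
    k = model.sides.index(side)
    t = np.arange(0.0, duration_s, dt_s)
    pos = start_pos_cm + 100.0 * v_mps * t
    centers = model.bin_centers
    j = np.clip(np.searchsorted(centers, pos), 0, model.n_bins - 1)
    trains: Dict[int, np.ndarray] = {}
    for i, uid in enumerate(model.unit_ids):
        lam = rate_gain * model.rates[i, k, j]
        fire = rng.random(len(t)) < lam * dt_s
        trains[uid] = start_s + t[fire]
    return trains


def planted_candidate(
    event_id: int,
    start_s: float,
    duration_s: float,
    choice: str,
    position_cm: float,
    travel: str = "outbound",
    region: str = "CA1",
) -> CandidateEvent:
    """CandidateEvent record for a planted event."""
    return CandidateEvent(
        event_id=event_id,
        region=region,
        start_s=start_s,
        end_s=start_s + duration_s,
        n_active=99,
        speed_cm_s=30.0,
        position_cm=position_cm,
        trial_id=0,
        travel=travel,
        choice=choice,
    )


def theta_modulated_train(
    duration_s: float,
    base_hz: float,
    theta_hz: float,
    mod_depth: float,
    rng: np.random.Generator,
    skip_gain: Optional[float] = None,
    dt_s: float = 0.001,
) -> np.ndarray:
    """Theta-modulated Poisson train; ``skip_gain`` damps odd cycles."""
    t = np.arange(0.0, duration_s, dt_s)
    lam = base_hz * (1.0 + mod_depth * np.cos(2 * np.pi * theta_hz * t))
    if skip_gain is not None:
        odd = (np.floor(theta_hz * t).astype(np.int64) % 2) == 1
        lam = lam * np.where(odd, skip_gain, 1.0)
    return t[rng.random(len(t)) < lam * dt_s]


def time_shuffled_pmat(pmat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute the time columns of a posterior (destroys sequence order)."""
    return pmat[:, rng.permutation(pmat.shape[1])]
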