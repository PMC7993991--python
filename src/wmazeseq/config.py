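"""Configuration dataclasses: maze geometry and simulation parameters."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Tuple

import numpy as np

OUTBOUND_TYPES = ("C-to-L", "C-to-R")
INBOUND_TYPES = ("L-to-C", "R-to-C")
TRAJECTORY_TYPES = OUTBOUND_TYPES + INBOUND_TYPES


def traj_side(traj_type: str) -> str:
    """Side arm ('L' or 'R') of a trajectory type."""
    if traj_type in ("C-to-L", "L-to-C"):
        return "L"
    if traj_type in ("C-to-R", "R-to-C"):
        return "R"
    raise ValueError(f"unknown trajectory type {traj_type!r}")


def traj_travel(traj_type: str) -> str:
    """Travel class ('outbound' or 'inbound') of a trajectory type."""
    if traj_type in OUTBOUND_TYPES:
        return "outbound"
    if traj_type in INBOUND_TYPES:
        return "inbound"
    raise ValueError(f"unknown trajectory type {traj_type!r}")


def traj_of(travel: str, side: str) -> str:
    """Trajectory type string from travel class and side."""
    if travel == "outbound":
        return f"C-to-{side}"
    if travel == "inbound":
        return f"{side}-to-C"
    raise ValueError(f"unknown travel {travel!r}")


@dataclass(frozen=True)
class MazeGeometry:
    """Idealized W-maze: three parallel arms joined by a top crossbar.

    The center well sits at the bottom of the middle arm; the choice point
    (CP) is where the center stem meets the crossbar.  The two outbound
    paths share the stem segment exactly, so linear positions on the stem
    are identical across trajectory types.
    """

    stem_len_cm: float = 60.0
    cross_len_cm: float = 40.0
    arm_len_cm: float = 60.0

    @property
    def well_c(self) -> Tuple[float, float]:
        return (self.cross_len_cm, 0.0)

    @property
    def well_l(self) -> Tuple[float, float]:
        return (0.0, 0.0)

    @property
    def well_r(self) -> Tuple[float, float]:
        return (2 * self.cross_len_cm, 0.0)

    @property
    def choice_point(self) -> Tuple[float, float]:
        return (self.cross_len_cm, self.stem_len_cm)

    @property
    def path_length_cm(self) -> float:
        return self.stem_len_cm + self.cross_len_cm + self.arm_len_cm

    @property
    def cp_arclength_cm(self) -> float:
        """Arclength of the choice point measured from the center well."""
        return self.stem_len_cm

    def well_xy(self, well: str) -> Tuple[float, float]:
        return {"C": self.well_c, "L": self.well_l, "R": self.well_r}[well]

    def path_polyline(self, side: str) -> np.ndarray:
        """Polyline from center well to side well (shape (4, 2), cm).

        Linear position along this polyline is 0 at the center well and
        increases toward the side well for both travel directions.
        """
        xc, _ = self.well_c
        top = self.stem_len_cm
        if side == "L":
            xs = 0.0
        elif side == "R":
            xs = 2 * self.cross_len_cm
        else:
            raise ValueError(f"side must be 'L' or 'R', got {side!r}")
        return np.array(
            [[xc, 0.0], [xc, top], [xs, top], [xs, 0.0]], dtype=float
        )

    def point_at_arclength(self, side: str, s) -> np.ndarray:
        """(x, y) at arclength ``s`` (cm from center well) on a side path."""
        poly = self.path_polyline(side)
        seg = np.diff(poly, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        s = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0.0, cum[-1])
        idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
        frac = (s - cum[idx]) / seg_len[idx]
        pts = poly[idx] + frac[:, None] * seg[idx]
        return pts


@dataclass
class SimConfig:
    """Parameters of a synthetic W-maze session."""

    seed: int = 0
    n_trials: int = 40
    maze: MazeGeometry = field(default_factory=MazeGeometry)
    n_ca1: int = 40
    n_pfc: int = 30
    selectivity_frac: float = 0.75
    field_width_cm: float = 12.0
    asymmetry: float = 0.0
    precession_slope_deg_per_cm: float = -6.0
    skip_frac: float = 0.0
    theta_hz: float = 8.0
    swr_rate_hz: float = 0.3
    replay_fidelity: float = 0.8
    error_rate: float = 0.15
    run_speed_cm_s: float = 30.0

    # secondary knobs (not part of the headline parameter set)
    fs_pos: float = 30.0
    fs_lfp: float = 1500.0
    ca1_peak_hz: float = 25.0
    pfc_peak_hz: float = 9.0
    pfc_field_scale: float = 2.0   # PFC fields this much wider than CA1
    baseline_hz: float = 0.05
    theta_mod_depth: float = 0.7
    skip_gain: float = 0.08
    selective_gain: float = 0.08   # non-preferred-side rate gain of selective units
    dwell_range_s: Tuple[float, float] = (2.0, 10.0)
    replay_reverse_frac: float = 0.5
    lfp_noise_sd: float = 0.15
    theta_amp: float = 1.0
    ripple_amp: float = 1.2
    ripple_hz: float = 200.0

    def __post_init__(self) -> None:
        fracs = {
            "selectivity_frac": self.selectivity_frac,
            "skip_frac": self.skip_frac,
            "replay_fidelity": self.replay_fidelity,
            "error_rate": self.error_rate,
            "replay_reverse_frac": self.replay_reverse_frac,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")
        for name in ("n_ca1", "n_pfc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 6.0 <= self.theta_hz <= 12.0:
            raise ValueError(f"theta_hz must be in [6, 12], got {self.theta_hz}")
        if not -1.0 <= self.asymmetry <= 1.0:
            raise ValueError("asymmetry must be in [-1, 1]")
        if self.run_speed_cm_s <= 0:
            raise ValueError("run_speed_cm_s must be > 0")

    def to_dict(self) -> Dict:
        d = asdict(self)
        d["maze"] = asdict(self.maze)
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "SimConfig":
        d = dict(d)
        maze = d.pop("maze", None)
        cfg_maze = MazeGeometry(**maze) if isinstance(maze, dict) else MazeGeometry()
        if "dwell_range_s" in d:
            d["dwell_range_s"] = tuple(d["dwell_range_s"])
        return cls(maze=cfg_maze, **d)
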