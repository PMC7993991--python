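"""Session container: spikes, position, LFP, trials and provenance.

Tables are stored as CSV (human-readable); LFP and other dense arrays go
into an HDF5 sidecar.  Ground truth (when the session is synthetic) is
kept as JSON + CSV so a round trip is lossless for testing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import h5py
import numpy as np
import pandas as pd

from .config import SimConfig


@dataclass
class SpikeSet:
    """Per-unit spike trains with a region tag per unit."""

    units: pd.DataFrame          # unit_id, region
    trains: Dict[int, np.ndarray]  # unit_id -> sorted spike times (s)

    def unit_ids(self, region: Optional[str] = None):
        u = self.units
        if region is not None:
            u = u[u.region == region]
        return list(u.unit_id)

    def region_of(self, unit_id: int) -> str:
        return str(self.units.set_index("unit_id").loc[unit_id, "region"])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        region = self.units.set_index("unit_id")["region"]
        for uid, t in self.trains.items():
            rows.append(
                pd.DataFrame(
                    {"unit_id": uid, "region": region.loc[uid], "time_s": t}
                )
            )
        if not rows:
            return pd.DataFrame(columns=["unit_id", "region", "time_s"])
        return pd.concat(rows, ignore_index=True).sort_values(
            ["unit_id", "time_s"], ignore_index=True
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpikeSet":
        units = (
            df[["unit_id", "region"]]
            .drop_duplicates()
            .sort_values("unit_id", ignore_index=True)
        )
        trains = {
            int(uid): np.sort(g.time_s.to_numpy(float))
            for uid, g in df.groupby("unit_id")
        }
        return cls(units=units, trains=trains)


@dataclass
class Session:
    """One recording (or simulated) session on a single clock."""

    spikes: SpikeSet
    position: pd.DataFrame       # time_s, x_cm, y_cm
    trials: pd.DataFrame
    lfp: Dict[str, np.ndarray]   # channel name -> samples
    fs_lfp: float
    config: Optional[SimConfig] = None
    ground_truth: Optional[object] = None  # synthio.GroundTruth for synthetic data
    meta: Dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return float(self.position.time_s.iloc[-1])

    # ------------------------------------------------------------------ I/O
    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.spikes.to_frame().to_csv(out / "spikes.csv", index=False)
        self.position.to_csv(out / "position.csv", index=False)
        self.trials.to_csv(out / "trials.csv", index=False)
        with h5py.File(out / "arrays.h5", "w") as f:
            f.attrs["fs_lfp"] = self.fs_lfp
            g = f.create_group("lfp")
            for name, x in self.lfp.items():
                g.create_dataset(name, data=x, compression="gzip")
        meta = dict(self.meta)
        if self.config is not None:
            meta["config"] = self.config.to_dict()
            meta["config_hash"] = config_hash(self.config)
        (out / "meta.json").write_text(json.dumps(meta, indent=2, default=str))
        if self.ground_truth is not None:
            self.ground_truth.save(out / "ground_truth")

    @classmethod
    def load(cls, in_dir) -> "Session":
        from .synthio import GroundTruth  # local import avoids a cycle

        src = Path(in_dir)
        spikes = SpikeSet.from_frame(pd.read_csv(src / "spikes.csv"))
        position = pd.read_csv(src / "position.csv")
        trials = pd.read_csv(src / "trials.csv")
        lfp: Dict[str, np.ndarray] = {}
        with h5py.File(src / "arrays.h5", "r") as f:
            fs_lfp = float(f.attrs["fs_lfp"])
            for name in f["lfp"]:
                lfp[name] = f["lfp"][name][()]
        meta = json.loads((src / "meta.json").read_text())
        cfg = SimConfig.from_dict(meta["config"]) if "config" in meta else None
        gt = None
        if (src / "ground_truth").exists():
            gt = GroundTruth.load(src / "ground_truth")
        return cls(
            spikes=spikes,
            position=position,
            trials=trials,
            lfp=lfp,
            fs_lfp=fs_lfp,
            config=cfg,
            ground_truth=gt,
            meta=meta,
        )


def config_hash(cfg: SimConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def frame_hash(df: pd.DataFrame) -> str:
    """Stable content hash of a table (used for determinism checks)."""
    payload = df.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()
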