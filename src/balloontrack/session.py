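"""Per-measurement session log: the evaluation module's input.

One record per real-time measurement, holding the acquired mode and
prescription offset, the detector's output, the controller's lost
counter, and (when the measurement came from the simulator) the ground
truth. Serializes to CSV and JSON-lines with a fixed, documented column
contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import Mode, TrackingParams

__all__ = ["SessionRecord", "SessionLog", "COLUMNS"]

COLUMNS = [
    "measurement_index", "mode", "central_offset", "found", "slice_index",
    "x", "y", "z", "peak", "lost_count",
    "true_x", "true_y", "true_z", "max_overlap", "is_leap",
]


@dataclass
class SessionRecord:
    measurement_index: int
    mode: Mode
    central_offset: float
    found: bool
    slice_index: int
    position: Optional[np.ndarray]
    peak: float
    lost_count: int
    true_center: Optional[np.ndarray] = None
    max_overlap: float = float("nan")
    is_leap: bool = False

    def to_row(self) -> dict:
        pos = (self.position if self.position is not None
               else np.full(3, np.nan))
        tru = (self.true_center if self.true_center is not None
               else np.full(3, np.nan))
        return {
            "measurement_index": int(self.measurement_index),
            "mode": Mode(self.mode).value,
            "central_offset": float(self.central_offset),
            "found": bool(self.found),
            "slice_index": int(self.slice_index),
            "x": float(pos[0]), "y": float(pos[1]), "z": float(pos[2]),
            "peak": float(self.peak),
            "lost_count": int(self.lost_count),
            "true_x": float(tru[0]), "true_y": float(tru[1]),
            "true_z": float(tru[2]),
            "max_overlap": float(self.max_overlap),
            "is_leap": bool(self.is_leap),
        }


@dataclass
class SessionLog:
    """Append-only list of per-measurement records."""

    records: list[SessionRecord] = field(default_factory=list)
    params: Optional[TrackingParams] = None

    def append(self, record: SessionRecord) -> None:
        self.records.append(record)

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([r.to_row() for r in self.records], columns=COLUMNS)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(json.dumps(r.to_row()) + "\n")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       params: Optional[TrackingParams] = None) -> "SessionLog":
        log = cls(params=params)
        for _, row in df.iterrows():
            pos = None
            if bool(row["found"]):
                pos = np.array([row["x"], row["y"], row["z"]], dtype=float)
            tru = None
            if np.isfinite(row.get("true_x", np.nan)):
                tru = np.array(
                    [row["true_x"], row["true_y"], row["true_z"]], dtype=float
                )
            log.append(SessionRecord(
                measurement_index=int(row["measurement_index"]),
                mode=Mode(row["mode"]),
                central_offset=float(row["central_offset"]),
                found=bool(row["found"]),
                slice_index=int(row["slice_index"]),
                position=pos,
                peak=float(row["peak"]),
                lost_count=int(row["lost_count"]),
                true_center=tru,
                max_overlap=float(row.get("max_overlap", np.nan)),
                is_leap=bool(row.get("is_leap", False)),
            ))
        return log

    @classmethod
    def from_csv(cls, path,
                 params: Optional[TrackingParams] = None) -> "SessionLog":
        path = Path(path)
        df = pd.read_csv(path)
        missing = set(COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"session log {path} missing columns {sorted(missing)}")
        return cls.from_dataframe(df, params=params)
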