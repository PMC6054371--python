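"""GPS relocation tracks: one individual's time-ordered fixes.

Coordinates are projected planar meters; timestamps are timezone-naive
(interpreted as UTC).  Tracks round-trip through delimited text with
columns ``id, timestamp, x, y`` (ISO-8601 timestamps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Track", "read_tracks", "write_tracks"]


@dataclass
class Track:
    individual_id: str
    t: np.ndarray  # datetime64[ns], strictly increasing
    x: np.ndarray
    y: np.ndarray
    deploy_time: np.datetime64 | None = None
    end_time: np.datetime64 | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype="datetime64[ns]")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if not np.all(np.isfinite(self.x)) or not np.all(np.isfinite(self.y)):
            raise ValueError("coordinates must be finite")
        if len(self.t) > 1 and not np.all(np.diff(self.t).astype(np.int64) > 0):
            raise ValueError("timestamps must be strictly increasing (no duplicates)")

    def __len__(self) -> int:
        return len(self.t)

    def replace(self, t=None, x=None, y=None, meta=None) -> "Track":
        return Track(
            self.individual_id,
            self.t if t is None else t,
            self.x if x is None else x,
            self.y if y is None else y,
            deploy_time=self.deploy_time,
            end_time=self.end_time,
            meta=dict(self.meta) if meta is None else meta,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.individual_id, "timestamp": self.t, "x": self.x, "y": self.y}
        )

    def dates(self) -> np.ndarray:
        return self.t.astype("datetime64[D]")


def write_tracks(tracks: list[Track], path: str | Path) -> None:
    frames = [tr.to_frame() for tr in tracks]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["id", "timestamp", "x", "y"]
    )
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_tracks(path: str | Path) -> list[Track]:
    df = pd.read_csv(path, dtype={"id": str})
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    out = []
    for ind, sub in df.groupby("id", sort=True):
        sub = sub.sort_values("timestamp")
        out.append(
            Track(str(ind), sub["timestamp"].to_numpy(), sub["x"].to_numpy(), sub["y"].to_numpy())
        )
    return out
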