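"""Linear water features (streams, canals, ditches) as projected polylines."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import LineString, MultiLineString

__all__ = ["FlowlineSet", "distance_to_flowline", "read_flowlines", "write_flowlines"]


@dataclass
class FlowlineSet:
    """A set of polylines, each an (k, 2) array of projected vertices."""

    polylines: list[np.ndarray]

    def __post_init__(self) -> None:
        clean = []
        for line in self.polylines:
            arr = np.asarray(line, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
                raise ValueError("each polyline needs >= 2 (x, y) vertices")
            if not np.all(np.isfinite(arr)):
                raise ValueError("polyline coordinates must be finite")
            clean.append(arr)
        self.polylines = clean

    def __len__(self) -> int:
        return len(self.polylines)

    def as_multilinestring(self) -> MultiLineString:
        return MultiLineString([LineString(p) for p in self.polylines])

    def distances(self, x, y) -> np.ndarray:
        """Euclidean distance from each point to the nearest flowline segment."""
        if not self.polylines:
            raise ValueError("flowline set is empty")
        pts = shapely.points(np.column_stack([np.atleast_1d(x), np.atleast_1d(y)]))
        return shapely.distance(pts, self.as_multilinestring())


def distance_to_flowline(point: tuple[float, float], flowlines: FlowlineSet) -> float:
    """Minimum point-to-segment distance (meters) over all flowline segments."""
    return float(flowlines.distances([point[0]], [point[1]])[0])


def write_flowlines(flowlines: FlowlineSet, path: str | Path) -> None:
    """Write one WKT LINESTRING per line."""
    with open(path, "w") as fh:
        for line in flowlines.polylines:
            fh.write(shapely.to_wkt(LineString(line), rounding_precision=-1) + "\n")


def read_flowlines(path: str | Path) -> FlowlineSet:
    lines = []
    with open(path) as fh:
        for raw in fh:
            raw = raw.strip()
            if raw:
                geom = shapely.from_wkt(raw)
                lines.append(np.asarray(geom.coords, dtype=float))
    return FlowlineSet(lines)
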