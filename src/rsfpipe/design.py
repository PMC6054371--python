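"""Used/available design construction for seasonal resource selection.

Fixes are assigned to agricultural seasons, availability is sampled from
each individual's 100% minimum convex polygon (one available location per
used location), and each location gets proportional land-cover coverage
within a buffer plus standardized linear and centered-quadratic
distance-to-flowline predictors.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.geometry.polygon import orient

from .flowlines import FlowlineSet
from .rasters import LandCoverRaster
from .tracks import Track

__all__ = [
    "Season",
    "AggregationScheme",
    "ConvexPolygon",
    "DEFAULT_SEASONS",
    "default_schemes",
    "assign_seasons",
    "minimum_convex_polygon",
    "sample_available",
    "coverage_proportions",
    "build_design_table",
    "build_design_tables",
    "UseAvailableTable",
]


@dataclass(frozen=True)
class Season:
    """A dated agricultural season; both endpoints inclusive."""

    name: str
    start_date: dt.date
    end_date: dt.date

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError(f"season {self.name}: start after end")


#: The four corn-phenology seasons of the source study year.
DEFAULT_SEASONS = [
    Season("early_growing", dt.date(2016, 3, 1), dt.date(2016, 5, 15)),
    Season("late_growing", dt.date(2016, 5, 16), dt.date(2016, 7, 31)),
    Season("harvest", dt.date(2016, 8, 1), dt.date(2016, 10, 31)),
    Season("fallow", dt.date(2016, 11, 1), dt.date(2017, 1, 31)),
]


@dataclass(frozen=True)
class AggregationScheme:
    """A mapping from raw land-cover codes to modeled categories.

    One category is the reference: its proportional coverage is recorded
    but excluded from the predictor set (proportions are compositional).
    """

    name: str
    mapping: dict[int, str]
    reference_category: str

    def __post_init__(self) -> None:
        if self.reference_category not in set(self.mapping.values()):
            raise ValueError(
                f"scheme {self.name}: reference category "
                f"{self.reference_category!r} not among mapped categories"
            )

    @property
    def categories(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    @property
    def predictor_categories(self) -> list[str]:
        return [c for c in self.categories if c != self.reference_category]


# CDL-style class codes used throughout (subset of the annual crop-layer
# code book): crops, idle cropland, water, developed/natural, wetlands.
_H1 = {
    1: "Corn", 2: "OtherCrop", 3: "Rice", 4: "OtherCrop", 5: "Soybeans",
    24: "OtherCrop", 26: "OtherCrop", 53: "OtherCrop", 59: "OtherCrop",
    61: "Fallow", 74: "OtherCrop", 92: "Water", 111: "Water",
    121: "OtherNoncrop", 122: "OtherNoncrop", 123: "OtherNoncrop",
    124: "OtherNoncrop", 131: "OtherNoncrop", 143: "OtherNoncrop",
    152: "OtherNoncrop", 176: "OtherNoncrop", 190: "Wetland", 195: "Wetland",
    240: "OtherCrop",
}


def default_schemes() -> list[AggregationScheme]:
    """The four competing land-cover aggregation hypotheses.

    H1: crops individually + wetland distinct from other natural cover.
    H2: crops individually, wetland merged into other non-crop.
    H3: all crops equivalent, wetland distinct.
    H4: all crops equivalent, all natural cover (incl. wetland) equivalent.
    """
    h2 = {c: ("OtherNoncrop" if lab == "Wetland" else lab) for c, lab in _H1.items()}
    crop = {"Corn", "Rice", "Soybeans", "OtherCrop", "Fallow"}
    h3 = {c: ("Crop" if lab in crop else lab) for c, lab in _H1.items()}
    h4 = {
        c: ("Crop" if lab in crop else "Water" if lab == "Water" else "Natural")
        for c, lab in _H1.items()
    }
    return [
        AggregationScheme("H1", dict(_H1), "Fallow"),
        AggregationScheme("H2", h2, "Fallow"),
        AggregationScheme("H3", h3, "Crop"),
        AggregationScheme("H4", h4, "Crop"),
    ]


# -- seasonality ---------------------------------------------------------------


def assign_seasons(
    track: Track,
    seasons: list[Season] | None = None,
    span_tolerance_days: float = 0.0,
) -> dict[str, tuple[Track, bool]]:
    """Partition a track's fixes by season and flag full-span inclusion.

    An individual is *included* for a season iff its overall first fix is on
    or before the season start (+ tolerance) and its last fix on or after
    the season end (- tolerance): only animals tracked across the entire
    season contribute to that season's model.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    seasons = DEFAULT_SEASONS if seasons is None else seasons
    _check_nonoverlap(seasons)
    dates = track.dates()
    first, last = dates[0], dates[-1]
    tol = np.timedelta64(int(round(span_tolerance_days)), "D")
    out: dict[str, tuple[Track, bool]] = {}
    for s in seasons:
        d0 = np.datetime64(s.start_date)
        d1 = np.datetime64(s.end_date)
        sel = (dates >= d0) & (dates <= d1)
        sub = Track(
            track.individual_id,
            track.t[sel],
            track.x[sel],
            track.y[sel],
            deploy_time=track.deploy_time,
            end_time=track.end_time,
            meta=dict(track.meta),
        )
        included = bool(first <= d0 + tol and last >= d1 - tol)
        out[s.name] = (sub, included)
    return out


def _check_nonoverlap(seasons: list[Season]) -> None:
    ordered = sorted(seasons, key=lambda s: s.start_date)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_date <= a.end_date:
            raise ValueError(f"seasons {a.name} and {b.name} overlap")


# -- availability sampling -----------------------------------------------------


@dataclass
class ConvexPolygon:
    """Convex polygon with counter-clockwise vertices (projected meters)."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)

    @property
    def area(self) -> float:
        return self.as_shapely().area

    def as_shapely(self) -> Polygon:
        return Polygon(self.vertices)

    def contains(self, x, y) -> np.ndarray:
        poly = self.as_shapely()
        pts = shapely.points(np.column_stack([np.atleast_1d(x), np.atleast_1d(y)]))
        return shapely.covers(poly, pts)


def minimum_convex_polygon(points: np.ndarray) -> ConvexPolygon:
    """100% minimum convex polygon (convex hull) of the given points."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 3:
        raise ValueError("need >= 3 points for a minimum convex polygon")
    hull = MultiPoint(points).convex_hull
    if not isinstance(hull, Polygon):
        raise ValueError("points are collinear; convex polygon is degenerate")
    ring = orient(hull, sign=1.0).exterior  # counter-clockwise
    verts = np.asarray(ring.coords)[:-1]  # drop closing vertex
    return ConvexPolygon(verts)


def sample_available(polygon: ConvexPolygon, n: int, seed: int) -> np.ndarray:
    """n i.i.d. uniform points in the polygon via bounding-box rejection."""
    if n < 0:
        raise ValueError("n must be >= 0")
    poly = polygon.as_shapely()
    if poly.area <= 0:
        raise ValueError("polygon has zero area")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = poly.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(64, int(1.6 * (n - len(out)) * (xmax - xmin) * (ymax - ymin) / poly.area))
        cand = np.column_stack(
            [rng.uniform(xmin, xmax, m), rng.uniform(ymin, ymax, m)]
        )
        keep = shapely.covers(poly, shapely.points(cand))
        out = np.vstack([out, cand[keep]])
    return out[:n]


# -- predictor extraction ------------------------------------------------------


def _gather_window(raster: LandCoverRaster, pts: np.ndarray, radius: float):
    """Codes of raster cells whose centers lie within ``radius`` of each point.

    Returns (codes, within) both shaped (n_points, n_window_cells); ``within``
    is False for cells outside the buffer, off the raster, or nodata.
    """
    w = int(np.ceil((radius + raster.cell_size / 2) / raster.cell_size))
    di, dj = np.mgrid[-w : w + 1, -w : w + 1]
    di, dj = di.ravel(), dj.ravel()
    row0, col0 = raster.cell_of(pts[:, 0], pts[:, 1])
    rows = row0[:, None] + di[None, :]
    cols = col0[:, None] + dj[None, :]
    inb = raster.in_bounds(rows, cols)
    rc = np.clip(rows, 0, raster.n_rows - 1)
    cc = np.clip(cols, 0, raster.n_cols - 1)
    codes = raster.values[rc, cc]
    cx, cy = raster.center_of(rows, cols)
    dist2 = (cx - pts[:, 0][:, None]) ** 2 + (cy - pts[:, 1][:, None]) ** 2
    within = inb & (dist2 <= radius**2 + 1e-9) & (codes != raster.nodata)
    return codes, within


def _fractions(codes, within, scheme: AggregationScheme) -> np.ndarray:
    """(n_points, n_categories) coverage fractions from gathered windows."""
    cats = scheme.categories
    cat_index = {c: i for i, c in enumerate(cats)}
    lut = np.full(max(scheme.mapping) + 1, -1, dtype=int)
    for code, lab in scheme.mapping.items():
        lut[code] = cat_index[lab]
    unmapped = within & (lut[np.clip(codes, 0, len(lut) - 1)] < 0)
    if np.any(unmapped):
        bad = np.unique(codes[unmapped])
        raise ValueError(f"raster codes not in scheme {scheme.name}: {bad.tolist()}")
    total = within.sum(axis=1).astype(float)
    if np.any(total == 0):
        raise ValueError("buffer contains only nodata cells for some point(s)")
    out = np.empty((len(codes), len(cats)))
    idx = lut[np.clip(codes, 0, len(lut) - 1)]
    for i in range(len(cats)):
        out[:, i] = ((idx == i) & within).sum(axis=1) / total
    return out


def coverage_proportions(
    raster: LandCoverRaster,
    point: tuple[float, float],
    radius: float = 100.0,
    scheme: AggregationScheme | None = None,
) -> dict[str, float]:
    """Proportional coverage by category within ``radius`` of a point.

    A raster cell contributes iff its center lies within ``radius`` of the
    point; nodata cells are excluded from numerator and denominator.
    """
    if scheme is None:
        raise ValueError("an aggregation scheme is required")
    pts = np.asarray([point], dtype=float)
    codes, within = _gather_window(raster, pts, radius)
    fr = _fractions(codes, within, scheme)[0]
    return dict(zip(scheme.categories, fr))


# -- the model-ready table -----------------------------------------------------


@dataclass
class UseAvailableTable:
    """Used/available rows with predictors, plus standardization constants.

    ``df`` columns: individual_id, season, used, prop_<Category>...,
    dist_flow_raw, dist_flow_std, dist_flow_quad_std.
    ``standardization[season]`` holds dist_mean, dist_sd, quad_mean, quad_sd
    (the quadratic term is (raw - dist_mean)^2, then z-standardized).
    """

    df: pd.DataFrame
    standardization: dict[str, dict[str, float]]
    scheme_name: str
    categories: list[str]
    reference_category: str
    radius: float
    seed: int | None = None

    @property
    def predictor_columns(self) -> list[str]:
        cats = [f"prop_{c}" for c in self.categories if c != self.reference_category]
        return cats + ["dist_flow_std", "dist_flow_quad_std"]

    def season_frame(self, season: str) -> pd.DataFrame:
        return self.df[self.df["season"] == season]

    def write(self, path: str | Path) -> None:
        meta = {
            "standardization": self.standardization,
            "scheme_name": self.scheme_name,
            "categories": self.categories,
            "reference_category": self.reference_category,
            "radius": self.radius,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(meta) + "\n")
            self.df.to_csv(fh, index=False, float_format=lambda v: repr(float(v)))

    @classmethod
    def read(cls, path: str | Path) -> "UseAvailableTable":
        with open(path) as fh:
            meta = json.loads(fh.readline().lstrip("# "))
            df = pd.read_csv(fh)
        return cls(
            df,
            meta["standardization"],
            meta["scheme_name"],
            meta["categories"],
            meta["reference_category"],
            meta["radius"],
            meta["seed"],
        )


def _standardize_season(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    raw = df["dist_flow_raw"].to_numpy()
    mean, sd = float(raw.mean()), float(raw.std(ddof=0))
    sd = sd if sd > 0 else 1.0
    quad = (raw - mean) ** 2  # centered before squaring
    qmean, qsd = float(quad.mean()), float(quad.std(ddof=0))
    qsd = qsd if qsd > 0 else 1.0
    df = df.copy()
    df["dist_flow_std"] = (raw - mean) / sd
    df["dist_flow_quad_std"] = (quad - qmean) / qsd
    return df, {"dist_mean": mean, "dist_sd": sd, "quad_mean": qmean, "quad_sd": qsd}


def build_design_tables(
    used_by_season: dict[str, list[Track]],
    raster: LandCoverRaster,
    flowlines: FlowlineSet,
    schemes: list[AggregationScheme],
    radius: float = 100.0,
    seed: int = 0,
) -> dict[str, UseAvailableTable]:
    """Build one model-ready table per aggregation scheme.

    The used and available point sets (and the raster windows and flowline
    distances derived from them) are shared across schemes, so AIC model
    competition compares aggregations on identical data.  Availability is
    one uniform point per used fix, drawn from the individual's per-season
    100% minimum convex polygon; individuals with < 3 fixes in a season are
    excluded with a warning recorded in the table metadata.
    """
    rows_base = []  # (individual, season, used, x, y)
    rng = np.random.default_rng(seed)
    for season_name, tracks in used_by_season.items():
        for tr in tracks:
            if len(tr) < 3:
                continue
            pts = np.column_stack([tr.x, tr.y])
            try:
                mcp = minimum_convex_polygon(pts)
            except ValueError:
                continue
            avail = sample_available(mcp, len(tr), int(rng.integers(2**31 - 1)))
            for used, arr in ((1, pts), (0, avail)):
                rows_base.append(
                    pd.DataFrame(
                        {
                            "individual_id": tr.individual_id,
                            "season": season_name,
                            "used": used,
                            "x": arr[:, 0],
                            "y": arr[:, 1],
                        }
                    )
                )
    if not rows_base:
        raise ValueError("no individual-season had enough fixes to build a table")
    base = pd.concat(rows_base, ignore_index=True)
    pts = base[["x", "y"]].to_numpy()
    codes, within = _gather_window(raster, pts, radius)
    dists = flowlines.distances(pts[:, 0], pts[:, 1])
    out: dict[str, UseAvailableTable] = {}
    for scheme in schemes:
        fr = _fractions(codes, within, scheme)
        df = base.drop(columns=["x", "y"]).copy()
        for i, cat in enumerate(scheme.categories):
            df[f"prop_{cat}"] = fr[:, i]
        df["dist_flow_raw"] = dists
        parts, std = [], {}
        for season_name in df["season"].unique():
            sub, st = _standardize_season(df[df["season"] == season_name])
            parts.append(sub)
            std[season_name] = st
        out[scheme.name] = UseAvailableTable(
            pd.concat(parts, ignore_index=True),
            std,
            scheme.name,
            scheme.categories,
            scheme.reference_category,
            radius,
            seed,
        )
    return out


def build_design_table(
    used_by_season: dict[str, list[Track]],
    raster: LandCoverRaster,
    flowlines: FlowlineSet,
    scheme: AggregationScheme,
    radius: float = 100.0,
    seed: int = 0,
) -> UseAvailableTable:
    """Single-scheme convenience wrapper around :func:`build_design_tables`."""
    return build_design_tables(used_by_season, raster, flowlines, [scheme], radius, seed)[
        scheme.name
    ]
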