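"""Synthetic landscapes, flowlines and GPS tracks with known selection truth.

Everything downstream (QC, design construction, model fitting, prediction,
map comparison) is exercised against data generated here, where the true
selection coefficients, the corrupted fixes and the dependent animal pair
are all known by construction.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .design import AggregationScheme, _fractions, _gather_window
from .flowlines import FlowlineSet
from .rasters import LandCoverRaster
from .tracks import Track

__all__ = [
    "TrueModel",
    "DEFAULT_CLASS_WEIGHTS",
    "generate_landscape",
    "generate_flowlines",
    "simulate_individual",
    "corrupt_track",
    "make_dependent_pair",
    "simulate_logistic_dataset",
]


#: Default landscape composition (fractions of cells by CDL-style code),
#: mirroring the study region's mix: corn 12%, rice 4%, soybeans 38%,
#: wetlands 23%, with the remainder split over cotton, idle cropland,
#: shrubland, open water and developed cover.
DEFAULT_CLASS_WEIGHTS: dict[int, float] = {
    1: 0.12,   # corn
    3: 0.04,   # rice
    5: 0.38,   # soybeans
    190: 0.23, # wetland
    2: 0.05,   # cotton (other crop)
    61: 0.08,  # idle cropland
    152: 0.06, # shrubland (other non-crop)
    111: 0.02, # open water
    121: 0.02, # developed
}


@dataclass
class TrueModel:
    """Ground-truth selection model used by the location sampler.

    ``beta_cover`` maps aggregation-scheme categories to coefficients on
    proportional coverage; the flowline terms act on distance in km
    (``d/1000``) and on the centered square ``((d - flow_center)/1000)^2``
    so their magnitudes are comparable to the coverage coefficients.
    ``sigma_b`` is the SD of the per-individual random intercept.
    """

    beta0: float = 0.0
    beta_cover: dict[str, float] = field(default_factory=dict)
    beta_flow_lin: float = 0.0
    beta_flow_quad: float = 0.0
    flow_center: float = 0.0
    sigma_b: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_b < 0:
            raise ValueError("sigma_b must be >= 0")


def generate_landscape(
    n_rows: int,
    n_cols: int,
    cell_size: float,
    class_weights: dict[int, float] | None = None,
    patch_scale: float = 4.0,
    seed: int = 0,
) -> LandCoverRaster:
    """Patchy categorical landscape via smoothed-noise thresholding.

    A Gaussian random field is smoothed at ``patch_scale`` (in cells) and
    split at its empirical quantiles so class frequencies match
    ``class_weights``; smoothing produces spatially contiguous patches.
    ``patch_scale = 0`` gives i.i.d. cells.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("raster dimensions must be >= 1")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if patch_scale < 0:
        raise ValueError("patch_scale must be >= 0")
    weights = DEFAULT_CLASS_WEIGHTS if class_weights is None else class_weights
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class weights must sum to 1, got {total}")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_rows, n_cols))
    if patch_scale > 0:
        noise = ndimage.gaussian_filter(noise, sigma=patch_scale, mode="wrap")
    ranks = noise.ravel().argsort().argsort().reshape(noise.shape)
    frac = (ranks + 0.5) / noise.size
    codes = list(weights)
    cuts = np.cumsum([weights[c] for c in codes])
    values = np.asarray(codes)[np.searchsorted(cuts, frac, side="left").clip(0, len(codes) - 1)]
    return LandCoverRaster(values.astype(np.int64), cell_size, (0.0, 0.0), nodata=-9999)


def generate_flowlines(
    extent: tuple[float, float, float, float],
    n_lines: int,
    seed: int = 0,
    n_vertices: int = 12,
    wiggle: float = 0.08,
) -> FlowlineSet:
    """Wavy polylines crossing a rectangular extent (streams/canals/ditches).

    Each line runs from one edge of ``extent`` to the opposite edge with
    lateral Gaussian wiggle, clamped inside the rectangle.
    """
    xmin, ymin, xmax, ymax = extent
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("degenerate extent")
    if n_lines < 0:
        raise ValueError("n_lines must be >= 0")
    rng = np.random.default_rng(seed)
    lines = []
    for _ in range(n_lines):
        vertical = rng.uniform() < 0.5
        along = np.linspace(0.0, 1.0, n_vertices)
        base = rng.uniform(0.15, 0.85)
        lateral = base + np.cumsum(rng.normal(0.0, wiggle, n_vertices))
        lateral = np.clip(lateral, 0.0, 1.0)
        if vertical:
            x = xmin + lateral * (xmax - xmin)
            y = ymin + along * (ymax - ymin)
        else:
            x = xmin + along * (xmax - xmin)
            y = ymin + lateral * (ymax - ymin)
        lines.append(np.column_stack([x, y]))
    return FlowlineSet(lines)


def _candidate_cells(landscape: LandCoverRaster, center, radius):
    """Rows/cols and center coordinates of raster cells inside the home disc."""
    cx, cy = center
    r0, c0 = landscape.cell_of(cx, cy)
    w = int(np.ceil(radius / landscape.cell_size)) + 1
    rows, cols = np.mgrid[r0 - w : r0 + w + 1, c0 - w : c0 + w + 1]
    rows, cols = rows.ravel(), cols.ravel()
    ok = landscape.in_bounds(rows, cols)
    rows, cols = rows[ok], cols[ok]
    x, y = landscape.center_of(rows, cols)
    ok = (x - cx) ** 2 + (y - cy) ** 2 <= radius**2
    rows, cols = rows[ok], cols[ok]
    ok = landscape.values[rows, cols] != landscape.nodata
    return rows[ok], cols[ok]


def simulate_individual(
    landscape: LandCoverRaster,
    flowlines: FlowlineSet,
    model: TrueModel,
    scheme: AggregationScheme,
    home_center: tuple[float, float],
    home_radius: float,
    n_fixes: int,
    interval_hours: float = 2.0,
    start_time: dt.datetime = dt.datetime(2016, 3, 1, 0, 0),
    seed: int = 0,
    individual_id: str = "ind",
    buffer_radius: float = 100.0,
) -> Track:
    """Simulate one animal's fixes by weighted sampling within a home disc.

    A random intercept b_i ~ N(0, sigma_b^2) is drawn once, then each fix
    falls in a candidate raster cell with probability proportional to
    exp(beta0 + b_i + sum_k beta_k x_k) evaluated at the cell center with
    the same coverage/distance predictors the analysis pipeline computes,
    jittered uniformly within the cell.  Timestamps sit on exact even hours.
    """
    if n_fixes < 1:
        raise ValueError("n_fixes must be >= 1")
    if interval_hours <= 0:
        raise ValueError("interval must be positive")
    rng = np.random.default_rng(seed)
    rows, cols = _candidate_cells(landscape, home_center, home_radius)
    if len(rows) == 0:
        raise ValueError("home disc does not intersect the raster")
    x, y = landscape.center_of(rows, cols)
    pts = np.column_stack([x, y])
    codes, within = _gather_window(landscape, pts, buffer_radius)
    fr = _fractions(codes, within, scheme)
    dists = flowlines.distances(x, y) if len(flowlines) else np.zeros(len(x))
    b_i = rng.normal(0.0, model.sigma_b) if model.sigma_b > 0 else 0.0
    eta = np.full(len(x), model.beta0 + b_i)
    for i, cat in enumerate(scheme.categories):
        eta += model.beta_cover.get(cat, 0.0) * fr[:, i]
    dkm = dists / 1000.0
    ckm = ((dists - model.flow_center) / 1000.0) ** 2
    eta += model.beta_flow_lin * dkm + model.beta_flow_quad * ckm
    w = np.exp(eta - eta.max())
    w /= w.sum()
    picks = rng.choice(len(x), size=n_fixes, p=w)
    jitter = rng.uniform(-0.5, 0.5, (n_fixes, 2)) * landscape.cell_size
    fx = x[picks] + jitter[:, 0]
    fy = y[picks] + jitter[:, 1]
    start = start_time.replace(minute=0, second=0, microsecond=0)
    if start.hour % 2:
        start += dt.timedelta(hours=1)
    t0 = np.datetime64(start)
    step = np.timedelta64(int(round(interval_hours * 3600)), "s")
    t = t0 + np.arange(n_fixes) * step
    return Track(individual_id, t.astype("datetime64[ns]"), fx, fy, meta={"b_i": b_i})


def corrupt_track(
    track: Track,
    spike_rate: float = 0.0,
    offhour_rate: float = 0.0,
    seed: int = 0,
    v_max_kmh: float = 20.0,
) -> Track:
    """Inject known QC defects into a clean track.

    Spikes are extra fixes inserted midway (in time) between consecutive
    fixes, displaced far enough that the implied velocity from the previous
    fix exceeds ``v_max_kmh``.  Off-hour corruption shifts existing
    timestamps 6-25 minutes off the hour.  The injected spike timestamps
    and shifted timestamps are recorded in ``meta`` so QC recall/precision
    is computable downstream.
    """
    if not 0 <= spike_rate <= 1 or not 0 <= offhour_rate <= 1:
        raise ValueError("rates must be in [0, 1]")
    if len(track) == 0:
        raise ValueError("empty track")
    rng = np.random.default_rng(seed)
    t = track.t.copy()
    x = track.x.copy()
    y = track.y.copy()

    off_times = np.array([], dtype="datetime64[ns]")
    if offhour_rate > 0 and len(t) > 0:
        n_off = int(round(offhour_rate * len(t)))
        idx = rng.choice(len(t), size=n_off, replace=False)
        shift_min = rng.integers(6, 26, size=n_off)
        sign = rng.choice([-1, 1], size=n_off)
        t[idx] = t[idx] + (sign * shift_min * np.timedelta64(60, "s"))
        off_times = np.sort(t[idx].copy())
        order = np.argsort(t, kind="stable")
        t, x, y = t[order], x[order], y[order]

    spike_times = np.array([], dtype="datetime64[ns]")
    if spike_rate > 0 and len(t) >= 2:
        n_gaps = len(t) - 1
        n_spikes = max(1, int(round(spike_rate * n_gaps)))
        gaps = rng.choice(n_gaps, size=min(n_spikes, n_gaps), replace=False)
        new_t, new_x, new_y = [], [], []
        for gi in np.sort(gaps):
            tm = t[gi] + (t[gi + 1] - t[gi]) / 2
            dt_h = (tm - t[gi]) / np.timedelta64(1, "h")
            dist = 2.0 * v_max_kmh * dt_h * 1000.0  # twice the removable limit
            ang = rng.uniform(0, 2 * np.pi)
            new_t.append(tm)
            new_x.append(x[gi] + dist * np.cos(ang))
            new_y.append(y[gi] + dist * np.sin(ang))
        spike_times = np.array(new_t, dtype="datetime64[ns]")
        t = np.concatenate([t, spike_times])
        x = np.concatenate([x, new_x])
        y = np.concatenate([y, new_y])
        order = np.argsort(t, kind="stable")
        t, x, y = t[order], x[order], y[order]

    meta = dict(track.meta)
    meta["spike_times"] = spike_times
    meta["offhour_times"] = off_times
    return Track(track.individual_id, t, x, y, track.deploy_time, track.end_time, meta)


def make_dependent_pair(track: Track, jitter_sd: float, seed: int = 0) -> Track:
    """Companion track: same timestamps, coordinates plus Gaussian jitter.

    With jitter small relative to the track's extent the coordinate
    correlations with the original exceed the dependence screen's
    threshold on both axes (r ~ sd(x) / sqrt(sd(x)^2 + jitter_sd^2)).
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    if len(track) == 0:
        raise ValueError("empty track")
    rng = np.random.default_rng(seed)
    return Track(
        track.individual_id + "_dep",
        track.t.copy(),
        track.x + rng.normal(0.0, jitter_sd, len(track)),
        track.y + rng.normal(0.0, jitter_sd, len(track)),
        meta={"companion_of": track.individual_id},
    )


def simulate_logistic_dataset(
    beta: np.ndarray,
    sigma_b: float,
    n_groups: int,
    n_per_group: int,
    seed: int = 0,
):
    """Design-level simulator for exercising the mixed-logit fitter.

    Covariates mimic one used/available design row: an intercept, a
    coverage proportion in [0, 1], and standardized linear and quadratic
    flowline-distance terms.  Returns (X, y, groups).
    """
    beta = np.asarray(beta, dtype=float)
    rng = np.random.default_rng(seed)
    n = n_groups * n_per_group
    cols = [np.ones(n), rng.uniform(0.0, 1.0, n)]
    while len(cols) < len(beta):
        cols.append(rng.standard_normal(n))
    X = np.column_stack(cols[: len(beta)])
    groups = np.repeat(np.arange(n_groups), n_per_group)
    b = rng.normal(0.0, sigma_b, n_groups) if sigma_b > 0 else np.zeros(n_groups)
    y = (rng.uniform(size=n) < expit(X @ beta + b[groups])).astype(float)
    return X, y, groups
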