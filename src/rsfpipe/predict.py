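"""Relative selection probabilities: gradient curves and landscape maps.

The fitted model's fixed effects define the relative selection probability

    p(l) = logistic(beta0 + beta_c x_c + beta_w x_w + beta_fl x_f + beta_fq x_f^2)

for a location whose buffer is covered by a crop (proportion P) and
wetlands (1 - P), at a given distance to the nearest flowline.  The random
intercept is excluded: predictions describe population-level trends.
Probabilities are relative within a season, not absolute probabilities of
use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .design import AggregationScheme, UseAvailableTable
from .flowlines import FlowlineSet
from .rasters import LandCoverRaster, Raster, category_fraction_stack
from .rsf import FittedRSF

__all__ = [
    "SelectionCurve",
    "PredictionRaster",
    "selection_probability",
    "selection_curves",
    "project_landscape",
]


@dataclass
class PredictionRaster(Raster):
    """Per-cell relative selection probability in (0, 1); NaN = nodata."""

    season: str = ""


@dataclass
class SelectionCurve:
    """Relative selection along the crop/wetland proportionality gradient."""

    crop: str
    distance: float  # meters to nearest flowline, fixed along the curve
    P: np.ndarray  # crop proportions, ascending in [0, 1]
    p_values: np.ndarray  # relative selection probability at each P

    @property
    def slope_sign(self) -> int:
        """Sign of the curve's monotone trend: sign(beta_crop - beta_wetland)."""
        d = np.diff(self.p_values)
        if np.all(np.abs(d) < 1e-15):
            return 0
        return 1 if d[0] > 0 else -1


def _standardized_distance_terms(model: FittedRSF, dist) -> tuple[np.ndarray, np.ndarray]:
    st = model.standardization
    for key in ("dist_mean", "dist_sd", "quad_mean", "quad_sd"):
        if key not in st:
            raise ValueError(f"model is missing standardization constant {key!r}")
    dist = np.asarray(dist, dtype=float)
    z = (dist - st["dist_mean"]) / st["dist_sd"]
    quad = (dist - st["dist_mean"]) ** 2
    zq = (quad - st["quad_mean"]) / st["quad_sd"]
    return z, zq


def selection_probability(
    model: FittedRSF,
    crop: str,
    P,
    dist,
    wetland_category: str = "Wetland",
) -> np.ndarray | float:
    """Relative selection probability for crop proportion P, wetlands 1 - P.

    All other coverage predictors are fixed at zero; the raw distance to
    flowline is transformed with the model's stored training-sample
    standardization (linear term and centered square).  Fixed effects only.
    """
    crop_key = f"prop_{crop}"
    wet_key = f"prop_{wetland_category}"
    if crop_key not in model.beta:
        raise ValueError(f"category {crop!r} is not a predictor of this model")
    if wet_key not in model.beta:
        raise ValueError(f"category {wetland_category!r} is not a predictor of this model")
    P = np.asarray(P, dtype=float)
    if np.any(P < 0) or np.any(P > 1):
        raise ValueError("P must be in [0, 1]")
    z, zq = _standardized_distance_terms(model, dist)
    eta = (
        model.beta0
        + model.beta[crop_key] * P
        + model.beta[wet_key] * (1.0 - P)
        + model.beta["dist_flow_std"] * z
        + model.beta["dist_flow_quad_std"] * zq
    )
    out = expit(eta)
    return float(out) if np.isscalar(P) or out.ndim == 0 else out


def selection_curves(
    model: FittedRSF,
    crops: list[str],
    table: UseAvailableTable,
    dist_quantiles: tuple[float, ...] = (0.0, 0.5, 1.0),
    grid_size: int = 101,
    wetland_category: str = "Wetland",
) -> list[SelectionCurve]:
    """One curve per (crop, flowline-distance quantile) over P in [0, 1].

    Distances are the requested quantiles of the raw distance-to-flowline
    values in the model's season rows of ``table`` (defaults: the minimum,
    median and maximum observed distance).
    """
    if not model.converged:
        raise ValueError("model did not converge; curves not meaningful")
    sub = table.season_frame(model.season)
    if sub.empty:
        raise ValueError(f"table has no rows for season {model.season!r}")
    dists = np.quantile(sub["dist_flow_raw"].to_numpy(), dist_quantiles)
    P = np.linspace(0.0, 1.0, grid_size)
    curves = []
    for crop in crops:
        for d in dists:
            p = selection_probability(model, crop, P, float(d), wetland_category)
            curves.append(SelectionCurve(crop, float(d), P, np.asarray(p)))
    return curves


def project_landscape(
    model: FittedRSF,
    raster: LandCoverRaster,
    flowlines: FlowlineSet,
    scheme: AggregationScheme,
    radius: float = 100.0,
) -> PredictionRaster:
    """Project the fitted model across the landscape.

    Per cell: proportional coverage by each category within the ``radius``
    buffer of the cell center (moving-window convolution, identical to the
    per-point cell-center rule), distance from the cell center to the
    nearest flowline, then the fixed-effects logistic evaluated with the
    model's training standardization.  Nodata propagates as NaN.
    """
    if scheme.name != model.scheme:
        warnings.warn(
            f"scheme {scheme.name!r} does not match the model's {model.scheme!r}"
        )
    cats = scheme.categories
    cat_index = {c: i for i, c in enumerate(cats)}
    code_to_index = {code: cat_index[lab] for code, lab in scheme.mapping.items()}
    stack = category_fraction_stack(raster, code_to_index, len(cats), radius)
    cx, cy = raster.center_grids()
    xr = raster.extent
    lb = flowlines.as_multilinestring().bounds if len(flowlines) else None
    if lb is not None and (lb[2] < xr[0] or lb[0] > xr[2] or lb[3] < xr[1] or lb[1] > xr[3]):
        warnings.warn("flowline extent does not overlap the raster; distances still computed")
    dist = flowlines.distances(cx.ravel(), cy.ravel()).reshape(cx.shape)
    z, zq = _standardized_distance_terms(model, dist)
    eta = np.full(raster.values.shape, model.beta0, dtype=float)
    for cat in cats:
        key = f"prop_{cat}"
        if key in model.beta:
            eta += model.beta[key] * stack[cat_index[cat]]
    eta += model.beta["dist_flow_std"] * z + model.beta["dist_flow_quad_std"] * zq
    p = expit(eta)
    p[raster.nodata_mask()] = np.nan
    p[np.isnan(stack).any(axis=0)] = np.nan
    return PredictionRaster(p, raster.cell_size, raster.origin, np.nan, season=model.season)
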