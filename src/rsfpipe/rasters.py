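"""Single-band rasters on a regular grid, in projected planar meters.

Rasters are stored row-major with row 0 at the *top* (northernmost) edge,
matching the ESRI ASCII grid convention used for on-disk storage.  The
``origin`` is the (x, y) of the grid's lower-left corner.  Land-cover
rasters carry integer class codes; prediction rasters carry floats with
NaN marking nodata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "Raster",
    "LandCoverRaster",
    "read_ascii_grid",
    "write_ascii_grid",
    "circular_kernel",
    "category_fraction_stack",
]


@dataclass
class Raster:
    """A regular single-band grid in projected meters.

    Parameters
    ----------
    values : ndarray, shape (n_rows, n_cols)
        Cell values; row 0 is the top row.
    cell_size : float
        Cell edge length in meters (square cells).
    origin : (float, float)
        Projected coordinates of the lower-left corner of the grid.
    nodata : int or float
        Value marking missing cells (NaN allowed for float rasters).
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float]
    nodata: float = -9999

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("raster values must be a 2-D grid with m, n >= 1")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.n_cols * self.cell_size, y0 + self.n_rows * self.cell_size)

    def nodata_mask(self) -> np.ndarray:
        if np.issubdtype(self.values.dtype, np.floating) and np.isnan(self.nodata):
            return np.isnan(self.values)
        return self.values == self.nodata

    # -- coordinate transforms -------------------------------------------------

    def cell_of(self, x, y):
        """Row/col of the cell containing projected point(s) (x, y)."""
        x0, y0 = self.origin
        col = np.floor((np.asarray(x) - x0) / self.cell_size).astype(int)
        row = self.n_rows - 1 - np.floor((np.asarray(y) - y0) / self.cell_size).astype(int)
        return row, col

    def center_of(self, row, col):
        """Projected coordinates of cell center(s) at (row, col)."""
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = y0 + (self.n_rows - np.asarray(row) - 0.5) * self.cell_size
        return x, y

    def center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates for every cell, each shaped like values."""
        rows, cols = np.mgrid[0 : self.n_rows, 0 : self.n_cols]
        return self.center_of(rows, cols)

    def in_bounds(self, row, col):
        row = np.asarray(row)
        col = np.asarray(col)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)


@dataclass
class LandCoverRaster(Raster):
    """Categorical land-cover raster with integer class codes."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.values.dtype, np.integer):
            self.values = self.values.astype(np.int64)

    def codes_present(self) -> np.ndarray:
        vals = self.values[~self.nodata_mask()]
        return np.unique(vals)


# -- text I/O (ESRI ASCII grid) ----------------------------------------------


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid (plain text, georeferenced).

    Integer rasters are written as integers; float rasters with ``repr``
    precision so the round-trip is bit-exact.
    """
    path = Path(path)
    is_int = np.issubdtype(raster.values.dtype, np.integer)
    nodata = raster.nodata
    vals = raster.values
    if not is_int and np.isnan(nodata):
        nodata = -9999.0
        vals = np.where(np.isnan(vals), nodata, vals)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {float(raster.origin[0])!r}\n")
        fh.write(f"yllcorner {float(raster.origin[1])!r}\n")
        fh.write(f"cellsize {float(raster.cell_size)!r}\n")
        if is_int:
            fh.write(f"NODATA_value {int(nodata)}\n")
            for row in vals:
                fh.write(" ".join(str(int(v)) for v in row) + "\n")
        else:
            fh.write(f"NODATA_value {float(nodata)!r}\n")
            for row in vals:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path, categorical: bool | None = None) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, str] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = val
        body = np.loadtxt(fh, ndmin=2)
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    origin = (float(header["xllcorner"]), float(header["yllcorner"]))
    cell_size = float(header["cellsize"])
    nodata_s = header["nodata_value"]
    if categorical is None:
        categorical = "." not in nodata_s and not np.any(body != np.round(body))
    if categorical:
        return LandCoverRaster(body.astype(np.int64), cell_size, origin, int(float(nodata_s)))
    nodata = float(nodata_s)
    vals = body.astype(float)
    vals[vals == nodata] = np.nan
    return Raster(vals, cell_size, origin, np.nan)


# -- moving-window proportional coverage --------------------------------------


def circular_kernel(cell_size: float, radius: float) -> np.ndarray:
    """0/1 kernel of cell-center offsets within ``radius`` of a cell center.

    Membership rule: a neighbouring cell belongs to the buffer iff its
    center lies within ``radius`` of the focal cell's center (30 m cells
    with a 100 m radius give the 37-cell disc).
    """
    w = int(radius // cell_size) + 1
    di, dj = np.mgrid[-w : w + 1, -w : w + 1]
    return ((di * di + dj * dj) * cell_size**2 <= radius**2 + 1e-9).astype(float)


def category_fraction_stack(
    raster: LandCoverRaster,
    code_to_index: dict[int, int],
    n_categories: int,
    radius: float,
) -> np.ndarray:
    """Per-cell proportional coverage of each category in a circular window.

    Returns an array of shape ``(n_categories, n_rows, n_cols)`` whose value
    at ``(c, i, j)`` is the fraction of valid cells, among those whose centers
    lie within ``radius`` of cell ``(i, j)``'s center, that map to category
    ``c``.  Nodata cells are excluded from numerator and denominator; windows
    clipped by the raster edge are renormalized over the surviving cells.
    Cells whose whole window is nodata get NaN in every layer.
    """
    kernel = circular_kernel(raster.cell_size, radius)
    valid = (~raster.nodata_mask()).astype(float)
    denom = ndimage.convolve(valid, kernel, mode="constant", cval=0.0)
    counts = np.zeros((n_categories, raster.n_rows, raster.n_cols))
    for code, idx in code_to_index.items():  # codes may share a category index
        ind = ((raster.values == code) & (valid > 0)).astype(float)
        counts[idx] += ndimage.convolve(ind, kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        stack = counts / denom
    stack[:, denom == 0] = np.nan
    return stack
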