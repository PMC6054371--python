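"""Raster similarity for probability maps.

The similarity between rasters A and B (B the *target*) is

    S = 1 - sum d_ij^2 / sum Delta_ij^2,

where d = A - B cellwise, and Delta_ij = max(B_ij, 1 - B_ij) is the
difference between B and the binary raster alpha arranged to maximize the
cellwise difference from B.  S runs from 0 (maximal dissimilarity against
the worst-case binary raster) to 1 (identical rasters), with no sampling
assumptions or hypothesis tests.  S is asymmetric: the denominator depends
on the target B.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .rasters import Raster

__all__ = ["SimilarityMatrix", "max_difference", "similarity", "pairwise_similarity"]


def _values_and_mask(r: Raster | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals = np.asarray(r.values if isinstance(r, Raster) else r, dtype=float)
    mask = ~np.isnan(vals)
    if isinstance(r, Raster) and not (
        np.issubdtype(np.asarray(r.nodata).dtype, np.floating) and np.isnan(r.nodata)
    ):
        mask &= vals != r.nodata
    if np.any((vals[mask] < 0) | (vals[mask] > 1)):
        raise ValueError("raster values must lie in [0, 1]")
    return vals, mask


def max_difference(B: Raster | np.ndarray) -> np.ndarray:
    """Cellwise maximum attainable difference against a binary raster.

    Delta_ij = max(B_ij, 1 - B_ij): the optimal binary raster puts 0 where
    B >= 0.5 and 1 elsewhere (at exactly 0.5 either choice gives 0.5).
    Nodata propagates as NaN.
    """
    vals, mask = _values_and_mask(B)
    out = np.full(vals.shape, np.nan)
    out[mask] = np.maximum(vals[mask], 1.0 - vals[mask])
    return out


def similarity(A: Raster | np.ndarray, B: Raster | np.ndarray) -> float:
    """S = 1 - sum d^2 / sum Delta^2 with B as the target raster.

    Cells that are nodata in either raster are excluded from both sums.
    """
    va, ma = _values_and_mask(A)
    vb, mb = _values_and_mask(B)
    if va.shape != vb.shape:
        raise ValueError(f"raster shapes differ: {va.shape} vs {vb.shape}")
    if isinstance(A, Raster) and isinstance(B, Raster):
        if A.cell_size != B.cell_size or A.origin != B.origin:
            raise ValueError("raster geometries (cell size / origin) differ")
    m = ma & mb
    if not m.any():
        raise ValueError("no overlapping valid cells")
    d2 = float(np.sum((va[m] - vb[m]) ** 2))
    delta = np.maximum(vb[m], 1.0 - vb[m])
    dd2 = float(np.sum(delta**2))
    return 1.0 - d2 / dd2


@dataclass
class SimilarityMatrix:
    """All ordered pairwise similarities; entry [i, j] uses raster j as target."""

    labels: list[str]
    S: np.ndarray

    def write(self, path: str | Path, decimals: int = 7) -> None:
        """Tab-delimited matrix rendered at the given precision."""
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                cells = "\t".join(f"{v:.{decimals}f}" for v in self.S[i])
                fh.write(lab + "\t" + cells + "\n")

    def lower_triangle(self, decimals: int = 7) -> str:
        """Lower-triangle rendering (row raster as A, column raster as target B)."""
        lines = ["\t" + "\t".join(self.labels)]
        for i, lab in enumerate(self.labels):
            cells = [f"{self.S[i, j]:.{decimals}f}" if j <= i else "" for j in range(len(self.labels))]
            lines.append(lab + "\t" + "\t".join(cells))
        return "\n".join(lines)


def pairwise_similarity(rasters: dict[str, Raster]) -> SimilarityMatrix:
    """Similarity for every ordered pair of equally-shaped rasters.

    The diagonal is exactly 1.  Off-diagonal entries are generally
    asymmetric because the denominator is defined by the column (target)
    raster.
    """
    if len(rasters) < 2:
        raise ValueError("need at least 2 rasters")
    labels = list(rasters)
    n = len(labels)
    S = np.empty((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i == j:
                S[i, j] = 1.0
                continue
            try:
                S[i, j] = similarity(rasters[a], rasters[b])
            except ValueError as err:
                raise ValueError(f"pair ({a}, {b}): {err}") from err
    return SimilarityMatrix(labels, S)
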