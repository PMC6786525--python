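"""Triangle-of-biomedicine density maps.

Articles are accumulated as unit (or weighted) point sources on a square
raster covering the triangle — overlapping coordinates simply sum — then
Gaussian-smoothed and pseudocoloured.  Ratio grids (e.g. the fraction of
articles per pixel that were clinically cited) divide two smoothed grids
with zero-denominator masking.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .scoring import SQRT3_2, TriCoordinate

__all__ = [
    "DensityGrid",
    "accumulate",
    "smooth",
    "smooth_and_colorize",
    "ratio_grid",
    "triangle_mask",
    "save_png",
    "write_grid_tsv",
]

#: plotting extent: x ∈ [−√3/2, √3/2], y ∈ [−1/2, 1]
EXTENT = (-SQRT3_2, SQRT3_2, -0.5, 1.0)
_TOL = 1e-9


@dataclass
class DensityGrid:
    """A square raster over the triangle; ``values[row, col]``, row 0 at y max."""

    values: np.ndarray
    extent: tuple[float, float, float, float] = EXTENT

    @property
    def size(self) -> int:
        return self.values.shape[0]

    def total(self) -> float:
        return float(self.values.sum())


def _barycentric(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """(h, a, mc) for planar points; negative components mean 'outside'."""
    h = (y + 0.5) / 1.5
    rest = 1.0 - h
    a = (rest + x / SQRT3_2) / 2.0
    mc = rest - a
    return np.stack([h, a, mc], axis=-1)


def triangle_mask(grid_size: int) -> np.ndarray:
    """Boolean raster of pixels whose centres lie inside the triangle."""
    xs, ys = _pixel_centres(grid_size)
    xg, yg = np.meshgrid(xs, ys)
    bary = _barycentric(xg, yg)
    return (bary >= -1e-6).all(axis=-1)


def _pixel_centres(grid_size: int) -> tuple[np.ndarray, np.ndarray]:
    x0, x1, y0, y1 = EXTENT
    xs = x0 + (np.arange(grid_size) + 0.5) * (x1 - x0) / grid_size
    ys = y1 - (np.arange(grid_size) + 0.5) * (y1 - y0) / grid_size
    return xs, ys


def accumulate(
    coords: Sequence[TriCoordinate] | np.ndarray,
    weights: Sequence[float] | None = None,
    grid_size: int = 512,
) -> DensityGrid:
    """Nearest-pixel binning of triangle coordinates; total weight conserved.

    ``coords`` may be TriCoordinates or an (n, 2) array.  Points outside
    the triangle (beyond numerical tolerance) are an error.
    """
    if len(coords) == 0:
        return DensityGrid(np.zeros((grid_size, grid_size)))
    arr = np.array(
        [(c.x, c.y) if isinstance(c, TriCoordinate) else tuple(c)
         for c in coords],
        dtype=float,
    )
    bary = _barycentric(arr[:, 0], arr[:, 1])
    if (bary < -1e-6).any():
        bad = arr[(bary < -1e-6).any(axis=-1)][0]
        raise ValueError(f"coordinate outside the triangle: {tuple(bad)}")
    w = np.ones(len(arr)) if weights is None else np.asarray(weights, float)
    x0, x1, y0, y1 = EXTENT
    col = ((arr[:, 0] - x0) / (x1 - x0) * grid_size).astype(int)
    row = ((y1 - arr[:, 1]) / (y1 - y0) * grid_size).astype(int)
    col = col.clip(0, grid_size - 1)
    row = row.clip(0, grid_size - 1)
    values = np.zeros((grid_size, grid_size))
    np.add.at(values, (row, col), w)
    return DensityGrid(values)


def smooth(grid: DensityGrid, sigma: float) -> DensityGrid:
    """Separable Gaussian smoothing in pixel units; sigma 0 is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be ≥ 0")
    if sigma == 0:
        return DensityGrid(grid.values.copy(), grid.extent)
    return DensityGrid(gaussian_filter(grid.values, sigma, mode="constant"),
                       grid.extent)


def ratio_grid(
    numerator: DensityGrid,
    denominator: DensityGrid,
    sigma: float = 0.0,
    min_denominator: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed numerator over smoothed denominator, masked where empty.

    Returns (ratio, valid_mask); ratio is NaN outside the mask.
    """
    num = smooth(numerator, sigma).values
    den = smooth(denominator, sigma).values
    valid = den > min_denominator
    out = np.full_like(num, np.nan)
    out[valid] = num[valid] / den[valid]
    return out, valid


def smooth_and_colorize(
    grid: DensityGrid,
    sigma: float,
    palette: str = "viridis",
    vmax: float | None = None,
) -> tuple[np.ndarray, dict]:
    """Smooth, normalise and pseudocolour a density grid.

    Returns an RGBA image array plus a legend dict (palette name, value
    range) so the colour scale can be reproduced exactly.
    """
    import matplotlib

    sm = smooth(grid, sigma).values
    top = float(sm.max()) if vmax is None else vmax
    norm = sm / top if top > 0 else sm
    rgba = matplotlib.colormaps[palette](norm.clip(0, 1))
    legend = {"palette": palette, "vmin": 0.0, "vmax": top, "sigma": sigma}
    return rgba, legend


def save_png(rgba: np.ndarray, path: str | Path) -> None:
    import matplotlib.pyplot as plt

    plt.imsave(str(path), rgba)


def write_grid_tsv(grid: DensityGrid, path: str | Path) -> None:
    np.savetxt(path, grid.values, delimiter="\t", fmt="%.10g")
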