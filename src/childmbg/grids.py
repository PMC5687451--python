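"""Raster grid container and text-based raster I/O.

Rasters are plain 2-D numpy arrays tied to a :class:`GridSpec` describing a
regular square-pixel grid in projected kilometre coordinates. Pixel indices
are 0-based row-major with row 0 at the top (north); pixel centres sit at
half-pixel offsets from the grid origin. On disk rasters use the ESRI ASCII
grid format, a plain-text header-plus-values layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster grid (distances in km)."""

    nrows: int
    ncols: int
    pixel_km: float = 5.0
    x0: float = 0.0  # west edge
    y0: float = 0.0  # south edge

    @property
    def shape(self) -> tuple[int, int]:
        return self.nrows, self.ncols

    @property
    def n_pixels(self) -> int:
        return self.nrows * self.ncols

    @property
    def pixel_area_km2(self) -> float:
        return self.pixel_km**2

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre coordinates, each shaped (nrows, ncols)."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.pixel_km
        ys = self.y0 + (self.nrows - np.arange(self.nrows) - 0.5) * self.pixel_km
        return np.meshgrid(xs, ys)

    def center_xy(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.x0 + (col + 0.5) * self.pixel_km
        y = self.y0 + (self.nrows - row - 0.5) * self.pixel_km
        return x, y

    def flat_centers(self) -> np.ndarray:
        """(n_pixels, 2) array of centre coordinates in row-major order."""
        xx, yy = self.centers()
        return np.column_stack([xx.ravel(), yy.ravel()])


def write_ascii_grid(path: str | Path, grid: GridSpec, values: np.ndarray) -> None:
    """Write a raster as an ESRI ASCII grid; NaNs become the nodata value."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(f"values shape {values.shape} != grid shape {grid.shape}")
    out = np.where(np.isnan(values), NODATA, values)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.x0}\n"
        f"yllcorner {grid.y0}\n"
        f"cellsize {grid.pixel_km}\n"
        f"NODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid; nodata values become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    grid = GridSpec(
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
        pixel_km=header["cellsize"],
        x0=header["xllcorner"],
        y0=header["yllcorner"],
    )
    values = np.atleast_2d(values)
    nodata = header.get("nodata_value", NODATA)
    values = np.where(values == nodata, np.nan, values)
    if values.shape != grid.shape:
        raise ValueError(f"data shape {values.shape} does not match header {grid.shape}")
    return grid, values
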