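"""Lightweight georeferenced grids.

A :class:`RasterLayer` is a 2-D numpy array anchored to a north-west corner
with square pixels; row 0 is the northern-most row.  A :class:`GridSpec`
describes the coarser analysis grid that all layers are summarized to.  Cell
extents are half-open squares ``[x, x+s) x (y-s, y]`` and cell ids run
row-major from the NW corner.

Rasters round-trip through the ESRI ASCII grid format (plain text), which
keeps fixtures and pipeline artifacts reviewable and avoids a hard dependency
on GDAL-backed readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GridSpec", "RasterLayer", "read_ascii_grid", "write_ascii_grid"]


@dataclass(frozen=True)
class GridSpec:
    """Analysis grid anchored at its NW corner."""

    origin_x: float
    origin_y: float
    cell_size_m: float
    n_rows: int
    n_cols: int
    crs: str = "local"

    def __post_init__(self) -> None:
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must contain at least one cell")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size_m**2 / 10_000.0

    def cell_id(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def rowcol_of(self, cell_id: np.ndarray | int) -> tuple[np.ndarray, np.ndarray]:
        cell_id = np.asarray(cell_id)
        return cell_id // self.n_cols, cell_id % self.n_cols

    def cell_of_point(self, x, y):
        """Row/col containing (x, y); -1 where outside the grid."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size_m).astype(int)
        row = np.floor((self.origin_y - y) / self.cell_size_m).astype(int)
        # northern edge belongs to row 0 (y == origin_y)
        row = np.where(
            np.isclose(self.origin_y - y, row * self.cell_size_m) | (y < self.origin_y),
            row,
            row,
        )
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        return row, col

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.origin_x + (col + 0.5) * self.cell_size_m
        y = self.origin_y - (row + 0.5) * self.cell_size_m
        return x, y

    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size_m,
            self.origin_x + self.n_cols * self.cell_size_m,
            self.origin_y,
        )


@dataclass
class RasterLayer:
    """Single-band raster with NW-corner anchoring and square pixels."""

    data: np.ndarray
    origin_x: float
    origin_y: float
    pixel_size: float
    nodata: float = -9999.0
    crs: str = "local"
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """x (1-D, per column) and y (1-D, per row) of pixel centers."""
        nr, nc = self.data.shape
        x = self.origin_x + (np.arange(nc) + 0.5) * self.pixel_size
        y = self.origin_y - (np.arange(nr) + 0.5) * self.pixel_size
        return x, y

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.data) & (self.data != self.nodata)

    def crop_to(self, grid: GridSpec) -> "RasterLayer":
        """Clip to the grid's bounding box (pixel-aligned, conservative)."""
        xmin, ymin, xmax, ymax = grid.extent()
        x, y = self.pixel_centers()
        cols = np.where((x >= xmin) & (x <= xmax))[0]
        rows = np.where((y >= ymin) & (y <= ymax))[0]
        if len(cols) == 0 or len(rows) == 0:
            raise ValueError("raster does not overlap the grid")
        sub = self.data[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
        return RasterLayer(
            sub,
            self.origin_x + cols[0] * self.pixel_size,
            self.origin_y - rows[0] * self.pixel_size,
            self.pixel_size,
            nodata=self.nodata,
            crs=self.crs,
            name=self.name,
        )

    def cell_index_of_pixels(self, grid: GridSpec) -> np.ndarray:
        """Flat analysis-cell id for every pixel (-1 outside the grid)."""
        x, y = self.pixel_centers()
        xx, yy = np.meshgrid(x, y)
        row, col = grid.cell_of_point(xx.ravel(), yy.ravel())
        out = np.where((row >= 0) & (col >= 0), row * grid.n_cols + col, -1)
        return out.reshape(self.data.shape)


def write_ascii_grid(layer: RasterLayer, path: str | Path) -> None:
    """Write an ESRI ASCII grid (text; yllcorner convention)."""
    nr, nc = layer.data.shape
    yll = layer.origin_y - nr * layer.pixel_size
    header = (
        f"ncols {nc}\n"
        f"nrows {nr}\n"
        f"xllcorner {layer.origin_x:.6f}\n"
        f"yllcorner {yll:.6f}\n"
        f"cellsize {layer.pixel_size:.6f}\n"
        f"NODATA_value {layer.nodata}\n"
    )
    body = np.where(np.isfinite(layer.data), layer.data, layer.nodata)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.6f")


def read_ascii_grid(path: str | Path, name: str = "") -> RasterLayer:
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    nodata = header.get("nodata_value", -9999.0)
    data = np.where(data == nodata, np.nan, data)
    pixel = header["cellsize"]
    origin_y = header["yllcorner"] + header["nrows"] * pixel
    return RasterLayer(
        data,
        header["xllcorner"],
        origin_y,
        pixel,
        nodata=nodata,
        name=name or Path(path).stem,
    )
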