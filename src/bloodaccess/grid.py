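"""Planar raster grid container and text raster I/O.

All rasters in this package live on a common planar grid in projected metre
coordinates: row 0 is the northernmost row, columns increase eastwards, and
every layer of one analysis shares the same shape, origin and cell size.
Rasters are serialised as ESRI ASCII grids (``.asc``), a plain-text format
readable by every mainstream GIS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["Grid", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class Grid:
    """A single-band raster on a planar grid.

    Parameters
    ----------
    data : ndarray of shape (rows, cols)
        Cell values. Row 0 is the northmost row.
    x0, y0 : float
        Coordinates (metres) of the *outer corner* of the top-left cell,
        i.e. the west edge and north edge of the grid.
    cell_size : float
        Cell edge length in metres (square cells).
    nodata : float
        Sentinel marking cells outside the study area.
    """

    data: np.ndarray
    x0: float = 0.0
    y0: float = 0.0
    cell_size: float = 100.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("Grid data must be 2-D (rows, cols)")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and self.x0 == other.x0
            and self.y0 == other.y0
            and self.cell_size == other.cell_size
        )

    def cell_center(self, row: np.ndarray, col: np.ndarray):
        """Planar coordinates of cell centers for (row, col) indices."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.x0 + (col + 0.5) * self.cell_size
        y = self.y0 - (row + 0.5) * self.cell_size
        return x, y

    def index_of(self, x, y):
        """(row, col) of the cells containing points (x, y).

        Half-open pixel convention: a point on the west/north edge of a cell
        belongs to that cell; points on the east/south boundary of the grid
        are out of range.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row = np.floor((self.y0 - y) / self.cell_size).astype(int)
        nr, nc = self.shape
        if np.any((row < 0) | (row >= nr) | (col < 0) | (col >= nc)):
            raise ValueError("point(s) outside the grid extent")
        return row, col

    def sample(self, x, y):
        """Values at the cells containing points (x, y)."""
        row, col = self.index_of(x, y)
        return self.data[row, col]

    def is_nodata(self) -> np.ndarray:
        if np.issubdtype(self.data.dtype, np.floating):
            return np.isnan(self.data) | (self.data == self.nodata)
        return self.data == self.nodata

    def copy_with(self, data: np.ndarray) -> "Grid":
        """New grid with the same georeferencing, different values."""
        return replace(self, data=np.asarray(data))


def write_ascii_grid(grid: Grid, path: str | Path) -> None:
    """Write a grid as an ESRI ASCII raster (text)."""
    path = Path(path)
    nr, nc = grid.shape
    yll = grid.y0 - nr * grid.cell_size
    header = (
        f"ncols {nc}\n"
        f"nrows {nr}\n"
        f"xllcorner {grid.x0!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    data = np.where(np.isnan(np.asarray(grid.data, dtype=float)), grid.nodata, grid.data)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> Grid:
    """Read an ESRI ASCII raster written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, value = line.strip().partition(" ")
            header[key.lower()] = float(value)
            pos = fh.tell()
        fh.seek(pos)
        data = np.loadtxt(fh)
    nr = int(header["nrows"])
    nc = int(header["ncols"])
    data = data.reshape(nr, nc)
    cell = header["cellsize"]
    return Grid(
        data=data,
        x0=header["xllcorner"],
        y0=header["yllcorner"] + nr * cell,
        cell_size=cell,
        nodata=header.get("nodata_value", -9999.0),
    )
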