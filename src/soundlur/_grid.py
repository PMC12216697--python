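"""Minimal planar raster grid with plain-text (ESRI ASCII grid) round-trip.

All coordinates are projected planar meters. Row index ``i`` increases
northward (``values[0]`` is the southernmost row); the on-disk ASCII grid
convention (top row first) is handled in the I/O functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid", "write_ascii_grid"]

NODATA = -9999.0


@dataclass
class RasterGrid:
    """A registered 2-D grid of values on a planar frame.

    Parameters
    ----------
    values
        Array of shape ``(ny, nx)``; row 0 is the southernmost row.
    x0, y0
        Coordinates of the lower-left corner of the grid (meters).
    cell_size
        Cell pitch in meters (square cells).
    classes
        For categorical grids, the class labels indexed by the integer
        codes stored in ``values``.
    """

    values: np.ndarray
    x0: float = 0.0
    y0: float = 0.0
    cell_size: float = 50.0
    classes: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")

    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.nx * self.cell_size,
            self.y0 + self.ny * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates as broadcastable 1-D arrays (xs, ys)."""
        xs = self.x0 + (np.arange(self.nx) + 0.5) * self.cell_size
        ys = self.y0 + (np.arange(self.ny) + 0.5) * self.cell_size
        return xs, ys

    def center_of(self, i: int, j: int) -> tuple[float, float]:
        return (
            self.x0 + (j + 0.5) * self.cell_size,
            self.y0 + (i + 0.5) * self.cell_size,
        )

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(i, j) of the cell containing the point; raises if outside."""
        j = int(np.floor((x - self.x0) / self.cell_size))
        i = int(np.floor((y - self.y0) / self.cell_size))
        if not (0 <= i < self.ny and 0 <= j < self.nx):
            raise ValueError(f"point ({x}, {y}) outside grid extent {self.extent}")
        return i, j

    def value_at(self, x: float, y: float):
        i, j = self.index_of(x, y)
        return self.values[i, j]

    def registered_with(self, other: "RasterGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and self.x0 == other.x0
            and self.y0 == other.y0
            and self.cell_size == other.cell_size
        )

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(values, self.x0, self.y0, self.cell_size, self.classes)


def write_ascii_grid(grid: RasterGrid, path) -> None:
    """Write an ESRI ASCII grid (text). NaN becomes the nodata value."""
    vals = np.asarray(grid.values, dtype=float)
    out = np.where(np.isfinite(vals), vals, NODATA)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.nx}\n")
        fh.write(f"nrows {grid.ny}\n")
        fh.write(f"xllcorner {grid.x0:.6f}\n")
        fh.write(f"yllcorner {grid.y0:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"NODATA_value {NODATA:.1f}\n")
        # top row first on disk
        for row in out[::-1]:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_ascii_grid(path) -> RasterGrid:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        rows = [np.fromstring(line, sep=" ") for line in fh if line.strip()]
    vals = np.vstack(rows)[::-1]
    nodata = header.get("nodata_value", NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    return RasterGrid(
        vals,
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        cell_size=header["cellsize"],
    )
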