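"""Planar raster grids and ESRI ASCII grid I/O.

Rasters follow the ESRI ASCII convention: row 0 is the northernmost row,
``(xllcorner, yllcorner)`` is the lower-left corner of the lower-left cell,
and all coordinates are planar metric (meters).  Zonal statistics in this
package sample geometry at cell centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "read_esri_ascii", "write_esri_ascii"]

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


@dataclass
class RasterGrid:
    """A rectangular raster with planar metric coordinates.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values, row 0 northernmost.
    xll, yll : float
        Coordinates of the lower-left corner of the grid (meters).
    cellsize : float
        Cell edge length in meters; must be positive.
    nodata : float
        Sentinel for missing cells.
    """

    values: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D matrix")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        return (
            self.xll,
            self.yll,
            self.xll + self.ncols * self.cellsize,
            self.yll + self.nrows * self.cellsize,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of cell-center coordinates, shape (nrows, ncols)."""
        cs = self.cellsize
        xs = self.xll + (np.arange(self.ncols) + 0.5) * cs
        ys = self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * cs
        return np.meshgrid(xs, ys)

    def mask_valid(self) -> np.ndarray:
        """Boolean mask of cells that are not nodata and not NaN."""
        v = self.values
        return ~(np.isnan(v) | np.isclose(v, self.nodata))

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing planar point (x, y)."""
        col = int(np.floor((x - self.xll) / self.cellsize))
        row = self.nrows - 1 - int(np.floor((y - self.yll) / self.cellsize))
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise IndexError(f"point ({x}, {y}) outside raster bounds {self.bounds}")
        return row, col

    def value_at(self, x: float, y: float) -> float:
        r, c = self.index_of(x, y)
        return float(self.values[r, c])

    def window(self, xmin: float, ymin: float, xmax: float, ymax: float) -> "RasterGrid":
        """Extract the sub-grid of cells whose centers fall in the box (clipped)."""
        cs = self.cellsize
        c0 = max(0, int(np.floor((xmin - self.xll) / cs)))
        c1 = min(self.ncols, int(np.ceil((xmax - self.xll) / cs)))
        r0 = max(0, self.nrows - int(np.ceil((ymax - self.yll) / cs)))
        r1 = min(self.nrows, self.nrows - int(np.floor((ymin - self.yll) / cs)))
        if r0 >= r1 or c0 >= c1:
            raise ValueError("window does not intersect the raster")
        sub = self.values[r0:r1, c0:c1].copy()
        return RasterGrid(
            sub,
            xll=self.xll + c0 * cs,
            yll=self.yll + (self.nrows - r1) * cs,
            cellsize=cs,
            nodata=self.nodata,
        )

    def like(self, values: np.ndarray) -> "RasterGrid":
        """A new grid sharing this grid's georeferencing."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise ValueError("shape mismatch with template grid")
        return RasterGrid(values, self.xll, self.yll, self.cellsize, self.nodata)


def read_esri_ascii(path: str | Path) -> RasterGrid:
    """Parse an ESRI ASCII grid file.

    Raises ``ValueError`` naming the offending line for malformed headers.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        lines = fh.readlines()
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed header at line {i + 1}: {line!r}") from exc
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise ValueError(f"{path}: missing header keys {missing} (header ends at line {i + 1})")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)
    data = np.loadtxt(lines[i:], dtype=float, ndmin=2)
    flat = data.ravel()
    if flat.size != nrows * ncols:
        raise ValueError(
            f"{path}: expected {nrows * ncols} values, found {flat.size} (data starts line {i + 1})"
        )
    return RasterGrid(
        flat.reshape(nrows, ncols),
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=nodata,
    )


def write_esri_ascii(grid: RasterGrid, path: str | Path, fmt: str = "%.6g") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xll:.6f}\n")
        fh.write(f"yllcorner {grid.yll:.6f}\n")
        fh.write(f"cellsize {grid.cellsize:.6f}\n")
        fh.write(f"NODATA_value {grid.nodata:.6g}\n")
        vals = np.where(np.isnan(grid.values), grid.nodata, grid.values)
        np.savetxt(fh, vals, fmt=fmt)
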