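"""Raster grid container and ESRI ASCII grid I/O.

The :class:`RasterGrid` is the universal spatial carrier of the package: a
rectangular 2D field of values with a square cell size in meters, a map-space
origin, and a nodata mask.  Row 0 is the northernmost row (north-up), matching
the ESRI ASCII grid convention; the center of cell ``(r, c)`` sits at
``(xllcorner + (c + 0.5) * cellsize, yllcorner + (nrows - r - 0.5) * cellsize)``.

Only the single-cellsize ASCII grid dialect is supported (``ncols``, ``nrows``,
``xllcorner``, ``yllcorner``, ``cellsize``, ``NODATA_value`` header followed by
row-major values).  Projection metadata, when present, is carried opaquely and
never re-projected: all internal math is planar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "RasterFormatError", "read_ascii_grid", "write_ascii_grid"]

DEFAULT_NODATA = -9999.0


class RasterFormatError(ValueError):
    """Malformed raster file (reported with the offending line number)."""


@dataclass
class RasterGrid:
    """A north-up rectangular raster with square cells.

    Parameters
    ----------
    values
        2D float array, shape ``(nrows, ncols)``; row 0 is the northern edge.
    cell_size_m
        Edge length of a (square) cell in meters; must be positive.
    origin
        ``(xllcorner, yllcorner)`` map coordinates of the lower-left corner
        of the grid (the outer corner of cell ``(nrows - 1, 0)``).
    nodata_mask
        Boolean array of the same shape; True where no value is defined.
    """

    values: np.ndarray
    cell_size_m: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    crs: str | None = None  # opaque projection tag, never interpreted

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2D array")
        if not self.cell_size_m > 0:
            raise ValueError(f"cell_size_m must be positive, got {self.cell_size_m}")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("nodata_mask shape does not match values shape")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of the center of cell ``(row, col)``."""
        x0, y0 = self.origin
        s = self.cell_size_m
        return (x0 + (col + 0.5) * s, y0 + (self.nrows - row - 0.5) * s)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays ``(X, Y)`` of all cell-center coordinates, shape = grid shape."""
        x0, y0 = self.origin
        s = self.cell_size_m
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        X = x0 + (cols[None, :] + 0.5) * s
        Y = y0 + (self.nrows - rows[:, None] - 0.5) * s
        return np.broadcast_to(X, self.shape).copy(), np.broadcast_to(Y, self.shape).copy()

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Grid index of the cell containing map point ``(x, y)``."""
        x0, y0 = self.origin
        s = self.cell_size_m
        col = int(np.floor((x - x0) / s))
        row = self.nrows - 1 - int(np.floor((y - y0) / s))
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise IndexError(f"point ({x}, {y}) outside grid extent")
        return row, col

    def same_geometry(self, other: "RasterGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size_m - other.cell_size_m) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )

    def copy_with(self, values: np.ndarray, nodata_mask: np.ndarray | None = None) -> "RasterGrid":
        """A new grid sharing this grid's geometry but carrying new values."""
        mask = self.nodata_mask.copy() if nodata_mask is None else nodata_mask
        return RasterGrid(np.asarray(values, dtype=float), self.cell_size_m, self.origin, mask, self.crs)


# -- ESRI ASCII grid -------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc).

    ``NODATA_value`` is honored (optional, default -9999).  Raises
    :class:`RasterFormatError` with a line number on malformed headers.
    """
    path = Path(path)
    header: dict[str, float] = {}
    nodata = DEFAULT_NODATA
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if not parts:
            continue
        key = parts[0].lower()
        if key in _HEADER_KEYS or key == "nodata_value":
            if len(parts) != 2:
                raise RasterFormatError(f"{path}:{i + 1}: malformed header line {line!r}")
            try:
                val = float(parts[1])
            except ValueError as exc:
                raise RasterFormatError(f"{path}:{i + 1}: non-numeric header value {parts[1]!r}") from exc
            if key == "nodata_value":
                nodata = val
            else:
                header[key] = val
        else:
            break  # first data line
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise RasterFormatError(f"{path}: missing header field(s) {missing}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    try:
        data = np.loadtxt(lines[i:], dtype=float, ndmin=2)
        data = data.reshape(nrows, ncols)
    except ValueError as exc:
        raise RasterFormatError(f"{path}: data block does not parse to {nrows}x{ncols}: {exc}") from exc
    mask = data == nodata
    values = np.where(mask, np.nan, data)
    return RasterGrid(
        values,
        cell_size_m=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        nodata_mask=mask,
    )


def write_ascii_grid(grid: RasterGrid, path: str | Path, nodata: float = DEFAULT_NODATA, fmt: str = "%.10g") -> None:
    """Write ``grid`` as an ESRI ASCII grid; nodata cells get ``nodata``."""
    path = Path(path)
    vals = np.where(grid.nodata_mask, nodata, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.origin[0]:.10g}\n")
        fh.write(f"yllcorner {grid.origin[1]:.10g}\n")
        fh.write(f"cellsize {grid.cell_size_m:.10g}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        np.savetxt(fh, vals, fmt=fmt)
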