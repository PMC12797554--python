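"""Planar axis-aligned raster grids.

Convention used throughout the package: the grid origin is the lower-left
corner of the raster, x grows east and y grows north, and the centre of cell
``(row, col)`` sits at ``(x0 + (col + 0.5) * cell_size,
y0 + (row + 0.5) * cell_size)``.  Row 0 is therefore the *southernmost* row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["RasterGrid", "GridMismatchError", "read_raster", "write_raster"]

#: hectares per square metre
_M2_PER_HA = 10_000.0


class GridMismatchError(ValueError):
    """Raised when two rasters that must be co-registered are not."""


@dataclass
class RasterGrid:
    """A single-band raster with planar georeferencing.

    Parameters
    ----------
    origin : (float, float)
        Lower-left corner ``(x0, y0)`` in metres.
    cell_size : float
        Side length of a (square) cell in metres; must be positive.
    values : numpy.ndarray
        2-D array of cell values, shape ``(n_rows, n_cols)``, row 0 south.
    nodata : float or int, optional
        Marker for cells carrying no value.
    """

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray
    nodata: float | int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- geometry ---------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def width_m(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def height_m(self) -> float:
        return self.n_rows * self.cell_size

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size * self.cell_size / _M2_PER_HA

    @property
    def area_ha(self) -> float:
        return self.values.size * self.cell_area_ha

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(x, y)`` coordinate arrays of all cell centres."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing point ``(x, y)``."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y - y0) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"point ({x}, {y}) outside raster extent")
        return row, col

    def same_grid(self, other: "RasterGrid", *, check_cell: bool = True) -> bool:
        """True if ``other`` shares origin, shape and (optionally) cell size."""
        return (
            np.isclose(self.origin[0], other.origin[0])
            and np.isclose(self.origin[1], other.origin[1])
            and self.values.shape == other.values.shape
            and (not check_cell or np.isclose(self.cell_size, other.cell_size))
        )

    def require_same_grid(self, other: "RasterGrid", what: str = "raster") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what} is not co-registered: origin/shape/cell-size differ "
                f"({self.origin}, {self.values.shape}, {self.cell_size}) vs "
                f"({other.origin}, {other.values.shape}, {other.cell_size})"
            )

    def mask_valid(self) -> np.ndarray:
        """Boolean mask of cells that are not nodata."""
        if self.nodata is None:
            return np.ones_like(self.values, dtype=bool)
        if isinstance(self.nodata, float) and np.isnan(self.nodata):
            return ~np.isnan(self.values)
        return self.values != self.nodata


# -- persistence ----------------------------------------------------------
def write_raster(grid: RasterGrid, path: str | Path) -> Path:
    """Write a :class:`RasterGrid` as a single-band TIFF.

    Heights/biomass are stored as float32, integer labels as int16.
    Georeferencing (origin, cell size, nodata, row order) goes into the TIFF
    image description as JSON so a round trip is lossless.
    """
    path = Path(path)
    arr = grid.values
    if np.issubdtype(arr.dtype, np.integer):
        data = arr.astype(np.int16)
    else:
        data = arr.astype(np.float32)
    meta = {
        "origin": list(grid.origin),
        "cell_size": grid.cell_size,
        "nodata": grid.nodata,
        "row_order": "south_to_north",
    }
    tifffile.imwrite(path, data, description=json.dumps(meta))
    return path


def read_raster(path: str | Path) -> RasterGrid:
    """Read a TIFF written by :func:`write_raster`."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        desc = page.tags.get("ImageDescription")
        if desc is None:
            raise ValueError(f"{path} carries no grid metadata")
        meta = json.loads(desc.value)
    return RasterGrid(
        origin=tuple(meta["origin"]),
        cell_size=float(meta["cell_size"]),
        values=data,
        nodata=meta.get("nodata"),
    )
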