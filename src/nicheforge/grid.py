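"""Raster grid and stack containers.

All rasters live on a regular lon/lat grid in WGS 84 (EPSG:4326). Arrays are
float64 with NaN as the nodata sentinel; row 0 is the northernmost row and
cells are addressed row-major. A point belongs to the cell whose half-open
interval [west, east) x [south, north) contains it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

#: authalic Earth radius, km (sphere with the same surface area as the WGS 84 ellipsoid)
EARTH_RADIUS_KM = 6371.0072

_ALIGN_TOL = 1e-9


class GridError(ValueError):
    """Raised for inconsistent grid geometry or mismatched grids."""


@dataclass(frozen=True)
class RasterGrid:
    """Geometry of a regular lon/lat raster.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; both must be >= 1.
    west, south, east, north
        Bounding box in decimal degrees.

    The cell size is derived from the extent and must be equal (within
    1e-9 degrees) along both axes.
    """

    n_rows: int
    n_cols: int
    west: float
    south: float
    east: float
    north: float

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise GridError("grid must have at least one row and one column")
        if not (self.east > self.west and self.north > self.south):
            raise GridError("extent must satisfy east > west and north > south")
        if not (-180.0 - _ALIGN_TOL <= self.west and self.east <= 180.0 + _ALIGN_TOL):
            raise GridError("longitude extent outside [-180, 180]")
        if not (-90.0 - _ALIGN_TOL <= self.south and self.north <= 90.0 + _ALIGN_TOL):
            raise GridError("latitude extent outside [-90, 90]")
        if abs(self.cell_width - self.cell_height) > _ALIGN_TOL:
            raise GridError(
                f"cells must be square: width {self.cell_width!r} != height {self.cell_height!r}"
            )

    @property
    def cell_width(self) -> float:
        return (self.east - self.west) / self.n_cols

    @property
    def cell_height(self) -> float:
        return (self.north - self.south) / self.n_rows

    @property
    def cell_size(self) -> float:
        """Cell edge length in degrees."""
        return self.cell_width

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    # --- point <-> cell mapping -------------------------------------------------

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Return (row, col) of the cell containing the point, or None if outside.

        The containing cell is the one whose half-open box
        [cell_west, cell_east) x [cell_south, cell_north) holds the point.
        """
        if not (self.west <= lon < self.east) or not (self.south <= lat < self.north):
            return None
        col = int(np.floor((lon - self.west) / self.cell_width))
        row_from_bottom = int(np.floor((lat - self.south) / self.cell_height))
        row = self.n_rows - 1 - row_from_bottom
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell (row, col)."""
        lon = self.west + (col + 0.5) * self.cell_width
        lat = self.north - (row + 0.5) * self.cell_height
        return lon, lat

    def flat_index(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def unflatten(self, flat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        flat = np.asarray(flat, dtype=np.int64)
        return flat // self.n_cols, flat % self.n_cols

    def lat_centers(self) -> np.ndarray:
        """Latitude of each row's cell centers, north to south."""
        return self.north - (np.arange(self.n_rows) + 0.5) * self.cell_height

    def lon_centers(self) -> np.ndarray:
        return self.west + (np.arange(self.n_cols) + 0.5) * self.cell_width

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RasterGrid):
            return NotImplemented
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.west - other.west) <= _ALIGN_TOL
            and abs(self.south - other.south) <= _ALIGN_TOL
            and abs(self.east - other.east) <= _ALIGN_TOL
            and abs(self.north - other.north) <= _ALIGN_TOL
        )

    def __hash__(self) -> int:
        return hash((self.n_rows, self.n_cols))


@dataclass
class Raster:
    """A single-band raster: a float array on a grid, NaN = nodata."""

    grid: RasterGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise GridError(
                f"array shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True on valid (non-nodata) cells."""
        return ~np.isnan(self.values)

    def at_cells(self, flat_indices: np.ndarray) -> np.ndarray:
        return self.values.ravel()[np.asarray(flat_indices, dtype=np.int64)]


@dataclass
class RasterStack:
    """Aligned multi-variable environmental stack for one period / climate source.

    ``variables`` preserves insertion order; all layers share the grid and the
    nodata mask.
    """

    grid: RasterGrid
    variables: dict[str, np.ndarray]
    period_label: str = "present"
    source_model_label: str = "observed"

    def __post_init__(self) -> None:
        if not self.variables:
            raise GridError("stack must contain at least one variable")
        cleaned: dict[str, np.ndarray] = {}
        ref_mask: np.ndarray | None = None
        for name, arr in self.variables.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.shape != self.grid.shape:
                raise GridError(f"variable {name!r} shape {arr.shape} != grid {self.grid.shape}")
            m = np.isnan(arr)
            if ref_mask is None:
                ref_mask = m
            elif not np.array_equal(ref_mask, m):
                raise GridError(f"nodata mask of variable {name!r} differs from the stack mask")
            cleaned[name] = arr
        self.variables = cleaned

    @property
    def var_names(self) -> list[str]:
        return list(self.variables)

    @property
    def mask(self) -> np.ndarray:
        first = next(iter(self.variables.values()))
        return ~np.isnan(first)

    @property
    def valid_flat_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask.ravel())

    def values_at_cells(self, flat_indices: Iterable[int], var_names: list[str] | None = None) -> np.ndarray:
        """Matrix (n_cells x n_vars) of variable values at the given flat cell indices."""
        idx = np.asarray(list(flat_indices) if not isinstance(flat_indices, np.ndarray) else flat_indices,
                         dtype=np.int64)
        names = var_names if var_names is not None else self.var_names
        missing = [n for n in names if n not in self.variables]
        if missing:
            raise KeyError(f"variables not in stack: {missing}")
        return np.column_stack([self.variables[n].ravel()[idx] for n in names])

    def subset(self, var_names: list[str]) -> "RasterStack":
        return RasterStack(
            grid=self.grid,
            variables={n: self.variables[n] for n in var_names},
            period_label=self.period_label,
            source_model_label=self.source_model_label,
        )


def require_same_grid(*objs) -> RasterGrid:
    grids = [o.grid for o in objs]
    first = grids[0]
    for g in grids[1:]:
        if g != first:
            raise GridError("rasters are not on the same grid")
    return first
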