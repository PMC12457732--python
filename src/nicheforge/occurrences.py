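"""Occurrence-record cleaning and rasterization to presence cells.

Herbarium-derived point records are standardized before modeling: rows with
missing or out-of-range coordinates and the (0, 0) null island point are
dropped, exact duplicates on (species, longitude, latitude) are collapsed to
their first appearance, and the survivors are mapped onto the environmental
grid. Modeling then operates on the resulting set of presence cells.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .grid import RasterGrid


@dataclass
class CleanReport:
    """Accounting of a cleaning pass; n_input = n_retained + all removals."""

    n_input: int = 0
    n_missing: int = 0
    n_invalid_coords: int = 0
    n_duplicates: int = 0
    n_out_of_grid: int = 0
    n_retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return asdict(self)

    def reconciles(self) -> bool:
        removals = self.n_missing + self.n_invalid_coords + self.n_duplicates + self.n_out_of_grid
        return self.n_input == self.n_retained + removals


@dataclass
class PresenceCells:
    """Occupied cells of one species on a grid (sorted unique flat indices)."""

    grid: RasterGrid
    cells: np.ndarray
    n_records_outside: int = 0

    def __post_init__(self) -> None:
        self.cells = np.unique(np.asarray(self.cells, dtype=np.int64))

    def __len__(self) -> int:
        return int(self.cells.size)


def clean_occurrences(records: pd.DataFrame) -> tuple[pd.DataFrame, CleanReport]:
    """Standardize an occurrence table.

    Removal order per record: missing coordinates (NaN, or the exact (0, 0)
    point, a standard marker for failed georeferencing), coordinates outside
    [-180, 180] x [-90, 90], then exact duplicates on
    (species, longitude, latitude) keeping the first in input order.
    An empty input yields an empty table and a zeroed report.
    """
    report = CleanReport(n_input=len(records))
    if len(records) == 0:
        return records.copy(), report

    df = records.copy().reset_index(drop=True)
    lon = pd.to_numeric(df["longitude"], errors="coerce")
    lat = pd.to_numeric(df["latitude"], errors="coerce")
    df["longitude"], df["latitude"] = lon, lat

    missing = lon.isna() | lat.isna() | ((lon == 0.0) & (lat == 0.0))
    report.n_missing = int(missing.sum())
    df = df[~missing]

    invalid = (df["longitude"].abs() > 180.0) | (df["latitude"].abs() > 90.0)
    report.n_invalid_coords = int(invalid.sum())
    df = df[~invalid]

    dup = df.duplicated(subset=["species", "longitude", "latitude"], keep="first")
    report.n_duplicates = int(dup.sum())
    df = df[~dup]

    report.n_retained = len(df)
    return df.reset_index(drop=True), report


def rasterize_presences(table: pd.DataFrame, grid: RasterGrid) -> PresenceCells:
    """Map records to their containing grid cells (half-open cell intervals).

    Multiple records in one cell collapse to a single presence cell; records
    outside the grid are counted and excluded. Raises if no record falls
    inside the grid.
    """
    flat: list[int] = []
    outside = 0
    for lon, lat in zip(table["longitude"].to_numpy(), table["latitude"].to_numpy()):
        rc = grid.cell_of(float(lon), float(lat))
        if rc is None:
            outside += 1
        else:
            flat.append(grid.flat_index(*rc))
    if not flat:
        raise ValueError("no occurrence record falls inside the grid")
    return PresenceCells(grid=grid, cells=np.asarray(flat, dtype=np.int64),
                         n_records_outside=outside)
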