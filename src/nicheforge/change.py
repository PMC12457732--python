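"""LPT binarization, range-change maps, and curvature-aware area accounting.

The consensus suitability map is binarized at the lowest presence threshold
(LPT) — the minimum predicted suitability at any known occurrence — so every
occurrence cell falls inside the predicted range by construction. Binary maps
for different periods are intersected into stable / lost / gained categories,
and areas are summed with the spherical per-cell area formula on WGS 84, so a
half-degree cell near the pole counts far less than one at the equator.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .ensemble import ConsensusRaster
from .grid import EARTH_RADIUS_KM, Raster, RasterGrid, require_same_grid
from .occurrences import PresenceCells

#: categorical codes for change maps
ABSENT, STABLE, LOST, GAINED = 0, 1, 2, 3
CHANGE_LABELS = {ABSENT: "absent", STABLE: "stable", LOST: "lost", GAINED: "gained"}


@dataclass
class BinaryRangeRaster:
    """Presence/absence raster: values in {0, 1, NaN}."""

    grid: RasterGrid
    values: np.ndarray
    threshold_used: float

    @property
    def mask(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass
class ChangeSummary:
    """Per-species area accounting between the present and one scenario."""

    species: str
    period_label: str
    present_area_km2: float
    scenario_area_km2: float
    stable_km2: float
    gained_km2: float
    lost_km2: float
    percent_change: float
    percent_maintained: float

    def as_dict(self) -> dict:
        return asdict(self)


def lowest_presence_threshold(consensus: ConsensusRaster,
                              presence_cells: PresenceCells) -> float:
    """Minimum consensus suitability over the species' occupied cells."""
    vals = consensus.at_cells(presence_cells.cells)
    bad = np.flatnonzero(np.isnan(vals))
    if bad.size:
        offenders = presence_cells.cells[bad].tolist()
        raise ValueError(f"presence cells on nodata consensus: {offenders}")
    return float(vals.min())


def binarize(consensus: ConsensusRaster | Raster, threshold: float) -> BinaryRangeRaster:
    """1 where suitability >= threshold (inclusive), 0 below, nodata preserved."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    vals = consensus.values
    out = np.where(np.isnan(vals), np.nan, (vals >= threshold).astype(np.float64))
    return BinaryRangeRaster(grid=consensus.grid, values=out, threshold_used=float(threshold))


def change_map(present: BinaryRangeRaster, scenario: BinaryRangeRaster) -> Raster:
    """Categorical raster: stable (1,1), lost (1,0), gained (0,1), absent (0,0)."""
    grid = require_same_grid(present, scenario)
    p, s = present.values, scenario.values
    out = np.full(grid.shape, np.nan)
    valid = ~np.isnan(p) & ~np.isnan(s)
    out[valid & (p == 1) & (s == 1)] = STABLE
    out[valid & (p == 1) & (s == 0)] = LOST
    out[valid & (p == 0) & (s == 1)] = GAINED
    out[valid & (p == 0) & (s == 0)] = ABSENT
    return Raster(grid=grid, values=out)


def cell_area_km2(row: int | np.ndarray, grid: RasterGrid) -> float | np.ndarray:
    """Spherical area of a cell in the given row (identical across a row).

    A = R^2 * dlambda * (sin(phi_north) - sin(phi_south)) with the authalic
    radius R = 6371.0072 km; accounts for the convergence of meridians.
    """
    row = np.asarray(row)
    if np.any(row < 0) or np.any(row >= grid.n_rows):
        raise ValueError("row outside grid")
    dlam = np.deg2rad(grid.cell_width)
    phi_n = np.deg2rad(grid.north - row * grid.cell_height)
    phi_s = np.deg2rad(grid.north - (row + 1) * grid.cell_height)
    area = EARTH_RADIUS_KM**2 * dlam * (np.sin(phi_n) - np.sin(phi_s))
    return float(area) if area.ndim == 0 else area


def total_area_km2(binary: BinaryRangeRaster) -> float:
    """Sum of per-cell spherical areas over presence cells."""
    row_areas = cell_area_km2(np.arange(binary.grid.n_rows), binary.grid)
    presence = np.nan_to_num(binary.values, nan=0.0)
    return float((presence.sum(axis=1) * row_areas).sum())


def percent_change(present_area: float, scenario_area: float) -> float:
    """(scenario - present) / present * 100; positive = expansion."""
    if present_area <= 0:
        raise ValueError("percent change undefined for zero present area")
    return (scenario_area - present_area) / present_area * 100.0


def summarize_change(species: str, present: BinaryRangeRaster,
                     scenario: BinaryRangeRaster, period_label: str) -> ChangeSummary:
    """Full area accounting between two binary range maps.

    stable + lost = present area and stable + gained = scenario area hold
    exactly (same cells, same per-cell areas).
    """
    cm = change_map(present, scenario)
    row_areas = cell_area_km2(np.arange(cm.grid.n_rows), cm.grid)

    def _area(code: int) -> float:
        cells = (cm.values == code).astype(np.float64)
        return float((cells.sum(axis=1) * row_areas).sum())

    stable, lost, gained = _area(STABLE), _area(LOST), _area(GAINED)
    present_area = stable + lost
    scenario_area = stable + gained
    return ChangeSummary(
        species=species,
        period_label=period_label,
        present_area_km2=present_area,
        scenario_area_km2=scenario_area,
        stable_km2=stable,
        gained_km2=gained,
        lost_km2=lost,
        percent_change=percent_change(present_area, scenario_area),
        # ratio first: stable == present_area must give exactly 100
        percent_maintained=(stable / present_area) * 100.0 if present_area > 0 else float("nan"),
    )
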