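"""Per-cell standard-deviation uncertainty maps.

Two families mirror the usual reporting of ensemble niche models: SD across
the per-GCM consensus maps (climate-source uncertainty) and SD across
per-algorithm sub-ensembles (method uncertainty). Sample SD (n-1 divisor);
cells with fewer than two valid members become nodata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import ConsensusRaster
from .grid import Raster, RasterGrid, require_same_grid


@dataclass
class UncertaintyRaster:
    grid: RasterGrid
    values: np.ndarray
    member_labels: list[str] = field(default_factory=list)


def sd_map(rasters: list[Raster | ConsensusRaster],
           member_labels: list[str] | None = None,
           ddof: int = 1) -> UncertaintyRaster:
    """Cell-wise sample standard deviation across member rasters."""
    if len(rasters) < 2:
        raise ValueError("at least 2 member rasters required")
    grid = require_same_grid(*rasters)
    cube = np.stack([r.values for r in rasters])
    valid = ~np.isnan(cube)
    count = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, np.nansum(cube, axis=0) / np.maximum(count, 1), np.nan)
        sq = np.nansum(np.where(valid, (cube - mean) ** 2, 0.0), axis=0)
        sd = np.where(count >= 2, np.sqrt(sq / np.maximum(count - ddof, 1)), np.nan)
    labels = member_labels if member_labels is not None else [f"member{i}" for i in range(len(rasters))]
    return UncertaintyRaster(grid=grid, values=sd, member_labels=list(labels))
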