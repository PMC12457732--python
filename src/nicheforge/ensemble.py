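"""TSS-squared weighted ensembling of retained replicate predictions.

Each retained replicate is first standardized by range normalization over its
own prediction raster, then the replicates are combined cell-wise by a
weighted mean with weights TSS_i^2, giving better-performing models more
influence. The same procedure applied within climate-model (GCM) groups
yields per-GCM consensus maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import Raster, RasterGrid, require_same_grid


class EnsembleError(ValueError):
    pass


@dataclass
class ConsensusRaster:
    """Weighted-mean suitability surface for one species and period."""

    grid: RasterGrid
    values: np.ndarray
    species: str = ""
    period_label: str = ""
    member_count: int = 0
    weight_sum: float = 0.0

    @property
    def mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def at_cells(self, flat_indices: np.ndarray) -> np.ndarray:
        return self.values.ravel()[np.asarray(flat_indices, dtype=np.int64)]

    def as_raster(self) -> Raster:
        return Raster(grid=self.grid, values=self.values)


def range_normalize(raster: Raster) -> Raster:
    """x' = (x - min) / (max - min) over the raster's valid cells.

    A constant raster cannot be normalized; reaching one here is a pipeline
    bug (a constant prediction cannot pass the TSS filter) and raises.
    """
    vals = raster.values
    lo = np.nanmin(vals)
    hi = np.nanmax(vals)
    if not np.isfinite(lo):
        raise EnsembleError("raster has no valid cells")
    if hi == lo:
        raise EnsembleError("constant raster cannot be range-normalized")
    return Raster(grid=raster.grid, values=(vals - lo) / (hi - lo))


def weighted_consensus(members: list[tuple[Raster, float]], species: str = "",
                       period_label: str = "",
                       renormalize_partial: bool = False) -> ConsensusRaster:
    """Per-cell weighted mean C = sum(tss_i^2 x_i) / sum(tss_i^2).

    By default a cell that is nodata in ANY member is nodata in the consensus
    (mask intersection); with ``renormalize_partial`` the mean is taken over
    the members valid at each cell instead.
    """
    if not members:
        raise EnsembleError("at least one member required")
    grid = require_same_grid(*[m[0] for m in members])
    weights = np.array([tss**2 for _, tss in members], dtype=np.float64)
    if weights.sum() <= 0:
        raise EnsembleError("all ensemble weights are zero")
    cube = np.stack([m[0].values for m in members])  # members x rows x cols

    if renormalize_partial:
        valid = ~np.isnan(cube)
        w = weights[:, None, None] * valid
        wsum = w.sum(axis=0)
        num = np.nansum(w * np.where(valid, cube, 0.0), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(wsum > 0, num / wsum, np.nan)
    else:
        values = np.tensordot(weights, cube, axes=(0, 0)) / weights.sum()

    return ConsensusRaster(grid=grid, values=values, species=species,
                           period_label=period_label, member_count=len(members),
                           weight_sum=float(weights.sum()))


def per_gcm_consensus(members: list[tuple[Raster, float, str]], species: str = "",
                      period_label: str = "") -> dict[str, ConsensusRaster]:
    """Group members by climate-model label and ensemble each group separately."""
    groups: dict[str, list[tuple[Raster, float]]] = {}
    for raster, tss, label in members:
        groups.setdefault(label, []).append((raster, tss))
    out: dict[str, ConsensusRaster] = {}
    for label, group in groups.items():
        if not group:
            warnings.warn(f"empty member group for {label!r}; omitted", stacklevel=2)
            continue
        out[label] = weighted_consensus(group, species=species, period_label=period_label)
    return out
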