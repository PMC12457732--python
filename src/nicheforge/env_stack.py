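"""Environmental stack preparation: resolution adjustment and collinearity pruning.

Predictor layers arrive at fine resolution and are block-aggregated to the
modeling resolution (e.g., 30 arc sec to 0.5 deg). Highly rank-correlated
predictors are then pruned with a greedy Spearman filter so no two retained
variables exceed the correlation threshold.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .grid import RasterGrid, RasterStack


class ResamplingError(ValueError):
    pass


def resample_stack(stack: RasterStack, target_cell_size: float) -> RasterStack:
    """Block-aggregate every layer to a coarser, integer-multiple cell size.

    Each output cell is the mean of its non-nodata source cells and nodata
    only when the whole block is nodata. The extent is preserved, so the grid
    dimensions must be divisible by the aggregation factor.
    """
    ratio = target_cell_size / stack.grid.cell_size
    factor = int(round(ratio))
    if factor < 1 or abs(ratio - factor) > 1e-9:
        raise ResamplingError(
            f"target cell size {target_cell_size} is not an integer multiple "
            f"of source cell size {stack.grid.cell_size}")
    if factor == 1:
        return stack
    g = stack.grid
    if g.n_rows % factor or g.n_cols % factor:
        raise ResamplingError(
            f"grid {g.shape} not divisible by aggregation factor {factor}")

    new_grid = RasterGrid(n_rows=g.n_rows // factor, n_cols=g.n_cols // factor,
                          west=g.west, south=g.south, east=g.east, north=g.north)
    out: dict[str, np.ndarray] = {}
    for name, arr in stack.variables.items():
        blocks = arr.reshape(new_grid.n_rows, factor, new_grid.n_cols, factor)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN blocks
            out[name] = np.nanmean(blocks, axis=(1, 3))
    return RasterStack(grid=new_grid, variables=out,
                       period_label=stack.period_label,
                       source_model_label=stack.source_model_label)


def spearman_matrix(stack: RasterStack, var_names: list[str] | None = None) -> np.ndarray:
    """Pairwise Spearman rank correlation over all valid cells (mid-ranks for ties)."""
    names = var_names or stack.var_names
    data = stack.values_at_cells(stack.valid_flat_indices, names)
    if len(names) == 1:
        return np.ones((1, 1))
    if len(names) == 2:  # scipy returns a scalar for exactly two columns
        r = float(stats.spearmanr(data[:, 0], data[:, 1]).statistic)
        return np.array([[1.0, r], [r, 1.0]])
    return np.asarray(stats.spearmanr(data).statistic)


def spearman_select(stack: RasterStack, threshold: float = 0.6,
                    priority: list[str] | None = None) -> list[str]:
    """Greedy collinearity pruning at a Spearman threshold.

    Scanning variables in ``priority`` order (default: stack order), a
    variable is kept iff its absolute rank correlation with every
    already-kept variable is <= threshold (inclusive, so a pair at exactly
    the threshold is allowed). Constant layers have undefined rank
    correlation and are excluded with a warning. Returns kept names in
    priority order.
    """
    names = stack.var_names
    priority = list(priority) if priority is not None else names
    if sorted(priority) != sorted(names):
        raise ValueError("priority must be a permutation of the stack's variable names")

    data = stack.values_at_cells(stack.valid_flat_indices, names)
    col = {n: i for i, n in enumerate(names)}
    constant = [n for n in names if np.nanstd(data[:, col[n]]) == 0]
    if constant:
        warnings.warn(f"constant variables excluded from selection: {constant}",
                      stacklevel=2)
    usable = [n for n in priority if n not in constant]
    if not usable:
        return []

    rho = spearman_matrix(stack.subset(usable) if len(usable) < len(names) else stack,
                          var_names=usable)
    idx = {n: i for i, n in enumerate(usable)}
    kept: list[str] = []
    for name in usable:
        if all(abs(rho[idx[name], idx[k]]) <= threshold for k in kept):
            kept.append(name)
    return kept
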