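"""Plain-text raster and table I/O.

Rasters are stored as ESRI ASCII grids (``.asc``) — a header of six
``key value`` lines followed by whitespace-separated cell values, row 0
(north) first. A multi-variable stack is a directory containing one ``.asc``
per variable plus ``stack.json`` with the variable order and period/source
labels. Occurrence tables are CSV with columns
``species, longitude, latitude, source``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import Raster, RasterGrid, RasterStack

_NODATA = -9999.0

OCCURRENCE_COLUMNS = ["species", "longitude", "latitude", "source"]


def write_ascii_grid(path: str | Path, raster: Raster) -> None:
    path = Path(path)
    g = raster.grid
    vals = np.where(np.isnan(raster.values), _NODATA, raster.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.west!r}\n")
        fh.write(f"yllcorner {g.south!r}\n")
        fh.write(f"cellsize {g.cell_size!r}\n")
        fh.write(f"nodata_value {_NODATA!r}\n")
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> Raster:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh, dtype=np.float64, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    cs = header["cellsize"]
    grid = RasterGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        west=header["xllcorner"],
        south=header["yllcorner"],
        east=header["xllcorner"] + n_cols * cs,
        north=header["yllcorner"] + n_rows * cs,
    )
    nodata = header.get("nodata_value", _NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    return Raster(grid=grid, values=vals)


def write_stack(directory: str | Path, stack: RasterStack) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, arr in stack.variables.items():
        write_ascii_grid(directory / f"{name}.asc", Raster(stack.grid, arr))
    meta = {
        "variables": stack.var_names,
        "period_label": stack.period_label,
        "source_model_label": stack.source_model_label,
    }
    (directory / "stack.json").write_text(json.dumps(meta, indent=2))


def read_stack(directory: str | Path) -> RasterStack:
    directory = Path(directory)
    meta = json.loads((directory / "stack.json").read_text())
    variables: dict[str, np.ndarray] = {}
    grid = None
    for name in meta["variables"]:
        r = read_ascii_grid(directory / f"{name}.asc")
        grid = r.grid
        variables[name] = r.values
    assert grid is not None
    return RasterStack(
        grid=grid,
        variables=variables,
        period_label=meta.get("period_label", "present"),
        source_model_label=meta.get("source_model_label", "observed"),
    )


def read_occurrences(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence CSV missing columns: {missing}")
    return df[OCCURRENCE_COLUMNS]


def write_occurrences(path: str | Path, table: pd.DataFrame) -> None:
    table[OCCURRENCE_COLUMNS].to_csv(path, index=False)


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
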