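"""Raster and climate-series I/O in plain-text formats.

Rasters are stored as ESRI ASCII grids (``.asc``): a six-line header
(ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value) followed by
rows of values, top row first.  A climate series is a directory of
per-step ``.asc`` rasters plus a ``times.json`` manifest mapping file
names to timestamps in years.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import InvalidInputError
from .grid import GridSpec
from .synthio import ClimateSeries

NODATA = -9999.0


def write_ascii_grid(path: str | Path, grid: GridSpec, values: np.ndarray) -> None:
    """Write one (n_rows, n_cols) raster; NaN becomes the NODATA value."""
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.n_rows, grid.n_cols):
        raise InvalidInputError("raster shape does not match the grid")
    out = np.where(np.isfinite(values), values, NODATA)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.x0}\n"
        f"yllcorner {grid.y0}\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value {NODATA}\n"
    )
    body = "\n".join(" ".join(f"{v:.10g}" for v in row) for row in out[::-1])
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid; NODATA cells become NaN."""
    lines = Path(path).read_text().splitlines()
    header = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        "xllcenter", "yllcenter",
    ):
        key, val = lines[i].split()[:2]
        header[key.lower()] = float(val)
        i += 1
    try:
        ncols, nrows = int(header["ncols"]), int(header["nrows"])
        cell = header["cellsize"]
    except KeyError as exc:
        raise InvalidInputError(f"ASCII grid header missing {exc}") from exc
    x0 = header.get("xllcorner", header.get("xllcenter", 0.0) - cell / 2)
    y0 = header.get("yllcorner", header.get("yllcenter", 0.0) - cell / 2)
    nodata = header.get("nodata_value", NODATA)
    data = np.loadtxt(lines[i:]).reshape(nrows, ncols)
    data = np.where(data == nodata, np.nan, data)[::-1]  # back to bottom-up rows
    return GridSpec(nrows, ncols, cell, x0, y0), data


def write_climate_series(cs: ClimateSeries, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for k, t in enumerate(cs.times):
        name = f"{cs.variable}_{k:04d}.asc"
        write_ascii_grid(out_dir / name, cs.grid, cs.values[k])
        manifest[name] = float(t)
    (out_dir / "times.json").write_text(
        json.dumps({"variable": cs.variable, "units": cs.units, "times": manifest}, indent=2)
    )


def read_climate_series(in_dir: str | Path) -> ClimateSeries:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "times.json").read_text())
    items = sorted(meta["times"].items(), key=lambda kv: kv[1])
    grids, values, times = [], [], []
    for name, t in items:
        g, v = read_ascii_grid(in_dir / name)
        grids.append(g)
        values.append(v)
        times.append(t)
    if len({(g.n_rows, g.n_cols, g.cell_size) for g in grids}) != 1:
        raise InvalidInputError("climate-series rasters disagree on grid shape")
    return ClimateSeries(grids[0], np.array(times), np.stack(values),
                         variable=meta.get("variable", "var"), units=meta.get("units", ""))
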