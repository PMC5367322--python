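"""File formats: point-cloud text tiles, TIFF rasters, plot tables.

Point clouds are stored as gzipped whitespace-separated text with the
columns ``x y z intensity range`` (z = height above ground, range in m),
one file per 30 m tile.  Rasters are written as single- or multi-band
float32/int16 TIFF with a JSON sidecar carrying the grid geometry (origin,
cell size), so round-trips preserve everything the pipeline consumes.
Field plots travel as plain CSV with the header
``plot_id,x,y,agb_Mg_ha,fc,gps_error_m``.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .lidar import PointCloudTile
from .scene import FieldPlot

__all__ = [
    "write_point_tile", "read_point_tile",
    "write_raster", "read_raster",
    "write_plots_csv", "read_plots_csv",
]


def write_point_tile(path: str | Path, tile: PointCloudTile,
                     cell_size_m: float = 30.0,
                     rng: np.random.Generator | None = None) -> None:
    """Write one tile as gzipped ``x y z intensity range`` text.

    Planimetric x/y are synthesized uniformly inside the cell footprint
    (the metrics are position-free within a cell); pass ``rng`` for
    reproducible coordinates.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = tile.n_returns
    r, c = tile.cell_id if tile.cell_id is not None else (0, 0)
    x = (c + rng.random(n)) * cell_size_m
    y = (r + rng.random(n)) * cell_size_m
    rng_m = tile.range_m if tile.range_m is not None else np.zeros(n)
    data = np.column_stack([x, y, tile.height_m, tile.intensity, rng_m])
    with gzip.open(path, "wt") as fh:
        fh.write(f"# cell {r} {c} area_m2 {tile.cell_area_m2}\n")
        np.savetxt(fh, data, fmt="%.6f")


def read_point_tile(path: str | Path) -> PointCloudTile:
    with gzip.open(path, "rt") as fh:
        header = fh.readline().strip().split()
        cell = (int(header[2]), int(header[3]))
        area = float(header[5])
        data = np.loadtxt(fh, ndmin=2)
    if data.size == 0:
        return PointCloudTile(np.empty(0), np.empty(0), np.empty(0),
                              cell_id=cell, cell_area_m2=area, empty_flag=True)
    return PointCloudTile(height_m=data[:, 2], intensity=data[:, 3],
                          range_m=data[:, 4], cell_id=cell, cell_area_m2=area)


def write_raster(path: str | Path, values: np.ndarray,
                 cell_size_m: float = 30.0,
                 origin: tuple[float, float] = (0.0, 0.0)) -> None:
    """Single- or multi-band raster as TIFF plus a JSON geometry sidecar."""
    path = Path(path)
    arr = np.asarray(values)
    if arr.dtype.kind == "f":
        arr = arr.astype(np.float32)
    tifffile.imwrite(path, arr)
    meta = {"cell_size_m": cell_size_m, "origin": list(origin),
            "shape": list(arr.shape), "dtype": str(arr.dtype)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_raster(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    arr = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return arr, meta


def write_plots_csv(path: str | Path, plots: list[FieldPlot],
                    cell_size_m: float = 30.0) -> None:
    rows = [{
        "plot_id": p.plot_id,
        "x": (p.cell[1] + 0.5) * cell_size_m,
        "y": (p.cell[0] + 0.5) * cell_size_m,
        "agb_Mg_ha": p.plot_agb_Mg_ha,
        "fc": p.fractional_cover,
        "gps_error_m": p.gps_error_m,
    } for p in plots]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plots_csv(path: str | Path, cell_size_m: float = 30.0) -> list[FieldPlot]:
    """Plots from CSV; tree lists are not persisted (plot AGB is)."""
    table = pd.read_csv(path)
    plots = []
    for _, row in table.iterrows():
        cell = (int(row["y"] // cell_size_m), int(row["x"] // cell_size_m))
        plots.append(FieldPlot(
            plot_id=int(row["plot_id"]), cell=cell, trees=[],
            plot_agb_Mg_ha=float(row["agb_Mg_ha"]),
            fractional_cover=float(row["fc"]),
            gps_error_m=float(row["gps_error_m"])))
    return plots
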