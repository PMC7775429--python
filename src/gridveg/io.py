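"""Cube I/O: NetCDF (CF-style time/y/x) and multi-band GeoTIFF stacks.

GeoTIFF stacks are stored as plain multi-page TIFFs (one band per time step)
with a YAML sidecar ``<path>.yaml`` carrying the grid spec, time axis, product
and variable names.  NetCDF files are classic-format (written through xarray's
scipy backend) with the same metadata in global attributes.  Invalid cells are
stored as NaN in both formats; valid values round-trip bit-exactly (float64).
"""

from __future__ import annotations

import os
from typing import Literal

import numpy as np
import tifffile
import xarray as xr
import yaml

from .cubes import ClimateCube, GridSpec, TimeAxis

Format = Literal["geotiff_stack", "netcdf"]


class CubeFormatError(ValueError):
    """Metadata inconsistent with the stored bands/dimensions."""


def _axis_to_meta(time: TimeAxis) -> dict:
    return {"resolution": time.resolution, "labels": [list(t) for t in time.labels]}


def _axis_from_meta(meta: dict) -> TimeAxis:
    return TimeAxis(meta["resolution"], tuple(tuple(t) for t in meta["labels"]))


def _grid_to_meta(grid: GridSpec) -> dict:
    return {
        "n_rows": grid.n_rows, "n_cols": grid.n_cols, "cell_size": grid.cell_size,
        "origin_x": grid.origin_x, "origin_y": grid.origin_y, "crs_label": grid.crs_label,
    }


def _grid_from_meta(meta: dict) -> GridSpec:
    return GridSpec(**meta)


def write_cube(cube: ClimateCube, path: str, fmt: Format) -> None:
    """Write a cube in one of the two native formats (invalid cells -> NaN)."""
    data = np.where(cube.valid_mask, cube.values, np.nan)
    if fmt == "geotiff_stack":
        tifffile.imwrite(path, data.astype(np.float64), photometric="minisblack")
        sidecar = {
            "product": cube.product, "variable": cube.variable,
            "grid": _grid_to_meta(cube.grid), "time": _axis_to_meta(cube.time),
        }
        with open(path + ".yaml", "w") as fh:
            yaml.safe_dump(sidecar, fh)
    elif fmt == "netcdf":
        ys, xs = cube.grid.pixel_centers()
        ds = xr.Dataset(
            {cube.variable: (("time", "y", "x"), data)},
            coords={"time": cube.time.to_datetimes(), "y": ys, "x": xs},
            attrs={
                "product": cube.product, "variable": cube.variable,
                "resolution": cube.time.resolution,
                "time_labels": yaml.safe_dump([list(t) for t in cube.time.labels]),
                "grid": yaml.safe_dump(_grid_to_meta(cube.grid)),
            },
        )
        ds.to_netcdf(path, engine="scipy")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_cube(path: str, fmt: Format) -> ClimateCube:
    """Read a cube; NaN/sentinel cells are marked invalid in the mask.

    Raises ``FileNotFoundError`` for missing files and
    :class:`CubeFormatError` when the stored band count disagrees with the
    declared time metadata.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt == "geotiff_stack":
        sidecar_path = path + ".yaml"
        if not os.path.exists(sidecar_path):
            raise FileNotFoundError(sidecar_path)
        with open(sidecar_path) as fh:
            meta = yaml.safe_load(fh)
        data = np.asarray(tifffile.imread(path), dtype=float)
        if data.ndim == 2:
            data = data[None, :, :]
        time = _axis_from_meta(meta["time"])
        grid = _grid_from_meta(meta["grid"])
        if data.shape[0] != len(time):
            raise CubeFormatError(
                f"{data.shape[0]} bands but {len(time)} declared time steps"
            )
        if data.shape[1:] != grid.shape:
            raise CubeFormatError("band shape does not match declared grid")
        return ClimateCube(meta["product"], meta["variable"], grid, time, data)
    elif fmt == "netcdf":
        with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
            ds = ds.load()
        grid = _grid_from_meta(yaml.safe_load(ds.attrs["grid"]))
        labels = tuple(tuple(t) for t in yaml.safe_load(ds.attrs["time_labels"]))
        time = TimeAxis(ds.attrs["resolution"], labels)
        var = ds.attrs["variable"]
        data = np.asarray(ds[var].values, dtype=float)
        if data.shape[0] != len(time):
            raise CubeFormatError(
                f"{data.shape[0]} time slices but {len(time)} declared time steps"
            )
        if data.shape[1:] != grid.shape:
            raise CubeFormatError("slice shape does not match declared grid")
        return ClimateCube(ds.attrs["product"], var, grid, time, data)
    raise ValueError(f"unknown format {fmt!r}")
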