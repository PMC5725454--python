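"""Standard-format I/O: NetCDF fields, triplet sparse matrices, CSV tables.

Gridded fields travel as CF-styled NetCDF (dimensions ``lat``, ``lon``,
``depth``; NetCDF-3 via the scipy backend so files remain dependency-light),
transport matrices as plain-text coordinate triplets with a JSON header
naming the grid, observations as CSV, and configuration as YAML.  All
round-trips are lossless for 64-bit floats.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import xarray as xr
import yaml

from .synthetic_ocean import (
    AncillaryFields,
    ConfigurationError,
    Grid,
    ObservationSet,
    Scenario,
    TransportMatrix,
    TruthScenario,
)

__all__ = [
    "FormatError",
    "grid_to_dataset",
    "dataset_to_grid",
    "write_netcdf",
    "read_netcdf",
    "write_transport",
    "read_transport",
    "write_observations",
    "read_observations",
    "write_config",
    "read_config",
    "save_scenario",
    "load_scenario",
]

NETCDF_ENGINE = "scipy"

TRANSPORT_MAGIC = "#docpump-transport"


class FormatError(ValueError):
    """A file does not match the expected dialect."""


# --------------------------------------------------------------------------
# gridded fields
# --------------------------------------------------------------------------

def grid_to_dataset(grid: Grid, fields: dict[str, np.ndarray] | None = None) -> xr.Dataset:
    """Pack grid geometry plus per-box/per-column fields into an xarray Dataset."""
    coords = {
        "lat": ("lat", grid.lat, {"units": "degrees_north"}),
        "lon": ("lon", np.arange(grid.n_lon), {"long_name": "basin sector index"}),
        "depth": ("depth", grid.z_center, {"units": "m", "positive": "down"}),
    }
    ds = xr.Dataset(coords=coords)
    ds["lat_edges"] = ("lat_edge", grid.lat_edges)
    ds["layer_bottoms"] = ("depth", grid.layer_bottoms, {"units": "m"})
    ds["density"] = (
        ("lat", "lon", "depth"),
        grid.density.reshape(grid.n_lat, grid.n_lon, grid.nz),
        {"units": "kg m-3"},
    )
    ds["euphotic_depth"] = (
        ("lat", "lon"), grid.euphotic_depth.reshape(grid.n_lat, grid.n_lon), {"units": "m"},
    )
    ds.attrs["basins"] = json.dumps(list(grid.basins))
    ds.attrs["Conventions"] = "CF-1.8"
    for name, v in (fields or {}).items():
        v = np.asarray(v, dtype=float)
        if v.shape == (grid.n_box,):
            ds[name] = (("lat", "lon", "depth"), v.reshape(grid.n_lat, grid.n_lon, grid.nz))
        elif v.shape == (grid.n_col,):
            ds[name] = (("lat", "lon"), v.reshape(grid.n_lat, grid.n_lon))
        else:
            raise ConfigurationError(f"field {name!r} has unexpected shape {v.shape}")
    return ds


def dataset_to_grid(ds: xr.Dataset) -> Grid:
    """Rebuild a :class:`Grid` from a dataset written by :func:`grid_to_dataset`."""
    try:
        basins = tuple(json.loads(ds.attrs["basins"]))
        return Grid(
            lat_edges=np.asarray(ds["lat_edges"].values, dtype=float),
            basins=basins,
            layer_bottoms=np.asarray(ds["layer_bottoms"].values, dtype=float),
            density=np.asarray(ds["density"].values, dtype=float).ravel(),
            euphotic_depth=np.asarray(ds["euphotic_depth"].values, dtype=float).ravel(),
        )
    except KeyError as exc:
        raise FormatError(f"dataset is missing grid variable/attribute {exc}") from exc


def write_netcdf(ds: xr.Dataset, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ds.to_netcdf(path, engine=NETCDF_ENGINE)
    return path


def read_netcdf(path: str | Path) -> xr.Dataset:
    return xr.load_dataset(path, engine=NETCDF_ENGINE)


def field_from_dataset(ds: xr.Dataset, name: str, grid: Grid) -> np.ndarray:
    """Flatten a stored field back to per-box (or per-column) ordering."""
    v = np.asarray(ds[name].values, dtype=float)
    return v.ravel()


# --------------------------------------------------------------------------
# transport triplets
# --------------------------------------------------------------------------

def write_transport(tm: TransportMatrix, path: str | Path, grid_name: str = "grid") -> Path:
    """Write a transport matrix as ``row,col,value`` triplets (yr⁻¹) with a
    JSON header line naming the grid and assembly parameters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    coo = tm.T.tocoo()
    header = {
        "grid": grid_name,
        "n_box": int(tm.n_box),
        "units": "yr-1",
        "seed": tm.seed,
        "params": {k: (float(v) if np.isscalar(v) else v) for k, v in tm.params.items()},
    }
    with open(path, "w") as fh:
        fh.write(f"{TRANSPORT_MAGIC} {json.dumps(header)}\n")
        fh.write("row,col,value\n")
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r},{c},{float(v)!r}\n")  # shortest lossless repr
    return path


def read_transport(path: str | Path, grid: Grid) -> TransportMatrix:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(TRANSPORT_MAGIC):
            raise FormatError(f"{path} is not a transport triplet file")
        header = json.loads(first[len(TRANSPORT_MAGIC):])
        df = pd.read_csv(fh, float_precision="round_trip")
    n = header["n_box"]
    if n != grid.n_box:
        raise FormatError(f"transport file is for {n} boxes, grid has {grid.n_box}")
    bad = df.index[(df.row < 0) | (df.row >= n) | (df.col < 0) | (df.col >= n)]
    if len(bad):
        # +3: magic line, column header, and 1-based file numbering
        raise FormatError(f"out-of-range box index at triplet row {int(bad[0]) + 3} of {path}")
    T = sp.coo_matrix((df.value, (df.row, df.col)), shape=(n, n)).tocsr()
    return TransportMatrix(T=T, grid=grid, params=header.get("params", {}),
                           seed=header.get("seed"))


# --------------------------------------------------------------------------
# observations
# --------------------------------------------------------------------------

def write_observations(obs: ObservationSet, grid: Grid, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    idx = obs.box_index
    pd.DataFrame({
        "box_index": idx,
        "lat": grid.box_lat[idx],
        "lon": np.tile(np.arange(grid.n_lon), grid.n_lat)[grid.box_col[idx]],
        "depth": grid.box_depth[idx],
        "basin": grid.box_basin[idx],
        "value": obs.values,
    }).to_csv(path, index=False, float_format="%.17g")
    return path


def read_observations(path: str | Path, grid: Grid) -> ObservationSet:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"box_index", "value"}
    if not required <= set(df.columns):
        raise FormatError(f"{path} lacks columns {sorted(required - set(df.columns))}")
    idx = df["box_index"].to_numpy(int)
    if (idx < 0).any() or (idx >= grid.n_box).any():
        raise FormatError(f"{path} has observation box indices outside the grid")
    return ObservationSet(
        box_index=idx, values=df["value"].to_numpy(float),
        fraction=np.nan, noise_sd=np.nan, withheld_basins=(), seed=None,
    )


# --------------------------------------------------------------------------
# config
# --------------------------------------------------------------------------

def write_config(config: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return path


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path} does not contain a mapping")
    return cfg


# --------------------------------------------------------------------------
# scenario bundles
# --------------------------------------------------------------------------

def save_scenario(scenario: Scenario, directory: str | Path) -> dict[str, Path]:
    """Write a scenario as NetCDF fields + transport triplets."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    g = scenario.grid
    t = scenario.truth
    ds = grid_to_dataset(g, {
        "doc": scenario.doc,
        "no3": scenario.no3,
        "j_prod": t.j_prod,
        "uptake": t.uptake,
        "background_doc": t.background_doc,
        "background_no3": t.background_no3,
        "sst": scenario.ancillary.sst,
        "npp": scenario.ancillary.npp,
        "f_pico": scenario.ancillary.f_pico,
        "c_export": scenario.ancillary.c_export,
    })
    ds.attrs.update({
        "lam_doc": t.lam_doc, "lam_no3": t.lam_no3,
        "production_depth": t.production_depth,
        "scenario_seed": scenario.seed,
        "ancillary_seed": -1 if scenario.ancillary.seed is None else scenario.ancillary.seed,
    })
    paths = {
        "fields": write_netcdf(ds, directory / "scenario.nc"),
        "transport": write_transport(scenario.transport, directory / "transport.csv"),
    }
    return paths


def load_scenario(directory: str | Path) -> Scenario:
    directory = Path(directory)
    ds = read_netcdf(directory / "scenario.nc")
    grid = dataset_to_grid(ds)
    transport = read_transport(directory / "transport.csv", grid)
    flat = lambda name: np.asarray(ds[name].values, dtype=float).ravel()
    truth = TruthScenario(
        j_prod=flat("j_prod"), uptake=flat("uptake"),
        lam_doc=float(ds.attrs["lam_doc"]), lam_no3=float(ds.attrs["lam_no3"]),
        background_doc=flat("background_doc"), background_no3=flat("background_no3"),
        production_depth=float(ds.attrs["production_depth"]),
        seed=int(ds.attrs["scenario_seed"]),
    )
    anc_seed = int(ds.attrs.get("ancillary_seed", -1))
    ancillary = AncillaryFields(
        sst=flat("sst"), npp=flat("npp"), f_pico=flat("f_pico"),
        c_export=flat("c_export"), no3_clim=flat("no3"),
        seed=None if anc_seed < 0 else anc_seed,
    )
    return Scenario(
        grid=grid, transport=transport, truth=truth,
        doc=flat("doc"), no3=flat("no3"), ancillary=ancillary,
        seed=int(ds.attrs["scenario_seed"]),
    )
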