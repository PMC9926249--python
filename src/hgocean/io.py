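"""NetCDF/CSV/YAML I/O and the run configuration.

State and forcing snapshots are written as classic NetCDF (xarray, scipy
backend) with CF-style unit attributes; diagnostics go to CSV with units in
the column names; the run configuration round-trips losslessly through YAML
with unknown keys rejected and a unit string recorded for every parameter.
Concentrations are stored in pM and fluxes in mol y-1 throughout (see
``hgocean.units`` for the single conversion table).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .forcing import FORCING_UNITS, ForcingCalibration, ForcingSet
from .grid import Grid
from .params import (PARAM_UNITS, PHYTO_GROUPS, ZOO_GROUPS, BioaccParams,
                     ExchangeParams, ModelParams, PartitionParams, RateParams)
from .transport import TRACERS, HgState


class ConfigError(ValueError):
    """Malformed configuration."""


class FileFormatError(ValueError):
    """Malformed state/forcing file."""


# --------------------------------------------------------------------------
# NetCDF state snapshots

_GRID_ATTRS = ("lat_edges", "depth_edges", "coastal_frac", "ocean_frac")


def _grid_attrs(grid: Grid) -> dict:
    return {
        "lat_edges": [float(v) for v in grid.lat_edges],
        "depth_edges": [float(v) for v in grid.depth_edges],
        "coastal_frac": grid.coastal_frac,
        "ocean_frac": grid.ocean_frac,
        "layer_index_convention": "0-based, layer 0 at the surface",
    }


def _grid_from_attrs(attrs) -> Grid:
    missing = [a for a in _GRID_ATTRS if a not in attrs]
    if missing:
        raise FileFormatError(f"file missing grid attributes: {missing}")
    return Grid(lat_edges=tuple(np.atleast_1d(attrs["lat_edges"])),
                depth_edges=tuple(np.atleast_1d(attrs["depth_edges"])),
                coastal_frac=float(attrs["coastal_frac"]),
                ocean_frac=float(attrs["ocean_frac"]))


def state_to_dataset(state: HgState) -> xr.Dataset:
    state.validate()
    g = state.grid
    coords = {
        "lat": ("band", g.lat_centers, {"units": "degrees_north"}),
        "region": ("region", ["open", "coastal"]),
        "depth": ("layer", g.z_centers, {"units": "m", "positive": "down"}),
    }
    data = {tr: (("band", "region", "layer"), getattr(state, tr),
                 {"units": "pM"}) for tr in TRACERS}
    ds = xr.Dataset(data, coords=coords, attrs=_grid_attrs(g))
    return ds


def write_state_netcdf(state: HgState, path) -> None:
    """Write a state snapshot; refuses states with negative concentrations."""
    state_to_dataset(state).to_netcdf(path, engine="scipy")


def read_state_netcdf(path) -> HgState:
    """Read a state snapshot; a missing tracer raises an error naming it."""
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    grid = _grid_from_attrs(ds.attrs)
    missing = [tr for tr in TRACERS if tr not in ds]
    if missing:
        raise FileFormatError(f"file missing tracer variable(s): {missing}")
    return HgState(grid, *(np.asarray(ds[tr].values, float)
                           for tr in TRACERS)).validate()


def forcing_to_dataset(f: ForcingSet) -> xr.Dataset:
    f.validate()
    g = f.grid
    dims4 = ("band", "region", "layer", "month")
    dims_srf = ("band", "region", "month")
    dims_if = ("band", "region", "interface", "month")
    data = {
        "t": (dims4, f.t), "chl": (dims4, f.chl), "doc": (dims4, f.doc),
        "poc": (dims4, f.poc), "ocrr": (dims4, f.ocrr),
        "u10": (dims_srf, f.u10), "f_ice": (dims_srf, f.f_ice),
        "i0": (dims_srf, f.i0),
        "k_mix": (dims_if, f.k_mix), "w_up": (dims_if, f.w_up),
        "biomass": (("group",) + dims4, f.biomass),
        "grazing": (("zoo_group", "phyto_group") + dims4, f.grazing),
        "zoo_mortality": (("zoo_group",) + dims4, f.zoo_mortality),
        "atm_hg0": (("band", "month"), f.atm_hg0),
        "dep_hg2": (("band", "month"), f.dep_hg2),
    }
    ds = xr.Dataset(
        {k: (d, v, {"units": FORCING_UNITS.get(k, "1")}) for k, (d, v) in data.items()},
        coords={
            "lat": ("band", g.lat_centers, {"units": "degrees_north"}),
            "region": ("region", ["open", "coastal"]),
            "depth": ("layer", g.z_centers, {"units": "m"}),
            "interface_depth": ("interface", g.z_interfaces, {"units": "m"}),
            "month": ("month", np.arange(1, g.n_months + 1)),
            "group": ("group", list(PHYTO_GROUPS + ZOO_GROUPS)),
            "zoo_group": ("zoo_group", list(ZOO_GROUPS)),
            "phyto_group": ("phyto_group", list(PHYTO_GROUPS)),
        },
        attrs={**_grid_attrs(g), "epoch": f.epoch})
    return ds


def write_forcing_netcdf(f: ForcingSet, path) -> None:
    forcing_to_dataset(f).to_netcdf(path, engine="scipy")


def read_forcing_netcdf(path) -> ForcingSet:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    grid = _grid_from_attrs(ds.attrs)
    fields = ("t", "u10", "f_ice", "i0", "chl", "doc", "poc", "ocrr",
              "biomass", "grazing", "zoo_mortality", "k_mix", "w_up",
              "atm_hg0", "dep_hg2")
    missing = [v for v in fields if v not in ds]
    if missing:
        raise FileFormatError(f"file missing forcing variable(s): {missing}")
    kw = {v: np.asarray(ds[v].values, float) for v in fields}
    return ForcingSet(epoch=str(ds.attrs.get("epoch", "present")), grid=grid,
                      **kw).validate()


# --------------------------------------------------------------------------
# Diagnostics CSV

def export_diagnostics_csv(table: pd.DataFrame, path) -> None:
    """One row per scenario, stable column order, units embedded in names.

    Missing entries are written as empty fields; re-export of identical input
    is byte-identical.
    """
    df = table.copy()
    df = df.reindex(sorted(df.columns), axis=1)
    df.index.name = "scenario"
    df.to_csv(path, float_format="%.10g", lineterminator="\n")


# --------------------------------------------------------------------------
# Run configuration

def _dataclass_from_dict(cls, d: dict, where: str):
    if not isinstance(d, dict):
        raise ConfigError(f"{where}: expected a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")
    kw = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kw[f.name] = v
    try:
        return cls(**kw)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"{where}: {e}") from e


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: grid, calibration, parameters,
    scenario list, seed and duration."""

    grid: Grid = field(default_factory=Grid)
    calib: ForcingCalibration = field(default_factory=ForcingCalibration)
    params: ModelParams = field(default_factory=ModelParams)
    scenarios: tuple = ("base",)
    seed: int = 0
    years: int = 10

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: clean(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return [clean(v) for v in obj]
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, np.floating):
                return float(obj)
            return obj
        d = clean(self)
        d["units"] = dict(PARAM_UNITS)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        if not isinstance(d, dict):
            raise ConfigError("config root must be a mapping")
        d = dict(d)
        d.pop("units", None)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"config: unknown keys {sorted(unknown)}")
        grid = _dataclass_from_dict(Grid, d.get("grid", {}), "grid")
        calib = _dataclass_from_dict(ForcingCalibration, d.get("calib", {}),
                                     "calib")
        pd_ = d.get("params", {})
        if not isinstance(pd_, dict):
            raise ConfigError("params: expected a mapping")
        unknown = set(pd_) - {"exchange", "rates", "partition", "bioacc"}
        if unknown:
            raise ConfigError(f"params: unknown keys {sorted(unknown)}")
        params = ModelParams(
            exchange=_dataclass_from_dict(ExchangeParams,
                                          pd_.get("exchange", {}),
                                          "params.exchange"),
            rates=_dataclass_from_dict(RateParams, pd_.get("rates", {}),
                                       "params.rates"),
            partition=_dataclass_from_dict(PartitionParams,
                                           pd_.get("partition", {}),
                                           "params.partition"),
            bioacc=_dataclass_from_dict(BioaccParams, pd_.get("bioacc", {}),
                                        "params.bioacc"),
        )
        return cls(grid=grid, calib=calib, params=params,
                   scenarios=tuple(d.get("scenarios", ("base",))),
                   seed=int(d.get("seed", 0)), years=int(d.get("years", 10)))


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return RunConfig.from_dict(d)
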