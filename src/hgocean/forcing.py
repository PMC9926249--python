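"""Synthetic present-day and 2100 (high-emission scenario) ocean forcings.

This module stands in for the archived earth-system-model / plankton
ecosystem fields that drive the mercury model.  Spatial patterns are smooth
analytic functions of latitude chosen to preserve the sign structure of the
projected changes (polar amplification of warming, extratropical wind
weakening with a tropical strengthening, polar sea-ice loss and shortwave
brightening with tropical dimming, reduced export production in upwelling
bands, a community shift from large eukaryotes toward *Synechococcus*), with
global-mean surface chlorophyll calibrated exactly to 2.52 mg m-3
(present day) and 1.17 mg m-3 (2100).  The seasonal cycle is a per-hemisphere
sinusoid; biogeochemical fields lag the radiation cycle by one month.

Three epochs are provided: ``present``, ``future`` and ``future_physics``;
the last equals ``future`` except that the ocean-acidification increment
(an OCRR enhancement and the *Synechococcus* community shift) is omitted.
Atmospheric Hg0 and HgII deposition are identical across epochs: the input
of Hg from the atmosphere is held constant so that differences between
scenarios isolate the ocean's response.

The random seed controls only a small (~5%), smooth, latitude-dependent
noise factor shared between epochs, so calibrated means and all inter-epoch
orderings (warming everywhere, ice loss, ...) survive any realization.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import Grid
from .params import PHYTO_GROUPS, ZOO_GROUPS

EPOCHS = ("present", "future", "future_physics")

FACTORS = ("circulation", "temperature", "radiation", "wind_speed", "sea_ice",
           "community_structure", "Chl", "DOC", "POC", "OCRR")

#: factor name -> ForcingSet field names it swaps in a scenario blend
FACTOR_FIELDS = {
    "circulation": ("k_mix", "w_up"),
    "temperature": ("t",),
    "radiation": ("i0",),
    "wind_speed": ("u10",),
    "sea_ice": ("f_ice",),
    "community_structure": ("biomass", "grazing", "zoo_mortality"),
    "Chl": ("chl",),
    "DOC": ("doc",),
    "POC": ("poc",),
    "OCRR": ("ocrr",),
}

FORCING_UNITS = {
    "t": "degC", "u10": "m s-1", "f_ice": "1", "i0": "W m-2",
    "chl": "mg m-3", "doc": "uM", "poc": "mg m-3", "ocrr": "mg C m-3 d-1",
    "biomass": "mg C m-3", "grazing": "mg C m-3 d-1",
    "zoo_mortality": "mg C m-3 d-1", "k_mix": "m2 s-1", "w_up": "m d-1",
    "atm_hg0": "ng m-3", "dep_hg2": "ug m-2 y-1",
}

#: reference prey density of the linear zooplankton functional response
PREY_REF_MG_M3 = 20.0


class ForcingError(ValueError):
    """Invalid forcing request or inconsistent forcing fields."""


@dataclass(frozen=True)
class ForcingCalibration:
    """Calibration constants and change amplitudes of the synthetic forcing.

    The chlorophyll means and the qualitative sign structure are fixed by the
    scenario being emulated; amplitudes without a printed counterpart are
    config-exposed here.
    """

    chl_surface_mean_present: float = 2.52   # mg m-3
    chl_surface_mean_future: float = 1.17    # mg m-3
    warming_surface_mean: float = 2.5        # degC, area-weighted
    wind_factor_extratropical: float = 0.90
    wind_factor_tropical: float = 1.03
    ice_loss_factor: float = 0.5
    rad_polar_brightening: float = 0.12      # fractional, poleward of ~45 deg
    rad_tropical_dimming: float = 0.03
    doc_future_factor: float = 1.10
    poc_factor_upwelling: float = 0.75
    poc_factor_background: float = 0.92
    poc_factor_coastal_surface: float = 1.05
    ocrr_factor_upwelling: float = 0.78
    ocrr_factor_background: float = 0.92
    acid_ocrr_factor: float = 1.08           # CO2-fertilization increment
    circulation_kmix_factor: float = 0.7
    circulation_wup_factor: float = 0.6
    noise_amplitude: float = 0.05
    #: community composition multipliers, future_physics epoch
    community_physics: dict = field(default_factory=lambda: {
        "diatom": 0.55, "other_large": 0.70, "synechococcus": 1.00,
        "prochlorococcus": 0.95, "diazotroph": 1.10, "coccolithophore": 0.90,
    })
    #: acidification-driven *Synechococcus* gain: 1 + base + slope*(|lat|/90)
    acid_syn_base: float = 0.2
    acid_syn_slope: float = 1.2
    acid_syn_coastal_extra: float = 0.2
    zoo_future_factor: float = 0.95
    atm_hg0_mean: float = 1.5                # ng m-3
    dep_hg2_mean: float = 10.0               # ug m-2 y-1


@dataclass
class ForcingSet:
    """One epoch's monthly climatological forcing on the model grid.

    Cell fields are (band, region, layer, month); surface fields are
    (band, region, month); mixing/upwelling are (band, region, interface,
    month); atmospheric boundary fields are (band, month).  Plankton fields
    carry a leading group axis ordered as PHYTO_GROUPS / ZOO_GROUPS, and
    ``grazing`` is (zoo, phyto, band, region, layer, month).
    """

    epoch: str
    grid: Grid
    t: np.ndarray
    u10: np.ndarray
    f_ice: np.ndarray
    i0: np.ndarray
    chl: np.ndarray
    doc: np.ndarray
    poc: np.ndarray
    ocrr: np.ndarray
    biomass: np.ndarray
    grazing: np.ndarray
    zoo_mortality: np.ndarray
    k_mix: np.ndarray
    w_up: np.ndarray
    atm_hg0: np.ndarray
    dep_hg2: np.ndarray

    def validate(self):
        g = self.grid
        nb, nr, nz, nm = g.n_bands, 2, g.n_layers, g.n_months
        ni = nz - 1
        shapes = {
            "t": (nb, nr, nz, nm), "u10": (nb, nr, nm), "f_ice": (nb, nr, nm),
            "i0": (nb, nr, nm), "chl": (nb, nr, nz, nm), "doc": (nb, nr, nz, nm),
            "poc": (nb, nr, nz, nm), "ocrr": (nb, nr, nz, nm),
            "biomass": (len(PHYTO_GROUPS) + len(ZOO_GROUPS), nb, nr, nz, nm),
            "grazing": (len(ZOO_GROUPS), len(PHYTO_GROUPS), nb, nr, nz, nm),
            "zoo_mortality": (len(ZOO_GROUPS), nb, nr, nz, nm),
            "k_mix": (nb, nr, ni, nm), "w_up": (nb, nr, ni, nm),
            "atm_hg0": (nb, nm), "dep_hg2": (nb, nm),
        }
        for name, shape in shapes.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ForcingError(f"field {name}: shape {arr.shape} != {shape}")
            if name != "t" and np.any(arr < 0):
                raise ForcingError(f"field {name} has negative values")
        if np.any(self.f_ice > 1.0):
            raise ForcingError("f_ice exceeds 1")
        if np.any((self.ocrr > 0) & (self.poc <= 0)):
            raise ForcingError("inconsistent forcing: OCRR > 0 where POC = 0")
        return self

    def copy(self) -> "ForcingSet":
        kw = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        for k, v in kw.items():
            if isinstance(v, np.ndarray):
                kw[k] = v.copy()
        return ForcingSet(**kw)

    def phyto_index(self, name: str) -> int:
        return PHYTO_GROUPS.index(name)

    def zoo_index(self, name: str) -> int:
        return ZOO_GROUPS.index(name)


# --------------------------------------------------------------------------
# pattern helpers

def _gauss(x, mu, sig):
    return np.exp(-((x - mu) / sig) ** 2)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _season(n_months: int) -> np.ndarray:
    """Northern-hemisphere seasonal sinusoid peaking in July."""
    m = (np.arange(n_months) + 0.5) / n_months
    return np.cos(2.0 * np.pi * (m - 7.0 / 12.0))


def _smooth_band_noise(seed: int, field_id: int, grid: Grid,
                       amp: float) -> np.ndarray:
    """Smooth multiplicative noise factor per band, ~(1 +- amp).

    A low-order random sinusoid in latitude, normalized to unit maximum and
    centred so its area-weighted mean is ~0 (mean-preserving by
    construction).  Seeded per field, *not* per epoch, so present/future
    orderings are unaffected.
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, field_id])
    x = (grid.lat_centers + 90.0) / 90.0
    eta = np.zeros_like(x)
    for k in (1, 2, 3):
        eta += rng.uniform(0.3, 1.0) * np.sin(np.pi * k * x + rng.uniform(0, 2 * np.pi))
    eta /= np.max(np.abs(eta))
    w = grid.band_area
    eta -= np.sum(eta * w) / np.sum(w)
    return 1.0 + amp * eta


_NOISE_IDS = {"t": 0, "u10": 1, "f_ice": 2, "i0": 3, "chl": 4, "doc": 5,
              "poc": 6, "ocrr": 7, "biomass": 8, "k_mix": 9, "w_up": 10}


def _surface_chl_mean(grid: Grid, chl: np.ndarray) -> float:
    """Annual, volume-weighted mean over the euphotic (0-100 m) layers."""
    w = grid.volume.copy()
    w[:, :, ~grid.surface_layers] = 0.0
    return float(np.sum(chl * w[..., None]) / (np.sum(w) * chl.shape[-1]))


# --------------------------------------------------------------------------

def generate_forcing(epoch: str, grid: Grid, seed: int,
                     calib: ForcingCalibration | None = None) -> ForcingSet:
    """Deterministic synthetic forcing for one epoch.

    Bit-identical for a fixed (epoch, grid, seed); calibrated so the global
    mean surface chlorophyll is exactly the epoch's target; the future epoch
    is warmer than the present in every cell.
    """
    if epoch not in EPOCHS:
        raise ForcingError(f"unknown epoch {epoch!r}; expected one of {EPOCHS}")
    if not isinstance(grid, Grid):
        raise ForcingError("grid must be a Grid instance")
    c = calib or ForcingCalibration()
    if not 1.0 <= c.warming_surface_mean <= 5.0:
        raise ForcingError("warming_surface_mean must lie in [1, 5] degC")

    nb, nr, nz, nm = grid.n_bands, 2, grid.n_layers, grid.n_months
    lat = grid.lat_centers                       # (nb,)
    alat = np.abs(lat)
    zc = grid.z_centers                          # (nz,)
    zi = grid.z_interfaces                       # (nz-1,)
    s = _season(nm)                              # (nm,)
    s_lag = np.roll(s, 1)
    hemi = np.tanh(lat / 15.0)                   # -1 (S) .. +1 (N)
    seas = hemi[:, None] * s[None, :]            # (nb, nm), +1 = local summer
    seas_lag = hemi[:, None] * s_lag[None, :]
    future = epoch in ("future", "future_physics")

    def noise(name):
        return _smooth_band_noise(seed, _NOISE_IDS[name], grid,
                                  c.noise_amplitude)

    def bcast_srf(band_month):                   # (nb, nm) -> (nb, nr, nm)
        return np.repeat(band_month[:, None, :], nr, axis=1)

    # -- temperature -------------------------------------------------------
    t_surf = -1.5 + 28.5 * np.cos(np.radians(lat)) ** 2                # (nb,)
    t_surf = t_surf[:, None] + 4.0 * np.sin(np.radians(lat[:, None])) ** 2 * seas
    t_deep = 2.0
    t = t_deep + (t_surf[:, :, None] - t_deep) * np.exp(-zc / 300.0)[None, None, :]
    t = np.maximum(t, -1.8)                                            # (nb, nm, nz)
    t = np.transpose(t, (0, 2, 1))                                     # (nb, nz, nm)
    t = np.repeat(t[:, None, :, :], nr, axis=1)                        # (nb, nr, nz, nm)
    t = t + 0.15 * (noise("t")[:, None, None, None] - 1.0) / c.noise_amplitude
    if future:
        pattern = 1.0 + 0.6 * (alat / 90.0)
        scale = c.warming_surface_mean / grid.area_mean(
            np.repeat(pattern[:, None], nr, axis=1))
        dt_surf = scale * pattern                                      # (nb,)
        dt = dt_surf[:, None] * (0.12 + 0.88 * np.exp(-zc / 800.0))[None, :]
        t = t + dt[:, None, :, None]

    # -- wind --------------------------------------------------------------
    u10 = (5.5 + 3.5 * _gauss(alat, 50.0, 12.0) + 1.5 * _gauss(lat, 0.0, 12.0))
    u10 = u10[:, None] * (1.0 - 0.08 * seas)     # stronger in local winter
    u10 = bcast_srf(u10) * noise("u10")[:, None, None]
    if future:
        trop = _gauss(lat, 0.0, 15.0)
        mult = (c.wind_factor_extratropical
                + (c.wind_factor_tropical - c.wind_factor_extratropical) * trop)
        u10 = u10 * mult[:, None, None]

    # -- sea ice -----------------------------------------------------------
    ice_ann = 0.85 * np.clip((alat - 55.0) / 32.0, 0.0, 1.0) ** 2
    f_ice = ice_ann[:, None] * (1.0 - 0.35 * seas)      # more ice in winter
    f_ice = bcast_srf(f_ice) * noise("f_ice")[:, None, None]
    if future:
        f_ice = f_ice * c.ice_loss_factor
    f_ice = np.clip(f_ice, 0.0, 1.0)

    # -- shortwave radiation -----------------------------------------------
    i_ann = 230.0 * np.maximum(np.cos(np.radians(lat)), 0.05) ** 1.3
    i0 = i_ann[:, None] * np.maximum(1.0 + 0.8 * np.abs(np.sin(np.radians(lat)))[:, None] * seas, 0.0)
    i0 = bcast_srf(i0) * noise("i0")[:, None, None]
    if future:
        mult = (1.0 + c.rad_polar_brightening * _sigmoid((alat - 45.0) / 8.0)
                - c.rad_tropical_dimming * _gauss(lat, 0.0, 18.0))
        i0 = i0 * mult[:, None, None]
    i0 = np.maximum(i0, 0.0)

    # -- chlorophyll (calibrated) -------------------------------------------
    upwelling = _gauss(lat, 0.0, 10.0) + 0.4 * _gauss(alat, 50.0, 10.0)
    chl_srf = 0.35 + 1.8 * _gauss(alat, 55.0, 14.0) + 1.3 * _gauss(lat, 0.0, 10.0)
    chl_srf = chl_srf[:, None] * (1.0 + 0.45 * seas_lag)               # (nb, nm)
    chl = chl_srf[:, None, None, :] * np.exp(-zc / 60.0)[None, None, :, None]
    chl = np.repeat(chl, nr, axis=1)
    chl[:, 1] *= 3.0                                                   # coastal
    chl = chl * noise("chl")[:, None, None, None]
    if future:
        chl = chl * (0.40 + 0.25 * (alat / 90.0))[:, None, None, None]
    target = (c.chl_surface_mean_future if future else c.chl_surface_mean_present)
    chl = chl * (target / _surface_chl_mean(grid, chl))

    # -- DOC ----------------------------------------------------------------
    doc_srf = 65.0 + 15.0 * _gauss(lat, 0.0, 20.0)
    doc = 40.0 + (doc_srf[:, None] - 40.0) * np.exp(-zc / 500.0)[None, :]
    doc = np.repeat(doc[:, None, :, None], nr, axis=1)
    doc = np.repeat(doc, nm, axis=3)
    doc[:, 1] *= 1.2
    doc = doc * noise("doc")[:, None, None, None]
    if future:
        doc = doc * c.doc_future_factor

    # -- POC and OCRR --------------------------------------------------------
    # present-day POC follows the (calibrated, present) chlorophyll surface
    # pattern with a power-law export profile tapered to ~0 in the abyss
    chl_srf_cal = chl_srf * (c.chl_surface_mean_present
                             / _surface_chl_mean(
                                 grid,
                                 np.repeat((chl_srf[:, None, None, :]
                                            * np.exp(-zc / 60.0)[None, None, :, None]),
                                           nr, axis=1)
                                 * np.array([1.0, 3.0])[None, :, None, None]))
    martin = (np.maximum(zc, 60.0) / 60.0) ** -0.9 * np.exp(-((zc / 2600.0) ** 2))
    poc = chl_srf_cal[:, None, None, :] * 10.0 * martin[None, None, :, None]
    poc = np.repeat(poc, nr, axis=1)
    poc[:, 1] *= 3.0
    poc = poc * (1.0 + 0.3 * upwelling)[:, None, None, None]
    poc = poc * noise("poc")[:, None, None, None]
    # remineralization peaks below the euphotic zone (sinking export is
    # consumed under the productive layer), which puts the methylation and
    # the CH3Hg maximum below 100 m as observed
    ocrr_shape = (0.4 * np.exp(-zc / 1200.0)
                  + 1.2 * (zc / 250.0) * np.exp(1.0 - zc / 250.0))
    ocrr = (poc[:, :, :1, :] * 0.03) * ocrr_shape[None, None, :, None]
    ocrr = ocrr * noise("ocrr")[:, None, None, None] / noise("poc")[:, None, None, None]
    if future:
        up_mask = (upwelling > 0.5)
        poc_mult = np.where(up_mask, c.poc_factor_upwelling, c.poc_factor_background)
        poc = poc * poc_mult[:, None, None, None]
        coastal_srf = np.ix_(np.arange(nb), [1],
                             np.where(grid.surface_layers)[0], np.arange(nm))
        poc[coastal_srf] *= (c.poc_factor_coastal_surface / 1.0)
        ocrr_mult = np.where(up_mask, c.ocrr_factor_upwelling, c.ocrr_factor_background)
        ocrr = ocrr * ocrr_mult[:, None, None, None]
        if epoch == "future":
            ocrr = ocrr * c.acid_ocrr_factor

    # -- plankton community ---------------------------------------------------
    # composition fractions by latitude (phyto); the community fields express
    # food-web *structure*: overall productivity changes are carried by the
    # Chl/POC/OCRR factors, so total biomass here uses the present pattern.
    frac = {
        "prochlorococcus": 0.45 * _gauss(lat, 0.0, 25.0) + 0.03,
        "synechococcus": 0.15 + 0.10 * _gauss(lat, 0.0, 35.0),
        "diatom": 0.10 + 0.40 * (alat / 90.0) + 0.15 * upwelling,
        "other_large": 0.15 * np.ones(nb),
        "diazotroph": 0.08 * _gauss(lat, 0.0, 15.0) + 0.005,
        "coccolithophore": 0.03 + 0.06 * _gauss(alat, 45.0, 15.0),
    }
    frac = {g: np.stack([v, v * (1.5 if g == "diatom" else 1.0)], axis=1)
            for g, v in frac.items()}                                   # (nb, nr)
    norm = sum(frac.values())
    frac = {g: v / norm for g, v in frac.items()}
    b_tot = chl_srf_cal[:, None, None, :] * 50.0 * np.exp(-zc / 60.0)[None, None, :, None]
    b_tot = np.repeat(b_tot, nr, axis=1)
    b_tot[:, 1] *= 3.0
    b_tot = b_tot * noise("biomass")[:, None, None, None]
    bio_phyto = {g: frac[g][:, :, None, None] * b_tot for g in PHYTO_GROUPS}
    if future:
        mult = dict(c.community_physics)
        bio_phyto = {g: bio_phyto[g] * mult[g] for g in PHYTO_GROUPS}
        if epoch == "future":
            syn_gain = 1.0 + c.acid_syn_base + c.acid_syn_slope * (alat / 90.0)
            syn_gain = np.stack([syn_gain,
                                 syn_gain + c.acid_syn_coastal_extra], axis=1)
            bio_phyto["synechococcus"] = (bio_phyto["synechococcus"]
                                          * syn_gain[:, :, None, None])
    prey = {"small_zoo": ("prochlorococcus", "synechococcus", "coccolithophore"),
            "large_zoo": ("diatom", "other_large", "diazotroph")}
    zoo_frac = {"small_zoo": 0.5, "large_zoo": 0.4}
    # zooplankton biomass follows the *present* prey base (grazing closure
    # damps its response); future applies only a mild factor
    prey_present = {z: sum(frac[g][:, :, None, None] * b_tot for g in prey[z])
                    for z in ZOO_GROUPS}
    bio_zoo = {z: zoo_frac[z] * prey_present[z] for z in ZOO_GROUPS}
    if future:
        bio_zoo = {z: v * c.zoo_future_factor for z, v in bio_zoo.items()}
    biomass = np.stack([bio_phyto[g] for g in PHYTO_GROUPS]
                       + [bio_zoo[z] for z in ZOO_GROUPS], axis=0)
    # linear functional response: grazing of zoo z on phyto p
    mu_z = {"small_zoo": 0.25, "large_zoo": 0.15}                      # d-1
    grazing = np.zeros((len(ZOO_GROUPS), len(PHYTO_GROUPS), nb, nr, nz, nm))
    for iz, z in enumerate(ZOO_GROUPS):
        for ip, g in enumerate(PHYTO_GROUPS):
            if g in prey[z]:
                grazing[iz, ip] = (mu_z[z] * bio_zoo[z]
                                   * bio_phyto[g] / PREY_REF_MG_M3)
    zoo_mortality = np.stack([0.05 * bio_zoo[z] for z in ZOO_GROUPS], axis=0)

    # -- circulation ----------------------------------------------------------
    winter = -seas                                                      # (nb, nm)
    # the thermocline term stands in for ventilation by subduction and
    # horizontal advection, which a vertical-only column cannot resolve
    k_mix = (5.0e-3 * np.exp(-((zi / 60.0) ** 2))[None, None, :, None]
             * (1.0 + 0.5 * winter[:, None, None, :])
             + 3.0e-4 * np.exp(-zi / 600.0)[None, None, :, None]
             + 1.0e-5)
    k_mix = np.broadcast_to(k_mix, (nb, nr, nz - 1, nm)).copy()
    k_mix = k_mix * noise("k_mix")[:, None, None, None]
    w_up = (0.05 + 0.35 * upwelling[:, None, None, None]
            * np.exp(-zi / 400.0)[None, None, :, None])
    w_up = np.broadcast_to(w_up, (nb, nr, nz - 1, nm)).copy()
    w_up = w_up * noise("w_up")[:, None, None, None]
    if future:
        k_mix = k_mix * c.circulation_kmix_factor
        w_up = w_up * c.circulation_wup_factor

    # -- atmospheric boundary (identical across epochs) ------------------------
    atm_hg0 = (c.atm_hg0_mean + 0.3 * np.tanh(lat / 30.0))[:, None] * np.ones(nm)
    dep_pat = 0.75 + 0.5 * _gauss(lat, 40.0, 25.0)
    dep_pat = dep_pat / grid.area_mean(np.repeat(dep_pat[:, None], nr, axis=1))
    dep_hg2 = (c.dep_hg2_mean * dep_pat)[:, None] * np.ones(nm)

    fs = ForcingSet(
        epoch=epoch, grid=grid, t=t, u10=u10, f_ice=f_ice, i0=i0, chl=chl,
        doc=doc, poc=poc, ocrr=ocrr, biomass=biomass, grazing=grazing,
        zoo_mortality=zoo_mortality, k_mix=k_mix, w_up=w_up,
        atm_hg0=atm_hg0, dep_hg2=dep_hg2,
    )
    return fs.validate()


def blend_scenarios(base: ForcingSet, future: ForcingSet,
                    factors) -> ForcingSet:
    """Forcing with the listed factors' fields from ``future``, rest from base.

    The factor -> field mapping is FACTOR_FIELDS; an empty set returns a copy
    of ``base`` and the full factor set returns ``future``'s fields.
    """
    factors = set(factors)
    unknown = factors - set(FACTORS)
    if unknown:
        raise ForcingError(f"unknown factors: {sorted(unknown)}")
    if base.grid != future.grid:
        raise ForcingError("base and future forcings are on different grids")
    out = base.copy()
    for f in factors:
        for name in FACTOR_FIELDS[f]:
            setattr(out, name, getattr(future, name).copy())
    out.epoch = f"blend({base.epoch}<-{future.epoch}:{','.join(sorted(factors))})"
    return out


def summarize_forcing(f: ForcingSet) -> pd.DataFrame:
    """Global-mean table, one row per field.

    ``mean`` is the volume-weighted (cell fields) or area-weighted (surface
    and boundary fields) annual global mean; cell fields also get a
    ``surface_mean`` over the euphotic (0-100 m) layers.  Plankton fields are
    summed over groups first.
    """
    g = f.grid
    vol = g.volume
    vol_s = vol.copy()
    vol_s[:, :, ~g.surface_layers] = 0.0
    rows = []

    def cell_means(arr):
        return (float(np.sum(arr * vol[..., None]) / (np.sum(vol) * arr.shape[-1])),
                float(np.sum(arr * vol_s[..., None]) / (np.sum(vol_s) * arr.shape[-1])))

    for name in ("t", "chl", "doc", "poc", "ocrr"):
        m, ms = cell_means(getattr(f, name))
        rows.append((name, m, ms, FORCING_UNITS[name]))
    m, ms = cell_means(f.biomass.sum(axis=0))
    rows.append(("biomass", m, ms, FORCING_UNITS["biomass"]))
    m, ms = cell_means(f.grazing.sum(axis=(0, 1)))
    rows.append(("grazing", m, ms, FORCING_UNITS["grazing"]))
    m, ms = cell_means(f.zoo_mortality.sum(axis=0))
    rows.append(("zoo_mortality", m, ms, FORCING_UNITS["zoo_mortality"]))
    area = g.area
    for name in ("u10", "f_ice", "i0"):
        arr = getattr(f, name)
        m = float(np.sum(arr * area[..., None]) / (np.sum(area) * arr.shape[-1]))
        rows.append((name, m, m, FORCING_UNITS[name]))
    for name in ("k_mix", "w_up"):
        arr = getattr(f, name)
        m = float(np.mean(np.sum(arr * area[:, :, None, None], axis=(0, 1))
                          / np.sum(area)))
        rows.append((name, m, float("nan"), FORCING_UNITS[name]))
    ba = g.band_area
    for name in ("atm_hg0", "dep_hg2"):
        arr = getattr(f, name)
        m = float(np.sum(arr * ba[:, None]) / (np.sum(ba) * arr.shape[-1]))
        rows.append((name, m, m, FORCING_UNITS[name]))
    return pd.DataFrame(rows, columns=["field", "mean", "surface_mean", "units"]
                        ).set_index("field")
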