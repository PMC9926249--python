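"""Reduced model grid: zonal bands x {open, coastal} region x depth layers.

The horizontal dimension is a set of latitude bands (default 18 bands of
10 degrees), each split into an open-ocean and a coastal column that share
the band's latitude but differ in area (the coastal column occupies a small
configurable fraction of the band).  The vertical dimension is a set of
depth layers whose edges must include exactly 100 m and 1000 m so that the
euphotic (0-100 m) and subsurface (100-1000 m) diagnostic masks are sharp.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_M = 6.371e6

#: default depth-layer edges, m (15 layers; 100 m and 1000 m are edges)
DEFAULT_DEPTH_EDGES = (
    0.0, 25.0, 50.0, 100.0, 200.0, 300.0, 450.0, 650.0, 850.0, 1000.0,
    1400.0, 1900.0, 2500.0, 3200.0, 4000.0, 5000.0,
)

REGIONS = ("open", "coastal")


class GridError(ValueError):
    """Invalid grid specification."""


@dataclass(frozen=True)
class Grid:
    """Geometry and diagnostic masks of the reduced global ocean.

    Parameters
    ----------
    lat_edges
        Monotone latitude band edges in degrees, from -90 to 90.
    depth_edges
        Monotone depth layer edges in metres starting at 0; must contain
        100 and 1000 exactly.
    coastal_frac
        Fraction of each band's ocean area assigned to the coastal column.
    ocean_frac
        Fraction of each band's spherical area that is ocean.
    """

    lat_edges: tuple = tuple(np.linspace(-90.0, 90.0, 19))
    depth_edges: tuple = DEFAULT_DEPTH_EDGES
    coastal_frac: float = 0.08
    ocean_frac: float = 0.70
    n_months: int = field(default=12)

    def __post_init__(self):
        lat = np.asarray(self.lat_edges, float)
        z = np.asarray(self.depth_edges, float)
        if lat.ndim != 1 or lat.size < 2 or np.any(np.diff(lat) <= 0):
            raise GridError("lat_edges must be monotone increasing with >= 2 entries")
        if lat[0] < -90 - 1e-9 or lat[-1] > 90 + 1e-9:
            raise GridError("lat_edges must lie within [-90, 90]")
        if z.ndim != 1 or z.size < 2 or z[0] != 0.0 or np.any(np.diff(z) <= 0):
            raise GridError("depth_edges must be monotone increasing from 0")
        for must in (100.0, 1000.0):
            if must < z[-1] and not np.any(np.isclose(z, must)):
                raise GridError(f"depth_edges must contain {must} m exactly")
        if not 0.0 < self.coastal_frac < 1.0:
            raise GridError("coastal_frac must be in (0, 1)")
        if not 0.0 < self.ocean_frac <= 1.0:
            raise GridError("ocean_frac must be in (0, 1]")

    # -- geometry ---------------------------------------------------------
    @property
    def n_bands(self) -> int:
        return len(self.lat_edges) - 1

    @property
    def n_regions(self) -> int:
        return 2

    @property
    def n_layers(self) -> int:
        return len(self.depth_edges) - 1

    @property
    def lat_centers(self) -> np.ndarray:
        lat = np.asarray(self.lat_edges, float)
        return 0.5 * (lat[:-1] + lat[1:])

    @property
    def dz(self) -> np.ndarray:
        z = np.asarray(self.depth_edges, float)
        return np.diff(z)

    @property
    def z_centers(self) -> np.ndarray:
        z = np.asarray(self.depth_edges, float)
        return 0.5 * (z[:-1] + z[1:])

    @property
    def z_interfaces(self) -> np.ndarray:
        """Depths of the internal interfaces (between layers), m."""
        return np.asarray(self.depth_edges, float)[1:-1]

    @property
    def dz_centers(self) -> np.ndarray:
        """Distance between adjacent layer centres (per internal interface), m."""
        return np.diff(self.z_centers)

    @property
    def band_area(self) -> np.ndarray:
        """Ocean area of each latitude band, m2."""
        phi = np.radians(np.asarray(self.lat_edges, float))
        return (2.0 * np.pi * EARTH_RADIUS_M**2
                * np.abs(np.diff(np.sin(phi))) * self.ocean_frac)

    @property
    def area(self) -> np.ndarray:
        """Horizontal area per (band, region) column, m2."""
        a = self.band_area
        return np.stack([a * (1.0 - self.coastal_frac), a * self.coastal_frac], axis=1)

    @property
    def volume(self) -> np.ndarray:
        """Cell volume (band, region, layer), m3."""
        return self.area[:, :, None] * self.dz[None, None, :]

    # -- diagnostic masks -------------------------------------------------
    @property
    def surface_layers(self) -> np.ndarray:
        """Boolean mask of layers wholly above 100 m (euphotic zone)."""
        z = np.asarray(self.depth_edges, float)
        return z[1:] <= 100.0 + 1e-9

    @property
    def subsurface_layers(self) -> np.ndarray:
        """Boolean mask of layers between 100 m and 1000 m."""
        z = np.asarray(self.depth_edges, float)
        return (z[:-1] >= 100.0 - 1e-9) & (z[1:] <= 1000.0 + 1e-9)

    @property
    def interface_100m(self) -> int:
        """Index of the internal interface at exactly 100 m depth."""
        return int(np.argmin(np.abs(self.z_interfaces - 100.0)))

    @property
    def interface_1000m(self) -> int:
        return int(np.argmin(np.abs(self.z_interfaces - 1000.0)))

    def layer_mask(self, which: str) -> np.ndarray:
        if which == "surface":
            return self.surface_layers
        if which == "subsurface":
            return self.subsurface_layers
        if which == "all":
            return np.ones(self.n_layers, bool)
        raise GridError(f"unknown layer mask {which!r}")

    def volume_mean(self, conc: np.ndarray, layers: str = "all",
                    region: str | None = None) -> float:
        """Volume-weighted mean of a (band, region, layer) field, optionally
        restricted to a layer mask and/or one region ('open'/'coastal')."""
        w = self.volume.copy()
        w[:, :, ~self.layer_mask(layers)] = 0.0
        if region is not None:
            w[:, [r for r in range(2) if REGIONS[r] != region], :] = 0.0
        return float(np.sum(conc * w) / np.sum(w))

    def area_mean(self, field2d: np.ndarray) -> float:
        """Area-weighted mean of a (band, region) surface field."""
        a = self.area
        return float(np.sum(field2d * a) / np.sum(a))
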