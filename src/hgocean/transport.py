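"""Tracer state and conservative vertical transport.

Transport is vertical-only: each (band, region) column mixes internally via
an explicit, sub-stepped flux-form exchange across layer interfaces.  The
exchange coefficient combines turbulent diffusion (K_mix/dz_c) with the
upwelling velocity: in a closed column with no resolved horizontal return
flow, upwelling is represented as a two-way water exchange w*(c_below -
c_above) across the interface, which conserves mass exactly and carries the
physically relevant signal (an enriched subsurface supplies the surface
faster when upwelling is strong).  Particle sinking is first-order upwind
with bottom-interface removal to a burial term.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import units
from .grid import Grid

TRACERS = ("hg0", "hg2d", "hgp", "mmhg", "dmhg")


class CFLError(ValueError):
    """Time step too large for the transport operator."""


@dataclass
class HgState:
    """Concentrations of the five mercury tracers, pM, on (band, region, layer)."""

    grid: Grid
    hg0: np.ndarray
    hg2d: np.ndarray
    hgp: np.ndarray
    mmhg: np.ndarray
    dmhg: np.ndarray

    @classmethod
    def zeros(cls, grid: Grid) -> "HgState":
        shape = (grid.n_bands, grid.n_regions, grid.n_layers)
        return cls(grid, *(np.zeros(shape) for _ in TRACERS))

    @classmethod
    def initial(cls, grid: Grid, hg2d_pm: float = 0.5) -> "HgState":
        """Spin-up initial condition: uniform dissolved HgII, all else zero."""
        s = cls.zeros(grid)
        s.hg2d += hg2d_pm
        return s

    def validate(self):
        shape = (self.grid.n_bands, self.grid.n_regions, self.grid.n_layers)
        for name in TRACERS:
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"tracer {name}: shape {arr.shape} != {shape}")
            if np.any(arr < 0):
                raise ValueError(f"tracer {name} has negative concentrations")
        return self

    def copy(self) -> "HgState":
        return HgState(self.grid, *(getattr(self, n).copy() for n in TRACERS))

    def total_per_cell(self) -> np.ndarray:
        """Total mercury per cell (all five tracers), pM."""
        return sum(getattr(self, n) for n in TRACERS)

    def inventory(self, tracer: str | None = None) -> float:
        """Global inventory in mol (one tracer, or total mercury)."""
        conc = getattr(self, tracer) if tracer else self.total_per_cell()
        return float(np.sum(conc * self.grid.volume)) * units.PM_M3_TO_MOL

    def stack(self) -> np.ndarray:
        return np.stack([getattr(self, n) for n in TRACERS], axis=-1)

    @classmethod
    def from_stack(cls, grid: Grid, arr: np.ndarray) -> "HgState":
        return cls(grid, *(arr[..., i].copy() for i in range(len(TRACERS))))


@dataclass
class BudgetLedger:
    """Cumulative boundary exchanges and conversions, mol.

    Closure: d(total ocean Hg) = deposition - evasion - burial for every
    step, which the scenario driver verifies to a 1e-10 relative tolerance.
    """

    deposition_hg2: float = 0.0
    evasion_hg0: float = 0.0
    evasion_dmhg: float = 0.0
    burial_hgp: float = 0.0
    conversions: dict = field(default_factory=dict)

    def add_conversion(self, name: str, mol: float):
        self.conversions[name] = self.conversions.get(name, 0.0) + mol

    def net_boundary(self) -> float:
        return (self.deposition_hg2 - self.evasion_hg0 - self.evasion_dmhg
                - self.burial_hgp)

    def snapshot(self) -> "BudgetLedger":
        return dataclasses.replace(self, conversions=dict(self.conversions))


def _exchange_coefficient(grid: Grid, k_mix: np.ndarray,
                          w_up: np.ndarray) -> np.ndarray:
    """Interface exchange velocity, m d-1: K/dz_c + w (per band, region, iface)."""
    dzc = grid.dz_centers                                    # (nz-1,)
    return (k_mix * units.M2_PER_S_TO_M2_PER_D / dzc[None, None, :] + w_up)


def step_transport(state: HgState, k_mix: np.ndarray, w_up: np.ndarray,
                   dt: float, max_substeps: int = 1000) -> HgState:
    """Vertical mixing + upwelling exchange over ``dt`` days.

    Conserves every tracer's global inventory exactly (flux form), keeps
    concentrations non-negative (positivity-limited sub-stepping) and is
    linear in the state.  ``k_mix`` (m2 s-1) and ``w_up`` (m d-1) are per
    (band, region, interface).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    g = state.grid
    ex = _exchange_coefficient(g, np.asarray(k_mix, float), np.asarray(w_up, float))
    if np.any(ex < 0):
        raise ValueError("mixing/upwelling coefficients must be >= 0")
    dz = g.dz
    # outflow rate of each cell: exchanges across its upper and lower interfaces
    lam = np.zeros((g.n_bands, g.n_regions, g.n_layers))
    lam[:, :, :-1] += ex / dz[None, None, :-1]
    lam[:, :, 1:] += ex / dz[None, None, 1:]
    lam_max = float(np.max(lam))
    n_sub = max(1, int(np.ceil(dt * lam_max / 0.9)))
    if n_sub > max_substeps:
        worst = np.unravel_index(int(np.argmax(lam)), lam.shape)
        raise CFLError(
            f"dt={dt} d violates the transport CFL limit at band={worst[0]}, "
            f"region={worst[1]}, layer={worst[2]} "
            f"(needs {n_sub} sub-steps, cap {max_substeps})")
    h = dt / n_sub
    conc = state.stack()                                      # (nb, nr, nz, 5)
    exh = ex[..., None] * h
    for _ in range(n_sub):
        flux = exh * (conc[:, :, 1:, :] - conc[:, :, :-1, :])  # pM * m, upward
        conc[:, :, :-1, :] += flux / dz[None, None, :-1, None]
        conc[:, :, 1:, :] -= flux / dz[None, None, 1:, None]
    return HgState.from_stack(g, conc)


def sink_particles(state: HgState, w_s: float, dt: float):
    """First-order upwind sinking of HgP; returns (new state, burial mol).

    Flux across an interface is w_s * HgP(layer above); the flux through the
    bottom interface leaves the ocean as burial.  ``w_s * dt`` must not
    exceed the thinnest layer (callers sub-step to satisfy this).
    """
    if w_s < 0:
        raise ValueError("sinking speed must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    g = state.grid
    dz = g.dz
    if w_s * dt > np.min(dz) + 1e-12:
        raise CFLError(
            f"w_s*dt = {w_s * dt:.1f} m exceeds the thinnest layer "
            f"({np.min(dz):.1f} m); reduce dt or sub-step")
    new = state.copy()
    hgp = new.hgp
    flux = w_s * hgp * dt                                     # pM * m per layer
    hgp -= flux / dz[None, None, :]
    hgp[:, :, 1:] += flux[:, :, :-1] / dz[None, None, 1:]
    burial_mol = float(np.sum(flux[:, :, -1] * g.area)) * units.PM_M3_TO_MOL
    return new, burial_mol


def sinking_flux_profile(state: HgState, w_s: float) -> np.ndarray:
    """Instantaneous HgP sinking flux across internal interfaces, pmol m-2 d-1."""
    return w_s * state.hgp[:, :, :-1] * units.PM_TIMES_M_TO_PMOL_M2
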