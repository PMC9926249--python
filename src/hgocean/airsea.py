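"""Air-sea exchange of elemental mercury and dimethylmercury.

Hg0 exchanges bidirectionally across the uncovered sea surface, driven by
the aqueous/atmospheric concentration gradient and a piston velocity that is
quadratic in the 10-m wind speed and Schmidt-number scaled.  Warming lowers
Hg0 solubility (2.5-2.9% per +1 degC in the 10-35 degC range under the
default van 't Hoff parameterization), which pushes the gradient toward
evasion.  DMHg is treated as one-way evasion: its atmospheric concentration
is taken as zero.
"""
from __future__ import annotations

import numpy as np

from . import units
from .params import ExchangeParams


def _check_temperature(t, p: ExchangeParams, lo=None, hi=None):
    t = np.asarray(t, float)
    lo = p.t_min if lo is None else lo
    hi = p.t_max if hi is None else hi
    if np.any(t < lo) or np.any(t > hi):
        raise ValueError(f"temperature outside [{lo}, {hi}] degC")
    return t


def henry_constant(t_c, p: ExchangeParams = ExchangeParams()):
    """Dimensionless gas-water partition coefficient K = exp(c - b/T_K).

    This is the volatility form (gas-phase over aqueous concentration at
    equilibrium): it increases with temperature, i.e. the aqueous solubility
    1/K strictly decreases with warming.
    """
    t = _check_temperature(t_c, p)
    tk = t + 273.15
    return np.exp(p.c_henry - p.b_vanthoff / tk)


def solubility(t_c, p: ExchangeParams = ExchangeParams()):
    """Dimensionless aqueous/gas solubility ratio, strictly decreasing in T."""
    return 1.0 / henry_constant(t_c, p)


def solubility_sensitivity(t_c, p: ExchangeParams = ExchangeParams()):
    """Fractional drop in Hg0 solubility per +1 degC at temperature ``t_c``.

    1 - S(T+1)/S(T) = 1 - exp(-b/(T_K (T_K+1))); decreasing in T, and within
    [0.025, 0.029] at mid-range ocean temperatures with default parameters.
    """
    t = _check_temperature(t_c, p, lo=10.0, hi=35.0)
    tk = t + 273.15
    return 1.0 - np.exp(-p.b_vanthoff / (tk * (tk + 1.0)))


def schmidt_number(t_c, p: ExchangeParams = ExchangeParams()):
    t = np.asarray(t_c, float)
    sc = sum(c * t**i for i, c in enumerate(p.sc_coeffs))
    if np.any(sc <= 0):
        raise ValueError("Schmidt-number polynomial non-positive at this temperature")
    return sc


def piston_velocity(u10, t_c, p: ExchangeParams = ExchangeParams()):
    """Gas transfer (piston) velocity, cm h-1: k = k_ref u10^2 (Sc/660)^-1/2."""
    u = np.asarray(u10, float)
    if np.any(u < 0):
        raise ValueError("wind speed must be >= 0")
    return p.k_ref * u**2 * (schmidt_number(t_c, p) / p.sc_ref) ** -0.5


def atm_equilibrium_pm(c_atm_ng_m3, t_c, p: ExchangeParams = ExchangeParams()):
    """Aqueous Hg0 concentration (pM) in equilibrium with the atmosphere.

    ng m-3 gas-phase -> pM gas-phase (pmol per litre of air), then divided by
    the gas-water partition coefficient.
    """
    c_gas_pm = np.asarray(c_atm_ng_m3, float) * units.NG_M3_TO_PM_GAS
    return c_gas_pm / henry_constant(t_c, p)


def hg0_flux(c_w_pm, c_atm_ng_m3, t_c, u10, f_ice,
             p: ExchangeParams = ExchangeParams()):
    """Net Hg0 evasion flux, pmol m-2 d-1 (positive = sea to air).

    F = k_w (1 - f_ice) (C_w - C_eq) over the uncovered sea surface, where
    C_eq is the aqueous concentration in equilibrium with atmospheric Hg0.
    """
    f_ice = np.asarray(f_ice, float)
    if np.any(f_ice < 0) or np.any(f_ice > 1):
        raise ValueError("f_ice must lie in [0, 1]")
    c_w = np.asarray(c_w_pm, float)
    if np.any(c_w < 0) or np.any(np.asarray(c_atm_ng_m3, float) < 0):
        raise ValueError("concentrations must be >= 0")
    k_w = piston_velocity(u10, t_c, p) * units.CM_PER_H_TO_M_PER_D  # m d-1
    c_eq = atm_equilibrium_pm(c_atm_ng_m3, t_c, p)
    return k_w * (1.0 - f_ice) * (c_w - c_eq) * units.PM_TIMES_M_TO_PMOL_M2


def dmhg_evasion(c_w_pm, t_c, u10, f_ice, p: ExchangeParams = ExchangeParams()):
    """One-way DMHg evasion flux, pmol m-2 d-1 (atmospheric DMHg ~ 0)."""
    f_ice = np.asarray(f_ice, float)
    if np.any(f_ice < 0) or np.any(f_ice > 1):
        raise ValueError("f_ice must lie in [0, 1]")
    c_w = np.asarray(c_w_pm, float)
    if np.any(c_w < 0):
        raise ValueError("concentrations must be >= 0")
    k_w = piston_velocity(u10, t_c, p) * units.CM_PER_H_TO_M_PER_D
    return k_w * (1.0 - f_ice) * c_w * units.PM_TIMES_M_TO_PMOL_M2
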