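"""Per-cell mercury reaction network.

Four dissolved tracers take part in chemistry — Hg0, dissolved HgII, MMHg
and DMHg (particle-bound HgP is handled by the partition/sinking operators):

    Hg0  <-> HgII : photochemical + OCRR-scaled biological reduction vs.
                    photochemical + constant dark oxidation
    HgII  -> MMHg : methylation proportional to OCRR (microbial activity)
    MMHg  -> HgII : photodemethylation (linear in local shortwave intensity)
                    + dark demethylation (Q10 temperature law)
    MMHg <-> DMHg : OCRR-scaled formation, constant decomposition

Everything is linear in the state, so one step is the exponential of the
per-cell rate matrix.  The propagator is evaluated by uniformization
(randomization): P = sum_n Poisson(lambda*dt; n) M^n with M = I + A/lambda a
column-stochastic matrix.  Truncation is renormalized, so the step conserves
total mercury per cell to round-off and can never produce a negative tracer.
"""
from __future__ import annotations

import numpy as np

from .params import RateParams

#: chemistry species order within the dissolved block
SPECIES = ("hg0", "hg2d", "mmhg", "dmhg")


def light_profile(i0, chl, doc, f_ice, dz, p: RateParams = RateParams()):
    """Shortwave intensity at each layer's mid-depth, W m-2.

    Beer-Lambert attenuation by water, chlorophyll and DOC, evaluated with
    half-layer attenuation at the layer centre; sea ice shields the whole
    column (I is scaled by the uncovered fraction 1 - f_ice).

    ``chl``/``doc`` are per-layer arrays whose last axis is depth; ``i0`` and
    ``f_ice`` broadcast against their leading axes.
    """
    chl = np.asarray(chl, float)
    doc = np.asarray(doc, float)
    i0 = np.asarray(i0, float)
    f_ice = np.asarray(f_ice, float)
    dz = np.asarray(dz, float)
    if np.any(chl < 0) or np.any(doc < 0) or np.any(i0 < 0):
        raise ValueError("light-profile inputs must be >= 0")
    if p.a_w < 0 or p.a_chl < 0 or p.a_doc < 0:
        raise ValueError("attenuation coefficients must be >= 0")
    a = p.a_w + p.a_chl * chl + p.a_doc * doc            # m-1 per layer
    tau = a * dz                                          # optical depth per layer
    cum = np.cumsum(tau, axis=-1) - 0.5 * tau             # to layer mid-depth
    return i0[..., None] * (1.0 - f_ice[..., None]) * np.exp(-cum)


def methylation_rate(ocrr, p: RateParams = RateParams()):
    """First-order HgII -> MMHg rate, d-1, exactly proportional to OCRR."""
    ocrr = np.asarray(ocrr, float)
    if np.any(ocrr < 0):
        raise ValueError("OCRR must be >= 0")
    return p.c_meth * ocrr


def dark_demethylation_rate(t_c, p: RateParams = RateParams()):
    """Temperature-dependent dark demethylation, d-1 (Q10 law about 20 degC)."""
    t = np.asarray(t_c, float)
    return p.k_dd20 * p.q10_dd ** ((t - 20.0) / 10.0)


def photodemethylation_rate(i, p: RateParams = RateParams()):
    """Light-driven MMHg decomposition, d-1, linear in shortwave intensity."""
    i = np.asarray(i, float)
    if np.any(i < 0):
        raise ValueError("shortwave intensity must be >= 0")
    return p.k_pd * i


def redox_rates(i, ocrr, t_c, p: RateParams = RateParams()):
    """Hg0/HgII conversion rates, d-1, as a dict.

    Dark oxidation is a constant; in a dark cell it is the only nonzero
    redox pathway, so Hg0 decays monotonically toward HgII there.
    """
    i = np.asarray(i, float)
    ocrr = np.asarray(ocrr, float)
    if np.any(i < 0) or np.any(ocrr < 0):
        raise ValueError("inputs must be >= 0")
    return {
        "k_red_photo": p.k_photored * i,
        "k_red_bio": p.k_biored * ocrr,
        "k_ox_photo": p.k_photoox * i,
        "k_ox_dark": np.broadcast_to(np.float64(p.k_darkox), i.shape).copy()
        if i.ndim else np.float64(p.k_darkox),
    }


def build_rates(i, ocrr, t_c, p: RateParams = RateParams()):
    """All first-order rates of the network for given local forcing fields."""
    r = redox_rates(i, ocrr, t_c, p)
    r["k_meth"] = methylation_rate(ocrr, p)
    r["k_pd_eff"] = photodemethylation_rate(i, p)
    r["k_dd"] = dark_demethylation_rate(t_c, p)
    r["k_mm_dm"] = p.c_dmhg * np.asarray(ocrr, float)
    r["k_dm_mm"] = np.broadcast_to(np.float64(p.k_dm_decomp),
                                   np.asarray(i, float).shape).copy()
    return r


_RATE_KEYS = ("k_red_photo", "k_red_bio", "k_ox_photo", "k_ox_dark",
              "k_meth", "k_pd_eff", "k_dd", "k_mm_dm", "k_dm_mm")


def rate_matrix(rates: dict) -> np.ndarray:
    """Per-cell generator matrix A (..., 4, 4) in SPECIES order.

    Columns sum to zero (a closed network): dC/dt = A @ C.
    """
    arrs = [np.asarray(rates[k], float) for k in _RATE_KEYS]
    for k, a in zip(_RATE_KEYS, arrs):
        if np.any(a < 0):
            raise ValueError(f"negative rate {k}")
    shape = np.broadcast_shapes(*(a.shape for a in arrs))
    (k_rp, k_rb, k_op, k_od, k_me, k_pd, k_dd, k_md, k_dm) = (
        np.broadcast_to(a, shape) for a in arrs)
    A = np.zeros(shape + (4, 4))
    k_ox = k_op + k_od
    k_red = k_rp + k_rb
    k_dem = k_pd + k_dd
    A[..., 0, 0] = -k_ox
    A[..., 1, 0] = k_ox
    A[..., 0, 1] = k_red
    A[..., 1, 1] = -(k_red + k_me)
    A[..., 2, 1] = k_me
    A[..., 1, 2] = k_dem
    A[..., 2, 2] = -(k_dem + k_md)
    A[..., 3, 2] = k_md
    A[..., 2, 3] = k_dm
    A[..., 3, 3] = -k_dm
    return A


def chem_propagator(rates: dict, dt: float, tol: float = 1e-15) -> np.ndarray:
    """exp(A dt) per cell via uniformization, column-renormalized.

    The renormalization divides by the truncated Poisson mass, so columns of
    the returned propagator sum to 1 up to round-off: the step is exactly
    conservative and non-negative for any admissible rates and dt.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    A = rate_matrix(rates)
    lam = np.maximum(-np.min(np.diagonal(A, axis1=-2, axis2=-1), axis=-1), 1e-12)
    M = A / lam[..., None, None]
    idx = np.arange(4)
    M[..., idx, idx] += 1.0
    lt = lam * dt
    lt_max = float(np.max(lt))
    # Poisson tail bound: generous fixed cap, cheap at 4x4
    n_max = int(np.ceil(lt_max + 12.0 * np.sqrt(lt_max + 1.0) + 25.0))
    eye = np.broadcast_to(np.eye(4), M.shape).copy()
    P = np.zeros_like(M)
    w = np.exp(-lt)                      # Poisson weight, n = 0
    wsum = np.zeros_like(lt)
    Mn = eye
    for n in range(n_max + 1):
        if n > 0:
            Mn = np.einsum("...ij,...jk->...ik", M, Mn)
            w = w * lt / n
        P += w[..., None, None] * Mn
        wsum += w
        if np.max(1.0 - wsum) < tol and n > 2:
            break
    P /= wsum[..., None, None]
    # exact column stochasticity against accumulated round-off
    P /= np.sum(P, axis=-2, keepdims=True)
    return P


def apply_propagator(P: np.ndarray, conc: np.ndarray) -> np.ndarray:
    """Apply a (..., 4, 4) propagator to a (..., 4) concentration block."""
    return np.einsum("...ij,...j->...i", P, conc)


def step_chemistry(conc: np.ndarray, rates: dict, dt: float) -> np.ndarray:
    """Advance the dissolved 4-species block by ``dt`` days.

    ``conc`` has the species on its last axis in SPECIES order.  The update
    conserves the per-cell sum exactly and keeps every tracer >= 0.
    """
    conc = np.asarray(conc, float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    return apply_propagator(chem_propagator(rates, dt), conc)
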