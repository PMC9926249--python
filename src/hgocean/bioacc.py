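"""Plankton methylmercury bioaccumulation.

Phytoplankton uptake is instantaneous: the intracellular concentration is
the seawater MMHg times a volume concentration factor VCF(d, DOC) that
decreases with cell diameter (surface-area-to-volume scaling) and with DOC
(complexation lowers bioavailability).  Zooplankton body burden is dynamic:
grazing intake assimilated with efficiency AE, first-order elimination, and
mortality that removes biomass and burden proportionally (leaving the
concentration unchanged).  Coupling is one-way — biotic uptake does not
deplete seawater MMHg.
"""
from __future__ import annotations

import numpy as np

from .params import BioaccParams, PlanktonGroup


def vcf(d, doc, p: BioaccParams = BioaccParams()):
    """Volume concentration factor, dimensionless.

    log10 VCF = v0 - alpha_d log10(d/d_ref) - alpha_doc log10(DOC/DOC_ref);
    strictly decreasing in both cell diameter and DOC.
    """
    d = np.asarray(d, float)
    doc = np.asarray(doc, float)
    if np.any(d <= 0) or np.any(doc <= 0):
        raise ValueError("cell diameter and DOC must be > 0")
    logv = (p.v0 - p.alpha_d * np.log10(d / p.d_ref)
            - p.alpha_doc * np.log10(doc / p.doc_ref))
    return 10.0 ** logv


def phyto_mmhg(group: PlanktonGroup, mmhg_w, doc, p: BioaccParams = BioaccParams()):
    """Intracellular MMHg of a phytoplankton group, pM on a cell-volume basis."""
    if group.trophic_role != "phyto":
        raise ValueError(f"{group.name} is not a phytoplankton group")
    mmhg_w = np.asarray(mmhg_w, float)
    if np.any(mmhg_w < 0):
        raise ValueError("seawater MMHg must be >= 0")
    return vcf(group.d, doc, p) * mmhg_w


def zoo_mmhg_step(q, grazing: dict, prey_conc: dict, biomass, group_name: str,
                  p: BioaccParams = BioaccParams(), dt: float = 1.0):
    """Advance a zooplankton body burden (pM per unit biovolume) by ``dt`` days.

    dQ/dt = AE * sum_prey(grazing_prey * C_prey) / biomass - k_elim * Q.
    Uses the exact exponential update of the linear ODE, so the steady state
    Q* = AE * intake / k_elim is recovered without time-step bias.
    """
    ae = p.ae[group_name]
    k = p.k_elim[group_name]
    if not 0.0 <= ae <= 1.0:
        raise ValueError("assimilation efficiency outside [0, 1]")
    q = np.asarray(q, float)
    biomass = np.asarray(biomass, float)
    intake = sum(np.asarray(grazing[prey], float) * np.asarray(prey_conc[prey], float)
                 for prey in grazing)
    if np.any(np.asarray(intake) < 0) or np.any(q < 0):
        raise ValueError("intake fluxes and burdens must be >= 0")
    spec_intake = np.where(biomass > 0, intake / np.where(biomass > 0, biomass, 1.0), 0.0)
    q_ss = ae * spec_intake / k
    return q_ss + (q - q_ss) * np.exp(-k * dt)
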