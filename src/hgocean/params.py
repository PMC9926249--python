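"""Parameter blocks: gas exchange, reaction kinetics, partitioning, and
bioaccumulation, each with explicit units.

Rate-constant defaults are order-of-magnitude choices calibrated so that the
base run's surface (~0.5 pM) and subsurface (~1 pM) inorganic Hg inventories,
the surface Hg0 fraction (~10%), and the methylated fraction (~10-30% of
total Hg) fall in the observed ranges; all of them are exposed through the
run configuration.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass(frozen=True)
class ExchangeParams:
    """Air-sea exchange constants.

    ``b_vanthoff``/``c_henry`` parameterize the dimensionless gas-water
    partition coefficient (volatility) of Hg0 in van 't Hoff form,
    K = exp(c - b/T_K); the aqueous solubility is 1/K and *decreases* with
    temperature at 2.5-2.9% per +1 degC in the 10-35 degC range.
    ``sc_coeffs`` is a Schmidt-number polynomial in T (degC); the default is
    the standard seawater gas-exchange fit used with the quadratic wind-speed
    transfer law and its 0.251 cm h-1 (m s-1)-2 coefficient.
    """

    b_vanthoff: float = 2404.3          # K
    c_henry: float = 6.92               # dimensionless
    k_ref: float = 0.251                # cm h-1 (m s-1)-2
    sc_coeffs: tuple = (2116.8, -136.25, 4.7353, -0.092307, 0.0007555)
    sc_ref: float = 660.0               # Schmidt number the transfer law is referenced to
    t_min: float = -2.0                 # degC, physical ocean range
    t_max: float = 40.0

    def __post_init__(self):
        if self.b_vanthoff < 0:
            raise ValueError("b_vanthoff must be >= 0")
        if self.k_ref < 0 or self.sc_ref <= 0:
            raise ValueError("k_ref must be >= 0 and sc_ref > 0")


@dataclass(frozen=True)
class RateParams:
    """First-order rate coefficients of the per-cell reaction network."""

    k_photored: float = 4.0e-4   # (W m-2)-1 d-1, HgII -> Hg0
    k_photoox: float = 1.2e-3    # (W m-2)-1 d-1, Hg0 -> HgII
    k_biored: float = 3.0e-3     # (mg C m-3 d-1)-1 d-1, HgII -> Hg0, scaled by OCRR
    k_darkox: float = 0.02       # d-1, Hg0 -> HgII in the dark
    c_meth: float = 1.5e-3       # (mg C m-3 d-1)-1 d-1, HgII -> MMHg, scaled by OCRR
    c_dmhg: float = 3.0e-4       # (mg C m-3 d-1)-1 d-1, MMHg -> DMHg, scaled by OCRR
    k_dm_decomp: float = 0.005   # d-1, DMHg -> MMHg
    k_pd: float = 2.5e-3         # (W m-2)-1 d-1, photodemethylation
    k_dd20: float = 0.015        # d-1, dark demethylation at 20 degC
    q10_dd: float = 2.0          # dimensionless
    a_w: float = 0.03            # m-1, clear-water shortwave attenuation
    a_chl: float = 0.012         # m-1 (mg Chl m-3)-1
    a_doc: float = 4.0e-4        # m-1 uM-1

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"rate parameter {f.name} must be >= 0")


@dataclass(frozen=True)
class PartitionParams:
    """HgII-particle partitioning and particle sinking."""

    kd: float = 3.0e-5        # (mg POC m-3)-1, equilibrium partition coefficient
    w_s: float = 100.0        # m d-1, particle sinking speed
    remin_scale: float = 1.0  # fraction of the local specific OCRR applied to HgP

    def __post_init__(self):
        if self.kd < 0 or self.w_s < 0 or self.remin_scale < 0:
            raise ValueError("partition parameters must be >= 0")


@dataclass(frozen=True)
class PlanktonGroup:
    name: str
    d: float                      # equivalent spherical cell diameter, um
    trophic_role: str             # 'phyto' | 'zoo'
    preferred_prey: tuple = ()    # group names, zoo only

    def __post_init__(self):
        if self.d <= 0:
            raise ValueError("cell diameter must be > 0")
        if self.trophic_role not in ("phyto", "zoo"):
            raise ValueError("trophic_role must be 'phyto' or 'zoo'")


#: canonical community; diazotroph/coccolithophore diameters are not
#: constrained by observations of this community and are config-exposed.
DEFAULT_GROUPS = {
    "diatom": PlanktonGroup("diatom", 12.0, "phyto"),
    "other_large": PlanktonGroup("other_large", 10.0, "phyto"),
    "synechococcus": PlanktonGroup("synechococcus", 1.8, "phyto"),
    "prochlorococcus": PlanktonGroup("prochlorococcus", 0.6, "phyto"),
    "diazotroph": PlanktonGroup("diazotroph", 5.0, "phyto"),
    "coccolithophore": PlanktonGroup("coccolithophore", 4.0, "phyto"),
    "small_zoo": PlanktonGroup(
        "small_zoo", 30.0, "zoo",
        ("prochlorococcus", "synechococcus", "coccolithophore")),
    "large_zoo": PlanktonGroup(
        "large_zoo", 300.0, "zoo",
        ("diatom", "other_large", "diazotroph")),
}

PHYTO_GROUPS = ("diatom", "other_large", "synechococcus", "prochlorococcus",
                "diazotroph", "coccolithophore")
ZOO_GROUPS = ("small_zoo", "large_zoo")


@dataclass(frozen=True)
class BioaccParams:
    """Phytoplankton VCF(d, DOC) uptake and zooplankton trophic transfer."""

    v0: float = 5.0            # log10 VCF at (d_ref, doc_ref)
    alpha_d: float = 0.8       # diameter exponent, dimensionless
    alpha_doc: float = 0.35    # DOC exponent, dimensionless
    d_ref: float = 10.0        # um
    doc_ref: float = 60.0      # uM
    ae: dict = field(default_factory=lambda: {"small_zoo": 0.30, "large_zoo": 0.30})
    k_elim: dict = field(default_factory=lambda: {"small_zoo": 0.10, "large_zoo": 0.02})

    def __post_init__(self):
        if self.alpha_d < 0 or self.alpha_doc < 0:
            raise ValueError("VCF exponents must be >= 0")
        if self.d_ref <= 0 or self.doc_ref <= 0:
            raise ValueError("VCF reference point must be positive")
        for g, v in self.ae.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"assimilation efficiency of {g} outside [0, 1]")
        for g, v in self.k_elim.items():
            if v <= 0:
                raise ValueError(f"elimination rate of {g} must be > 0")


#: unit strings for every configurable parameter (written into configs)
PARAM_UNITS = {
    "exchange.b_vanthoff": "K",
    "exchange.c_henry": "1",
    "exchange.k_ref": "cm h-1 (m s-1)-2",
    "exchange.sc_coeffs": "1 (polynomial in degC)",
    "exchange.sc_ref": "1",
    "exchange.t_min": "degC",
    "exchange.t_max": "degC",
    "rates.k_photored": "(W m-2)-1 d-1",
    "rates.k_photoox": "(W m-2)-1 d-1",
    "rates.k_biored": "(mg C m-3 d-1)-1 d-1",
    "rates.k_darkox": "d-1",
    "rates.c_meth": "(mg C m-3 d-1)-1 d-1",
    "rates.c_dmhg": "(mg C m-3 d-1)-1 d-1",
    "rates.k_dm_decomp": "d-1",
    "rates.k_pd": "(W m-2)-1 d-1",
    "rates.k_dd20": "d-1",
    "rates.q10_dd": "1",
    "rates.a_w": "m-1",
    "rates.a_chl": "m-1 (mg Chl m-3)-1",
    "rates.a_doc": "m-1 uM-1",
    "partition.kd": "(mg POC m-3)-1",
    "partition.w_s": "m d-1",
    "partition.remin_scale": "1",
    "bioacc.v0": "log10(1)",
    "bioacc.alpha_d": "1",
    "bioacc.alpha_doc": "1",
    "bioacc.d_ref": "um",
    "bioacc.doc_ref": "uM",
    "bioacc.ae": "1 (per zoo group)",
    "bioacc.k_elim": "d-1 (per zoo group)",
}


@dataclass(frozen=True)
class ModelParams:
    """All parameter blocks bundled."""

    exchange: ExchangeParams = field(default_factory=ExchangeParams)
    rates: RateParams = field(default_factory=RateParams)
    partition: PartitionParams = field(default_factory=PartitionParams)
    bioacc: BioaccParams = field(default_factory=BioaccParams)
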