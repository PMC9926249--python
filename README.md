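# hgocean

A reduced-complexity, mass-conserving simulator of the global marine mercury
cycle, built to study how twenty-first-century climate change reshapes
seawater methylmercury and its entry into plankton food webs.

Methylmercury (CH₃Hg) is the neurotoxic mercury species that bioaccumulates
in seafood.  Its ocean budget sits downstream of a chain of
climate-sensitive processes: atmospheric Hg deposition, air–sea exchange of
elemental Hg⁰, redox cycling, scavenging of Hgᴵᴵ onto sinking organic
particles, microbial methylation fueled by organic-carbon remineralization,
photochemical and dark demethylation, and size-dependent uptake by
phytoplankton with trophic transfer to zooplankton.  `hgocean` represents
this full process network on a deliberately small grid (zonal bands ×
{open, coastal} columns × depth layers) so that the *one-factor-at-a-time*
climate experiment design — run the present day, then flip exactly one
forcing (temperature, wind, sea ice, radiation, circulation, community
structure, Chl, DOC, POC or OCRR) to its 2100 state — can be executed,
audited and tested on a desktop.  It is aimed at biogeochemical modellers
and ecotoxicologists who want a transparent sandbox for climate–mercury
interaction mechanisms rather than a production GCM.

## Model core

Five tracers per grid cell (pM): Hg⁰, dissolved Hgᴵᴵ, particle-bound Hgᴾ,
CH₃Hg (MMHg) and (CH₃)₂Hg (DMHg).

**Air–sea exchange.** Net Hg⁰ evasion over the uncovered surface,
F = k_w (1 − f_ice)(C_w − C_atm/K_H), with piston velocity
k_w = 0.251 u₁₀² (Sc/660)^(−1/2) cm h⁻¹ and a van 't Hoff gas–water
partition coefficient K_H = exp(6.92 − 2404.3/T_K).  The implied solubility
1/K_H drops 2.5–2.9 % per +1 °C in the 10–35 °C range, the quantity that
makes warming favour evasion.  DMHg evades one-way (atmospheric DMHg ≈ 0).

**Chemistry** (per cell, linear network, exactly mass-conserving):
photochemical/biological reduction and photochemical/dark oxidation between
Hg⁰ and Hgᴵᴵ; methylation Hgᴵᴵ → MMHg at k = c_meth·OCRR; demethylation
MMHg → Hgᴵᴵ at k_pd·I(z) + k_dd20·Q10^((T−20)/10); MMHg ⇌ DMHg with an
OCRR-scaled forward rate.  Light I(z) follows Beer–Lambert attenuation by
water, chlorophyll and DOC and is shielded by sea ice — the lever behind the
chlorophyll, radiation and sea-ice responses.

**Particles.** Hgᴾ is in instantaneous equilibrium with dissolved Hgᴵᴵ,
HgP/HgII_total = K_d·POC/(1 + K_d·POC); it sinks upwind at w_s = 100 m d⁻¹,
remineralizes with the local specific OCRR, and is buried at the sea floor.

**Bioaccumulation.** Phytoplankton CH₃Hg is instantaneous,
C = VCF(d, DOC)·MMHg with log₁₀ VCF decreasing in cell diameter and DOC.
Zooplankton body burden integrates dQ/dt = AE·intake − k_elim·Q, with slower
elimination for large grazers.

**Experiments.** Every scenario spins up 10 years on repeating monthly
forcing and reports last-year diagnostics (volume-weighted surface 0–100 m,
subsurface 100–1000 m and coastal means, annual fluxes, plankton burdens),
plus percent changes against the base run, a `_physics`/`_acid` split of the
biogeochemical factors, and the additivity residual of the decomposition.

The synthetic forcing generator supplies both epochs with analytic
latitude/season patterns calibrated so that, e.g., global-mean surface
chlorophyll is exactly 2.52 (present) and 1.17 mg m⁻³ (2100), warming covers
every cell, wind weakens outside the tropics, polar ice halves, and the
plankton community shifts from large eukaryotes toward *Synechococcus*.

## Worked example

```python
import hgocean as h
from hgocean.experiments import ScenarioSpec, run_scenario, percent_change

grid = h.Grid()
present = h.generate_forcing("present", grid, seed=0)
future = h.generate_forcing("future", grid, seed=0)
physics = h.generate_forcing("future_physics", grid, seed=0)

base = run_scenario(ScenarioSpec.from_name("base"), present, future, physics)
temp = run_scenario(ScenarioSpec.from_name("temperature"), present, future, physics)

d = base.diagnostics
print(f"present-day surface inorganic Hg : {d['surface_hg_inorg_pM']:.2f} pM")
print(f"present-day subsurface inorganic : {d['subsurface_hg_inorg_pM']:.2f} pM")
print(f"surface CH3Hg                    : {d['surface_mmhg_pM']:.3f} pM")
print(f"net Hg0 evasion                  : {d['evasion_hg0_mol_yr']:.3g} mol/yr")

pct = percent_change(temp.diagnostics, d)
print(f"warming-only: net evasion {pct['evasion_hg0_mol_yr']:+.1f} %, "
      f"surface inorganic Hg {pct['surface_hg_inorg_pM']:+.1f} %, "
      f"surface CH3Hg {pct['surface_mmhg_pM']:+.1f} %")
```

prints

```
present-day surface inorganic Hg : 0.51 pM
present-day subsurface inorganic : 0.43 pM
surface CH3Hg                    : 0.052 pM
net Hg0 evasion                  : 1.4e+07 mol/yr
warming-only: net evasion +2.3 %, surface inorganic Hg -3.1 %, surface CH3Hg -12.3 %
```

The base state sits at observed open-ocean magnitudes (≈0.5 pM total
inorganic Hg; net evasion ≈ 1.4 × 10⁷ mol y⁻¹ ≈ 2.8 kt y⁻¹).  Warming alone
increases Hg⁰ evasion (solubility drop), which lowers surface inorganic Hg,
and accelerates dark demethylation, which lowers surface CH₃Hg — the two
contrasting air–sea levers of the climate response.

The full suite (base, all, ten single factors) runs in well under a minute:

```sh
hgocean suite --seed 0 --out-prefix suite     # CSV diagnostics + percent tables
hgocean run --scenario Chl                    # single experiment
hgocean generate-forcing --epoch future --out future.nc
```

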