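# hgocean: model description and methods

## Scope and philosophy

`hgocean` is a reduced-complexity simulator of the global marine mercury
cycle: five tracers (Hg⁰, dissolved Hgᴵᴵ, particulate Hgᴾ, CH₃Hg, (CH₃)₂Hg)
on a zonal-band grid, driven by synthetic monthly climatologies for a
present-day epoch and an end-of-century high-emission epoch, with a
one-factor-at-a-time experiment suite that attributes the simulated change
to individual forcing factors.  The design goal is mechanism transparency
and testability, not spatial realism: every process operator is separately
unit-tested against closed forms or independent oracles, total mercury is
conserved to round-off, and the full 12-scenario suite runs in well under a
minute on one CPU core.

## Grid and calendar

The ocean is discretized into 18 latitude bands of 10°, each split into an
open-ocean column and a coastal column holding 8 % of the band's area
(configurable; a reduced grid has no literal coastline, so the coastal
fraction is a free parameter).  The vertical uses 15 layers from 0 to
5000 m whose edges include exactly 100 m and 1000 m, so the euphotic
(0–100 m) and subsurface (100–1000 m) diagnostic masks are sharp layer
unions.  70 % of each band's spherical area is treated as ocean.  Time runs
on a 360-day year of twelve 30-day months with a 1-day operator-splitting
step; monthly forcing repeats as a climatological cycle.  Problem size:
18 × 2 × 15 = 540 cells.

## Process operators and numerics

Operator order per day: chemistry → remineralization → equilibrium
partitioning → particle sinking → vertical transport → air–sea exchange and
deposition → zooplankton burden update.  Splitting error is second order in
the daily step at the rate magnitudes used (all first-order rates
≤ ~0.4 d⁻¹).

**Chemistry.**  The per-cell network is linear, dC/dt = A·C with A a
generator matrix (columns sum to zero).  One step applies
P = exp(A·dt), evaluated by uniformization: with λ the largest outflow rate
in the cell and M = I + A/λ (a column-stochastic, non-negative matrix),
P = Σₙ Poisson(λ dt; n) Mⁿ.  The truncated sum is renormalized by the
truncated Poisson mass and its columns normalized to 1, so the update is
*exactly* conservative and non-negative at any truncation; the truncation
depth (λdt + 12√(λdt+1) + 25 terms) puts the series error near machine
precision.  Tests verify agreement with `scipy.linalg.expm` (an independent
oracle) to far better than the 0.1 % requirement.  Because forcing is
monthly, the scenario driver caches twelve propagators per run; a daily step
is then a single batched 4×4 mat-vec.

Reactions: Hg⁰ ⇌ Hgᴵᴵ with reduction k_photored·I + k_biored·OCRR and
oxidation k_photoox·I + k_darkox; methylation c_meth·OCRR; demethylation
k_pd·I + k_dd20·Q10^((T−20)/10); MMHg → DMHg at c_dmhg·OCRR and DMHg → MMHg
at a constant k_dm_decomp.  Methylation acts on *dissolved* Hgᴵᴵ only, and
MMHg denotes the dissolved phase (no particulate MMHg pool) — both choices
made where the process literature is ambiguous, and documented here.

**Light.**  I(z) = I₀(1 − f_ice)·exp(−∫(a_w + a_chl·Chl + a_doc·DOC)dz),
evaluated at layer mid-depth with half-layer attenuation.  Sea ice shields
the entire column; per typical concentrations DOC attenuates far less than
chlorophyll (a_doc·70 µM ≈ 0.03 m⁻¹ vs a_chl·2.5 mg m⁻³ ≈ 0.03 m⁻¹ per the
defaults below — the chlorophyll term varies much more strongly between
epochs, which is what makes it the dominant photodemethylation lever).

**Partitioning and sinking.**  Hgᴾ is diagnosed each step from the total
divalent pool: HgP/HgII_tot = K_d·POC/(1+K_d·POC) (instantaneous
equilibrium, following the diagnostic reading of the partition
formulation).  Sinking is first-order upwind at w_s with sub-stepping so
w_s·Δt never exceeds the thinnest layer; flux through the bottom interface
is removed as burial.  Remineralization releases Hgᴾ to dissolved Hgᴵᴵ at
remin_scale·OCRR/POC; under instantaneous re-partitioning this release is a
phase transfer that the next partition step re-splits, so in the coupled
loop it is effectively diagnostic — the operator is retained (and tested)
because it matters whenever kinetic partitioning or partitioning-free
configurations are explored.

**Vertical transport.**  Explicit flux-form exchange across layer
interfaces with coefficient K/Δz_c + w_up, positivity-limited sub-stepping,
and no horizontal exchange between bands.  Upwelling is implemented as a
two-way exchange w·(c_below − c_above): a one-way upward advection in a
closed column with no resolved return flow cannot conserve mass, and the
exchange form carries the relevant signal (an enriched subsurface supplies
the surface faster when upwelling is strong).  The operator is linear,
conserves each tracer exactly, and rejects configurations needing more than
1000 sub-steps per day, naming the offending interface.

**Air–sea exchange.**  Piston velocity k_w = k_ref·u₁₀²·(Sc/660)^(−1/2)
with the standard quadratic-wind seawater transfer coefficient
k_ref = 0.251 cm h⁻¹ (m s⁻¹)⁻² and a quartic Schmidt-number polynomial in
temperature; monthly-mean winds are used directly (no gustiness
enhancement).  The Hg⁰ gas–water partition coefficient is van 't Hoff,
K_H = exp(6.92 − 2404.3/T_K) (gas/aqueous form; the aqueous solubility is
1/K_H and falls 2.5–2.9 % per +1 °C at mid-range temperatures, the printed
constraint the parameterization is pinned to).  The top-layer update is an
exact exponential relaxation toward atmospheric equilibrium, with the
evaded mass booked from the actual inventory change so the budget closes to
round-off.  DMHg evasion is one-way (atmospheric DMHg ≈ 0).  Deposition of
Hgᴵᴵ enters the top layer regardless of ice cover and is identical in all
epochs, so scenario differences isolate the ocean's response.

**Bioaccumulation.**  log₁₀ VCF = v₀ − α_d log₁₀(d/d_ref) − α_doc
log₁₀(DOC/DOC_ref): a power law in cell diameter (surface-to-volume
scaling) and DOC (complexation lowers bioavailability); only the monotone
directions are empirically constrained, so the exponents are
config-exposed.  Phytoplankton burden is instantaneous VCF·MMHg.
Zooplankton burden integrates dQ/dt = AE·Σ(g_p·C_p)/B_z − k_elim·Q with the
exact exponential update; mortality removes biomass and burden
proportionally (Q unchanged) and does not return CH₃Hg to the water by
default, keeping the water-column budget closed without double counting.
Coupling is one-way (uptake does not deplete seawater MMHg).

## Parameters

Defaults, units, and the reasoning behind each (all exposed in the YAML
configuration with unit strings):

| block | parameter | default | why |
|---|---|---|---|
| exchange | B, C (van 't Hoff) | 2404.3 K, 6.92 | reproduces the 2.5–2.9 %/°C solubility drop at mid-range T |
| exchange | k_ref | 0.251 cm h⁻¹ (m s⁻¹)⁻² | standard quadratic-wind seawater transfer velocity |
| rates | k_photored / k_photoox | 4.0e-4 / 1.2e-3 (W m⁻²)⁻¹ d⁻¹ | surface redox turnover of hours–days; sets Hg⁰ ≈ 10–15 % of the surface inorganic pool so evasion balances deposition near 0.5 pM |
| rates | k_biored | 3.0e-3 (mgC m⁻³ d⁻¹)⁻¹ d⁻¹ | biological reduction comparable to photoreduction at typical OCRR |
| rates | k_darkox | 0.02 d⁻¹ | dark Hg⁰ lifetime ~50 d at depth |
| rates | c_meth | 1.5e-3 (mgC m⁻³ d⁻¹)⁻¹ d⁻¹ | subsurface methylation ~0.004 d⁻¹ at OCRR maxima; MMHg ≈ 10–30 % of total Hg |
| rates | k_pd | 2.5e-3 (W m⁻²)⁻¹ d⁻¹ | photodemethylation of several %/day at surface light, the observed range |
| rates | k_dd20, Q10 | 0.015 d⁻¹, 2.0 | dark demethylation lifetime ~2 months at 20 °C, halving per −10 °C |
| rates | c_dmhg, k_dm_decomp | 3.0e-4, 0.005 d⁻¹ | DMHg a small, evasion-controlled side pool; the slow decomposition makes ice-modulated evasion its dominant polar sink |
| rates | a_w, a_chl, a_doc | 0.03, 0.012, 4e-4 | Beer–Lambert coefficients; chlorophyll dominates the variable attenuation |
| partition | K_d | 3.0e-5 (mg POC m⁻³)⁻¹ | surface particulate fraction ~0.1–0.5 %, giving an Hgᴾ export flux ≈ 25–30 % of atmospheric deposition (the observed order).  A 10–30 % particulate fraction, sometimes quoted for particle-rich waters, is incompatible with w_s = 100 m d⁻¹ under instantaneous partitioning: it would evacuate the surface ocean in days |
| partition | w_s | 100 m d⁻¹ | fast-sinking aggregate speed |
| bioacc | v₀, α_d, α_doc | 5.0, 0.8, 0.35 | VCF ~10⁵ at (10 µm, 60 µM), decreasing ~6-fold from 0.6 to 12 µm |
| bioacc | AE, k_elim | 0.3; 0.10 / 0.02 d⁻¹ | assimilation ~30 %; large grazers eliminate 5× slower, giving them higher steady-state burdens on identical diets |

Deposition is 10 µg m⁻² y⁻¹ (≈ 1.8 × 10⁷ mol y⁻¹ ocean-wide) against
1.5 ng m⁻³ atmospheric Hg⁰ — both held fixed across epochs.

## The synthetic forcing generator

The generator emulates, with smooth analytic latitude/season functions, the
features of the archived earth-system and ecosystem fields that drive the
mercury response:

- **Calibrated means.**  Global-mean surface (0–100 m) chlorophyll is
  rescaled to exactly 2.52 mg m⁻³ (present) and 1.17 mg m⁻³ (2100), i.e. a
  54 % decline; mean surface warming is 2.5 °C (configurable within
  1–5 °C), amplified poleward and decaying with depth but positive in
  every cell.
- **Sign structure of the 2100 changes.**  Wind: −10 % outside the tropics,
  +3 % inside (net evasion falls).  Sea ice: halved.  Shortwave: +12 %
  poleward of ~45°, −3 % in the tropics.  POC and OCRR: −25 %/−22 % in
  upwelling bands, −8 % elsewhere.  DOC: +10 %.  Circulation: mixing ×0.7,
  upwelling ×0.6.  Amplitudes without a published counterpart are fixed
  once here and config-exposed; they were chosen so the generator
  reproduces the documented direction of each single-factor response,
  which is the generator's contract.
- **Vertical structure.**  Chlorophyll decays on 60 m; POC follows a
  power-law export profile tapered to ~0 below 2.5 km; OCRR peaks at
  200–400 m (remineralization is concentrated under the euphotic zone),
  which places the CH₃Hg maximum below 100 m as observed — this is what
  gives the circulation factor its sign (weaker exchange starves the
  surface of both substrate and CH₃Hg supplied from below).
- **Community structure.**  Six phytoplankton groups (diatom 12 µm, other
  large 10 µm, *Synechococcus* 1.8 µm, *Prochlorococcus* 0.6 µm, diazotroph
  5 µm, coccolithophore 4 µm — the last two diameters are not published and
  are free defaults) plus small (30 µm) and large (300 µm) zooplankton.
  2100 composition multipliers: diatoms ×0.55, other large ×0.7,
  *Prochlorococcus* ×0.95, plus an acidification-driven *Synechococcus*
  gain growing poleward (×1.2–2.4, stronger in coastal columns).  The
  community fields express food-web *structure*; productivity magnitude
  changes are carried by the Chl/POC/OCRR factors, so total biomass uses
  the present pattern.  Zooplankton grazing is bilinear in predator and
  prey biomass (linear functional response, reference prey 20 mg C m⁻³):
  a diet-share-normalized formulation was rejected because added
  *Synechococcus* could then never raise total intake, contradicting the
  small-grazer burden increase the community shift is known to produce.
- **Acidification split.**  `future_physics` equals `future` minus the
  acidification increment: OCRR without the +8 % CO₂-fertilization factor
  and no *Synechococcus* gain.  The `_acid` contribution of a factor is
  diagnosed as (full-factor percent change) − (`_physics` percent change),
  mirroring the construction of physics-only ecosystem runs.
- **Noise.**  The seed drives a ±5 % smooth multiplicative band-noise per
  field, identical across epochs (seeded per field, not per epoch) and
  centred to zero area-weighted mean, so calibrations and all inter-epoch
  orderings survive any realization.  Temperature receives an additive
  analogue; calibrated chlorophyll is rescaled after noising.

What the generator does **not** emulate: longitudinal structure (no
monsoon basins, boundary currents or regional seas), ENSO/interannual
variability, riverine nutrient or mercury inputs, and any feedback of the
mercury state onto the ecosystem.  Passing tests therefore demonstrate that
the *process network* responds with the documented signs under forcing
changes of realistic magnitude and pattern class — not that regional
magnitudes would be reproduced with real forcing fields.

## Experiments

Scenarios: `base` (empty factor set), `all` (all ten), one per factor, and
`_physics` variants that blend from the physics-only future.  Each runs 10
years from a uniform 0.5 pM dissolved-Hgᴵᴵ initial state (immediately
partitioned) and reports final-year means.  Steady state is *tested*, not
assumed: the runner records per-year global tracer means and flags any run
whose year-10/year-9 drift exceeds 1 % for any tracer (the reduced model's
slowest modes — DMHg under weakened circulation, for instance — can sit
just above that line; the flag is surfaced in results and CLI exit codes
rather than silently accepted).  Mass closure (Δ total Hg = deposition −
evasion − burial) is asserted every step at 10⁻¹⁰ relative tolerance.  The
one-at-a-time decomposition need not sum to the `all` response, so the
report includes the additivity residual per diagnostic.

## Numerical choices and degenerate inputs

Sub-step counts are positivity-driven (outflow rate × sub-step ≤ 0.9);
CFL violations beyond the sub-step cap raise an error naming the interface.
`w_s·dt` greater than the thinnest layer is rejected outright in the public
sinking operator; the driver sub-steps internally.  Zero biomass, zero POC
and fully ice-covered columns are all valid inputs (intake, particulate
fraction and light respectively go to zero); OCRR > 0 with POC = 0 is
rejected as inconsistent forcing.  Percent changes against a zero baseline
are reported as missing, not infinite.

## Known limitations

- Vertical-only transport: horizontal redistribution is absorbed into the
  synthetic fields; how much this biases the circulation-factor response
  relative to a 3-D flow field is unknown and undocumented by construction.
- Equilibrium partitioning makes remineralization release diagnostic (see
  above) and ties Hgᴾ rigidly to POC.
- No fish or higher-trophic-level bioenergetics; plankton burdens are the
  end of the modelled food web.
- No riverine inputs, sediment resuspension, estuarine burial, in-ice
  chemistry, or ligand speciation of Hgᴵᴵ; anthropogenic emissions and
  atmospheric boundary conditions are fixed.
- The 360-day calendar and monthly climatology exclude synoptic and
  interannual variability in the fluxes.
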