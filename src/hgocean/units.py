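"""Central unit-conversion table.

Concentrations are carried in pM (pmol per litre of seawater), fluxes across
the sea surface in pmol m-2 d-1, budget terms in mol, mixing coefficients in
m2 s-1 (converted to m2 d-1 inside the transport operator), sinking and
piston velocities in m d-1 (piston velocities are *specified* in cm h-1, the
field convention, and converted here).  Keeping every conversion in this one
module is deliberate: the literature mixes pM, ng m-3, mg m-3, cm h-1 and
percent, and a single conversion site prevents silent unit bugs.
"""

#: molar mass of mercury, g mol-1
M_HG = 200.59

#: cm h-1 -> m d-1  (piston velocities)
CM_PER_H_TO_M_PER_D = 24.0 / 100.0

#: m2 s-1 -> m2 d-1  (vertical mixing coefficients)
M2_PER_S_TO_M2_PER_D = 86400.0

#: (pM × m d-1) -> pmol m-2 d-1 : 1 pM = 1e3 pmol m-3
PM_TIMES_M_TO_PMOL_M2 = 1.0e3

#: (pM × m3) -> mol : 1 pM = 1e3 pmol m-3 = 1e-9 mol m-3
PM_M3_TO_MOL = 1.0e-9

#: atmospheric ng m-3 -> gas-phase pM (pmol per litre of air)
NG_M3_TO_PM_GAS = 1.0 / M_HG

#: deposition µg m-2 y-1 -> pmol m-2 d-1
UG_M2_Y_TO_PMOL_M2_D = 1.0e6 / M_HG / 365.0

#: days per model year / month (monthly-climatology calendar)
DAYS_PER_YEAR = 360
DAYS_PER_MONTH = 30
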