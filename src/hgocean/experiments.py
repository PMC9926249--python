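"""Climate scenario suite: base, all, and one-factor-at-a-time experiments.

Each scenario integrates the coupled mercury model (chemistry, partitioning,
sinking, vertical transport, air-sea exchange, plankton bioaccumulation)
over a repeating monthly climatology for a 10-year spin-up and reports
diagnostics from the final year only.  A scenario sets a chosen subset of
forcing factors to their 2100 state while everything else repeats the
present day; "_physics" variants take the future fields computed without the
ocean-acidification increment, and the acidification contribution of a
factor is diagnosed as (full-factor percent change) minus ("_physics"
percent change).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import airsea, bioacc, chem, units
from .forcing import (FACTORS, ForcingError, ForcingSet, blend_scenarios,
                      generate_forcing)
from .grid import Grid
from .params import DEFAULT_GROUPS, PHYTO_GROUPS, ZOO_GROUPS, ModelParams
from .partition import particulate_fraction, remineralize
from .transport import (BudgetLedger, HgState, sink_particles, step_transport)

SCENARIO_NAMES = ("base", "all") + FACTORS

#: diagnostic masks: (label, layer mask name, region restriction)
_MASKS = (("surface", "surface", None),
          ("subsurface", "subsurface", None),
          ("coastal_surface", "surface", "coastal"))

_TRACER_DIAGS = ("hg0", "hg2d", "hgp", "mmhg", "dmhg", "hg_inorg")


class ScenarioError(ValueError):
    """Unknown or inconsistent scenario specification."""


@dataclass(frozen=True)
class ScenarioSpec:
    """A named experiment: which factors take their 2100 state."""

    name: str
    factors: frozenset
    years: int = 10
    use_physics_forcing: bool = False

    @classmethod
    def from_name(cls, name: str, years: int = 10) -> "ScenarioSpec":
        phys = name.endswith("_physics")
        stem = name[: -len("_physics")] if phys else name
        if stem == "base":
            if phys:
                raise ScenarioError("base has no _physics variant")
            return cls(name, frozenset(), years, False)
        if stem == "all":
            return cls(name, frozenset(FACTORS), years, phys)
        if stem in FACTORS:
            return cls(name, frozenset({stem}), years, phys)
        raise ScenarioError(f"unknown scenario {name!r}")


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    state: HgState
    ledger: BudgetLedger
    diagnostics: dict
    yearly_means: pd.DataFrame        # global mean per tracer per spin-up year
    drift: dict                       # |year N / year N-1 - 1| per tracer
    converged: bool


# ---------------------------------------------------------------------------

class _MonthlyCache:
    """Per-month operators precomputed from a blended forcing."""

    def __init__(self, f: ForcingSet, params: ModelParams, dt: float):
        g = f.grid
        self.grid = g
        p = params
        dz = g.dz
        self.chem_prop = []
        self.f_part = []
        self.remin_rate = []
        self.airsea_rate_hg0 = []
        self.airsea_rate_dmhg = []
        self.c_eq = []
        self.dep_flux = []
        self.zoo_coef = {z: [] for z in ZOO_GROUPS}
        self.vcf_groups = {gname: [] for gname in PHYTO_GROUPS}
        self.phyto_coef = []
        self.rate_fields = []
        for m in range(g.n_months):
            i_col = chem.light_profile(f.i0[:, :, m], f.chl[:, :, :, m],
                                       f.doc[:, :, :, m], f.f_ice[:, :, m],
                                       dz, p.rates)
            rates = chem.build_rates(i_col, f.ocrr[:, :, :, m],
                                     f.t[:, :, :, m], p.rates)
            self.rate_fields.append(rates)
            self.chem_prop.append(chem.chem_propagator(rates, dt))
            self.f_part.append(particulate_fraction(f.poc[:, :, :, m], p.partition))
            poc = f.poc[:, :, :, m]
            ocrr = f.ocrr[:, :, :, m]
            self.remin_rate.append(
                np.where(poc > 0, p.partition.remin_scale * ocrr
                         / np.where(poc > 0, poc, 1.0), 0.0))
            k_w = (airsea.piston_velocity(f.u10[:, :, m], f.t[:, :, 0, m],
                                          p.exchange)
                   * units.CM_PER_H_TO_M_PER_D)                    # m d-1
            open_frac = 1.0 - f.f_ice[:, :, m]
            self.airsea_rate_hg0.append(k_w * open_frac / dz[0])   # d-1
            self.airsea_rate_dmhg.append(k_w * open_frac / dz[0])
            self.c_eq.append(airsea.atm_equilibrium_pm(
                f.atm_hg0[:, None, m], f.t[:, :, 0, m], p.exchange))
            self.dep_flux.append(f.dep_hg2[:, None, m]
                                 * units.UG_M2_Y_TO_PMOL_M2_D)     # pmol m-2 d-1
            doc = f.doc[:, :, :, m]
            vcfs = {gname: bioacc.vcf(DEFAULT_GROUPS[gname].d, doc, p.bioacc)
                    for gname in PHYTO_GROUPS}
            for gname in PHYTO_GROUPS:
                self.vcf_groups[gname].append(vcfs[gname])
            b_phyto = {gname: f.biomass[f.phyto_index(gname), :, :, :, m]
                       for gname in PHYTO_GROUPS}
            b_tot = sum(b_phyto.values())
            self.phyto_coef.append(
                np.where(b_tot > 0,
                         sum(b_phyto[gn] * vcfs[gn] for gn in PHYTO_GROUPS)
                         / np.where(b_tot > 0, b_tot, 1.0), 0.0))
            for iz, z in enumerate(ZOO_GROUPS):
                bz = f.biomass[len(PHYTO_GROUPS) + iz, :, :, :, m]
                intake = sum(f.grazing[iz, ip, :, :, :, m] * vcfs[gn]
                             for ip, gn in enumerate(PHYTO_GROUPS))
                self.zoo_coef[z].append(
                    np.where(bz > 0, intake / np.where(bz > 0, bz, 1.0), 0.0))


def run_scenario(spec: ScenarioSpec, base_forcing: ForcingSet,
                 future_forcing: ForcingSet,
                 future_physics_forcing: ForcingSet | None = None,
                 params: ModelParams | None = None,
                 dt: float = 1.0, init_hg2d_pm: float = 0.5,
                 budget_rtol: float = 1e-10) -> ScenarioResult:
    """Integrate one scenario and return last-year diagnostics.

    Deterministic for fixed inputs.  Mass closure (d total Hg = deposition -
    evasion - burial) is verified every step to ``budget_rtol``; spin-up
    convergence (last-year drift of every global tracer mean < 1%) is flagged
    in the result, not silently accepted.
    """
    params = params or ModelParams()
    donor = future_forcing
    if spec.use_physics_forcing:
        if future_physics_forcing is None:
            raise ScenarioError(f"{spec.name} needs the future_physics forcing")
        donor = future_physics_forcing
    f = blend_scenarios(base_forcing, donor, spec.factors)
    g = f.grid
    cache = _MonthlyCache(f, params, dt)

    state = HgState.initial(g, init_hg2d_pm)
    # partition the initial divalent pool so HgP starts consistent
    d, pp = state.hg2d - state.hg2d * cache.f_part[0], state.hg2d * cache.f_part[0]
    state.hg2d, state.hgp = d, pp
    ledger = BudgetLedger()
    zoo_q = {z: np.zeros((g.n_bands, g.n_regions, g.n_layers)) for z in ZOO_GROUPS}

    vol = g.volume
    area = g.area
    dz = g.dz
    i100 = g.interface_100m          # sinking flux source layer index
    w_s = params.partition.w_s
    n_sink_sub = max(1, int(np.ceil(w_s * dt / (0.9 * float(np.min(dz))))))
    h_sink = dt / n_sink_sub

    days_per_year = units.DAYS_PER_YEAR
    n_days = spec.years * days_per_year
    final_year_start = n_days - days_per_year

    yearly = []
    acc = {tr: np.zeros_like(state.hg0) for tr in ("hg0", "hg2d", "hgp",
                                                   "mmhg", "dmhg")}
    acc_zoo = {z: np.zeros_like(state.hg0) for z in ZOO_GROUPS}
    acc_phyto = np.zeros_like(state.hg0)
    acc_phyto_groups = {gn: np.zeros_like(state.hg0) for gn in PHYTO_GROUPS}
    flux100_mol = 0.0
    year_fluxes = {"evasion_hg0": 0.0, "evasion_dmhg": 0.0,
                   "deposition": 0.0, "burial": 0.0}
    n_acc = 0

    for day in range(n_days):
        month = (day // units.DAYS_PER_MONTH) % g.n_months
        in_final = day >= final_year_start
        inv0 = state.inventory()

        # 1) chemistry on the dissolved block
        block = np.stack([state.hg0, state.hg2d, state.mmhg, state.dmhg], axis=-1)
        rates = cache.rate_fields[month]
        meth_mol = float(np.sum(rates["k_meth"] * state.hg2d * vol)) \
            * dt * units.PM_M3_TO_MOL
        dem_mol = float(np.sum((rates["k_pd_eff"] + rates["k_dd"])
                               * state.mmhg * vol)) * dt * units.PM_M3_TO_MOL
        block = chem.apply_propagator(cache.chem_prop[month], block)
        state.hg0, state.hg2d, state.mmhg, state.dmhg = (
            block[..., 0], block[..., 1], block[..., 2], block[..., 3])
        ledger.add_conversion("methylation", meth_mol)
        ledger.add_conversion("demethylation", dem_mol)

        # 2) remineralization release, then 3) equilibrium repartitioning
        released = state.hgp * (1.0 - np.exp(-cache.remin_rate[month] * dt))
        state.hgp -= released
        state.hg2d += released
        ledger.add_conversion("remineralization",
                              float(np.sum(released * vol)) * units.PM_M3_TO_MOL)
        total2 = state.hg2d + state.hgp
        fp = cache.f_part[month]
        state.hgp = total2 * fp
        state.hg2d = total2 - state.hgp

        # 4) particle sinking (sub-stepped; integrate the 100 m flux)
        burial_step = 0.0
        for _ in range(n_sink_sub):
            if in_final:
                flux100_mol += float(np.sum(w_s * state.hgp[:, :, i100]
                                            * h_sink * area)) * units.PM_M3_TO_MOL
            state, b = sink_particles(state, w_s, h_sink)
            burial_step += b
        ledger.burial_hgp += burial_step

        # 5) vertical mixing + upwelling
        state = step_transport(state, f.k_mix[:, :, :, month],
                               f.w_up[:, :, :, month], dt)

        # 6) air-sea exchange and deposition (top layer)
        r0 = cache.airsea_rate_hg0[month]
        c_eq = cache.c_eq[month]
        c_old = state.hg0[:, :, 0].copy()
        state.hg0[:, :, 0] = c_eq + (c_old - c_eq) * np.exp(-r0 * dt)
        ev_hg0 = float(np.sum((c_old - state.hg0[:, :, 0]) * dz[0] * area)) \
            * units.PM_M3_TO_MOL
        ledger.evasion_hg0 += ev_hg0
        rd = cache.airsea_rate_dmhg[month]
        c_old = state.dmhg[:, :, 0].copy()
        state.dmhg[:, :, 0] = c_old * np.exp(-rd * dt)
        ev_dm = float(np.sum((c_old - state.dmhg[:, :, 0]) * dz[0] * area)) \
            * units.PM_M3_TO_MOL
        ledger.evasion_dmhg += ev_dm
        dep = cache.dep_flux[month]                        # pmol m-2 d-1
        state.hg2d[:, :, 0] += dep * dt / (dz[0] * units.PM_TIMES_M_TO_PMOL_M2)
        dep_mol = float(np.sum(dep * dt * area)) * 1e-12
        ledger.deposition_hg2 += dep_mol

        # budget closure check
        inv1 = state.inventory()
        closure = inv1 - inv0 - (dep_mol - ev_hg0 - ev_dm - burial_step)
        if abs(closure) > budget_rtol * max(inv1, 1e-30):
            raise RuntimeError(
                f"budget closure violated on day {day}: residual {closure:.3e} mol")

        # 7) zooplankton body burden (diagnostic, one-way coupling)
        for z in ZOO_GROUPS:
            k = params.bioacc.k_elim[z]
            q_ss = params.bioacc.ae[z] * cache.zoo_coef[z][month] \
                * state.mmhg / k
            zoo_q[z] = q_ss + (zoo_q[z] - q_ss) * np.exp(-k * dt)

        if in_final:
            n_acc += 1
            for tr in acc:
                acc[tr] += getattr(state, tr)
            for z in ZOO_GROUPS:
                acc_zoo[z] += zoo_q[z]
            acc_phyto += cache.phyto_coef[month] * state.mmhg
            for gn in PHYTO_GROUPS:
                acc_phyto_groups[gn] += cache.vcf_groups[gn][month] * state.mmhg
            year_fluxes["evasion_hg0"] += ev_hg0
            year_fluxes["evasion_dmhg"] += ev_dm
            year_fluxes["deposition"] += dep_mol
            year_fluxes["burial"] += burial_step

        if (day + 1) % days_per_year == 0:
            yearly.append({tr: g.volume_mean(getattr(state, tr))
                           for tr in ("hg0", "hg2d", "hgp", "mmhg", "dmhg")})

    yearly_df = pd.DataFrame(yearly)
    yearly_df.index = np.arange(1, len(yearly) + 1)
    drift = {}
    if len(yearly_df) >= 2:
        last, prev = yearly_df.iloc[-1], yearly_df.iloc[-2]
        for tr in yearly_df.columns:
            denom = abs(prev[tr]) if abs(prev[tr]) > 1e-30 else 1e-30
            drift[tr] = abs(last[tr] - prev[tr]) / denom
    converged = all(v < 0.01 for v in drift.values()) if drift else False

    mean_state = {tr: acc[tr] / n_acc for tr in acc}
    diags = {}
    for label, layers, region in _MASKS:
        inorg = mean_state["hg0"] + mean_state["hg2d"] + mean_state["hgp"]
        fields = dict(mean_state)
        fields["hg_inorg"] = inorg
        for tr in _TRACER_DIAGS:
            diags[f"{label}_{tr}_pM"] = g.volume_mean(fields[tr], layers, region)
    # fluxes scaled to a 365-day year for mol y-1 reporting
    to_year = 365.0 / days_per_year
    diags["evasion_hg0_mol_yr"] = year_fluxes["evasion_hg0"] * to_year
    diags["evasion_dmhg_mol_yr"] = year_fluxes["evasion_dmhg"] * to_year
    diags["deposition_mol_yr"] = year_fluxes["deposition"] * to_year
    diags["burial_mol_yr"] = year_fluxes["burial"] * to_year
    diags["hgp_flux_100m_mol_yr"] = flux100_mol * to_year
    for z in ZOO_GROUPS:
        diags[f"burden_{z}_pM"] = g.volume_mean(acc_zoo[z] / n_acc, "surface")
    for gn in PHYTO_GROUPS:
        diags[f"burden_{gn}_pM"] = g.volume_mean(acc_phyto_groups[gn] / n_acc,
                                                 "surface")
    diags["burden_phyto_mean_pM"] = g.volume_mean(acc_phyto / n_acc, "surface")
    diags["coastal_burden_phyto_mean_pM"] = g.volume_mean(
        acc_phyto / n_acc, "surface", "coastal")
    diags["open_burden_phyto_mean_pM"] = g.volume_mean(
        acc_phyto / n_acc, "surface", "open")
    diags["converged"] = float(converged)

    return ScenarioResult(spec, state, ledger.snapshot(), diags, yearly_df,
                          drift, converged)


# ---------------------------------------------------------------------------

def percent_change(scenario_row: dict, base_row: dict) -> dict:
    """Per-diagnostic percent change, 100 (s - b)/b; None where base ~ 0."""
    if set(scenario_row) != set(base_row):
        raise ScenarioError("diagnostics schemas differ")
    out = {}
    for k, b in base_row.items():
        s = scenario_row[k]
        if k == "converged":
            continue
        if b is None or abs(b) < 1e-300:
            out[k] = None
        else:
            out[k] = 100.0 * (s - b) / b
    return out


def factor_decomposition(rows: dict) -> dict:
    """Factor-decomposition report from a suite of diagnostics rows.

    ``rows`` maps scenario name -> diagnostics dict and must contain 'base',
    'all' and the ten single factors.  Returns values and percent-change
    tables, acidification rows (factor minus its _physics variant, where
    present) and the additivity residual (the 'all' percent change minus the
    sum of the single-factor changes — one-at-a-time decompositions need not
    add up).
    """
    missing = [n for n in SCENARIO_NAMES if n not in rows]
    if missing:
        raise ScenarioError(f"missing scenarios: {missing}")
    values = pd.DataFrame({name: row for name, row in rows.items()}).T
    base = rows["base"]
    pct = pd.DataFrame({name: percent_change(rows[name], base)
                        for name in rows if name != "base"}).T
    acid = {}
    for name in list(rows):
        if name.endswith("_physics") and name[:-8] in rows:
            full = percent_change(rows[name[:-8]], base)
            phys = percent_change(rows[name], base)
            acid[name[:-8] + "_acid"] = {
                k: (None if full[k] is None or phys[k] is None
                    else full[k] - phys[k]) for k in full}
    residual = (pct.loc["all"]
                - pct.loc[list(FACTORS)].sum(axis=0, skipna=False))
    return {"values": values, "percent": pct,
            "acid": pd.DataFrame(acid).T if acid else pd.DataFrame(),
            "additivity_residual": residual}


def run_suite(grid: Grid | None = None, seed: int = 0, years: int = 10,
              params: ModelParams | None = None, calib=None,
              names=None, extra_physics=(), progress=None) -> dict:
    """Generate forcings once and run the named scenarios.

    Default suite: base, all, and the ten single-factor experiments, plus any
    requested "_physics" variants.  Returns {'results': name->ScenarioResult,
    'report': factor_decomposition output (when the full suite was run)}.
    """
    grid = grid or Grid()
    params = params or ModelParams()
    names = list(names) if names is not None else list(SCENARIO_NAMES)
    names += [n for n in extra_physics if n not in names]
    base_f = generate_forcing("present", grid, seed, calib)
    fut_f = generate_forcing("future", grid, seed, calib)
    phys_f = generate_forcing("future_physics", grid, seed, calib)
    results = {}
    for name in names:
        spec = ScenarioSpec.from_name(name, years)
        if progress:
            progress(name)
        results[name] = run_scenario(spec, base_f, fut_f, phys_f, params)
    report = None
    if all(n in results for n in SCENARIO_NAMES):
        report = factor_decomposition(
            {n: r.diagnostics for n, r in results.items()})
    return {"results": results, "report": report,
            "forcings": {"present": base_f, "future": fut_f,
                         "future_physics": phys_f}}
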