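import numpy as np
import pandas as pd
import pytest

import hgocean as h
from hgocean.experiments import (SCENARIO_NAMES, ScenarioError, ScenarioSpec,
                                 factor_decomposition, percent_change,
                                 run_scenario)
from hgocean.forcing import FACTORS


def test_scenario_name_parsing():
    assert ScenarioSpec.from_name("base").factors == frozenset()
    assert ScenarioSpec.from_name("all").factors == frozenset(FACTORS)
    s = ScenarioSpec.from_name("Chl_physics")
    assert s.factors == frozenset({"Chl"}) and s.use_physics_forcing
    with pytest.raises(ScenarioError):
        ScenarioSpec.from_name("salinity")
    with pytest.raises(ScenarioError):
        ScenarioSpec.from_name("base_physics")


def test_percent_change_basics():
    row = {"a": 1.0, "b": 3.0, "converged": 1.0}
    base = {"a": 2.0, "b": 3.0, "converged": 1.0}
    pc = percent_change(row, base)
    assert pc["a"] == pytest.approx(-50.0)
    assert pc["b"] == pytest.approx(0.0)
    assert percent_change(base, base)["a"] == 0.0
    with pytest.raises(ScenarioError):
        percent_change({"a": 1.0}, base)


def test_percent_change_zero_base_reported_missing():
    pc = percent_change({"a": 1.0}, {"a": 0.0})
    assert pc["a"] is None


def test_factor_decomposition_of_identical_rows():
    row = {"x": 2.0, "y": -1.0}
    rows = {name: dict(row) for name in SCENARIO_NAMES}
    rep = factor_decomposition(rows)
    assert (rep["percent"].abs() < 1e-12).all().all()
    assert rep["additivity_residual"].abs().max() < 1e-12


def test_factor_decomposition_reports_missing_scenarios():
    with pytest.raises(ScenarioError, match="missing"):
        factor_decomposition({"base": {"x": 1.0}})


def test_run_determinism_and_null_blend(small_forcings, params):
    base_f = small_forcings["present"]
    fut_f = small_forcings["future"]
    phys_f = small_forcings["future_physics"]
    spec = ScenarioSpec.from_name("base", years=2)
    r1 = run_scenario(spec, base_f, fut_f, phys_f, params)
    r2 = run_scenario(spec, base_f, fut_f, phys_f, params)
    assert r1.diagnostics == r2.diagnostics
    # an empty factor set ignores the supplied future forcing entirely
    r3 = run_scenario(ScenarioSpec("null", frozenset(), 2), base_f, fut_f,
                      phys_f, params)
    for k, v in r1.diagnostics.items():
        assert r3.diagnostics[k] == pytest.approx(v, rel=1e-12)


def test_budget_ledger_closes(small_forcings, params):
    spec = ScenarioSpec.from_name("base", years=1)
    res = run_scenario(spec, small_forcings["present"],
                       small_forcings["future"],
                       small_forcings["future_physics"], params)
    # closure is enforced every step inside the run; verify the annual sums
    led = res.ledger
    inv = res.state.inventory()
    init = h.HgState.initial(res.state.grid, 0.5).inventory()
    assert inv - init == pytest.approx(led.net_boundary(), rel=1e-9)


def test_yearly_means_and_drift_reported(small_forcings, params):
    spec = ScenarioSpec.from_name("base", years=3)
    res = run_scenario(spec, small_forcings["present"],
                       small_forcings["future"],
                       small_forcings["future_physics"], params)
    assert len(res.yearly_means) == 3
    assert set(res.drift) == {"hg0", "hg2d", "hgp", "mmhg", "dmhg"}
    assert isinstance(res.converged, bool)


def test_suite_report_structure(suite):
    rep = suite["report"]
    assert set(SCENARIO_NAMES) <= set(suite["results"])
    assert isinstance(rep["percent"], pd.DataFrame)
    assert "all" in rep["percent"].index
    assert np.isfinite(rep["additivity_residual"]["surface_mmhg_pM"])
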