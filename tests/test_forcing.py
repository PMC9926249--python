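import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hgocean as h
from hgocean.forcing import (FACTORS, FACTOR_FIELDS, ForcingError,
                             _surface_chl_mean, blend_scenarios,
                             generate_forcing, summarize_forcing)


def test_determinism_bit_identical(small_grid):
    a = generate_forcing("present", small_grid, seed=7)
    b = generate_forcing("present", small_grid, seed=7)
    for name in ("t", "u10", "chl", "biomass", "k_mix"):
        assert np.array_equal(getattr(a, name), getattr(b, name))


def test_seed_changes_realization(small_grid):
    a = generate_forcing("present", small_grid, seed=1)
    b = generate_forcing("present", small_grid, seed=2)
    assert not np.array_equal(a.u10, b.u10)


def test_chlorophyll_calibration(grid, forcings):
    assert abs(_surface_chl_mean(grid, forcings["present"].chl) - 2.52) < 0.005
    assert abs(_surface_chl_mean(grid, forcings["future"].chl) - 1.17) < 0.005


def test_warming_everywhere_and_calibrated_mean(grid, forcings):
    dt = forcings["future"].t - forcings["present"].t
    assert np.all(dt > 0)
    surf_warming = grid.area_mean(dt[:, :, 0, :].mean(axis=-1))
    assert 1.0 <= surf_warming <= 5.0


def test_wind_weaker_extratropics_stronger_tropics(grid, forcings):
    ratio = (forcings["future"].u10 / forcings["present"].u10).mean(axis=(1, 2))
    lat = np.abs(grid.lat_centers)
    assert np.all(ratio[lat < 10] > 1.0)
    assert np.all(ratio[lat > 25] < 1.0)
    # lower in most bands
    assert np.sum(ratio < 1.0) > grid.n_bands / 2


def test_sea_ice_loss_in_polar_bands(grid, forcings):
    pres, fut = forcings["present"].f_ice, forcings["future"].f_ice
    assert np.all((pres >= 0) & (pres <= 1) & (fut >= 0) & (fut <= 1))
    polar = np.abs(grid.lat_centers) > 65
    assert np.all(fut[polar].mean(axis=-1) < pres[polar].mean(axis=-1))


def test_radiation_polar_brightening_tropical_dimming(grid, forcings):
    ratio = ((forcings["future"].i0.mean(axis=-1) + 1e-12)
             / (forcings["present"].i0.mean(axis=-1) + 1e-12))
    lat = np.abs(grid.lat_centers)
    assert np.all(ratio[lat > 55] > 1.0)
    assert np.all(ratio[lat < 15] < 1.0)


def test_export_declines_in_upwelling_bands(grid, forcings):
    lat = np.abs(grid.lat_centers)
    up = lat < 10
    for name in ("poc", "ocrr"):
        pres = getattr(forcings["present"], name)[up]
        fut = getattr(forcings["future"], name)[up]
        assert fut.sum() < pres.sum()


def test_physics_epoch_omits_only_the_acidification_increment(forcings):
    fut, phys = forcings["future"], forcings["future_physics"]
    for name in ("t", "u10", "f_ice", "i0", "k_mix", "w_up", "chl", "doc",
                 "poc"):
        assert np.array_equal(getattr(fut, name), getattr(phys, name)), name
    # OCRR carries the CO2-fertilization increment
    assert np.all(fut.ocrr > phys.ocrr)
    # community shift toward Synechococcus only in the acidified epoch
    i_syn = fut.phyto_index("synechococcus")
    i_dia = fut.phyto_index("diatom")
    assert np.all(fut.biomass[i_syn] >= phys.biomass[i_syn])
    assert fut.biomass[i_syn].sum() > phys.biomass[i_syn].sum()
    assert np.array_equal(fut.biomass[i_dia], phys.biomass[i_dia])


def test_atmospheric_boundary_identical_across_epochs(forcings):
    for name in ("atm_hg0", "dep_hg2"):
        assert np.array_equal(getattr(forcings["present"], name),
                              getattr(forcings["future"], name))


def test_all_fields_nonnegative(forcings):
    f = forcings["present"]
    for name in ("u10", "f_ice", "i0", "chl", "doc", "poc", "ocrr",
                 "biomass", "grazing", "zoo_mortality", "k_mix", "w_up",
                 "atm_hg0", "dep_hg2"):
        assert np.all(getattr(f, name) >= 0), name


def test_unknown_epoch_and_bad_grid_rejected(small_grid):
    with pytest.raises(ForcingError):
        generate_forcing("rcp26", small_grid, 0)
    with pytest.raises(ForcingError):
        generate_forcing("present", "not a grid", 0)


# -- blending ---------------------------------------------------------------

def test_blend_empty_and_full_factor_sets(small_forcings):
    base, fut = small_forcings["present"], small_forcings["future"]
    out = blend_scenarios(base, fut, set())
    for fields in FACTOR_FIELDS.values():
        for name in fields:
            assert np.array_equal(getattr(out, name), getattr(base, name))
    out = blend_scenarios(base, fut, set(FACTORS))
    for fields in FACTOR_FIELDS.values():
        for name in fields:
            assert np.array_equal(getattr(out, name), getattr(fut, name))


def test_blend_single_factor(small_forcings):
    base, fut = small_forcings["present"], small_forcings["future"]
    out = blend_scenarios(base, fut, {"temperature"})
    assert np.array_equal(out.t, fut.t)
    assert np.array_equal(out.chl, base.chl)


def test_blend_errors(small_forcings, forcings):
    base, fut = small_forcings["present"], small_forcings["future"]
    with pytest.raises(ForcingError):
        blend_scenarios(base, fut, {"salinity"})
    with pytest.raises(ForcingError):
        blend_scenarios(base, forcings["future"], {"temperature"})


@settings(derandomize=True, max_examples=25, deadline=None)
@given(split=st.lists(st.sampled_from(FACTORS), max_size=10),
       extra=st.lists(st.sampled_from(FACTORS), max_size=10))
def test_blend_composes_over_disjoint_factor_sets(small_forcings, split, extra):
    base, fut = small_forcings["present"], small_forcings["future"]
    f1 = set(split)
    f2 = set(extra) - f1
    once = blend_scenarios(base, fut, f1 | f2)
    twice = blend_scenarios(blend_scenarios(base, fut, f1), fut, f2)
    for fields in FACTOR_FIELDS.values():
        for name in fields:
            assert np.array_equal(getattr(once, name), getattr(twice, name))


def test_summary_chl_reduction_rounds_to_54_percent(forcings):
    s_pres = summarize_forcing(forcings["present"])
    s_fut = summarize_forcing(forcings["future"])
    a = s_pres.loc["chl", "surface_mean"]
    b = s_fut.loc["chl", "surface_mean"]
    assert round(100.0 * (a - b) / a) == 54
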