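import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hgocean.grid import Grid
from hgocean.transport import (CFLError, HgState, sink_particles,
                               sinking_flux_profile, step_transport)


def two_layer_grid():
    return Grid(lat_edges=(-10.0, 10.0), depth_edges=(0.0, 100.0, 200.0))


def iface_fields(grid, k_mix=0.0, w_up=0.0):
    shape = (grid.n_bands, grid.n_regions, grid.n_layers - 1)
    return np.full(shape, k_mix), np.full(shape, w_up)


def test_no_mixing_no_change(small_grid):
    s = HgState.initial(small_grid, 0.5)
    s.mmhg += np.random.default_rng(0).uniform(0, 0.1, s.mmhg.shape)
    k, w = iface_fields(small_grid)
    out = step_transport(s, k, w, 1.0)
    for tr in ("hg2d", "mmhg"):
        np.testing.assert_array_equal(getattr(out, tr), getattr(s, tr))


def test_uniform_column_invariant_under_mixing(small_grid):
    s = HgState.initial(small_grid, 0.7)
    k, w = iface_fields(small_grid, k_mix=1e-3, w_up=0.5)
    out = step_transport(s, k, w, 1.0)
    np.testing.assert_allclose(out.hg2d, 0.7, rtol=1e-13)


def test_two_box_exchange_reaches_equal_concentrations():
    g = two_layer_grid()
    s = HgState.zeros(g)
    s.mmhg[:, :, 0] = 2.0
    k, w = iface_fields(g, k_mix=5e-3)
    for _ in range(2000):
        s = step_transport(s, k, w, 1.0)
    np.testing.assert_allclose(s.mmhg, 1.0, rtol=1e-6)


def test_transport_conserves_each_tracer(small_grid):
    rng = np.random.default_rng(5)
    s = HgState.zeros(small_grid)
    for tr in ("hg0", "hg2d", "hgp", "mmhg", "dmhg"):
        getattr(s, tr)[...] = rng.uniform(0, 1, s.hg0.shape)
    k, w = iface_fields(small_grid, k_mix=2e-3, w_up=0.3)
    inv0 = {tr: s.inventory(tr) for tr in ("hg0", "hg2d", "hgp", "mmhg", "dmhg")}
    for _ in range(100):
        s = step_transport(s, k, w, 1.0)
        assert np.all(s.stack() >= 0)
    for tr, v in inv0.items():
        assert s.inventory(tr) == pytest.approx(v, rel=1e-12)


@settings(derandomize=True, max_examples=15, deadline=None)
@given(seed=st.integers(0, 1000), alpha=st.floats(0.1, 10.0))
def test_transport_is_linear_in_state(small_grid, seed, alpha):
    rng = np.random.default_rng(seed)
    s = HgState.zeros(small_grid)
    s.mmhg[...] = rng.uniform(0, 1, s.mmhg.shape)
    sa = s.copy()
    sa.mmhg *= alpha
    k, w = iface_fields(small_grid, k_mix=1e-3, w_up=0.2)
    out = step_transport(s, k, w, 1.0)
    out_a = step_transport(sa, k, w, 1.0)
    np.testing.assert_allclose(out_a.mmhg, alpha * out.mmhg, rtol=1e-12)


def test_cfl_violation_names_the_interface(small_grid):
    s = HgState.initial(small_grid, 0.5)
    k, w = iface_fields(small_grid, k_mix=50.0)  # absurdly strong mixing
    with pytest.raises(CFLError, match="interface|layer"):
        step_transport(s, k, w, 1.0, max_substeps=4)


# -- sinking ----------------------------------------------------------------

def test_zero_sinking_speed_is_identity(small_grid):
    s = HgState.initial(small_grid, 0.5)
    s.hgp += 0.1
    out, burial = sink_particles(s, 0.0, 1.0)
    np.testing.assert_array_equal(out.hgp, s.hgp)
    assert burial == 0.0


def test_single_layer_column_fully_buried():
    g = Grid(lat_edges=(-10.0, 10.0), depth_edges=(0.0, 100.0))
    s = HgState.zeros(g)
    s.hgp += 1.0
    inv0 = s.inventory("hgp")
    buried = 0.0
    for _ in range(2000):
        s, b = sink_particles(s, 10.0, 1.0)
        buried += b
    assert s.hgp.max() < 1e-8
    assert buried == pytest.approx(inv0, rel=1e-8)


def test_two_layer_upwind_update_hand_computed():
    g = two_layer_grid()
    s = HgState.zeros(g)
    s.hgp[:, :, 0] = 1.0
    # w_s*dt = 50 m = half the upper layer: upper loses half, lower gains
    # the volume-scaled amount (equal thicknesses here)
    out, burial = sink_particles(s, 50.0, 1.0)
    np.testing.assert_allclose(out.hgp[:, :, 0], 0.5)
    np.testing.assert_allclose(out.hgp[:, :, 1], 0.5)
    assert burial == 0.0
    # only HgP moves
    np.testing.assert_array_equal(out.hg2d, s.hg2d)


def test_sinking_cfl_rejected(small_grid):
    s = HgState.initial(small_grid, 0.5)
    with pytest.raises(CFLError):
        sink_particles(s, 100.0, 1.0)  # 100 m > thinnest layer (50 m)


def test_flux_profile_matches_upwind_flux():
    g = two_layer_grid()
    s = HgState.zeros(g)
    s.hgp[:, :, 0] = 2.0
    flux = sinking_flux_profile(s, 50.0)
    np.testing.assert_allclose(flux[:, :, 0], 50.0 * 2.0 * 1e3)
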