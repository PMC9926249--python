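import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hgocean import chem
from hgocean.params import RateParams

P = RateParams()


def random_rates(rng, shape=()):
    """Random admissible first-order rates, d-1 (surface-ocean magnitudes)."""
    def draw(hi):
        return rng.uniform(0.0, hi, shape) if shape else rng.uniform(0.0, hi)
    return {
        "k_red_photo": draw(0.2), "k_red_bio": draw(0.05),
        "k_ox_photo": draw(0.4), "k_ox_dark": draw(0.05),
        "k_meth": draw(0.02), "k_pd_eff": draw(0.3), "k_dd": draw(0.05),
        "k_mm_dm": draw(0.01), "k_dm_mm": draw(0.1),
    }


# -- light profile ----------------------------------------------------------

def test_ice_shields_the_whole_column():
    dz = np.array([25.0, 75.0, 200.0])
    i = chem.light_profile(200.0, np.zeros(3), np.zeros(3), 1.0, dz)
    assert np.all(i == 0.0)


def test_clear_water_beer_lambert():
    dz = np.array([20.0, 30.0, 50.0])
    z_mid = np.array([10.0, 35.0, 75.0])
    i = chem.light_profile(100.0, np.zeros(3), np.zeros(3), 0.0, dz)
    assert i == pytest.approx(100.0 * np.exp(-P.a_w * z_mid))


def test_shading_by_upper_layer_chlorophyll():
    dz = np.array([25.0, 75.0, 200.0])
    chl = np.array([1.0, 0.5, 0.1])
    doc = np.full(3, 60.0)
    i1 = chem.light_profile(200.0, chl, doc, 0.0, dz)
    chl2 = chl.copy()
    chl2[0] *= 2.0
    i2 = chem.light_profile(200.0, chl2, doc, 0.0, dz)
    assert np.all(i2[1:] < i1[1:])
    assert np.all(np.diff(i1) < 0)  # monotone attenuation


def test_negative_inputs_rejected():
    dz = np.array([25.0])
    with pytest.raises(ValueError):
        chem.light_profile(-1.0, np.zeros(1), np.zeros(1), 0.0, dz)


# -- individual rate laws ---------------------------------------------------

def test_methylation_proportional_to_ocrr():
    assert chem.methylation_rate(0.0) == 0.0
    assert chem.methylation_rate(1.0) == pytest.approx(P.c_meth)
    assert chem.methylation_rate(4.0) == pytest.approx(2.0 * chem.methylation_rate(2.0))


def test_dark_demethylation_q10_law():
    assert chem.dark_demethylation_rate(20.0) == pytest.approx(P.k_dd20)
    assert chem.dark_demethylation_rate(30.0) == pytest.approx(2.0 * P.k_dd20)
    assert chem.dark_demethylation_rate(25.0) > chem.dark_demethylation_rate(15.0)


def test_photodemethylation_linear_in_light():
    assert chem.photodemethylation_rate(0.0) == 0.0
    assert chem.photodemethylation_rate(100.0) == pytest.approx(
        2.0 * chem.photodemethylation_rate(50.0))


def test_dark_cell_has_only_dark_oxidation():
    r = chem.redox_rates(np.float64(0.0), np.float64(0.0), 4.0)
    assert r["k_red_photo"] == 0.0 and r["k_red_bio"] == 0.0
    assert r["k_ox_photo"] == 0.0
    assert r["k_ox_dark"] == pytest.approx(P.k_darkox)


def test_zero_coefficients_give_zero_rates():
    p0 = RateParams(k_photored=0, k_photoox=0, k_biored=0, k_darkox=0)
    r = chem.redox_rates(np.float64(150.0), np.float64(3.0), 20.0, p0)
    assert all(np.all(v == 0) for v in r.values())


def test_dark_cell_hg0_decays_exponentially():
    rates = {k: 0.0 for k in ("k_red_photo", "k_red_bio", "k_ox_photo",
                              "k_meth", "k_pd_eff", "k_dd", "k_mm_dm",
                              "k_dm_mm")}
    rates["k_ox_dark"] = 0.02
    conc = np.array([1.0, 0.0, 0.0, 0.0])
    for _ in range(50):
        conc = chem.step_chemistry(conc, rates, 1.0)
    assert conc[0] == pytest.approx(np.exp(-0.02 * 50), rel=1e-10)
    assert conc[1] == pytest.approx(1.0 - np.exp(-0.02 * 50), rel=1e-10)


# -- the coupled step -------------------------------------------------------

def test_zero_rates_identity():
    rates = {k: 0.0 for k in ("k_red_photo", "k_red_bio", "k_ox_photo",
                              "k_ox_dark", "k_meth", "k_pd_eff", "k_dd",
                              "k_mm_dm", "k_dm_mm")}
    conc = np.array([0.1, 0.4, 0.05, 0.002])
    out = chem.step_chemistry(conc, rates, 1.0)
    assert out == pytest.approx(conc, rel=1e-12)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_step_conserves_total_and_stays_nonnegative(seed):
    rng = np.random.default_rng(seed)
    rates = random_rates(rng, shape=(8,))
    conc = rng.uniform(0.0, 1.0, (8, 4))
    out = chem.step_chemistry(conc, rates, 1.0)
    assert np.all(out >= 0.0)
    np.testing.assert_allclose(out.sum(axis=-1), conc.sum(axis=-1), rtol=1e-12)


def test_negative_rates_rejected():
    rng = np.random.default_rng(0)
    rates = random_rates(rng)
    rates["k_meth"] = -1e-3
    with pytest.raises(ValueError):
        chem.step_chemistry(np.ones(4), rates, 1.0)


def test_propagator_matches_matrix_exponential_oracle():
    from scipy.linalg import expm
    rng = np.random.default_rng(42)
    worst = 0.0
    for _ in range(25):
        rates = random_rates(rng)
        a = chem.rate_matrix(rates)
        conc = rng.uniform(0.0, 1.0, 4)
        ours = chem.step_chemistry(conc, rates, 1.0)
        ref = expm(a * 1.0) @ conc
        worst = max(worst, np.max(np.abs(ours - ref)) / conc.sum())
    assert worst < 1e-10


def test_two_species_balance_recovers_closed_form():
    # isolated HgII <-> MMHg subsystem: steady ratio = k_meth / (k_pd + k_dd)
    rates = {k: 0.0 for k in ("k_red_photo", "k_red_bio", "k_ox_photo",
                              "k_ox_dark", "k_mm_dm", "k_dm_mm")}
    rates.update({"k_meth": 0.004, "k_pd_eff": 0.01, "k_dd": 0.006})
    conc = np.array([0.0, 0.5, 0.0, 0.0])
    for _ in range(2000):
        conc = chem.step_chemistry(conc, rates, 1.0)
    assert conc[2] / conc[1] == pytest.approx(0.004 / 0.016, rel=1e-6)
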