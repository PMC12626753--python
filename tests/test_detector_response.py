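"""Spectrum-weighted response Y, correction factors k_NR, medium ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import magnaspec as m
from magnaspec.detector_response import (
    DetectorResponse,
    build_correction_table,
    k_nr,
    load_detector,
    response_weighted_y,
    spectrum_averaged_ratio,
)
from magnaspec.physics_data import CoefficientTable
from magnaspec.synthetic_fixtures import ToySpectrumSpec, make_softened_pair
from magnaspec.transport_mc import Spectrum


def _flat_response(lo=0.005, hi=15.0):
    e = np.array([lo, hi])
    return DetectorResponse("flat", e, np.ones(2))


def _toy_table(energies, muen):
    """Minimal coefficient table with prescribed muen/rho values."""
    e = np.asarray(energies, dtype=float)
    mu = np.asarray(muen, dtype=float) * 3.0
    return CoefficientTable(
        medium="toy",
        energies=e,
        total_mu_rho=mu,
        partial_mu_rho={
            "compton": mu * 0.98,
            "photoelectric": mu * 0.02,
            "pair": np.zeros_like(mu),
        },
        muen_rho=np.asarray(muen, dtype=float),
        density=1.0,
    )


# ---------------------------------------------------------------------------
# shipped response fixtures


def test_farmer_fixture_near_flat():
    resp = load_detector("farmer_ne2571")
    sel = (resp.energies >= 0.1) & (resp.energies <= 10.0)
    r = resp.r[sel]
    assert r.max() / r.min() <= 1.01
    assert np.all(resp.r > 0)


def test_tld_and_osld_over_respond_at_low_energy():
    tld = load_detector("lif_tld")
    osld = load_detector("al2o3_osld")
    for resp in (tld, osld):
        low = resp.energies < 0.2
        # response rises monotonically toward low energies below ~0.2 MeV
        assert np.all(np.diff(resp.r[low]) <= 1e-6)
        assert resp.r[low][0] > 1.1
    grid = np.array([0.02, 0.03, 0.05, 0.1])
    assert np.all(osld.at(grid) > tld.at(grid))


def test_unknown_detector_rejected():
    with pytest.raises(ValueError, match="diode"):
        load_detector("diode")


# ---------------------------------------------------------------------------
# Y


def test_flat_response_gives_unity(water):
    spec = Spectrum(
        np.linspace(0.05, 5.0, 50), np.random.default_rng(0).random(49),
        np.zeros(49),
    )
    assert response_weighted_y(spec, _flat_response(), water) == pytest.approx(
        1.0, abs=1e-12
    )


def test_single_bin_returns_pointwise_response(water):
    edges = np.array([0.95, 1.05])
    spec = Spectrum(edges, np.array([7.0]), np.zeros(1))
    resp = load_detector("al2o3_osld")
    assert response_weighted_y(spec, resp, water) == pytest.approx(
        resp.at(1.0), rel=1e-12
    )


def test_two_bin_hand_computed_ratio():
    """Brute-force oracle: two bins with stated phi, r, muen values."""
    edges = np.array([0.1, 0.2, 1.0])  # centers 0.15 and 0.6
    phi = np.array([4.0, 1.0])
    spec = Spectrum(edges, phi, np.zeros(2))
    table = _toy_table([0.15, 0.6], [0.0277, 0.0329])
    resp = DetectorResponse("toy", np.array([0.15, 0.6]), np.array([1.3, 1.0]))
    # weights w_i = muen_i * phi_i * E_i (the explicit bin width cancels
    # against the differential-fluence conversion)
    w1 = 0.0277 * 4.0 * 0.15
    w2 = 0.0329 * 1.0 * 0.6
    expected = (1.3 * w1 + 1.0 * w2) / (w1 + w2)
    assert response_weighted_y(spec, resp, table) == pytest.approx(
        expected, rel=1e-12
    )


def test_empty_spectrum_and_coverage_gap_rejected(water):
    empty = Spectrum(np.array([0.1, 0.2]), np.array([0.0]), np.zeros(1))
    with pytest.raises(ValueError, match="nonzero"):
        response_weighted_y(empty, _flat_response(), water)
    narrow = DetectorResponse("narrow", np.array([0.5, 1.0]), np.ones(2))
    spec = Spectrum(np.array([0.1, 0.2]), np.array([1.0]), np.zeros(1))
    with pytest.raises(ValueError):
        response_weighted_y(spec, narrow, water)


# ---------------------------------------------------------------------------
# k_NR


def test_identical_spectra_give_unity(water, toy_edges):
    spec = Spectrum(
        toy_edges, np.exp(-0.5 * np.arange(len(toy_edges) - 1)),
        np.zeros(len(toy_edges) - 1),
    )
    for det in ("farmer_ne2571", "lif_tld", "al2o3_osld"):
        res = k_nr(spec, spec, load_detector(det), water)
        assert res.k_nr == pytest.approx(1.0, abs=1e-12)
        assert res.k_nr == pytest.approx(res.y_ref / res.y_clin)


def test_flat_detector_gives_unity_for_any_spectra(water):
    base = ToySpectrumSpec(bin_edges=tuple(np.linspace(0.05, 6.0, 40)))
    ref, clin = make_softened_pair(base, 0.5)
    res = k_nr(ref, clin, _flat_response(), water)
    assert res.k_nr == pytest.approx(1.0, abs=1e-12)


def test_softer_spectrum_with_over_responder_gives_k_below_unity(water):
    # quartile injection lands below ~0.5 MeV, where the over-response is
    base = ToySpectrumSpec(bin_edges=tuple(np.linspace(0.02, 2.0, 41)))
    ref, clin = make_softened_pair(base, 0.3)
    for det in ("lif_tld", "al2o3_osld"):
        res = k_nr(ref, clin, load_detector(det), water)
        assert res.k_nr < 1.0


@settings(max_examples=50, deadline=None)
@given(scale=st.floats(min_value=1e-6, max_value=1e6))
def test_fluence_rescaling_invariance(scale):
    """Y and k_NR are invariant under any positive rescaling of phi."""
    water = m.load_medium("water")
    edges = np.linspace(0.05, 6.0, 30)
    rng = np.random.default_rng(3)
    flu = rng.random(29) + 0.1
    a = Spectrum(edges, flu, np.zeros(29))
    b = Spectrum(edges, flu * scale, np.zeros(29))
    resp = load_detector("al2o3_osld")
    ya = response_weighted_y(a, resp, water)
    yb = response_weighted_y(b, resp, water)
    assert yb == pytest.approx(ya, rel=1e-9)


def test_rebinning_stability(water):
    """Halving the bin width (fluence split proportionally, smooth
    weighting functions) changes Y by less than 0.1%."""
    edges = np.linspace(0.1, 6.0, 60)
    centers = 0.5 * (edges[:-1] + edges[1:])
    flu = np.exp(-centers / 0.8)
    coarse = Spectrum(edges, flu, np.zeros_like(flu))
    fine_edges = np.linspace(0.1, 6.0, 119)
    fine_flu = np.repeat(flu / 2.0, 2)[: len(fine_edges) - 1]
    fine = Spectrum(fine_edges, fine_flu, np.zeros_like(fine_flu))
    resp = load_detector("lif_tld")
    y1 = response_weighted_y(coarse, resp, water)
    y2 = response_weighted_y(fine, resp, water)
    assert abs(y2 - y1) / y1 < 1e-3


def test_softening_series_monotone_deviation(water):
    """Progressively softer clinical spectra
    give monotonically growing |1 - k_NR| for over-responding detectors."""
    base = ToySpectrumSpec(bin_edges=tuple(np.linspace(0.02, 2.0, 41)))
    for det in ("lif_tld", "al2o3_osld"):
        resp = load_detector(det)
        devs = []
        for frac in (0.0, 0.1, 0.2, 0.4, 0.6):
            ref, clin = make_softened_pair(base, frac)
            devs.append(abs(1 - k_nr(ref, clin, resp, water).k_nr))
        assert all(b >= a - 1e-12 for a, b in zip(devs, devs[1:]))
        assert devs[0] == pytest.approx(0.0, abs=1e-12)


def test_softening_three_bin_brute_force(water):
    """Moving weight from a higher to a lower bin never increases k_NR for
    a detector with non-increasing response."""
    edges = np.array([0.05, 0.15, 1.0, 3.0])
    resp = DetectorResponse(
        "toy", np.array([0.05, 3.0]), np.array([2.0, 1.0])
    )  # log-interp: non-increasing in E
    rng = np.random.default_rng(8)
    for _ in range(25):
        flu = rng.random(3) + 0.2
        ref = Spectrum(edges, flu, np.zeros(3))
        j, i = 2, rng.integers(0, 2)  # move mass from bin 2 down to i
        amount = 0.5 * flu[j]
        soft = flu.copy()
        soft[j] -= amount
        soft[i] += amount
        clin = Spectrum(edges, soft, np.zeros(3))
        k_soft = k_nr(ref, clin, resp, water).k_nr
        assert k_soft <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# correction tables


def _toy_condition_spectra(toy_edges):
    rng = np.random.default_rng(5)
    n = len(toy_edges) - 1
    out = {}
    ref = Spectrum(toy_edges, rng.random(n) + 0.5, np.zeros(n))
    out[("6mv", "reference", 10.0)] = ref
    for phantom in ("big", "small"):
        for depth in (0.0, 10.0, 35.0):
            if phantom == "small" and depth == 35.0:
                continue  # deeper than the phantom
            out[("6mv", phantom, depth)] = Spectrum(
                toy_edges, rng.random(n) + 0.5, np.zeros(n)
            )
    return out


def test_correction_table_identity_condition(toy_edges):
    rng = np.random.default_rng(2)
    n = len(toy_edges) - 1
    ref = Spectrum(toy_edges, rng.random(n) + 0.5, np.zeros(n))
    tab = build_correction_table(
        {("6mv", "reference", 10.0): ref},
        ("lif_tld",),
        ("6mv", "reference", 10.0),
    )
    assert np.allclose(tab.data["k_nr"], 1.0)


def test_correction_table_marks_missing_depths_absent(toy_edges):
    spectra = _toy_condition_spectra(toy_edges)
    tab = build_correction_table(
        spectra, ("lif_tld",), ("6mv", "reference", 10.0)
    )
    cell = tab.data.query(
        "phantom == 'small' and depth_cm == 35.0"
    )["k_nr"]
    assert len(cell) == 1 and np.isnan(cell.iloc[0])
    populated = tab.data.query("phantom == 'big'")["k_nr"]
    assert populated.notna().all()
    wide = tab.to_wide("lif_tld")
    assert wide.shape[0] == 3  # depths 0, 10, 35


def test_correction_table_flat_detector_rounds_to_unity(toy_edges):
    spectra = _toy_condition_spectra(toy_edges)
    tab = build_correction_table(
        spectra, (_flat_response(),), ("6mv", "reference", 10.0)
    )
    k = tab.data["k_nr"].dropna()
    assert np.all(np.abs(k - 1.0) < 0.004)


def test_correction_table_requires_reference(toy_edges):
    spectra = _toy_condition_spectra(toy_edges)
    del spectra[("6mv", "reference", 10.0)]
    with pytest.raises(ValueError, match="reference"):
        build_correction_table(
            spectra, ("lif_tld",), ("6mv", "reference", 10.0)
        )


def test_correction_sanity_band(correction_grid):
    k = correction_grid["k_nr"].dropna()
    assert np.all((k > 0.5) & (k < 1.5))


# ---------------------------------------------------------------------------
# medium-conversion ratio


def test_spectrum_averaged_ratio_identity_and_single_bin(water):
    spec = Spectrum(np.array([0.5, 0.7]), np.array([2.0]), np.zeros(1))
    assert spectrum_averaged_ratio(spec, water, water) == pytest.approx(1.0)
    pmma = m.load_medium("pmma")
    expected = m.interpolate(water, 0.6, "muen_rho") / m.interpolate(
        pmma, 0.6, "muen_rho"
    )
    assert spectrum_averaged_ratio(spec, water, pmma) == pytest.approx(
        expected, rel=1e-12
    )


def test_spectrum_averaged_ratio_two_bin_hand_computed():
    e = [0.15, 0.6]
    a = _toy_table(e, [0.0277, 0.0329])
    b = _toy_table(e, [0.0269, 0.0320])
    spec = Spectrum(np.array([0.1, 0.2, 1.0]), np.array([4.0, 1.0]), np.zeros(2))
    w1, w2 = 4.0 * 0.15, 1.0 * 0.6  # energy-fluence weights
    expected = (w1 * 0.0277 / 0.0269 + w2 * 0.0329 / 0.0320) / (w1 + w2)
    assert spectrum_averaged_ratio(spec, a, b) == pytest.approx(
        expected, rel=1e-12
    )
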