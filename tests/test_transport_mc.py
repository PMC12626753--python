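"""Transport engine: source models, sampling oracles, scoring estimators."""

import numpy as np
import pytest
from scipy.integrate import quad

import magnaspec as m
from magnaspec.transport_mc import (
    MEC2,
    SourceModel,
    Spectrum,
    sample_klein_nishina,
)


def _mono_source(energy):
    """Single-line emission spectrum centred on ``energy``."""
    spec = Spectrum(
        np.array([energy, energy + 0.005]),
        np.array([1.0]),
        np.array([0.0]),
        location="source",
    )
    return SourceModel("6mv", spec)


# ---------------------------------------------------------------------------
# source model


def test_source_spectra_normalized_and_bounded():
    for nominal, e_max in (("6MV", 6.0), ("10MV", 10.0)):
        src = m.build_source(nominal)
        assert src.spectrum.fluence.sum() == pytest.approx(1.0)
        assert np.all(src.spectrum.fluence >= 0)
        assert src.e_max <= e_max + 1e-12


def test_10mv_harder_than_6mv():
    e6 = m.mean_energy(m.build_source("6MV").spectrum)
    e10 = m.mean_energy(m.build_source("10MV").spectrum)
    assert e10 > e6


def test_unsupported_nominal_energy():
    with pytest.raises(ValueError, match="15MV"):
        m.build_source("15MV")


# ---------------------------------------------------------------------------
# mean energy


def test_mean_energy_examples():
    single = Spectrum(np.array([0.95, 1.05]), np.array([3.0]), np.zeros(1))
    assert m.mean_energy(single) == pytest.approx(1.0)
    equal = Spectrum(
        np.array([0.75, 1.25, 1.75, 2.25]),
        np.array([1.0, 0.0, 1.0]),
        np.zeros(3),
    )
    assert m.mean_energy(equal) == pytest.approx(1.5)
    # three-bin toy, hand-summed weighted mean
    toy = Spectrum(
        np.array([0.25, 0.75, 1.25, 2.75]),
        np.array([1.0, 2.0, 1.0]),
        np.zeros(3),
    )
    expected = (1 * 0.5 + 2 * 1.0 + 1 * 2.0) / 4
    assert m.mean_energy(toy) == pytest.approx(expected)


def test_mean_energy_rejects_empty_spectrum():
    empty = Spectrum(np.array([0.0, 1.0, 2.0]), np.zeros(2), np.zeros(2))
    with pytest.raises(ValueError):
        m.mean_energy(empty)


def test_energy_fluence_weighting_shifts_mean_up():
    toy = Spectrum(
        np.array([0.0, 1.0, 2.0]), np.array([1.0, 1.0]), np.zeros(2)
    )
    assert m.mean_energy(toy, "energy_fluence") > m.mean_energy(toy)


# ---------------------------------------------------------------------------
# Klein-Nishina sampler


def test_klein_nishina_bounds_and_mean():
    """Sampled eps = E'/E stays within kinematic limits and its mean
    matches the numerically integrated Klein-Nishina expectation."""
    rng = np.random.default_rng(42)
    energy = 1.0
    k = energy / MEC2
    eps0 = 1.0 / (1.0 + 2.0 * k)

    def dsde(eps):
        t = (1.0 - eps) / (k * eps)
        return eps + 1.0 / eps - t * (2.0 - t)

    expected = quad(lambda e: e * dsde(e), eps0, 1.0)[0] / quad(
        dsde, eps0, 1.0
    )[0]
    eps = sample_klein_nishina(rng, energy, 100_000)
    assert eps.min() >= eps0 - 1e-12
    assert eps.max() <= 1.0 + 1e-12
    se = eps.std(ddof=1) / np.sqrt(eps.size)
    assert abs(eps.mean() - expected) < 3 * se


# ---------------------------------------------------------------------------
# transport oracles


def test_narrow_beam_attenuation_matches_closed_form(water):
    """Uncollided fluence of a monoenergetic pencil beam decays as
    exp(-mu rho d); scored with fine bins so in-bin forward scatter is
    negligible."""
    src = _mono_source(1.0)
    geom = m.GeometryConfig(
        ssd=50.0,
        field_size_at_surface=(0.1, 0.1),
        phantom_dims=(40.0, 40.0, 40.0),
        intervening_medium="vacuum",
    )
    sc = m.ScoringConfig(
        spectrum_depths=(0.0, 5.0, 10.0),
        spectrum_voxel=(2.0, 2.0, 0.5),
        profile_lateral=(2.0, 2.0),
        histories=100_000,
        seed=3,
        energy_bin_width=0.005,
    )
    res = m.run_transport(src, geom, sc)
    mu = m.interpolate(water, 1.0025, "total_mu_rho") * water.density
    i = int(1.0 / 0.005)
    for spec in res.spectra:
        d = spec.depth_cm
        expected = (np.exp(-mu * d) - np.exp(-mu * (d + 0.5))) / mu / 2.0
        assert abs(spec.fluence[i] - expected) < 3 * spec.uncertainty[i]


def test_surface_spectrum_matches_source_without_upstream_material():
    """With a vacuum gap and nothing upstream, the surface spectrum keeps
    the emission spectrum's mean energy within statistics."""
    src = m.build_source("6MV")
    geom = m.GeometryConfig(
        ssd=100.0,
        field_size_at_surface=(10.0, 10.0),
        phantom_dims=(40.0, 40.0, 0.2),  # thin slab: no scatter buildup
        intervening_medium="vacuum",
    )
    sc = m.ScoringConfig(
        spectrum_depths=(0.0,),
        spectrum_voxel=(4.0, 4.0, 0.2),
        profile_lateral=(2.0, 2.0),
        depth_bin=0.1,
        histories=50_000,
        seed=5,
    )
    res = m.run_transport(src, geom, sc)
    scored = m.mean_energy(res.spectra[0])
    emitted = m.mean_energy(src.spectrum)
    assert scored == pytest.approx(emitted, rel=0.025)


def test_determinism_bit_identical():
    src = m.build_source("6MV")
    geom = m.GeometryConfig(
        ssd=100.0,
        field_size_at_surface=(10.0, 10.0),
        phantom_dims=(40.0, 40.0, 40.0),
    )
    sc = m.ScoringConfig(
        spectrum_depths=(0.0, 10.0),
        spectrum_voxel=(4.0, 4.0, 0.5),
        profile_lateral=(2.0, 2.0),
        histories=20_000,
        seed=11,
    )
    a = m.run_transport(src, geom, sc)
    b = m.run_transport(src, geom, sc)
    for sa, sb in zip(a.spectra, b.spectra):
        assert np.array_equal(sa.fluence, sb.fluence)
        assert np.array_equal(sa.uncertainty, sb.uncertainty)
    assert np.array_equal(a.profile.kerma, b.profile.kerma)
    spectra, profile = a  # tuple-style unpacking
    assert spectra is a.spectra and profile is a.profile


def test_uncertainty_scales_as_inverse_sqrt_histories():
    src = m.build_source("6MV")
    geom = m.GeometryConfig(
        ssd=100.0,
        field_size_at_surface=(10.0, 10.0),
        phantom_dims=(40.0, 40.0, 40.0),
    )

    def med_rel(n, seed):
        sc = m.ScoringConfig(
            spectrum_depths=(10.0,),
            spectrum_voxel=(4.0, 4.0, 0.5),
            profile_lateral=(2.0, 2.0),
            histories=n,
            seed=seed,
        )
        s = m.run_transport(src, geom, sc).spectra[0]
        mask = s.fluence > 0
        return float(np.median(s.uncertainty[mask] / s.fluence[mask]))

    r1 = med_rel(25_000, 13)
    r2 = med_rel(100_000, 14)
    # quadrupling histories should halve the relative error (within noise)
    assert 1.4 < r1 / r2 < 2.9


def test_no_annihilation_photons_below_pair_threshold():
    geom = m.GeometryConfig(
        ssd=50.0,
        field_size_at_surface=(5.0, 5.0),
        phantom_dims=(40.0, 40.0, 40.0),
        intervening_medium="vacuum",
    )
    sc = m.ScoringConfig(
        spectrum_depths=(5.0,),
        spectrum_voxel=(4.0, 4.0, 0.5),
        profile_lateral=(2.0, 2.0),
        histories=20_000,
        seed=7,
    )
    below = m.run_transport(_mono_source(0.9), geom, sc)
    assert below.stats["n_pair_events"] == 0
    above = m.run_transport(_mono_source(6.0), geom, sc)
    assert above.stats["n_pair_events"] > 0


def test_invalid_scoring_rejected():
    src = m.build_source("6MV")
    geom = m.GeometryConfig(
        ssd=100.0,
        field_size_at_surface=(10.0, 10.0),
        phantom_dims=(40.0, 40.0, 30.0),
    )
    with pytest.raises(ValueError, match="histories"):
        m.ScoringConfig(histories=0)
    sc = m.ScoringConfig(spectrum_depths=(0.0, 35.0), histories=10)
    with pytest.raises(ValueError, match="outside the phantom"):
        m.run_transport(src, geom, sc)


def test_magna_softer_than_reference_at_depth(study_grid):
    """At matched 10 cm depth the magna-field spectrum is softer than the
    reference-field spectrum for the same source."""
    spectra = study_grid["spectra"]
    for energy in ("6mv", "10mv"):
        ref = m.mean_energy(spectra[(energy, "reference_10x10", 10.0)])
        magna = m.mean_energy(spectra[(energy, "magna_nearinfinite", 10.0)])
        assert magna < ref
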