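"""Shared fixtures, including the session-level simulated condition grid."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import magnaspec as m
from magnaspec.detector_response import build_correction_table
from magnaspec.pipeline import PRESETS

GRID_SEED = 1
GRID_HISTORIES = 1_000_000
DEPTHS = (0.0, 5.0, 10.0, 20.0, 35.0)
CONDITIONS = (
    "reference_10x10",
    "magna_nearinfinite",
    "magna_adult",
    "magna_small",
)
DETECTORS = ("farmer_ne2571", "lif_tld", "al2o3_osld")


@pytest.fixture(scope="session")
def water():
    return m.load_medium("water")


@pytest.fixture(scope="session")
def study_grid():
    """Simulate the full study grid once per session.

    Both nominal energies under the reference 10x10 condition and the
    three magna phantom sizes, at a desk-scale number of histories, with
    spectra at the standard depths and a central-axis depth profile.
    """
    spectra, profiles = {}, {}
    for energy in ("6mv", "10mv"):
        source = m.build_source(energy)
        for name in CONDITIONS:
            preset = PRESETS[name]
            pz = preset.geometry.phantom_dims[2]
            scoring = m.ScoringConfig(
                spectrum_depths=tuple(d for d in DEPTHS if d <= pz),
                spectrum_voxel=preset.spectrum_voxel,
                profile_lateral=preset.profile_lateral,
                histories=GRID_HISTORIES,
                seed=GRID_SEED,
            )
            res = m.run_transport(source, preset.geometry, scoring)
            profiles[(energy, name)] = res.profile
            for spec in res.spectra:
                spectra[(energy, name, spec.depth_cm)] = spec
    return {"spectra": spectra, "profiles": profiles}


@pytest.fixture(scope="session")
def correction_grid(study_grid):
    """Tidy k_NR table over the magna grid for all three dosimeters."""
    frames = []
    for energy in ("6mv", "10mv"):
        sub = {
            k: v for k, v in study_grid["spectra"].items() if k[0] == energy
        }
        tab = build_correction_table(
            sub, DETECTORS, (energy, "reference_10x10", 10.0)
        )
        frames.append(tab.data)
    df = pd.concat(frames, ignore_index=True)
    return df[df["phantom"] != "reference_10x10"].reset_index(drop=True)


@pytest.fixture()
def toy_edges():
    return np.arange(0.0, 6.05, 0.05)
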