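"""Spectrum-weighted detector response and energy-dependence corrections.

The central quantity is the spectrum-weighted relative response

    Y = sum_i r(E_i) (muen/rho)(E_i) phi(E_i) E_i dE_i
        / sum_i (muen/rho)(E_i) phi(E_i) E_i dE_i

with phi the differential photon fluence, r the detector's relative energy
response per unit water dose, and muen/rho the water mass energy-absorption
coefficient (secondary electronic equilibrium in water assumed).  The
non-reference correction factor is k_NR = Y_ref / Y_clin: it converts a
reading calibrated in the reference beam quality into dose under the
clinical (here magna-field) spectrum.  Over-responding detectors in a
softened beam give k_NR < 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .physics_data import CoefficientTable, load_medium
from .transport_mc import Spectrum, mean_energy

__all__ = [
    "DetectorResponse",
    "CorrectionResult",
    "CorrectionTable",
    "SUPPORTED_DETECTORS",
    "load_detector",
    "response_weighted_y",
    "k_nr",
    "build_correction_table",
    "spectrum_averaged_ratio",
]

SUPPORTED_DETECTORS = ("farmer_ne2571", "lif_tld", "al2o3_osld")


@dataclass(frozen=True)
class DetectorResponse:
    """Relative energy-response curve r(E) for a named dosimeter."""

    detector: str
    energies: np.ndarray  # MeV
    r: np.ndarray  # dimensionless, > 0

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        r = np.asarray(self.r, dtype=float)
        if np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly increasing")
        if np.any(r <= 0):
            raise ValueError("relative response must be strictly positive")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "r", r)

    def at(self, energy):
        """r interpolated linearly in log(E); no extrapolation."""
        e = np.asarray(energy, dtype=float)
        if np.any(e < self.energies[0]) or np.any(e > self.energies[-1]):
            raise ValueError(
                f"energy outside the {self.detector} response grid"
            )
        out = np.interp(np.log(e), np.log(self.energies), self.r)
        return float(out) if np.ndim(energy) == 0 else out

    def normalized_at(self, energy: float) -> "DetectorResponse":
        """Copy rescaled so r(energy) = 1 (normalization point is a pure
        convention: it cancels exactly in k_NR)."""
        return DetectorResponse(
            self.detector, self.energies, self.r / self.at(energy)
        )


@dataclass(frozen=True)
class CorrectionResult:
    """Y_ref, Y_clin and k_NR = Y_ref/Y_clin for one condition."""

    detector: str
    y_ref: float
    y_clin: float
    k_nr: float
    condition: tuple = ()

    def __post_init__(self):
        if self.k_nr <= 0:
            raise ValueError("k_nr must be positive")


@lru_cache(maxsize=None)
def load_detector(detector: str) -> DetectorResponse:
    """Load a shipped relative energy-response fixture."""
    key = str(detector).lower()
    if key not in SUPPORTED_DETECTORS:
        raise ValueError(
            f"unsupported detector {detector!r}; available: "
            f"{', '.join(SUPPORTED_DETECTORS)}"
        )
    ref = resources.files("magnaspec.data.detectors") / f"{key}.csv"
    rows = [
        [float(v) for v in line.split(",")]
        for line in ref.read_text().splitlines()
        if line.strip() and not line.startswith(("#", "energy_MeV"))
    ]
    arr = np.array(rows)
    return DetectorResponse(detector=key, energies=arr[:, 0], r=arr[:, 1])


def _weights(spectrum: Spectrum, water: CoefficientTable):
    """Energy-fluence x muen/rho weights on the nonzero spectrum bins."""
    mask = spectrum.fluence > 0
    if not mask.any():
        raise ValueError("spectrum has no nonzero bins")
    centers = spectrum.bin_centers[mask]
    if np.any(centers < water.e_min) or np.any(centers > water.e_max):
        raise ValueError(
            "coefficient grid does not cover the spectrum support"
        )
    from .physics_data import interpolate

    muen = interpolate(water, centers, "muen_rho")
    # phi is differential fluence: per-bin fluence / bin width, and the
    # explicit dE factor restores the bin weight -- so per-bin fluence is
    # used directly and Y is invariant to rebinning.
    w = muen * spectrum.fluence[mask] * centers
    return centers, w


def response_weighted_y(
    spectrum: Spectrum, response: DetectorResponse, water: CoefficientTable
) -> float:
    """Spectrum-weighted relative response Y of a detector."""
    centers, w = _weights(spectrum, water)
    r = response.at(centers)
    return float((r * w).sum() / w.sum())


def k_nr(
    spectrum_ref: Spectrum,
    spectrum_clin: Spectrum,
    response: DetectorResponse,
    water: CoefficientTable | None = None,
    condition: tuple = (),
) -> CorrectionResult:
    """Energy-dependence correction factor k_NR = Y_ref / Y_clin."""
    if water is None:
        water = load_medium("water")
    y_ref = response_weighted_y(spectrum_ref, response, water)
    y_clin = response_weighted_y(spectrum_clin, response, water)
    return CorrectionResult(
        detector=response.detector,
        y_ref=y_ref,
        y_clin=y_clin,
        k_nr=y_ref / y_clin,
        condition=tuple(condition),
    )


def spectrum_averaged_ratio(
    spectrum: Spectrum,
    medium_a: CoefficientTable,
    medium_b: CoefficientTable,
) -> float:
    """Energy-fluence-weighted mean of (muen/rho)_a / (muen/rho)_b.

    The medium-conversion ratio used to relate dose-to-phantom-medium to
    dose-to-water for a given beam spectrum.
    """
    from .physics_data import interpolate

    mask = spectrum.fluence > 0
    if not mask.any():
        raise ValueError("spectrum has no nonzero bins")
    centers = spectrum.bin_centers[mask]
    for tab in (medium_a, medium_b):
        if np.any(centers < tab.e_min) or np.any(centers > tab.e_max):
            raise ValueError(
                "coefficient grid does not cover the spectrum support"
            )
    w = spectrum.fluence[mask] * centers
    ratio = interpolate(medium_a, centers, "muen_rho") / interpolate(
        medium_b, centers, "muen_rho"
    )
    return float((w * ratio).sum() / w.sum())


@dataclass(frozen=True)
class CorrectionTable:
    """k_NR values on a detector x energy x phantom x depth grid.

    ``data`` is a tidy DataFrame with columns detector, energy, phantom,
    depth_cm, y_ref, y_clin, k_nr; cells absent from the simulated grid
    (e.g. depths beyond a phantom's thickness) carry NaN.
    """

    data: pd.DataFrame
    reference_condition: tuple

    def to_wide(self, detector: str, digits: int = 3) -> pd.DataFrame:
        """Published-style layout: rows = depth, columns = phantom x energy,
        rounded to ``digits`` decimals."""
        sub = self.data[self.data["detector"] == detector]
        wide = sub.pivot_table(
            index="depth_cm",
            columns=["phantom", "energy"],
            values="k_nr",
            dropna=False,
        )
        return wide.round(digits)

    def max_abs_deviation_pct(
        self, detector=None, depths=None
    ) -> float:
        """max |1 - k_NR| x 100 over the (optionally filtered) grid."""
        sub = self.data
        if detector is not None:
            sub = sub[sub["detector"] == detector]
        if depths is not None:
            sub = sub[sub["depth_cm"].isin(depths)]
        k = sub["k_nr"].dropna()
        if k.empty:
            raise ValueError("no populated cells match the filter")
        return float(np.max(np.abs(1.0 - k.to_numpy())) * 100.0)


def build_correction_table(
    spectra_by_condition: dict,
    detectors,
    reference_condition: tuple,
    normalize_reference: bool = True,
) -> CorrectionTable:
    """k_NR grid against one reference condition.

    ``spectra_by_condition`` maps (energy, phantom, depth_cm) tags to
    Spectrum objects; the reference tag must be present.  The requested
    grid is the product of the energies, phantoms, and depths that occur in
    the map; combinations without a spectrum (depths beyond a phantom) are
    recorded with NaN.  Each detector's response is normalized to 1 at the
    reference spectrum's mean energy (presentation only; k_NR is unchanged).
    """
    if reference_condition not in spectra_by_condition:
        raise ValueError(
            f"reference condition {reference_condition!r} missing from the "
            "spectra map"
        )
    water = load_medium("water")
    ref_spec = spectra_by_condition[reference_condition]
    grid_keys = [
        c for c in spectra_by_condition if c != tuple(reference_condition)
    ] or [tuple(reference_condition)]
    energies = sorted({c[0] for c in grid_keys})
    phantoms = sorted({c[1] for c in grid_keys})
    depths = sorted({c[2] for c in grid_keys})
    rows = []
    for name in detectors:
        resp = load_detector(name) if isinstance(name, str) else name
        if normalize_reference:
            resp = resp.normalized_at(mean_energy(ref_spec))
        for en in energies:
            for ph in phantoms:
                for d in depths:
                    tag = (en, ph, d)
                    row = {
                        "detector": resp.detector,
                        "energy": en,
                        "phantom": ph,
                        "depth_cm": d,
                    }
                    spec = spectra_by_condition.get(tag)
                    if spec is None:
                        row.update(y_ref=np.nan, y_clin=np.nan, k_nr=np.nan)
                    else:
                        res = k_nr(ref_spec, spec, resp, water, condition=tag)
                        row.update(
                            y_ref=res.y_ref, y_clin=res.y_clin, k_nr=res.k_nr
                        )
                    rows.append(row)
    return CorrectionTable(
        data=pd.DataFrame(rows), reference_condition=tuple(reference_condition)
    )
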