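"""CSV round-trip readers and writers for run artifacts."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .beam_quality import DepthCurve
from .transport_mc import DepthProfile, Spectrum

__all__ = [
    "write_spectra_csv",
    "read_spectra_csv",
    "write_profile_csv",
    "read_profile_csv",
    "write_curve_csv",
    "read_curve_csv",
]


def write_spectra_csv(spectra, path):
    """Long-format spectra: depth_cm, e_low_MeV, e_high_MeV, fluence, rel_unc."""
    frames = []
    for spec in spectra:
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(
                spec.fluence > 0, spec.uncertainty / spec.fluence, 0.0
            )
        frames.append(
            pd.DataFrame(
                {
                    "depth_cm": spec.depth_cm,
                    "e_low_MeV": spec.bin_edges[:-1],
                    "e_high_MeV": spec.bin_edges[1:],
                    "fluence": spec.fluence,
                    "rel_unc": rel,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spectra_csv(path):
    """Inverse of :func:`write_spectra_csv`; returns a list of Spectrum."""
    df = pd.read_csv(path)
    out = []
    for depth, sub in df.groupby("depth_cm", sort=True):
        sub = sub.sort_values("e_low_MeV")
        edges = np.append(
            sub["e_low_MeV"].to_numpy(), sub["e_high_MeV"].iloc[-1]
        )
        flu = sub["fluence"].to_numpy()
        out.append(
            Spectrum(
                bin_edges=edges,
                fluence=flu,
                uncertainty=sub["rel_unc"].to_numpy() * flu,
                location=f"depth_{depth:g}cm",
                depth_cm=float(depth),
            )
        )
    return out


def write_profile_csv(profile: DepthProfile, path):
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(
            profile.kerma > 0, profile.uncertainty / profile.kerma, 0.0
        )
    pd.DataFrame(
        {
            "depth_cm": profile.depths,
            "kerma": profile.kerma,
            "mean_energy_MeV": profile.mean_energy,
            "rel_unc": rel,
        }
    ).to_csv(path, index=False)


def read_profile_csv(path) -> DepthProfile:
    df = pd.read_csv(path)
    kerma = df["kerma"].to_numpy()
    return DepthProfile(
        depths=df["depth_cm"].to_numpy(),
        kerma=kerma,
        mean_energy=df["mean_energy_MeV"].to_numpy(),
        uncertainty=df["rel_unc"].to_numpy() * kerma,
    )


def write_curve_csv(curve: DepthCurve, path):
    pd.DataFrame({"depth_cm": curve.depths, "value": curve.values}).to_csv(
        path, index=False
    )


def read_curve_csv(path) -> DepthCurve:
    df = pd.read_csv(path)
    return DepthCurve(df["depth_cm"].to_numpy(), df["value"].to_numpy())
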