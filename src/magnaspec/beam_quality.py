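"""Depth-dose post-processing: PDD, Mayneord F factor, TPR, spoiler shift.

Central-axis kerma profiles from the transport engine are turned into
percent-depth-dose (PDD) curves, converted between SSDs with the Mayneord
F factor (inverse-square only; phantom-scatter terms omitted), and into
tissue-phantom ratios (TPR) referenced to d_max.  A depth-shift utility
accounts for the water-equivalent thickness of a beam spoiler when
comparing spoiled and unspoiled curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transport_mc import DepthProfile

__all__ = [
    "DepthCurve",
    "BeamQualityCurves",
    "pdd_from_profile",
    "mayneord_f",
    "tpr_from_pdd",
    "shift_for_spoiler",
    "interp_to_grid",
    "derive_curves",
]


@dataclass(frozen=True)
class DepthCurve:
    """A value-vs-depth curve on the simulation depth grid."""

    depths: np.ndarray  # cm
    values: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.depths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if d.shape != v.shape or d.ndim != 1:
            raise ValueError("depths and values must be equal-length 1-D")
        if np.any(np.diff(d) <= 0):
            raise ValueError("depths must be strictly increasing")
        object.__setattr__(self, "depths", d)
        object.__setattr__(self, "values", v)

    def at(self, depth) -> float:
        """Linear interpolation within the support; no extrapolation."""
        depth = float(depth)
        if depth < self.depths[0] or depth > self.depths[-1]:
            raise ValueError(f"depth {depth} cm outside curve support")
        return float(np.interp(depth, self.depths, self.values))


@dataclass(frozen=True)
class BeamQualityCurves:
    """PDD and TPR for one condition, with the parameters that made them."""

    pdd: DepthCurve  # percent of the value at d_max
    tpr: DepthCurve  # ratio, 1 at d_max
    d_max: float
    ssd: float
    f_factor_params: tuple | None = None  # (ssd_from, ssd_to, d_max)


def pdd_from_profile(
    profile: DepthProfile, normalization_depth: float
) -> DepthCurve:
    """Percent depth dose: 100 * kerma(d) / kerma(normalization_depth)."""
    curve = DepthCurve(profile.depths, profile.kerma)
    ref = curve.at(normalization_depth)
    if ref <= 0:
        raise ValueError(
            f"zero kerma at normalization depth {normalization_depth} cm"
        )
    return DepthCurve(curve.depths, 100.0 * curve.values / ref)


def mayneord_f(ssd_from, ssd_to, d, d_max):
    """Mayneord F factor converting a PDD from one SSD to another.

    F = ((ssd_to + d_max) / (ssd_from + d_max))^2
        * ((ssd_from + d) / (ssd_to + d))^2

    Multiplying PDD(d) measured at ``ssd_from`` by F predicts the PDD at
    ``ssd_to`` under inverse-square-only assumptions (no change in phantom
    scatter).  Accepts scalars or arrays for ``d``.
    """
    ssd_from, ssd_to, d_max = float(ssd_from), float(ssd_to), float(d_max)
    d_arr = np.asarray(d, dtype=float)
    if ssd_from <= 0 or ssd_to <= 0 or d_max <= 0 or np.any(d_arr < 0):
        raise ValueError("distances must be positive and depth non-negative")
    f = ((ssd_to + d_max) / (ssd_from + d_max)) ** 2 * (
        (ssd_from + d_arr) / (ssd_to + d_arr)
    ) ** 2
    return float(f) if np.ndim(d) == 0 else f


def tpr_from_pdd(pdd: DepthCurve, ssd: float, d_max: float) -> DepthCurve:
    """Tissue-phantom ratio from a PDD measured at a fixed SSD.

    TPR(d) = [PDD(d) / PDD(d_max)] * ((ssd + d) / (ssd + d_max))^2,
    so TPR(d_max) = 1 exactly and pure inverse-square fall-off maps to
    TPR = 1 at every depth.  Phantom-scatter-ratio corrections are
    deliberately omitted (documented approximation).
    """
    ref = pdd.at(d_max)
    if ref == 0:
        raise ValueError(f"PDD is zero at d_max = {d_max} cm")
    geo = ((ssd + pdd.depths) / (ssd + d_max)) ** 2
    return DepthCurve(pdd.depths, pdd.values / ref * geo)


def shift_for_spoiler(curve: DepthCurve, shift: float) -> DepthCurve:
    """Translate the depth axis by +shift cm (spoiler-equivalent depth).

    The curve values are unchanged; the support moves with the shift, so a
    round trip (+s then -s) recovers the original curve exactly.
    """
    if shift < 0:
        raise ValueError("shift must be non-negative")
    return DepthCurve(curve.depths + float(shift), curve.values)


def _shift_any(curve: DepthCurve, shift: float) -> DepthCurve:
    """Signed translation used internally for round-trip comparisons."""
    return DepthCurve(curve.depths + float(shift), curve.values)


def interp_to_grid(curve: DepthCurve, grid) -> DepthCurve:
    """Resample onto ``grid`` by linear interpolation, dropping points
    outside the original support."""
    grid = np.asarray(grid, dtype=float)
    inside = (grid >= curve.depths[0]) & (grid <= curve.depths[-1])
    g = grid[inside]
    return DepthCurve(g, np.interp(g, curve.depths, curve.values))


def derive_curves(
    profile: DepthProfile,
    ssd: float,
    d_max: float,
    f_to_ssd: float | None = None,
) -> BeamQualityCurves:
    """PDD (normalized at d_max) and TPR for one simulated profile.

    When ``f_to_ssd`` is given, the PDD is additionally Mayneord-corrected
    from ``ssd`` to ``f_to_ssd`` before the TPR conversion (the conversion
    then uses ``f_to_ssd`` as the measurement SSD).
    """
    pdd = pdd_from_profile(profile, d_max)
    params = None
    eff_ssd = ssd
    if f_to_ssd is not None:
        f = mayneord_f(ssd, f_to_ssd, pdd.depths, d_max)
        pdd = DepthCurve(pdd.depths, pdd.values * f)
        params = (ssd, f_to_ssd, d_max)
        eff_ssd = f_to_ssd
    tpr = tpr_from_pdd(pdd, eff_ssd, d_max)
    return BeamQualityCurves(
        pdd=pdd, tpr=tpr, d_max=d_max, ssd=ssd, f_factor_params=params
    )
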