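"""Photon interaction-coefficient tables for water, PMMA (Lucite), and air.

Ships energy-gridded mass attenuation coefficients (total and per process:
Compton, photoelectric, pair production) and mass energy-absorption
coefficients on a 0.01-12 MeV grid, with coherent (Rayleigh) scattering
folded out of the totals, plus log-log interpolation between grid nodes.

The tables are versioned fixture CSVs under ``data/coefficients``; see
``scripts/generate_physics_fixtures.py`` for their construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = ["CoefficientTable", "load_medium", "interpolate", "QUANTITIES"]

SUPPORTED_MEDIA = ("water", "pmma", "air")
PROCESSES = ("compton", "photoelectric", "pair")
QUANTITIES = ("total_mu_rho", "muen_rho") + PROCESSES


@dataclass(frozen=True)
class CoefficientTable:
    """Energy-gridded interaction coefficients for one medium.

    Attributes
    ----------
    medium : str
        One of ``water``, ``pmma``, ``air``.
    energies : ndarray
        Strictly increasing photon energy grid, MeV.
    total_mu_rho : ndarray
        Coherent-free mass attenuation coefficient, cm^2/g.
    partial_mu_rho : dict of str -> ndarray
        Per-process mass attenuation coefficients (``compton``,
        ``photoelectric``, ``pair``), cm^2/g.  They sum to the total.
    muen_rho : ndarray
        Mass energy-absorption coefficient, cm^2/g.
    density : float
        Bulk density, g/cm^3.
    """

    medium: str
    energies: np.ndarray
    total_mu_rho: np.ndarray
    partial_mu_rho: dict
    muen_rho: np.ndarray
    density: float

    @property
    def e_min(self) -> float:
        return float(self.energies[0])

    @property
    def e_max(self) -> float:
        return float(self.energies[-1])

    def quantity(self, name: str) -> np.ndarray:
        if name == "total_mu_rho":
            return self.total_mu_rho
        if name == "muen_rho":
            return self.muen_rho
        if name in self.partial_mu_rho:
            return self.partial_mu_rho[name]
        raise KeyError(
            f"unknown quantity {name!r}; expected one of {QUANTITIES}"
        )


@lru_cache(maxsize=None)
def load_medium(medium: str) -> CoefficientTable:
    """Load the embedded coefficient table for a medium.

    Raises
    ------
    ValueError
        If ``medium`` is not one of ``water``, ``pmma``, ``air``.
    """
    key = str(medium).lower()
    if key not in SUPPORTED_MEDIA:
        raise ValueError(
            f"unsupported medium {medium!r}; available media are "
            f"{', '.join(SUPPORTED_MEDIA)}"
        )
    ref = resources.files("magnaspec.data.coefficients") / f"{key}.csv"
    density = None
    rows = []
    for line in ref.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "density_g_cm3" in line:
                density = float(line.split("=")[1])
            continue
        if line.startswith("energy_MeV"):
            continue
        rows.append([float(v) for v in line.split(",")])
    arr = np.array(rows)
    if density is None:  # pragma: no cover - fixture contract
        raise ValueError(f"fixture for {key} lacks a density header")
    return CoefficientTable(
        medium=key,
        energies=arr[:, 0],
        total_mu_rho=arr[:, 1],
        partial_mu_rho={
            "compton": arr[:, 2],
            "photoelectric": arr[:, 3],
            "pair": arr[:, 4],
        },
        muen_rho=arr[:, 5],
        density=density,
    )


def _loglog_interp(e_grid, y_grid, energy):
    """Log-log linear interpolation, falling back to linear where y <= 0.

    Exact at grid nodes.  Zeros occur only in the pair-production column
    below its threshold; there the bracketing interval is interpolated
    linearly in energy so the result stays finite and non-negative.
    """
    energy = np.asarray(energy, dtype=float)
    if np.all(y_grid > 0):
        return np.exp(
            np.interp(np.log(energy), np.log(e_grid), np.log(y_grid))
        )
    lin = np.interp(energy, e_grid, y_grid)
    positive = y_grid > 0
    if not positive.any():
        return lin
    # log-log only where the bracketing nodes are both positive
    first_pos = e_grid[positive][0]
    safe = energy >= first_pos
    out = lin
    if np.any(safe):
        logy = np.where(positive, np.log(np.where(positive, y_grid, 1.0)), 0.0)
        ll = np.exp(np.interp(np.log(energy), np.log(e_grid), logy))
        out = np.where(safe, ll, lin)
    return out


def interpolate(table: CoefficientTable, energy, quantity: str):
    """Interpolate a coefficient at arbitrary energies within the grid span.

    Log-log linear between bracketing nodes (cross sections are near
    power-law there); exact at grid nodes; no extrapolation.

    Parameters
    ----------
    table : CoefficientTable
    energy : float or array_like
        Photon energy in MeV; must lie within ``[table.e_min, table.e_max]``.
    quantity : str
        One of ``total_mu_rho``, ``muen_rho``, ``compton``,
        ``photoelectric``, ``pair``.

    Returns
    -------
    float or ndarray, cm^2/g
    """
    e = np.asarray(energy, dtype=float)
    if np.any(e < table.e_min) or np.any(e > table.e_max):
        raise ValueError(
            f"energy outside the {table.medium} grid span "
            f"[{table.e_min}, {table.e_max}] MeV; no extrapolation"
        )
    y = _loglog_interp(table.energies, table.quantity(quantity), e)
    if np.isscalar(energy) or np.ndim(energy) == 0:
        return float(y)
    return y
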