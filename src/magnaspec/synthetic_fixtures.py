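"""Deterministic toy-spectrum generators for testing downstream stages.

Every generator is a pure function of its spec (seed included), so the
depth-dose and correction-factor machinery can be exercised without
running the transport engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .transport_mc import Spectrum

__all__ = ["ToySpectrumSpec", "make_spectrum", "make_softened_pair"]

_SHAPES = ("delta", "flat", "exponential")


@dataclass(frozen=True)
class ToySpectrumSpec:
    """Recipe for an analytic spectrum.

    ``shape`` is ``delta`` (all weight in the bin containing
    ``delta_energy``), ``flat`` (equal weight per bin), or ``exponential``
    (weight ~ exp(-E/softness); smaller softness = softer spectrum).  With
    a ``noise_seed``, per-bin Poisson counting noise of mean
    ``amplitude * shape`` is applied.
    """

    bin_edges: tuple
    shape: str = "flat"
    delta_energy: float = 1.0
    softness: float = 1.0  # MeV, exponential-tail parameter
    amplitude: float = 1000.0
    noise_seed: int | None = None

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        if edges.size < 2:
            raise ValueError("need at least one bin (two edges)")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {_SHAPES}")
        if self.shape == "exponential" and self.softness <= 0:
            raise ValueError("softness must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        object.__setattr__(self, "bin_edges", tuple(edges))


def make_spectrum(spec: ToySpectrumSpec) -> Spectrum:
    """Deterministic spectrum with the requested analytic shape."""
    edges = np.asarray(spec.bin_edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if spec.shape == "delta":
        if not edges[0] <= spec.delta_energy <= edges[-1]:
            raise ValueError("delta_energy outside the bin range")
        weights = np.zeros(centers.size)
        idx = min(
            int(np.searchsorted(edges, spec.delta_energy, side="right")) - 1,
            centers.size - 1,
        )
        weights[idx] = 1.0
    elif spec.shape == "flat":
        weights = np.ones(centers.size)
    else:
        weights = np.exp(-centers / spec.softness)
    fluence = spec.amplitude * weights / weights.sum()
    if spec.noise_seed is not None:
        rng = np.random.default_rng(spec.noise_seed)
        fluence = rng.poisson(fluence).astype(float)
    return Spectrum(
        bin_edges=edges,
        fluence=fluence,
        uncertainty=np.sqrt(np.maximum(fluence, 0.0)),
        location=f"toy_{spec.shape}",
    )


def make_softened_pair(
    base: ToySpectrumSpec, shift_fraction: float
) -> tuple:
    """(reference, clinical) pair where the clinical spectrum is softened.

    A fraction ``shift_fraction`` of the total fluence is removed
    proportionally from every bin and re-deposited uniformly across the
    lowest-energy quartile of bins, emulating the buildup of low-energy
    scattered photons in a broad field.  ``shift_fraction = 0`` returns two
    identical spectra.
    """
    if not 0.0 <= shift_fraction <= 1.0:
        raise ValueError("shift_fraction must lie in [0, 1]")
    reference = make_spectrum(base)
    flu = reference.fluence.copy()
    total = flu.sum()
    moved = shift_fraction * total
    flu *= 1.0 - shift_fraction
    n_low = max(1, int(np.ceil(flu.size / 4)))
    flu[:n_low] += moved / n_low
    clinical = Spectrum(
        bin_edges=reference.bin_edges,
        fluence=flu,
        uncertainty=np.zeros_like(flu),
        location=f"{reference.location}_softened",
    )
    return reference, clinical
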