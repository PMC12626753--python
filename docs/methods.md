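# Methods

## Physical model

`magnaspec` implements an analog photon-only Monte Carlo in a simple
layered geometry: a point source at the origin emits photons into a
divergent rectangular aperture defined at the phantom entrance plane; the
photons traverse an intervening medium (air by default, vacuum for
verification runs), optionally a PMMA beam-spoiler slab, and a box water
phantom. Three interactions are sampled in every medium, with
probabilities proportional to the per-process mass attenuation
coefficients at the photon energy:

* **Compton scattering** off free electrons at rest, with the scattered
  energy fraction drawn by composition–rejection sampling of the
  Klein–Nishina distribution and the polar angle fixed by the Compton
  kinematics; azimuth uniform. Electron binding (incoherent scattering
  function, Doppler broadening) is neglected; below ~50 keV this
  overstates the scattering cross section by up to tens of percent, but
  photon removal there is photoelectric-dominated so the effect on scored
  spectra is small.
* **Photoelectric absorption**, terminating the history with local energy
  deposition.
* **Pair production** above 1.022 MeV, replacing the photon with two
  0.511 MeV annihilation photons emitted back-to-back with isotropic
  orientation at the interaction point (positron range neglected).

Coherent (Rayleigh) scattering is folded out of the interaction tables
entirely: at MeV energies its angular deflections are small and it neither
absorbs energy nor changes the photon energy, and omitting it keeps the
sampler to three processes.

Photons falling below **10 keV** are terminated with local absorption —
the photon analogue of a short electron production threshold. Photons
leaving the world box (the phantom's downstream face, or a generous
lateral margin) are discarded; backscatter from air behind the phantom is
therefore neglected.

**Electron transport is omitted.** All secondary-electron energy deposits
at the point of transfer, so the depth quantity the engine scores is
collision kerma: track-length fluence × E × (μen/ρ)water per depth bin.
Consequently there is no buildup region and the depth of maximum dose is a
*configured* nominal value (1.5 cm for 6 MV, 2.5 cm for 10 MV), used as
the TPR reference depth, not an argmax of the kerma curve. For the
package's deliverables — photon spectra and spectrum-weighted response
ratios, both defined under electronic equilibrium — this approximation is
exact in the regions of interest and merely blurs the first ~2 cm of the
depth-dose curves.

## Cross-section and response data

The interaction tables (water, PMMA at 1.19 g/cm³, air at
1.205 × 10⁻³ g/cm³; 0.01–12 MeV) are versioned CSV fixtures generated by
`scripts/generate_physics_fixtures.py`: exact integrated Klein–Nishina
cross sections per electron × N_A(Z/A) for Compton, a per-medium
photoelectric power law `τ₀·(E/0.01 MeV)^-3.3` anchored to standard
reference coherent-free totals at 0.01 MeV, and a pair-production shape
`(1 − 1.022/E)³ ln(1+E)` anchored at 10 MeV. μen/ρ is transcribed from
standard reference tables. Totals agree with reference compilations to a
few percent over the whole grid, and the per-process partials sum to the
total exactly. Interpolation is log–log linear (cross sections are close
to power laws between nodes); no extrapolation is permitted.

Detector response fixtures `r(E)` (relative response per unit water dose,
normalized to 1 at 1.25 MeV):

* **NE 2571 Farmer chamber** — hand-maintained near-flat curve (within
  ±0.5% over 0.1–10 MeV, mild structure around 60–100 keV, falling below
  50 keV), representative of published Farmer-type data.
* **LiF TLD and Al₂O₃:C OSLD** — computed by
  `scripts/generate_detector_fixtures.py` from the first-order cavity
  model, r(E) = (μen/ρ)detector / (μen/ρ)water, using the same analytic
  cross-section machinery as the interaction tables. This reproduces the
  well-known over-response magnitudes (≈1.4 for LiF, ≈3.6 for Al₂O₃:C near
  30 keV) and the return to ~1 above 0.2 MeV. Measured luminescent-detector
  curves tend to sit somewhat below the μen ratio at the lowest energies
  (self-absorption, luminescence efficiency); the fixtures therefore give
  a conservative (slightly large) low-energy over-response. This is the
  main reason the computed OSLD correction maximum (~5.5%) modestly
  exceeds published magna-field values (~4.6–4.8%).

## Sources

The 6 and 10 MV sources are analytic bremsstrahlung-shaped emission
spectra `p(E) ∝ E·exp(−E/Ep)·(1 − E/Emax)`, zeroed below 0.1 MeV
(flattening-filter hardening), discretized in uniform bins. The peak
parameters (Ep = 1.15 MeV for 6 MV, 1.80 MeV for 10 MV) were chosen once
so the in-air mean energies (≈1.7 and ≈2.7 MeV) lie in the range typical
of clinical linacs; the resulting in-phantom mean at 10 cm depth under
reference conditions is ≈1.3 MeV (6 MV) and ≈2.3 MeV (10 MV). Hardness is
a user parameter (`build_source(..., {"peak_energy": ...})`), not a fit.

## Scoring

Fluence spectra use a track-length estimator in central-axis voxels at the
requested depths (default depths 0, 5, 10, 20, 35 cm, half-open bins
[d, d+t)). Energy bins are uniform with a **0.01 MeV default width**: Y is
evaluated with coefficients and responses at bin centers, and with 50 keV
bins the steep rise of μen/ρ below 30 keV makes the lowest bin's
center-value unrepresentative, inflating Y by several percent in softened
spectra; at 10 keV bins Y is converged (≤0.1% change on further halving).

The 5 × 5 × 5 mm voxel of cluster-scale studies is the dataclass default, but at
desk-scale statistics (10⁶–2×10⁶ histories versus 2×10¹¹ in
cluster-scale studies) a 5 mm voxel in a 180 × 180 cm field collects only
a handful of primaries. The presets therefore widen the scoring voxel
laterally — 15 × 15 cm (magna) and 4 × 4 cm (reference), 5 mm thick —
exploiting the lateral near-uniformity of the central region of these very
large (or reference-sized) fields; the depth-profile column is widened
likewise (10 × 10 cm magna, 2 × 2 cm reference, 2 mm depth bins).
Statistical uncertainties are estimated from the spread over 10
independent history batches, each driven by a generator seeded
deterministically from (seed, batch index); runs are bit-reproducible for
a fixed configuration.

## Beam-quality processing

PDD is 100 × kerma(d)/kerma(d_ref). The Mayneord F factor

F = ((ssd₂+d_max)/(ssd₁+d_max))² · ((ssd₁+d)/(ssd₂+d))²

converts PDDs between SSDs under inverse-square-only assumptions, and
TPR(d) = PDD(d)/PDD(d_max) · ((ssd+d)/(ssd+d_max))²; phantom-scatter-ratio
terms are deliberately omitted from both (no scatter-factor tables exist
for these conditions), which is the documented approximation the TPR
comparisons inherit. Both routes to a magna-comparable TPR are available:
directly from a magna profile, or from a reference profile via the F
factor (`derive_curves(..., f_to_ssd=450)`). A spoiler shift utility
translates a curve's depth axis by the spoiler-equivalent thickness when
comparing spoiled and unspoiled conditions.

## Correction factors

Y and k_NR = Y_ref/Y_clin follow the spectrum-weighted response
definition with φ interpreted as differential fluence (per-bin fluence
divided by bin width), which makes Y invariant to rebinning. The reference
condition is the 10 × 10 cm², SSD 100 cm spectrum at 10 cm depth of the
same nominal energy. Detector curves are renormalized to 1 at the
reference spectrum's mean energy for presentation; k_NR is a ratio, so the
normalization point cancels exactly. Grid cells whose depth exceeds the
phantom thickness (35 cm in the 30 cm phantom) are recorded as absent.
Published-style tables round to three decimals.

## Synthetic toy spectra

`synthetic_fixtures` generates delta/flat/exponential-tail spectra and
softened pairs (a stated fraction of the total fluence moved into the
lowest-energy quartile of bins, emulating low-energy Compton buildup) as
pure functions of their spec; optional counting noise is Poisson on
per-bin counts. These exercise every downstream stage without the
transport engine. What passing toy-based tests do **not** show: anything
about angular/spatial phase-space structure, or about real measured
detector signals (fading, dose-rate, angular dependence are all out of
scope).

## Known limitations

* Kerma approximation: no buildup, surface dose from spoiler-generated
  electrons is not modelled (the spoiler acts only as a photon
  attenuator/scatterer here).
* Ideal aperture collimation: no jaw transmission or head scatter.
* Free-electron Compton and no Rayleigh scattering (see above).
* The analytic source is a stand-in with tunable hardness, not a modelled
  linac head; absolute spectra are indicative, while condition-to-condition
  ratios (the package's purpose) are robust.
* Detector curves are model-based approximations of measured responses;
  correction-factor tables are therefore expected to match published
  magna-field values in pattern and magnitude class, not cell-by-cell.
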