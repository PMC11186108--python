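# Methods

`rptdose` is a desk-scale, fully synthetic re-enactment of an end-to-end
validation of image-based radiopharmaceutical therapy (RPT) dosimetry: a
digital Jaszczak-style phantom holding an I-131 source sphere and six
TLD-carrying probes is imaged by a surrogate SPECT/CT model, the image is
quantified with a calibration factor and a recovery coefficient, a voxel
Monte Carlo engine computes absorbed dose from both the quantified image and
the exact stylized geometry, and a TLD measurement model reduces synthetic
chip readings to measured doses that are compared probe by probe against the
image-based result under an explicit uncertainty budget.

## Phantom and coordinate conventions

World coordinates are right-handed, in mm, with grids addressed at voxel
centers (the world position of index (0,0,0) is the grid origin).  The
phantom is a water cylinder (default 6.4 L; radius 108 mm, the standard
flangeless Jaszczak, height solved from the volume) whose axis is z.  The
source is a 16 ml sphere, radius r = (3V/4π)^(1/3) = 15.63 mm, centered at
the origin by default, holding all activity at uniform concentration
(748 MBq administered / 16 ml = 46.7 MBq/ml at reference time).  Each probe
is one vertical acrylic cylinder (12.7 mm diameter; post and cap merged)
reaching from the cylinder floor to just above its scoring point; o-rings,
studs and threads are sub-voxel and ignored.  The six default scorer
positions sit 29.7–87.7 mm from the sphere center, staggered so the photon
dose spans roughly a 10× range; positions are plain configuration because
no authoritative coordinates exist — all downstream code treats them as
data.

Voxelization samples `subsamples³` points per voxel: materials by majority
vote, activity by the in-source point fraction, renormalized so the
voxelized total equals the nominal activity exactly at every grid spacing.

## Decay bookkeeping

Activities are Bq and times days at every interface; the single day→second
conversion happens inside the cumulated-activity integral

    Ã = (A_admin/λ)(1 − e^(−λ t_exposed)),  λ = ln2 / 8.0197 d,

which for 748 MBq over 16.87 d gives 5.737×10¹⁴ Bq·s.  Absolute dose is
D = Ã × D_history with D_history the Monte Carlo dose per decay.  I-131
emission data (photon lines 80.2–722.9 keV with yields, per-decay mean beta
energy 191.6 keV) ship as a CSV compiled from published decay-data
evaluations and are overridable; daughter buildup and resolved
internal-conversion spectra are out of scope.

## Synthetic SPECT/CT

Projection, OSEM reconstruction, collimator-detector-response modeling and
triple-energy-window scatter correction are replaced by an image-domain
surrogate: resample truth to the 128³ × 4.42 mm SPECT grid, convolve with an
isotropic Gaussian PSF (default FWHM 12 mm, representative of high-energy
general-purpose collimation at 364 keV; configurable), scale by
sensitivity × scan duration (defaults 1×10⁻⁵ counts per Bq·s and 3600 s,
i.e. 120 projections × 30 s), and Poisson-sample.  The surrogate reproduces
what the quantification chain must correct — partial volume, count
calibration, noise — but not reconstruction artifacts: Gibbs ringing is a
documented non-feature.  Absolute counts are therefore never a validation
quantity.  The CT model maps material density to a CT-number scale
(piecewise linear, 0.001 g/cm³ → −1000, water → 0, slope 1000 per g/cm³
above water) on the fine grid; quantification inverts it exactly and
classifies density into air/water/acrylic by thresholds (0.05 and
1.10 g/cm³).

The CT and dose grids are unified at 247 × 253 × 52 voxels of
0.977 × 0.977 × 5.00 mm — carrying one fine grid avoids a second resample.

## Quantification

* Calibration factor: total true activity / total counts of a uniformly
  filled 5.64 L cylinder scan — unbiased for a uniform source.
* Background zeroing: all voxels outside the sphere VOI set to zero; the
  removed fraction is reported.  The VOI is the *analytic* sphere boundary
  rasterized center-inside on the working grid: using truth instead of an
  image segmentation isolates the quantification arithmetic from
  segmentation error (deliberate simplification).
* Recovery coefficient: measured noise-free on the same scanner model as
  the ratio of blurred to unblurred VOI means of a digitized sphere, so it
  isolates PSF spill-out — RC = 1 exactly at zero PSF and decreases
  monotonically with PSF width.  It is applied as a uniform in-VOI rescale;
  a volume-averaged correction cannot be applied voxel by voxel.
* Percent differences use 100·(A − reference)/reference with the reference
  the decay-corrected administered concentration at scan time.
* Resampling to the dose grid interpolates concentration (intensive),
  then recomputes per-voxel Bq; the change in VOI mean is reported as a
  diagnostic.

Center-inside rasterization at 4.42 mm underestimates the sphere volume
(≈13.8 vs 16 ml), so the sphere *activity* estimate used for the image-mode
cumulated activity is corrected mean concentration × the known 16 ml sphere
volume — the quantity the chain actually measures — while the resampled map
supplies only the spatial sampling distribution (the per-history dose is
normalized per decay, so only the distribution matters).  The residual
quantification bias at default conditions is the center-inside VOI
digitization, about −3% on the corrected mean.

## Monte Carlo dose engine

Analog photon transport on the material grid with Woodcock (delta) tracking
against the energy-dependent majorant attenuation.  Cross sections
(10–800 keV, log-spaced) are computed from elemental composition:
incoherent scattering from the analytic Klein–Nishina free-electron cross
section × electron density, photoelectric absorption from a parametric
Z^4.5/E³ fit anchored to water at 30 keV.  Coherent scattering,
characteristic x rays and bremsstrahlung are omitted — few-percent effects
in low-Z media at 80–723 keV, inside the validation envelope — and the
free-electron approximation slightly overestimates incoherent scattering
below ~100 keV.  At real collisions, photoelectric events deposit the full
photon energy locally; Compton scattering samples Kahn's rejection method
for the Klein–Nishina distribution, deposits the electron energy locally
and continues the photon; photons end below the 10 keV cutoff (deposited)
or on grid exit (escaped), so deposited + escaped = emitted exactly in
every batch — an identity the tests assert.

One history is one decay; each draws one photon from the emission lines
with statistical weight equal to the total photon yield (0.995/decay).
Betas are deposited as their expected value — per-decay mean beta energy
apportioned over source voxels by activity — because the I-131 beta range
in water (≲2.3 mm at the spectral endpoint) is below the grid spacing:
local deposition has no stochastic transport, so the expected-value tally
is exact with zero variance.  Probe doses are consequently
photon-dominated, as intended for probes outside the source.

Scoring is threefold:

* per-voxel analog dose (deposited energy / voxel mass), Gy per history,
  with batch-statistics uncertainties (default 10 batches; independent
  per-batch RNG streams spawned from the run seed);
* track-length fluence spectra in the 5 mm cubic scorer at each probe
  (5 keV bins, 0–730 keV), every Woodcock step segment crediting its chord
  length at the photon's current energy; the fluence-weighted mean energy
  feeds the TLD beam-quality correction;
* the scorer (probe) dose via the collision-kerma track-length estimator,
  Σ Φ(E)·E·μ_tr/ρ(E) with μ_tr/ρ from the same tables (Klein–Nishina mean
  energy-transfer fraction + photoelectric).  This low-variance estimator
  is used for probe doses because analog deposition in a 5 mm cube up to
  9 cm from the source would need ~10⁸ histories for comparable precision;
  it is exact under charged-particle equilibrium, which holds for a small
  low-Z scorer in a photon field at these energies.

Default workload: 8×10⁶ histories (image mode) and 12×10⁶ (idealized mode)
in 10 batches, sized so every probe's statistical precision stays below the
targeted bounds (3.8% image mode, 2.3% idealized) with margin; this is the
scaled-down stand-in for the reference workload of 10⁶ decays per source
voxel, and full fidelity is a configuration change.

## TLD measurement model

Synthetic chip signals are dose × reader gain × relative energy response,
with 3% multiplicative chip-to-chip repeatability (4 chips per probe).
Calibration chips are exposed at the 111 keV calibration beam quality to
doses 0.25–4 Gy and fitted linearly (dose = a·signal + b); the residual
standard deviation is a budget component.  The beam-quality correction
interpolates the relative response linearly in log energy between anchors
and multiplies the calibrated dose by response(calibration beam) /
response(probe spectrum mean energy), the mean energy coming from the
idealized-mode fluence tally.  The bundled response curve is synthetic
(anchors bounded by the documented ~40% LiF:Mg,Ti low-energy over-response,
normalized to 662 keV) and overridable; no validation quantity depends on
it because the same curve generates and reduces the readings.  No fading
correction is applied.  Readings deviating more than 6% from the group
mean are flagged but retained in all statistics.

The uncertainty budget combines components in quadrature, k·√(Σcᵢ²), with
default components {4.4, 0.6, 2.0, 4.0}% at k = 1 (handling+calibration,
energy-correction factors, energy interpolation, setup/modeling) — 6.3%
combined, 12.6% expanded at k = 2 — alongside a stated conservative
adopted envelope of 10% at k = 2, which is what agreement verdicts use by
default; both numbers are always reported.

## Agreement report

Per probe: measured dose (mean of 4 corrected chips, sd% of the mean),
image-mode and idealized-mode doses with their MC precisions, percent
differences 100·(measured − comparator)/measured (measured is the
reference; a comparator above the measurement is negative), and a verdict
|diff| ≤ adopted expanded uncertainty.  Ranges (min, max) of the
differences summarize the run.  The report is a pure function of its
inputs.

## What the synthetic closure does and does not show

Passing tests demonstrate internal consistency of the chain — calibration,
PVC, resampling, transport, integration and TLD reduction compose to
agreement within the budget under the modeled physics.  They do not test
reconstruction artifacts, scatter/attenuation correction errors, dead time,
segmentation error, real TLD energy response or probe positioning — the
synthetic scanner has none of these.  Reported probe doses and mean
energies depend on the configured probe coordinates and PSF and are
self-consistent quantities, not external reference values.

## Numerical choices and degenerate inputs

Trilinear resampling clamps nothing and zero-fills outside the source
support; CT-derived densities are clamped to [0.001, 3] g/cm³ with a
warning.  Cross-section lookups interpolate linearly in log energy on a
512-point grid and clamp to the table range with the engine warning
at emission time only through validation (emission lines must sit inside
the spectrum bins).  An empty VOI, zero total counts, a zero-activity
source, a rank-deficient calibration fit and non-overlapping grids raise
explicit errors.  Ties in the majority vote resolve to the lowest material
code (deterministic).  All stochastic stages draw from
seed-sequence-spawned generators keyed to the single run seed; identical
configurations reproduce bit-identical outputs.

## Known limitations

Image formation is an image-domain surrogate (no projections, no Gibbs
ringing); photon physics omits coherent scattering and binding corrections;
electron transport is local deposition only, so the engine is not suitable
for dose gradients at sub-voxel scales or for scorers inside the source;
the TLD response curve is synthetic; probe geometry is configuration, not
reconstruction of any physical setup.
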