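# Methods

`coloct` re-implements, as a tested end-to-end pipeline, the computational
chain behind a forward-looking MEMS-scanned swept-source OCT probe for
colorectal lesion assessment: digital tissue phantoms, fringe simulation,
A-scan/B-scan reconstruction, multi-lane mosaicking with self-calibration,
contrast enhancement, quantitative lesion features, and cohort descriptive
statistics.  No raw scans from the physical device are publicly available,
so a synthetic-data generator with full ground truth stands in for the ex
vivo tissue; everything downstream of the generator is the same code a real
dataset would run through.

## Signal model

A swept-source A-scan records the spectral interference fringe

    f(k) = S(k) · Re Σ_i A_i exp(i 2 k z_i) + n(k)

with `S(k)` the Gaussian source amplitude envelope (centre wavelength
λ₀ = 1060 nm, FWHM bandwidth Δλ), `z_i` the optical path from the probe
apex to scatterer *i* and `A_i` its complex amplitude.  Under the
single-scatter Beer–Lambert model, |A_i| ∝ √(backscatter·ds) ·
exp(−∫ μ_s ds), so reconstructed intensity decays as exp(−2 μ_s z) — the
relation the attenuation-coefficient estimator inverts (μ̂ = −slope/2 of
ln I vs z).

The depth profile is the magnitude of the inverse DFT of the DC-subtracted,
apodized fringe; with N uniform k-samples spaced δk the axial pixel pitch is
π/(N·δk), divided by the assumed group index.  For a Gaussian source the
axial PSF FWHM is δz = (2 ln 2/π)·λ₀²/Δλ; the probe's stated 6 µm axial
resolution at 1060 nm fixes Δλ = 82.6 nm, which the package adopts as the
source default.  The sweep is linear in wavelength by default (realistic
swept-laser behaviour and deliberately non-uniform in k, so the
k-resampling step is genuinely exercised); a `linear_k` mode exists for
closed-form work.

Two scatterer models are provided.  With speckle on (default), scatterers
sit at fixed path steps (10 per coherence length by default) and their
phasors come from a counter-based hash of the *spatial cell* they occupy,
keyed to the phantom seed.  This makes the speckle a property of the
tissue, not of the beam: two scan lanes crossing the same voxel see the
same scatterers, which is precisely what makes overlap-based
self-calibration possible, and summing many independent circular-Gaussian
phasors per resolution cell yields exactly exponential intensity statistics
(fully developed speckle).  With speckle off, only layer interfaces carry
(specular) reflectors — a deterministic model used for closed-form
Beer–Lambert tests.

## Phantoms

A phantom is a layered volume — epithelium, the thin bright lamina
propria/muscularis mucosae (LP/MM) band, submucosa with ellipsoidal vessel
lumens — described by continuous per-(x, y) interface depth maps plus a
voxel label grid.  No measured tissue optical coefficients are available for this probe and
tissue combination, so the defaults are placeholders calibrated to the one
quantitative anchor available, an imaging depth of about 1 mm: epithelium μ_s = 1.5 /mm,
LP/MM 4 /mm, submucosa 2 /mm, vessel lumen 0.3 /mm, detector noise at
25 dB fringe SNR.  The LP/MM backscatter is set 6× the epithelium's so the
band reads as the clearly hyperreflective layer it is clinically, even over
a moderately hyperreflective epithelium.  All depths are optical path
divided by a single group index (1.38); the coupling medium above the
tissue is treated as index-matched fluid (the probe is designed for
fluid-filled organs), so geometric depth is optical/1.38 everywhere.

Backscatter is modulated by two deterministic position-hashed fields:
smooth multi-scale heterogeneity (±60%, octaves from 80 µm) and dark
crypt/gland-like micro-voids (50 µm cells, ~15% volume fraction, 85%
backscatter drop).  These emulate the macroscopic texture of real mucosa;
their sharp, beam-independent structure is what the mosaicking
self-calibration locks onto (pencil-beam speckle decorrelates between lanes
that cross a region at different fan angles, so texture, voids and vessels
carry essentially all of the cross-lane alignment signal).

Polyp variants thicken the mucosa, optionally efface the LP/MM band
(merging it into the mucosa), raise epithelial backscatter by a gain
factor, and add band-limited surface roughness.  Roughness is a seeded
0.3 mm-wavelength sinusoid (direction within 30° of the lane axis) rather
than broadband noise: its local RMS is laterally uniform, so every imaged
patch of an "irregular" lesion actually carries the nominal roughness.
Ground-truth lesion flags (`effaced`, `hyperreflective`,
`irregular_surface`) record the construction.

## Scan geometry and mosaicking

The MEMS mirror fans the beam across a 20° sector inside the slice plane
(the y–z plane at the stage x position); the stage steps 0.1 mm along x and
jumps 0.3 mm between parallel lanes along y.  `mounting_angle` is modelled
as an in-plane rotation of the whole fan about the probe axis.  (A
tilt of the B-scan plane out of the slice plane was considered instead, but
with 0.1 mm step quantization a 2° tilt displaces sampling by under ~25 µm —
far below the step pitch — making that parameter unrecoverable from overlap
quality; the in-plane rotation matches the "mounting in the stage"
variability being corrected and keeps projection two-dimensional.)

Scan conversion maps sector pixels (r = depth from the zero-delay at the
apex, θ = fan angle through the *assumed* intrinsics) onto a Cartesian grid
by bilinear interpolation; radii under 0.1 mm (zero-delay artifact region)
and angles outside the sector are invalid, never extrapolated.  Slices
composite overlapping lanes by the nearest-slice rule — each pixel takes
the value of the B-scan whose apex is laterally closest, ties to the lower
lane index, no averaging (averaging would make the overlap's noise
statistics visibly differ from the rest of the image); per-pixel provenance
records the chosen lane.  Plain averaging remains available behind a flag
for comparison only.

Self-calibration maximizes the mean normalized cross-correlation of
band-passed log intensities over the overlap regions of adjacent lanes,
sampled over up to 15 slices: a 3-px blur averages uncorrelated speckle
down, a broad mask-aware high-pass (25 px) removes the depth-decay profile
that would correlate even when misaligned, and a 4-px erosion of the sector
masks keeps filter residue along the mask edges from biasing the optimum.
The optimizer is deterministic and derivative-free: a 0.5° coarse grid over
the bounds followed by golden-section refinement, coordinate-wise, two
passes.  On two-lane phantoms this recovers a 3° field-of-view perturbation
and a 2° mounting rotation to within ±0.5°.

Contrast enhancement is "equal normalization" — percentiles (default 1/99)
computed once over the pooled valid pixels of *all* slices of a sample
define a single linear window — followed by gamma correction (default 0.7).

## Feature operators

All operators work on the dB view (20·log₁₀ amplitude) of a Cartesian
image.  The verbal clinical criteria become explicit, config-exposed
operators; every threshold below is a package choice, not a validated
clinical cut-off.

- **Surface**: per column, the first crossing of (noise floor + 6 dB) by the
  axially smoothed profile, where the noise floor is mean + 2 SD of the
  deepest 10% of pixels.  A crossing counts only if a clear run of
  background lies above it and the signal below is sustained and strong;
  grazing cuts along the sector edge (the cone apex sits close to the
  surface, so outer columns clip into tissue) are rejected, and only
  dominant smooth runs of columns are kept.
- **Layer segmentation**: the LP/MM band is found globally on the
  surface-flattened mean profile — a quadratic baseline (refit with the
  candidate excluded) absorbs the attenuation decay, a genuine band must
  stand ≥ 4 dB proud of it, and most columns must place their own brightest
  point at the same depth below the surface (depth consistency ≥ 60%),
  which scattered texture cannot do.  Columns then confirm the band locally
  (≥ 1.5 dB over the decay-compensated submucosal level below it).  Without
  a band, the mucosa/submucosa split comes from a broken-stick (two-segment
  linear) fit of the mean depth profile, which picks up the attenuation
  and/or brightness change at the boundary.
- **Effacement**: band found in < 30% of surfaced columns (strict).
- **Hyperreflectivity** (with compensation on): a backscatter-level
  comparison.  The epithelium's decay line is fitted on the column-median
  flattened profile (medians resist the void/vessel minority); its intercept
  at the surface is compared with the submucosal level extrapolated to the
  submucosa's top, corrected for transmission through the mucosa using the
  epithelium's own slope.  In the single-scatter model this difference is
  exactly the backscatter step, independent of the attenuation coefficients.
  The band's extra transmission loss — observable as its own internal decay,
  aligned per column by each column's band top — is subtracted when a band
  is present.  Flag at > 3 dB.  With compensation off the ratio is the raw
  regional mean difference (what an uncompensated visual comparison sees).
- **Surface irregularity**: an image is non-smooth when the RMS residual of
  its surface profile about a 2nd-order polynomial fit exceeds 30 µm; the
  lesion is irregular when at least 50% of its images are non-smooth
  (inclusive, per the clinical rule).
- **Imaging depth**: median over columns of (deepest crossing of noise
  floor + 3 dB) − surface depth.
- **Attenuation coefficient**: μ̂ = −slope/2 of ln intensity vs depth over a
  configurable window, reported with R²; intended for averaged A-scans
  (≥ ~100 to tame speckle).

`analyze_sample` crops each image to its surfaced wedge, aggregates
per-image measurements by median, and emits a `FeatureReport`.

## Problem sizes and numerical choices

Full-fidelity single-fringe work uses 2048 samples spanning 2.5× the FWHM
bandwidth (2.7 µm axial pitch in air).  Multi-lane scan simulation uses a
desk-scale preset: 768 samples spanning 1.25× FWHM (≈ 3.9 µm geometric
pitch at n = 1.38, 1.5 mm range), 48 A-scans per B-scan, scatterer density
5 per coherence length, working distance 0.3 mm (deep lane overlap for
calibration) or 1.2 mm with 1408 samples for feature work (wide surface
wedge).  Spectral truncation at 1.25× FWHM costs a little axial resolution,
which mosaicking and feature extraction tolerate.  Hann apodization is the
default window (configurable; PSF measurements use none); DC is removed by
per-fringe mean subtraction; resampling uses cubic splines; interpolation in
images is bilinear with NaN propagation, never extrapolation.

The lesion-flag factorial (effaced × hyperreflective × irregular) uses
two-lane, five-step scans per cell; the non-effaced cells carry a 0.5 mm
mucosa (0.4 epithelium + 0.1 band), the effaced cells 0.6 mm (a thick
effaced mucosa pushes the submucosa below the noise floor, which is
physically why invasion depth cannot be assessed in such lesions — the
imaging-depth measurement demonstrates that regime instead).
Hyperreflective cells use gain 2 when the band is present (a much brighter
epithelium would bury the band's contrast, which is a real, not numerical,
ambiguity) and gain 3 when effaced.

## What the generator does and does not emulate

It emulates: layered wall optics with realistic relative backscatter,
speckle with exact exponential statistics shared between crossing beams,
Beer–Lambert depth attenuation, macroscopic tissue texture, sector-beam
geometry with lane-based stage motion, wavelength-linear sweep
nonlinearity, and additive detector noise.  It does not emulate: beam
lateral width (a pencil-ray model; the 30 µm lateral resolution enters only
through geometry, so lateral speckle statistics are not those of a finite
beam), refraction at interfaces, dispersion, multiple scattering,
polarization, confocal gating, motion artifacts, or absorption separate
from scattering.  Passing tests therefore show that the *processing chain*
recovers what this forward model encodes, not that the features are
clinically validated on real tissue.

## Known limitations

- Tissue optical coefficients are plausibility-calibrated placeholders, not
  literature-fitted values.
- The hyperreflectivity ratio is one operationalization of a criterion that
  clinical readers themselves apply subjectively; its band-loss correction assumes the
  single-scatter model.
- Mounting-angle recovery relies on sub-resolution axial alignment of
  texture; its identifiability is weaker than the field of view's, and the
  ±0.5° tolerance is near the limit of what a two-lane overlap supports.
- The glandular-structures reading criterion is not implemented: no
  operational definition exists for it and the phantoms do not model
  glandular architecture.
- Diagnostic classification (polyp type, dysplasia grade) is explicitly out
  of scope.
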