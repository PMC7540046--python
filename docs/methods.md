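# Methods

`holopipe` quantifies marine particle size and concentration from
point-source digital inline holographic microscope (DIHM) recordings. This
note describes the forward model behind the built-in simulator, the
reconstruction and detection procedure, the two instrument corrections, the
statistics, the numerical choices, and what the synthetic validation does
and does not demonstrate.

## Instrument model and coordinates

A laser (wavelength λ = 0.386 µm) behind a sub-micron pinhole emits a
diverging spherical wave. Particles at distance z from the source, inside
the cone between source and camera (source–camera distance L = 100,000 µm),
cast diffraction patterns magnified by M(z) = L/z onto a 2056 × 2060 sensor
with 7.4 µm pixels. Distances are micrometres from the source, +z toward
the camera. Refocusing is performed over the 18 mm viewable focal depth,
positioned at z ∈ [1,000, 19,000] µm by default.

The sampled volume is modelled as a conical frustum ("beam boundary") with
near/far radii r2, r1. The default boundary is an *effective detection
envelope*, not the geometric light cone: detected-particle clouds are far
narrower than the illumination (the fitted radial detection width is only
466 µm), so the default frustum tapers gently (r1/r2 = 1.3) and is scaled
so its geometric volume equals the instrument's calibrated working volume
of 0.063 mL. A second preset carries the 0.1 mL nominal per-image volume
quoted for this instrument class; volume bookkeeping reports the override
(0.063 mL by default) in preference to the raw frustum volume.

## Forward model (simulator)

Opaque particles are modelled as amplitude masks (disks or ESD-preserving
ellipses). The point-source geometry is reduced to an equivalent collimated
problem by the Fresnel scaling theorem: a particle at z behaves like its
M(z)-times magnified silhouette propagated over D(z) = L(L−z)/z in
collimated light, sampled directly on the sensor grid. Each particle's
scattered field is propagated independently with the band-limited
angular-spectrum method and superposed on the unit reference (Babinet's
principle), which is accurate for the sparse scenes simulated here; the
renderer agrees with a direct Rayleigh–Sommerfeld quadrature oracle to
below 2% relative RMS on a central crop. Sensor noise is additive Gaussian
on the normalized intensity (default sd 0.01, clipped at zero); real
sensors add structured fixed-pattern and shot noise that this does not
emulate.

Particle populations follow the study conditions: positions uniform per
unit volume in the frustum (inverse-CDF sampling of the cross-section),
diameters from a truncated power law (Junge-type spectrum; slope −4 over
10–120 µm for the surface-ocean case), and optional Bernoulli thinning by
the detection-probability model below. Every sampler takes an explicit
seed; no global random state is used.

## Reconstruction

Frames are background-corrected with the pixel-wise median of up to three
preceding and three following frames (the frame itself excluded); division
by the median is the default, subtraction is available. This removes
stationary patterns such as debris stuck to instrument windows: the stuck
pattern's refocused peak contrast drops well below the detection floor. A
frame with fewer than three neighbours passes through unchanged with a
warning.

Refocusing normalizes the hologram by its median, removes the unit
reference, and back-propagates the residual contrast over D(z) with the
band-limited angular spectrum method (evanescent waves removed; the band
further limited so the transfer-function phase stays below the Nyquist rate
of the frequency grid, which suppresses FFT wrap-around). The focal-plane
image is the **contrast magnitude** |U_back|: ≈ 0 in clear water, ≈ 1 over
an in-focus opaque particle.

The contrast-magnitude convention matters. At this geometry's Fresnel
numbers the sensor lies in the far field of mid-depth particles, and the
relative phase between reference and refocused image rotates quickly with
defocus; an amplitude image that re-adds the reference (dark-silhouette
convention) flips between dark and bright interiors within a single 250 µm
z-step and is useless for thresholding. The modulus is insensitive to that
phase and degrades smoothly with defocus.

## Detection

1. **Sharpness.** Tenengrad score per pixel (squared Sobel gradient of the
   contrast amplitude, smoothed with a 3 px Gaussian), computed for every
   plane of the stack; the per-pixel maximum over planes and its plane are
   kept, along with the per-pixel maximum contrast. Ties break toward
   smaller z everywhere, so the chain is deterministic.
2. **Segmentation.** A pixel is foreground-eligible when its implied
   transmission falls below the instrument threshold 0.95 of the local
   background (peak contrast > 0.05 × background) *and* its sharpness
   reaches the segmentation floor (0.02). Connected foreground is split by
   a marker watershed whose markers are contrast cores (> 0.45 ×
   background): fringe-halo-only components carry no core and are dropped,
   and overlapping halos of neighbouring particles are divided between
   their cores. Components below 4 px are discarded. An optional
   local-adaptive background level (Gaussian-smoothed) is off by default.
3. **Focus refinement.** Per segment, the plane maximizing the summed
   sharpness over the segment's pixels.
4. **Contour extraction.** At the focus plane, after a 3×3 unsharp mask
   (strength 0.5), a seeded random-walker segmentation is run: sure
   foreground is the eroded half-level core around the segment's brightest
   pixel, sure background lies outside its dilation. The result is reduced
   to one hole-filled connected component; pixel area is converted to
   object-plane µm² through M², and ESD = 2√(area/π). The per-detection
   record keeps the region sharpness and the in-focus peak contrast.
5. **Deduplication and artifact removal.** Overlapping contours
   (centroid distance below 60% of summed radii or 1.8× the larger radius)
   keep only the sharpest member; detections are then filtered by a region
   sharpness floor (0.07) and a peak-contrast floor (0.7). The two floors
   and the contrast criterion were calibrated on labelled synthetic scenes,
   where true in-focus particles reach peak contrast ≥ 0.96 while defocused
   fringe ghosts stay below ≈ 0.6.

Validated operating regime: 20–60 µm particles, 2–4 per 512 px sensor crop
with sensor-plane separations ≥ 110 px, z in the central 12–18 mm band,
noise sd 0.01. There recall is ≥ 90%, particle-free frames yield no
detections, and raw ESD is biased about −5% with ≈ 2% scatter. Above
~70 µm the twin-image term of inline holography (which this package, by
design, does not suppress) increasingly corrupts contours; very dense
scenes merge. Real data add polydisperse shapes, phase objects, flow and
illumination drift that the simulator does not emulate, so passing tests
demonstrate the machinery, not field accuracy.

## Size correction

Reconstructed contour sizes carry an instrument-specific distance
dependence, calibrated against spheres of known diameter as

    S_corr = a · S_m · D_m^b        (sizes and distances in mm)

with reference coefficients a = 0.121, b = 0.76. `fit_size_calibration`
recovers (a, b) by ordinary least squares of log(S_true/S_m) on log D_m and
requires at least two distinct distances. The simulated instrument itself
has nearly distance-free sizing, so self-calibration returns b ≈ 0 and
a ≈ 1.05 — the fitted law then simply absorbs the mean contouring bias.
The exponent bound accepts −2 < b < 2 with an informational log when
b ≤ 0.

## Concentration correction

Detection probability is nonuniform: a separable Gaussian

    C(x, y, z) = exp(−½[(r/g_r)² + ((z − z_o)/g_z)²]),  r = √(x² + y²)

with reference coefficients z_o = 8,000 µm, g_r = 466 µm, g_z = 6,400 µm.
Each artifact-filtered detection is weighted by the integer replication
factor m = clamp(⌊1/C⌋, 1, 8) — one original plus at most seven replicas —
which rescales counts by position while leaving the shape of the size
distribution untouched (thinning is size-independent). The alternative
reading of the replication rule (⌊1/C⌋ *added* copies) is available behind
`added_replicas=True`.

Because the weight is rounded *down*, the estimator is conservative:
E[C·⌊1/C⌋] < 1 except at exact reciprocal integers. Monte Carlo over the
default frustum gives corrected/true ≈ 0.82 restricted to the clamp-valid
region C ≥ 1/8 (≈ 0.74 overall, where the clamp adds further loss). A
round-trip test asserting recovery within ±15% therefore fails, and is left
failing deliberately: the rounding rule is part of the published procedure,
and an unbiased variant (e.g. stochastic rounding) would no longer be the
same estimator.

**Fitting the model from data.** `fit_detection_model` fits an isotropic 2D
Gaussian to the depth-collapsed XY histogram (bin width 50 µm) and a 1D
Gaussian to the z histogram (bin width 500 µm). Raw histograms of detected
positions confound detection probability with sampling geometry (the
frustum cross-section grows as R(z)², and the beam truncates the radial
Gaussian at ≈ 2σ), biasing the fitted axial peak by 10–20%. When the beam
boundary is supplied, each histogram is therefore normalized by the count
expected from a *uniform* particle field in that geometry — column depth
for XY bins, detection-weighted cross-section for z bins — and since each
marginal's baseline depends on the other marginal's parameters, one
refinement pass alternates the two fits. With this estimator the reference
coefficients are recovered from 2×10⁵ thinned positions to well within 2%.
Structureless (uniform) inputs produce widths exceeding the beam dimensions
and a logged warning.

## Statistics

- **Size spectra.** Half-open bins; linear mode uses 3 µm bins with first
  centre 3.5 µm (instrument-resolution limited), log mode uses 12
  geometric bins over 10–120 µm (environmental samples). Size-specific
  concentration = replication-weighted count / (volume × bin width),
  particles (mL·µm)⁻¹. Geometric bin centres are used in log mode, which
  makes the binned spectrum of an exact power law exactly log-log linear
  (binning bias moves into the intercept only).
- **Spectral slope.** Model I (OLS) fit of log₁₀ ssc on log₁₀ centre,
  empty bins excluded, ≥ 3 occupied bins required.
- **Overall concentration.** Weighted count divided by (number of holograms
  × per-hologram volume).
- **Model II regression.** Geometric-mean (reduced major axis):
  slope = sign(corr)·sd(y)/sd(x), intercept through the means, r² = corr².
  Chosen over major-axis regression as the common limnology/oceanography
  default; selectable in principle by computing on transformed axes.
- **Through-origin log-log fit.** y = x·10^m with m = mean(log₁₀ y/x);
  r² is computed against the constrained model's residuals relative to the
  variance of log₁₀ y.
- **Mean difference.** mean and sd (ddof = 1) of 100·(a − b)/a; zero
  reference values are excluded with a logged count. The statistic is not
  antisymmetric under swapping instruments (the normalizer changes).

## Numerical and design choices

- Band-limited angular spectrum: unitary on the propagating, non-aliased
  band; a pre-filtered field round-trips to machine precision and plane
  energy matches the band-limited hologram contrast energy within 1%.
- Anti-aliased (1 px soft edge) silhouettes in the renderer.
- Bin membership is half-open [low, high); argmax ties break to smaller z.
- Detection tables travel as CSV (frame, x_um, y_um, z_um, area_um2,
  esd_raw_um, esd_corrected_um, sharpness, multiplicity); configuration is
  strict-schema YAML (unknown keys rejected); each pipeline run writes a
  manifest with input hashes, a config snapshot and per-stage counts.
- Stage order is fixed: background → refocus → detect → artifact-filter →
  size-correct → concentration-correct → statistics; concentration scaling
  never precedes artifact removal.
- Sensor crops: validation scenes use 512×512 crops. Smaller (256 px) crops
  truncate the fringe field enough to degrade focus scoring for mid-depth
  particles and are used only where focus accuracy is not at stake.
- Problem sizes in the shipped validation: detection-model recovery uses
  2×10⁵ accepted positions; spectral-slope recovery 10⁵ diameters; the
  end-to-end sizing run uses 18 + 18 frames (3–5 spheres each) in the
  acceptance script and 10 + 10 frames in the test suite.

## Known limitations

- No twin-image suppression or phase retrieval: sizing fidelity degrades
  above ~70 µm and for crowded fields (by design out of scope).
- The floor-based replication weighting under-corrects concentration by
  ~20% (see above); comparisons between similarly processed samples are
  unaffected, absolute concentrations are conservative.
- The renderer assumes opaque, sparse, motion-free particles in uniform
  illumination; the Gaussian detection-probability model is the only place
  nonuniform illumination enters.
- Background division assumes a quasi-static background over a 7-frame
  window.
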