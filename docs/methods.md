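# Methods

`holokit` models a lens-less digital inline holographic microscope (DIHM): a
point-like source (a fibre-coupled 405 nm laser diode, or a 430 nm LED behind
a 15 µm pinhole) at distance *f* from a bare CMOS detector, with the sample on
a glass plate at object–detector distance *s*. The scattered and unscattered
waves interfere on the detector; the recorded intensity (the hologram) is
numerically refocused to recover the object. This note records the model, its
assumptions, the defaults, and the numerical choices.

## Forward model

Light is treated as a scalar field. A sample plane is a complex transmission
map t(x, y):

* **opaque disk** — amplitude transmittance `a` inside radius `r`, 1 outside
  (polystyrene-microsphere-like; `a = 0` by default);
* **phase sphere** — projected-thickness phase
  `exp(i k Δn · 2 √(r² − ρ²))` with uniform index contrast Δn
  (red-blood-cell-like; transparent by default);
* **bar target** — five dark bars of one line width, gaps one width, bar
  length five widths, in either orientation (USAF-1951-style).

Disk and bar edges are rendered with fractional pixel coverage so sub-pixel
size differences survive discretisation.

Multi-plane scenes are imaged by a thin-object cascade: multiply by the
plane's transmission, angular-spectrum propagate to the next plane, repeat to
the detector. This assumes weakly scattering, effectively two-dimensional
objects — the regime the instrument is designed for; volumetric scattering
and multiple scattering between planes are not modelled.

Illumination is a paraxial spherical wave (amplitude 1/d, phase
k(d + ρ²/2d), d the source–plane distance) or a plane wave. The unscattered
reference is carried analytically and only the compact scattered field is
propagated numerically (`aperture="infinite"`), so the illumination
effectively extends beyond the simulated window; `aperture="finite"`
propagates the truncated full field instead, which is the exact situation
the brute-force oracle computes and is used when validating against it.

**Oracle.** `direct_integral_oracle` evaluates the Fresnel–Kirchhoff double
sum U(X,Y) = −(i/λ) Σ U_in t · exp(ikr)/r · Δx² with exact non-paraxial
distances, on grids up to 64². It is the independent reference for the FFT
path, never a production path. Two discretisation limits matter when
comparing: the sampled spatial kernel is only valid where the local fringe
frequency stays below the grid Nyquist, and a hard-truncated unit aperture
carries Fresnel edge ripple of several percent at every distance where the
sampling is valid — the free-propagation flatness check therefore asserts a
5 % coefficient of variation, not an arbitrary smaller figure.

## Angular-spectrum propagation

`propagate` multiplies the field spectrum by
`H = exp(i z √(k² − 4π²(f_x² + f_y²)))`, zeroing evanescent components
(they decay within nanometres at these distances; zeroing is numerically
safe). Without padding the convolution is circular — exact for periodic
band-limited fields, energy conserving (Parseval), and the mode used for
reconstruction. With `pad=True` the grid is zero-padded (≥ 2× per side, or
`pad_to`) and the kernel is band-limited to
|f| ≤ 1/(λ√((2 Δf z)² + 1)) per axis — the frequencies whose discrete kernel
phase is free of aliasing. Long-distance propagation of compact fields
(hologram formation) needs this: the retained band must cover the content of
interest, so the pad size is chosen per study (e.g. 512 for the 64² oracle
comparison at s = 5.91 mm, where the agreement is then ≈ 0.04 % RMS; 1152
for the 768² bar-target studies, covering fringe frequencies to ≈ 2.5·10⁵
cycles/m).

## Reconstruction

Reconstruction back-propagates by −z. Two modes:

* **contrast** (default, matching the common background-subtracted
  workflow): back-propagate (I − B), shifted to zero mean and scaled to unit
  maximum. Objects appear bright on a dark background.
* **brightfield**: back-propagate the reference-normalised hologram I/B as a
  whole, so the unscattered wave keeps its propagation phase relative to the
  scattered field. Absorbing objects appear dark on a unit bright background.
  The in-line twin image — inherent to this geometry, and deliberately not
  removed — then shifts profile maxima and minima together instead of
  multiplying the object contrast, which is what makes per-element contrast
  values comparable across element sizes. (Adding the unscattered wave back
  *after* back-propagation is wrong by the reference's own phase e^{−ikz}
  and produces contrast inversions; the normalised hologram must travel
  whole.)

Point-source magnification is handled by the plane-wave equivalence
M = f/(f−z), z_eff = z(f−z)/f with the pixel pitch divided by M
(`use_effective_geometry=True`); the returned images are then sampled at p/M
in object-plane coordinates. Default off, matching plain plane-wave
refocusing at the nominal distance.

**Autofocus** does a coarse grid search followed by golden-section
refinement. The coarse pass scores the normalized variance (variance/mean²)
of the reconstructed *intensity*: its fourth-moment weighting keeps the
focused spot ahead of the residual fringe field, whose amplitude variance
otherwise grows monotonically toward z → 0 on large grids. The refinement
scores the *amplitude*, whose variance peaks at the geometric plane; the
intensity metric shows side peaks offset by about one axial resolution for
absorbing disks. Both are exposed through `focus_metric` (normalized
variance; scale-invariant, zero for a constant image, replaceable by Tamura
or gradient-energy scores behind the same contract). Known limitation: for
weak phase objects at high recording NA (short object distances) the
amplitude-sharpness optimum sits 1.5–3 axial-resolution units off the
geometric plane (defocus phase contrast); the recovery fixture keeps its
phase spheres at z ≥ 2 mm where the bias is negligible.

## Partial coherence

A finite bandwidth and a finite source are modelled by incoherent averaging
of coherent intensity holograms: Gauss–Hermite nodes (7 by default) sample a
Gaussian spectral line of FWHM Δλ, and a Vogel-spiral set of points (13 by
default) samples the source disk uniformly; each source point displaces the
point source, or equivalently tilts the plane wave by offset/f, which
reproduces the object-plane blur s·D/f of a source of diameter D. With one
node, one point and zero width/diameter the result is bit-identical to the
coherent hologram. The defaults keep an LED bar-target study (11 elements ×
91 components at 768²) within a few minutes on one core.

What this model does and does not capture: it reproduces the fringe-count
reduction, the visibility loss with source size, and the chromatic
refocusing blur (reconstruction at the centre wavelength of a broadband
hologram defocuses the spectral wings by z·Δλ/λ, the dominant resolution
limit of the LED arm at these parameters, including contrast-reversal
side-structure inside wide bars). It does not model detector quantum
efficiency, Bayer mosaics, read noise (shot noise and quantization are
available separately via `NoiseModel`), source speckle, or mechanical drift
— so passing the synthetic studies bounds the *computational* pipeline, not
every hardware effect in a physical instrument.

## Bar-target contrast analysis

Within each element's region of interest the image is averaged along the bar
axis; alternating extrema of the (smoothed) profile are located and each
consecutive (maximum, minimum) pair gives K = (I_max − I_min)/(I_max +
I_min). Five bars ⇒ five minima and four interior maxima ⇒ exactly four K
values. An element is *resolvable* when all four values are found in both
orientations and their mean is ≥ 0.05 (a deliberately permissive,
configurable threshold — the visual judgement it replaces is not
standardised); the last resolvable element is the finest one reached before
the first failure, scanning coarse to fine.

Defaults follow the generic procedure: 3-sample moving-average smoothing,
strict alternation (of two same-type neighbours the weaker is dropped), and
a 10⁻⁹-of-range prominence floor so float-level plateau noise never counts
as modulation. The resolution *study* layers three analysis choices on top,
each forced by working with sparse single-element frames from a coherent
chain:

1. **K on the raw bright-field amplitude.** Percentile contrast enhancement
   (`normalize_enhance`, 0.2 % clip by default) is kept for full-field
   images and the CLI pipeline, but a single element covers < 0.2 % of its
   frame and would be clipped flat; per-frame min–max mapping also couples K
   to frame-specific extremes and biases element-to-element comparison.
2. **Gaussian smoothing with σ = w/4** (w the bar width in pixels): the
   attenuation of the bar fundamental is then the same factor
   (exp(−π²/32) ≈ 0.73) for every element — a discrete window whose length
   jumps with w imprints a sawtooth on the K-versus-frequency curve — while
   sub-bar-width structure (edge ringing, broadband double-dip artifacts)
   is suppressed.
3. **Prominence floor 0.25 of the profile range**, rejecting the remaining
   secondary structure as non-modulation.

## Resolution studies (scaled surrogates)

The validation studies run at reduced grid sizes; the per-unit-area optics
(wavelengths, distances, pixel pitch, bandwidth, pinhole diameter) are those
of the reference instruments, only the recorded window is smaller, so the
pixel-limited resolution bound δ = sλ/(Np) is evaluated at the grid actually
used (N = 768: δ_laser = 2.78 µm, δ_LED = 2.95 µm) rather than at the full
2464-pixel sensor.

Design choices of the bar-target study:

* **Plane-wave illumination with tilt-averaged source points.** The bound
  δ = sλ/(Np) comes from the detector-edge NA; with plane waves it applies
  exactly and the generator grid coincides with the reconstruction grid.
  (Under a point source the magnification compensates: NA = Np/2s either
  way; the point-source path is exercised by the recovery suite instead.)
* **One element per frame, centred on its modulation axis.** An element
  displaced along its modulation axis keeps one diffraction sideband beyond
  the nominal cutoff (oblique-illumination asymmetry) and resolves past the
  two-sided bound; displacing each orientation only along its *bar* axis
  (±100 µm) keeps the cutoff symmetric while letting both orientations share
  one simulation.
* **Ladder g6e1–g7e5.** One-plus octave above each arm's expected cutoff.
  Coarser elements are excluded: once the element span approaches the
  in-line twin's Fresnel zone (span² ≳ 2λs, i.e. line widths ≳ 7.7 µm here)
  the defocused twin lands on the element itself and the contrast statistic
  is no longer comparable across sizes.

Measured outcome (deterministic): the coherent laser arm resolves down to
group 7 element 4 (2.76 µm line width, within one USAF step of the 2.78 µm
prediction, as the coherent transfer is flat to its cutoff), the LED arm to
group 6 element 6 (4.38 µm), limited jointly by the 15 µm pinhole blur
(s·D/f ≈ 3 µm) and the chromatic refocusing of the 15 nm line — the same
ordering and the same kind of gap the physical instruments show.

The particle-recovery suite fixes ten scenes (seven opaque disks, three
phase spheres; 384² grid, depths 1.2–2.4 mm so the recording NA stays
meaningful on a small window) and requires (x, y) within 1 pixel, z within
2·δ_ax = 4s²λ/(Np)², radius within 1 pixel. The radius estimator reads the
outermost half-maximum crossing of the azimuthally averaged radial profile
about the detected centroid — unbiased for both filled (absorbing) and
ring-structured (phase) objects, unlike thresholded-area estimators. Phase
sphere fixtures keep the projected phase below 2π (index contrasts
0.045–0.05, radii 4–4.5 µm — plasma-relative red-cell-like values); beyond
that the amplitude signature develops interference nulls and a 1-pixel
radius is not observable from the amplitude image at these NAs.

## Degenerate inputs and conventions

All internal lengths are metres; config files require explicit unit
suffixes. Grids are row-major with the origin at pixel (rows//2, cols//2);
z is positive from the detector toward the source, and `propagate(u, d)`
moves the field d downstream. Zero-bandwidth coherence length returns
`inf` rather than raising (laser-like configurations are legitimate).
A constant image normalises to zeros with a warning; an all-zero image has
no defined focus score and raises. Autofocus returns the window boundary
with a warning when the optimum lies on it. Stochastic noise without a seed
is an error; all randomness in the package is seeded and reproducible.
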