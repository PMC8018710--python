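# Methods

This note documents the models, numerical choices, and limitations behind
`histopam`, module by module.

## Focal-field model (`field_model`)

**Model.** The therapy source is a spherically curved shell of focal length
F = 60 mm whose projection onto the aperture plane is an ellipse with full
axes 90 × 70 mm, driven continuous-wave at 1.5 MHz under linear (low
amplitude) conditions. The field is the Rayleigh–Sommerfeld sum of
spherical wavelets `dA · e^{ikR}/R` over the discretized shell. Constant
prefactors are dropped: every derived quantity (−6 dB widths, thresholded
footprint) depends only on relative magnitude, and the field is rescaled to
the calibrated focal peak (35 MPa peak negative pressure) when a footprint
is formed. No nonlinear propagation is modeled: the characterization is of
the linear focal geometry, and the supra-threshold footprint uses the
empirical 27.4 MPa bubble-cloud threshold for agarose rather than any
cavitation physics.

**Assumptions.**
- The eight sector elements are driven in parallel, so the shell is modeled
  as a single uniform aperture (sectoring is acoustically irrelevant at
  linear amplitude).
- The central cutout for the coaxial imaging array is a centered rectangle.
  Its true dimensions are unpublished; the default is 40 mm along the 9 cm
  (azimuth) axis × 14 mm along the 7 cm (elevation) axis, a plausible
  footprint for an L11-5v-like linear array whose azimuth must image the
  vessel cross-section. This is the dominant uncertainty in the axial lobe
  length, which is why the focal-characterization checks carry a wide (20%)
  band.
- Medium defaults are water at 37 °C: c = 1524 m/s, ρ = 993 kg/m³.
- Axis naming: x = 9 cm aperture axis = imaging azimuth; y = 7 cm axis =
  elevation; z = beam (range) axis. The larger aperture focuses tighter, so
  the *narrower* lateral width belongs to the azimuth axis.

**Numerics.** The shell is sampled on a regular aperture-plane grid at
pitch λ/N (default N = 4) and lifted onto the sphere; each point carries
the curved element area `pitch²/cosθ`. The curved area is what makes the
on-axis sum agree with the O'Neil closed form (the package's oracle test,
< 0.1% at λ/4 over 0.5–1.5 F); the planar projected areas are kept
alongside for bookkeeping. Distances are computed through the Gram-matrix
identity in float64; the trigonometric kernel may run in float32 (phase
error < 1e-4 rad at these path lengths), halving the cost of the ~1e9-term
sums. Field points nearer than half the sampling pitch to the shell clamp
the 1/R kernel. Derived metrics converge early: widths and footprint change
by < 0.2% between λ/2 and λ/4 sampling; λ/2 is therefore used in the test
suite and λ/3 in the acceptance script as deliberate cost/accuracy choices.

**Width and footprint measurement.** −6 dB widths are the extents of the
connected region around the peak where magnitude ≥ half the peak, measured
along each principal axis through the peak with linear sub-grid
interpolation of the crossings; a contour clipped by the grid raises an
error rather than returning a biased width. The footprint is the in-plane
(azimuth × range) pixel set whose scaled pressure reaches the threshold,
with ellipse axes measured the same interpolated way; the threshold is
compared inclusively, so threshold = drive peak collapses to the peak pixel
and a threshold above the drive yields an explicitly empty footprint.

## Passive cavitation mapping (`pam`)

**Model.** Broadband time-domain processing, exactly the printed
correlation form: per pixel, channels are delay-aligned with FFT
phase-ramp (band-limited) interpolation using relative delays
`(d_n − min d_m)/c`; the correlation matrix `R = ∫ s_n s_m dt` is formed
over the full record `T_H` and eigendecomposed; the robust Capon power is

    P_RCB = 4π d̄^e / (T_H ρ c) · 1 / (âᵀ R⁻¹ â),
    âᵀR⁻¹â = Σ_i λ²γ_i z_i² / (1 + λγ_i)²,  z = Uᵀā,

with λ > 0 the root of the monotone constraint Σ z_i²/(1+λγ_i)² = ε
(bracketed bisection via Brent, bracket `[0, 1/(ε γ_max)]` with geometric
expansion). This per-eigenvalue kernel is the standard robust-Capon power
and the dimensionally consistent reading of the published expression, and
it is verified in the tests against a dense constrained-optimization oracle
(minimize aᵀR⁻¹a over ‖a − ā‖² ≤ ε) to 0.1%.

**Parameters.**
- ε (steering-vector uncertainty): default 0.1·N. The value used in the
  original processing is unpublished; ε → 0 recovers the standard Capon
  estimate (a tested property), and the emission centroid/1-dB area are
  insensitive to ε over 0.01·N–0.5·N.
- Diagonal loading 1e-6 · trace(R)/N before eigendecomposition, for PSD
  safety; it also guarantees the λ root is bracketed.
- Exponent e on the mean pixel-to-element distance d̄: the published
  rendering is ambiguous; default e = 2 (energy-conserving spherical
  spreading), configurable. Map *shape* along azimuth is unaffected; the
  choice tilts power along range.
- "Within 1 dB of the peak" is interpreted on the acoustic-power scale
  (10·log10 ⇒ threshold peak·10^−0.1); the amplitude convention
  (20·log10) is a switch.
- Module default grid: 0.2 mm azimuth × 0.5 mm range over ±12 mm × 40–80 mm;
  the demo pipelines use a reduced desk-scale grid (below).

**Resolution behavior.** Azimuth localization of a point emitter is exact
to the grid step at ≥ 20 dB SNR. Range is diffraction-limited: the axial
point-spread of a receive aperture at F/3 spans the whole demo range
window, and together with the d̄² prefactor it biases the power-weighted
emission centroid ~0.7 mm toward far range. This mirrors the physical
system's reduced range resolution and is treated as such in the tests
(azimuth asserted to one grid step; the total targeting error to the
per-axis grid steps).

## Segmentation and accuracy metrics (`segmentation_metrics`)

Otsu's threshold (maximum between-class variance, via scikit-image) with a
bright/dark polarity switch, speck removal (< 5 px), hole filling, and
largest-component selection segments lumen, clot, and liquefaction regions.
The clot — manually traced in the physical experiment — is segmented here
as the brighter Otsu class *within* the lumen; a hand-drawn mask file is
accepted anywhere a clot mask is consumed. All distances operate on
member-pixel centers in world millimetres (world = origin + index ×
spacing, 0-based). Dice is 2|A∩B|/(|A|+|B|) on a shared grid; Hausdorff is
the directed max-min form by default (symmetric available, since "maximum
distance between predicted and actual" is ambiguous), computed with a k-d
tree and cross-checked against an independent library implementation.
Fiducial registration is the closed-form least-squares rigid (optionally
similarity) fit; masks are moved between frames by nearest-neighbour
resampling so they stay strictly binary.

## Path planning (`path_planning`)

Waypoint paths are piecewise-linear chains re-parameterized by arc length
and sampled every `step` (default 0.5 mm); the terminal waypoint is always
a stop, even when the last spacing is short, so the treated extent equals
the planned extent. A 1 cm vessel path at 0.5 mm spacing yields 21 stops
(~20 locations). Higher-order splines are deliberately not used: waypoints
sit ~5 mm apart on a near-straight vessel and nothing constrains the curve
between them. Areal plans are triangular lattices (rows pitch·√3/2 apart,
alternate rows shifted pitch/2) anchored at the region centroid with rows
along azimuth, clipped boundary-inclusively to the region; a region smaller
than one cell yields its centroid as the single stop. Plans carry pulse
bookkeeping as metadata only (clots: 500 pulses/stop at 40 Hz with every
10th pulse imaged ⇒ 50 frames/stop; phantoms: 200 single-cycle pulses/stop).

## Synthetic data (`synthetic_data`)

**What it emulates.** Bubble-cloud emissions as broadband point emitters
(Gaussian-windowed sinusoid, 3 MHz center, 100% fractional bandwidth —
emission spectra are uncharacterized, so a generic broadband pulse in the
receive band is used) with exact 1/R spreading and analytic retarded-time
evaluation (no interpolation error), plus white Gaussian noise at a stated
SNR; an L11-5v-like array (128 elements, 0.3 mm pitch, 7.8 MHz, sampled at
31.25 MHz); the model vessel cross-section as an intensity map (bright
0.79 mm wall annulus around a dark 6.35 mm lumen with a mid-intensity
~2 mm clot disk and smoothed multiplicative speckle-like noise, coefficient
of variation 0.15); and liquefaction outcomes as unions of per-stop
footprint ellipses with seeded Gaussian stop jitter (default 0.2 mm, the
scale of the system's own placement error) and 1–2 px boundary erosion to
mimic the observed under-treatment relative to prediction.

**What it does not emulate.** RF-level speckle/B-mode physics (downstream
operations consume grayscale intensity only), bubble dynamics, nonlinear
propagation, attenuation, or respiratory/bulk motion. Passing closed-loop
tests therefore demonstrates the correctness of the measurement chain —
beamforming, segmentation, registration, metrics — under known truth, not
the fidelity of any physical ablation prediction.

All generators are byte-reproducible from their seed.

## Pipelines (`pipeline`, CLI `histopam`)

The clot assessment builds the vessel truth, interpolates the path,
simulates per-stop emission frames, beamforms and averages them, and
reduces to per-stop targeting errors (centroid vs. clot center) and Dice of
the 1-dB emission area against clot and lumen. The phantom assessment
hex-packs a drawn region, forms the predicted mask as the union of
footprints derived from the field model, generates a jittered/eroded
outcome mask, displaces it rigidly, recovers the displacement through
fiducial registration, and reports Dice and Hausdorff. Reports carry a
config hash and all seeds; identical config + seed reproduces a
byte-identical report. Demo problem sizes are deliberate desk-scale
choices: 64 receive elements, 384-sample records, and a 0.5 × 1.0 mm grid
over ±6 × 54–66 mm (the full-scale defaults remain available through
config). Zero-noise/zero-jitter runs recover ground truth exactly
(Dice = 1, Hausdorff = 0, centroid within the grid step per axis).

## Known limitations

- The imaging-window geometry of the physical source is unknown; the axial
  width and footprint major axis inherit that uncertainty (simulated 4.76
  and 2.89 mm against measured 4.8 and 3.4 mm).
- The emission-centroid range bias described above is inherent to
  diffraction-limited passive mapping with a power-law range prefactor.
- Dice of the 1-dB emission area against clot/lumen cross-sections is
  grid- and aperture-dependent at desk scale and is reported, not asserted,
  by the demos.
- Registration accuracy is limited by nearest-neighbour mask resampling to
  about one pixel at the mask spacing.
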