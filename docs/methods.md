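# Methods

## Problem and model

Radiochromic film (EBT3-class) darkens with absorbed dose; digitised on a
flatbed scanner in transmission mode, its dose-response signal is the net
optical density of the red channel,

    netOD = log10( (PV_unexp − PV_bckg) / (PV_exp − PV_bckg) ),

with PV the mean pixel value of the film before/after exposure and of a
zero-light (opaque) strip. The batch calibration maps netOD to dose with the
polynomial analytical form

    D(netOD) = a·netOD + b·netOD^n,        n fixed (2.5 here),

fitted by Levenberg–Marquardt least squares with a, b free. The package
implements two routes to that curve:

* **Benchmark calibration (BC).** Ten strips exposed to uniform fields at
  known doses (1–5.5 Gy in 0.5 Gy steps); one (netOD, dose) point per strip
  from a 1×1 mm central ROI.
* **Physical-wedge (PW) calibration.** A strip exposed once under a 60°
  physical wedge records a continuous lateral dose gradient. Given the
  wedge's normalised reference dose profile p(x) (p(0) = 1 at the central
  axis) and its CAX transmission, the dose at every film position is
  D_CAX·p(x) (self-similar scaling), so a single exposure yields hundreds of
  calibration points. Narrow gradients can be extrapolated through the
  fitted form, and several gradients can be pooled into one fit.

Uncertainty is budgeted per calibration point as an experimental component
(netOD reading uncertainty through the curve slope), a fit component (from
the parameter covariance), and their quadrature total; PW curves are judged
by their relative deviation |D_BC − D_PW|/D_BC at the BC points.

## Scan reduction

Each strip is scanned five times; each scan is 3×3 median filtered (impulse
noise; the smallest impulse-removing window — only the final Wiener window
is prescribed by the protocol), the stack is averaged in floating point, and
the average is passed through an adaptive 7×7 Wiener filter. All filters use
reflect padding so strip borders are not darkened, which would bias edge
segmentation. The Wiener filter is the classical local-MMSE estimator
(local mean/variance over the window, noise power = spatial mean of the
local variances), implemented on `scipy.ndimage.uniform_filter` because
`scipy.signal.wiener` zero-pads borders.

Positions follow one package-wide convention: `position_mm = index·25.4/dpi`,
0-based from the raster corner; CAX-centred coordinates are obtained by
subtracting the detected field centre. ROIs are specified in mm, snapped to
the nearest pixel centre, sizes rounded half-away-from-zero (1×1 mm = 5×5 px
at 127 dpi). The sigma of an ROI reading is the standard deviation of the
pixels inside the ROI — deliberately not sd/√n, the conservative convention
of the underlying film-dosimetry protocol. The alternative (sd of
repeat-scan means) would be smaller; the choice only affects the budgets,
not the fits, which are unweighted by default.

## Wedge profile extraction

From the netOD map of a wedge strip: the 25 lines nearest the transverse
centre are averaged; field edges are the maxima of the numerical gradient
magnitude in each half of the (lightly pre-smoothed, window 5) profile, with
a noise floor of 3× the median absolute gradient of the outer 10 % of
samples; the segmented span is sanity-checked against the divergence-scaled
aperture, field_size·(SSD+depth)/SSD (157.5 mm for 15 cm at SSD 100/depth
5 cm), at ±5 %; the central 20–80 % of the segmented span is kept (penumbra
removal, floor-index arithmetic so the trimmed length is exactly
⌊0.8L⌋−⌊0.2L⌋); the result is smoothed with an 11-sample centred moving
mean (≈2.2 mm at 127 dpi — wide enough to suppress pixel noise, narrow
enough not to flatten a 60° gradient; windows shrink at the boundaries);
and the longest strictly monotone run is extracted (ties broken toward the
run containing the profile midpoint). Profiles are mirrored if netOD
increases with position, so the thick end of the wedge is always at +x.
A warning (never an exception) is raised when the two edges' gradient widths
differ by more than 50 %, a signature of a rotated film; no rotation
correction is attempted.

### Registration

Film and reference are aligned by placing the midpoint of the field edges at
the CAX. Two refinements beyond plain integer argmax proved necessary:

* edge positions are refined to sub-sample precision by parabolic
  interpolation of the gradient-magnitude peak (the pixel pitch of 0.2 mm is
  otherwise the floor on registration accuracy);
* the gradient peaks of a *netOD* profile are displaced asymmetrically by
  the nonlinear film response (the peak of |d netOD/dx| sits where the
  response slope is large, not exactly at the dose inflection), so the raw
  edge midpoint is a biased CAX estimate — by 0.4–1 mm here. Because a wedge
  profile is locally exponential, a registration error δ is indistinguishable
  from a dose-scale error e^{kδ} inside the monotone region, so it cannot be
  fitted away; instead the bias is *predicted* by running the identical edge
  detector on a model netOD profile (the reference dose profile mapped
  through the current calibration estimate, which only needs to be roughly
  right) and subtracted. Two passes (fit → predict bias → refit) converge;
  the removed bias is recorded per exposure in the extraction diagnostics.

Pairing then interpolates the reference dose linearly at each netOD sample's
centred position and multiplies by D_CAX. Points pooled across exposures are
sorted by netOD and fitted exactly like the benchmark points (no
per-gradient weighting).

## Calibration fitting

Unweighted least squares in dose (`scipy.optimize.curve_fit`, LM, xtol/ftol
1e-12, 10 000 evaluations max); netOD uncertainties are carried for the
budgets only. A weighted mode (weights = dose-equivalent of sigma_netOD via
the slope of a preliminary unweighted fit) is available but off by default.
Initialisation is deterministic: a0 from the chord through the two lowest
netOD points, b0 = 0. Parameter sigmas are the square roots of the
covariance diagonal. The curve inverse (netOD from dose) uses bisection on
the monotone forward map to 1e-10. Evaluating a curve outside the netOD
range it was fitted on is permitted — that is the extrapolation mode — and
flagged through `CalibrationCurve.is_extrapolated`.

## Synthetic study generator

The generator emulates the full study: ten benchmark strips (25.4×203.2 mm,
127 dpi, uniform fields 1–5.5 Gy), five wedge strips (D_CAX = 1–5 Gy), each
as unexposed/exposed/background stacks of five repeat scans.

* **Ground truth response**: the same polynomial form, a = 10 Gy, b = 40 Gy,
  n = 2.5 (netOD ≈ 0.10 at 1 Gy, ≈ 0.32 at 5.5 Gy — an EBT3-like red-channel
  response). Dose→netOD inversion by vectorised bisection (tol 1e-10).
* **Wedge profile**: a parametric stand-in, not a replica of a measured
  water-tank profile: transmission exponential in the lateral coordinate
  (uniform wedge material, thickness linear in x), logistic penumbra
  roll-offs with 5 mm 80–20 width, 2 % scatter floor outside the field. The
  dynamic range across the trimmed central 60 % defaults to 3, so a 5 Gy
  exposure spans ≈2.9–8.7 Gy and a 1 Gy exposure ≈0.58–1.73 Gy. The exact
  same profile is emitted as the reference (sampled at 0.5 mm), so the
  pipeline is self-consistent; CAX transmission is the configured 0.2654.
* **Noise model**: each repeat scan adds independent Gaussian noise with
  sd = 0.5 % of the pixel value; the film's base density varies by a
  correlated Gaussian field (sd 0.3 %, Gaussian kernel sigma = 25 mm, i.e. a
  5 cm correlation scale) multiplying the unexposed PV. Because the same
  film is scanned before and after exposure, base variation cancels in
  netOD — which is precisely why the protocol scans each strip both ways.
  Unexposed mean PV 40000, background 1000 (16-bit scale; arbitrary but
  recorded in the manifest). Pixel values stay floating point in memory;
  quantisation to 16-bit integers happens only when rasters are written to
  TIFF.
* **Determinism**: all randomness flows through one seeded generator; equal
  seeds give byte-identical datasets.

What the generator does **not** emulate — so what passing tests do not show
about real films: scanner lateral-response artefacts and film curvature
(physically excluded by the positioner in the emulated protocol), film
*response* (active-layer) nonuniformity, energy dependence, film rotation in
the phantom, post-irradiation darkening kinetics, and any non-exponential
structure (horns, off-axis softening) of a real wedge profile. The
benchmark-vs-wedge comparisons therefore validate the numerical chain and
its noise robustness under the stated model, not the dosimetric accuracy of
any particular film batch.

## Validation setup and problem sizes

The replication harness simulates 20 independently seeded studies (seeds
drawn from one master generator), fits the benchmark and all wedge variants
in each, and takes worst cases across replicates. Each gradient contributes
≈470–480 calibration points (60 % of the 157.5 mm span at 5 px/mm).
Deviations are evaluated at the benchmark points, taking D_BC as the
benchmark curve's dose at the measured netOD. Degenerate inputs fail loudly:
all-equal netOD designs, non-converged fits, profiles without a gradient
peak above the noise floor, and ROI or interpolation requests outside their
supports all raise typed exceptions rather than returning numbers.

## Known limitations

* The edge-midpoint bias correction assumes the reference profile's shape is
  accurate near the penumbra; a badly wrong reference would leave a residual
  registration error that re-enters the curve as a scale factor.
* The moving-mean boundary shrink biases the first/last half-window of the
  trimmed profile by up to ≈0.6 % (slope × half window); these few samples
  are retained for fidelity to the procedure and dominate the residual of
  the self-similarity check.
* Unweighted fitting makes the high-netOD points (smallest relative noise)
  no more influential than the noisy low-netOD tail; the weighted mode
  exists but changes the benchmark comparison only marginally under the
  default noise.
* With a locally exponential wedge, dose-scale and registration errors are
  confounded (see Registration); wedges with stronger profile curvature
  would make the two separable.
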