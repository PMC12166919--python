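"""Wedge-gradient film calibration.

A physical wedge (here a motorised 60 degree wedge in a 6 MV, 15x15 cm2
beam) imprints a known lateral dose gradient on a single film strip.  Once
the wedge's normalised dose profile and its central-axis (CAX) transmission
are measured in reference conditions, the dose delivered at every position
of the strip is known — so one exposure provides hundreds of calibration
points instead of one.

Extraction chain for one exposed strip (netOD map in, calibration points
out): average the central lines along the wedge axis, locate the field edges
from the numerical gradient, sanity-check the edge span against the
divergence-scaled collimator aperture, keep the central 20-80 % of the
segmented span (removing penumbra remnants), smooth with a moving mean,
keep the longest strictly monotone run, and pair each netOD sample with the
dose interpolated from the reference profile scaled by the nominal CAX dose
(dose profiles are self-similar: D(x; D_CAX) = D_CAX * p(x) with p(0) = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .calibration import (CalibrationCurve, CalibrationPoint, deviation_pct,
                          dose_from_netod, fit_calibration)
from .densitometry import NetODMap, NetODProfile, netod_map
from .errors import (DimensionError, DomainError, ExtrapolationError,
                     RegistrationError, RotationWarning, SegmentationError)
from .scan_io import ScanImage, reduce_scan_stack


@dataclass
class FieldGeometry:
    """Beam geometry defining the measurement plane of film and reference."""

    field_size_cm: float = 15.0
    ssd_cm: float = 100.0
    depth_cm: float = 5.0
    wedge_angle_deg: float = 60.0

    @property
    def projected_span_mm(self) -> float:
        """Collimator aperture scaled by beam divergence to the film depth."""
        return self.field_size_cm * 10.0 * (self.ssd_cm + self.depth_cm) / self.ssd_cm

    def to_dict(self) -> dict:
        return {"field_size_cm": self.field_size_cm, "ssd_cm": self.ssd_cm,
                "depth_cm": self.depth_cm, "wedge_angle_deg": self.wedge_angle_deg}

    @classmethod
    def from_dict(cls, d: dict) -> "FieldGeometry":
        return cls(**d)


@dataclass
class WedgeReference:
    """Normalised wedge dose profile plus CAX transmission and geometry.

    ``dose_rel`` is the dose profile along the wedge gradient axis normalised
    to 1 at the CAX (position 0); multiplying by the nominal CAX dose gives
    absolute dose at every position.
    """

    positions_mm: np.ndarray
    dose_rel: np.ndarray
    attenuation_cax: float
    geometry: FieldGeometry

    def __post_init__(self):
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.dose_rel = np.asarray(self.dose_rel, dtype=float)
        if len(self.positions_mm) != len(self.dose_rel):
            raise DimensionError("reference arrays must have equal length")
        if not np.all(np.diff(self.positions_mm) > 0):
            raise DimensionError("reference positions must be strictly increasing")
        if np.any(self.dose_rel <= 0):
            raise DomainError("reference dose profile must be positive everywhere")
        if not 0 < self.attenuation_cax < 1:
            raise DomainError("attenuation_cax must lie in (0, 1)")
        cax = np.interp(0.0, self.positions_mm, self.dose_rel)
        if abs(cax - 1.0) > 1e-6:
            raise DomainError(f"reference profile must equal 1 at the CAX, got {cax}")

    def to_files(self, csv_path, yaml_path) -> None:
        pd.DataFrame({"position_mm": self.positions_mm,
                      "dose_rel": self.dose_rel}).to_csv(csv_path, index=False)
        with open(yaml_path, "w") as fh:
            yaml.safe_dump({"attenuation_cax": float(self.attenuation_cax),
                            "geometry": self.geometry.to_dict()}, fh)

    @classmethod
    def from_files(cls, csv_path, yaml_path) -> "WedgeReference":
        df = pd.read_csv(csv_path)
        with open(yaml_path) as fh:
            meta = yaml.safe_load(fh)
        return cls(positions_mm=df["position_mm"].to_numpy(),
                   dose_rel=df["dose_rel"].to_numpy(),
                   attenuation_cax=meta["attenuation_cax"],
                   geometry=FieldGeometry.from_dict(meta["geometry"]))


@dataclass
class WedgeExposure:
    """One wedge-field strip: repeat-scan stacks, nominal CAX dose, axis."""

    unexposed: list[ScanImage]
    exposed: list[ScanImage]
    background: list[ScanImage]
    d_cax_gy: float
    axis: str = "x"

    def __post_init__(self):
        if self.d_cax_gy <= 0:
            raise DomainError("d_cax_gy must be > 0")


@dataclass
class DoseProfile:
    """1-D absolute dose profile (Gy) on strictly increasing positions (mm)."""

    positions_mm: np.ndarray
    dose_gy: np.ndarray

    def __post_init__(self):
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.dose_gy = np.asarray(self.dose_gy, dtype=float)
        if len(self.positions_mm) != len(self.dose_gy):
            raise DimensionError("profile arrays must have equal length")
        if not np.all(np.diff(self.positions_mm) > 0):
            raise DimensionError("profile positions must be strictly increasing")


@dataclass
class LengthCheck:
    passed: bool
    span_mm: float
    expected_mm: float
    tolerance: float


@dataclass
class WedgeExtraction:
    """Intermediate products and diagnostics of one wedge-profile extraction."""

    profile: NetODProfile            # final: trimmed, smoothed, monotone, oriented
    trimmed: NetODProfile            # trimmed + smoothed, before monotone extraction
    edges_idx: tuple[int, int]
    center_mm: float
    length_check: LengthCheck | None
    flipped: bool
    warnings: list[str] = field(default_factory=list)
    registration_bias_mm: float = 0.0   # systematic edge-midpoint shift removed


def average_central_lines(nmap: NetODMap, axis: str = "x",
                          n_lines: int = 25) -> NetODProfile:
    """Average the ``n_lines`` lines nearest the transverse centre.

    ``axis='x'`` means the wedge gradient runs along columns, so rows are the
    transverse direction being averaged.  Invalid (masked) pixels are
    excluded; samples with no valid pixel at all are dropped.
    """
    if axis not in ("x", "y"):
        raise DomainError(f"axis must be 'x' or 'y', got {axis!r}")
    vals = nmap.netod if axis == "x" else nmap.netod.T
    sig = nmap.sigma_netod if axis == "x" else nmap.sigma_netod.T
    n_trans = vals.shape[0]
    if n_trans < n_lines:
        raise DimensionError(
            f"map has {n_trans} transverse lines, fewer than n_lines={n_lines}"
        )
    start = n_trans // 2 - n_lines // 2
    block = vals[start:start + n_lines]
    sblock = sig[start:start + n_lines]
    count = np.sum(np.isfinite(block), axis=0)
    keep = count > 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(block, axis=0)
        var = np.nanmean(sblock**2, axis=0)
    positions = np.arange(vals.shape[1]) * nmap.mm_per_px
    return NetODProfile(positions_mm=positions[keep], netod=mean[keep],
                        sigma_netod=np.sqrt(var[keep] / count[keep]))


def _moving_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean with window shrinking at the boundaries."""
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(values)))
    n = len(values)
    i = np.arange(n)
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def segment_field(profile: NetODProfile, presmooth_window: int = 5,
                  noise_floor_factor: float = 3.0,
                  outer_frac: float = 0.1) -> tuple[int, int]:
    """Locate the field edges as the gradient-magnitude peaks of each half.

    The profile is lightly moving-mean smoothed (for localisation only), the
    numerical gradient is taken, and the left/right halves each contribute
    their maximum-|gradient| sample.  The noise floor is ``noise_floor_factor``
    times the median absolute gradient of the outer ``outer_frac`` of samples
    at each end; a peak not exceeding it raises SegmentationError.  A warning
    is emitted when the two edges' gradient widths differ by more than 50 %
    (possible film rotation); no correction is attempted.
    """
    n = len(profile)
    if n < 16:
        raise DimensionError(f"profile too short to segment ({n} samples)")
    sm = _moving_mean(profile.netod, presmooth_window)
    grad = np.gradient(sm, profile.positions_mm)
    mag = np.abs(grad)
    n_outer = max(1, int(round(outer_frac * n)))
    outer = np.concatenate([mag[:n_outer], mag[-n_outer:]])
    floor = noise_floor_factor * np.median(outer)
    half = n // 2
    left = int(np.argmax(mag[:half]))
    right = half + int(np.argmax(mag[half:]))
    scale = max(np.max(np.abs(sm)), 1.0) * 1e-12
    if mag[left] <= max(floor, scale) or mag[right] <= max(floor, scale):
        raise SegmentationError(
            f"no gradient peak above noise floor {floor:.3g} "
            f"(peaks {mag[left]:.3g}, {mag[right]:.3g})"
        )
    wl = _edge_width(mag, left)
    wr = _edge_width(mag, right)
    if min(wl, wr) > 0 and abs(wl - wr) / min(wl, wr) > 0.5:
        warnings.warn(
            f"field-edge gradient widths differ by more than 50% "
            f"({wl} vs {wr} samples): film may be rotated",
            RotationWarning,
        )
    return left, right


def _subsample_peak(mag: np.ndarray, idx: int, positions: np.ndarray) -> float:
    """Parabolic sub-sample refinement of a gradient-magnitude peak position."""
    if idx <= 0 or idx >= len(mag) - 1:
        return float(positions[idx])
    y0, y1, y2 = mag[idx - 1], mag[idx], mag[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(positions[idx])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    step = positions[min(idx + 1, len(positions) - 1)] - positions[idx] \
        if idx + 1 < len(positions) else positions[idx] - positions[idx - 1]
    return float(positions[idx] + delta * step)


def segment_field_positions(profile: NetODProfile, presmooth_window: int = 5,
                            noise_floor_factor: float = 3.0,
                            outer_frac: float = 0.1) -> tuple[float, float]:
    """Continuous (sub-sample) field-edge positions in mm.

    Same detector as :func:`segment_field`, refined by parabolic
    interpolation of the gradient-magnitude peaks.  Used for registration,
    where sub-pixel precision of the field centre matters; index-based
    segmentation still drives the slicing.
    """
    left, right = segment_field(profile, presmooth_window=presmooth_window,
                                noise_floor_factor=noise_floor_factor,
                                outer_frac=outer_frac)
    sm = _moving_mean(profile.netod, presmooth_window)
    mag = np.abs(np.gradient(sm, profile.positions_mm))
    return (_subsample_peak(mag, left, profile.positions_mm),
            _subsample_peak(mag, right, profile.positions_mm))


def _edge_width(mag: np.ndarray, peak: int) -> int:
    """Number of contiguous samples around ``peak`` with |gradient| >= half peak."""
    thresh = mag[peak] / 2.0
    lo = peak
    while lo > 0 and mag[lo - 1] >= thresh:
        lo -= 1
    hi = peak
    while hi < len(mag) - 1 and mag[hi + 1] >= thresh:
        hi += 1
    return hi - lo + 1


def sanity_check_length(edge_span_mm: float, geometry: FieldGeometry,
                        tolerance: float = 0.05) -> LengthCheck:
    """Compare the segmented span to the divergence-scaled aperture.

    At depth d below the surface the aperture projects to
    field_size * (SSD + d) / SSD; a film at that plane must record a profile
    of (slightly more than) that length.
    """
    expected = geometry.projected_span_mm
    passed = abs(edge_span_mm - expected) <= tolerance * expected
    return LengthCheck(passed=bool(passed), span_mm=float(edge_span_mm),
                       expected_mm=float(expected), tolerance=float(tolerance))


def trim_profile(profile: NetODProfile, lo_frac: float = 0.2,
                 hi_frac: float = 0.8) -> NetODProfile:
    """Keep samples floor(lo*L) <= i < floor(hi*L) of the segmented profile."""
    if not (0 <= lo_frac < hi_frac <= 1):
        raise DomainError("need 0 <= lo_frac < hi_frac <= 1")
    L = len(profile)
    start = int(np.floor(lo_frac * L))
    stop = int(np.floor(hi_frac * L))
    if stop <= start:
        raise DomainError(f"trim ({lo_frac}, {hi_frac}) of {L} samples is empty")
    return profile.slice(start, stop)


def smooth_profile(profile: NetODProfile, window: int = 11) -> NetODProfile:
    """Centered moving mean; the window shrinks near the boundaries.

    Sample uncertainties are propagated as the rms of the window divided by
    the (local) window length, treating samples as independent.
    """
    if window < 1 or window % 2 == 0 or window > len(profile):
        raise DomainError(
            f"window must be odd, >= 1 and <= profile length, got {window}"
        )
    if window == 1:
        return profile
    vals = _moving_mean(profile.netod, window)
    half = window // 2
    n = len(profile)
    i = np.arange(n)
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half + 1, n)
    csum2 = np.concatenate(([0.0], np.cumsum(profile.sigma_netod**2)))
    sig = np.sqrt(csum2[hi] - csum2[lo]) / (hi - lo)
    return NetODProfile(profile.positions_mm, vals, sig)


def extract_monotone(profile: NetODProfile) -> NetODProfile:
    """Longest contiguous strictly monotone run, in the overall trend direction.

    Ties between equally long runs are broken toward the run containing (or
    nearest to) the profile midpoint, earlier run first.
    """
    v = profile.netod
    L = len(v)
    if L == 0:
        raise DomainError("empty profile")
    if L == 1:
        return profile
    trend = v[-1] - v[0]
    if trend == 0:
        trend = float(np.polyfit(np.arange(L), v, 1)[0])
    decreasing = trend <= 0
    ok = (np.diff(v) < 0) if decreasing else (np.diff(v) > 0)
    runs = []
    start = 0
    for i, good in enumerate(ok):
        if not good:
            runs.append((start, i))
            start = i + 1
    runs.append((start, L - 1))
    best_len = max(e - s for s, e in runs)
    mid = (L - 1) / 2.0
    candidates = [(s, e) for s, e in runs if e - s == best_len]

    def dist(run):
        s, e = run
        if s <= mid <= e:
            return 0.0
        return min(abs(s - mid), abs(e - mid))

    s, e = min(candidates, key=dist)  # ties: earlier run (min is stable)
    return profile.slice(s, e + 1)


def orient_decreasing(profile: NetODProfile) -> tuple[NetODProfile, bool]:
    """Flip the spatial axis if netOD increases with position.

    Profiles are paired with a reference whose dose decreases toward +x
    (thick end of the wedge at +x); a mirrored film is detected from its
    netOD trend and reflected about the field centre.
    """
    if len(profile) < 2 or profile.netod[-1] <= profile.netod[0]:
        return profile, False
    return profile.mirrored(), True


def estimate_dose_profile(ref: WedgeReference, d_cax_gy: float,
                          positions_mm) -> np.ndarray:
    """Dose (Gy) at ``positions_mm``: reference profile scaled by the CAX dose.

    Linear interpolation on the reference grid; positions outside the
    reference support raise ExtrapolationError.
    """
    if d_cax_gy <= 0:
        raise DomainError("d_cax_gy must be > 0")
    pos = np.asarray(positions_mm, dtype=float)
    if np.any(pos < ref.positions_mm[0]) or np.any(pos > ref.positions_mm[-1]):
        raise ExtrapolationError(
            "positions outside the reference profile support "
            f"[{ref.positions_mm[0]}, {ref.positions_mm[-1]}] mm"
        )
    out = d_cax_gy * np.interp(pos, ref.positions_mm, ref.dose_rel)
    return float(out) if out.ndim == 0 else out


def attenuation_coefficient(d_wedged_cax_gy: float, d_open_cax_gy: float) -> float:
    """CAX transmission of the wedge: wedged / open dose at the same point."""
    if d_wedged_cax_gy <= 0 or d_open_cax_gy <= 0:
        raise DomainError("doses must be > 0")
    return d_wedged_cax_gy / d_open_cax_gy


def wedged_mu(d_cax_gy: float, output_gy_per_mu: float, attenuation: float) -> float:
    """Monitor units delivering ``d_cax_gy`` through the wedge.

    MU = D_CAX / (output * attenuation), with output the open-field
    calibration (Gy/MU) at the reference point.
    """
    if d_cax_gy <= 0 or output_gy_per_mu <= 0:
        raise DomainError("dose and output must be > 0")
    if not 0 < attenuation < 1:
        raise DomainError("attenuation must lie in (0, 1)")
    return d_cax_gy / (output_gy_per_mu * attenuation)


def pair_profiles(dose_profile: DoseProfile,
                  netod_profile: NetODProfile) -> list[CalibrationPoint]:
    """Pair each netOD sample with the dose interpolated at its position."""
    lo, hi = dose_profile.positions_mm[0], dose_profile.positions_mm[-1]
    pos = netod_profile.positions_mm
    if pos[0] > hi or pos[-1] < lo:
        raise RegistrationError("netOD and dose profile supports do not overlap")
    if np.any(pos < lo) or np.any(pos > hi):
        raise RegistrationError("netOD samples outside the dose profile support")
    doses = np.interp(pos, dose_profile.positions_mm, dose_profile.dose_gy)
    return [CalibrationPoint(netod=float(x), sigma_netod=float(s), dose_gy=float(d))
            for x, s, d in zip(netod_profile.netod, netod_profile.sigma_netod, doses)]


def extract_wedge_profile(nmap: NetODMap, geometry: FieldGeometry | None = None,
                          axis: str = "x", n_lines: int = 25,
                          trim: tuple[float, float] = (0.2, 0.8),
                          smooth_window: int = 11, presmooth_window: int = 5,
                          length_tolerance: float = 0.05) -> WedgeExtraction:
    """Run the full profile-extraction chain on one netOD map."""
    notes = []
    raw = average_central_lines(nmap, axis=axis, n_lines=n_lines)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", RotationWarning)
        left, right = segment_field(raw, presmooth_window=presmooth_window)
    for w in caught:
        notes.append(str(w.message))
        warnings.warn_explicit(w.message, w.category, w.filename, w.lineno)
    x_left, x_right = segment_field_positions(raw, presmooth_window=presmooth_window)
    seg = raw.slice(left, right + 1)
    span = x_right - x_left
    check = None
    if geometry is not None:
        check = sanity_check_length(span, geometry, tolerance=length_tolerance)
        if not check.passed:
            notes.append(
                f"segmented span {check.span_mm:.1f} mm outside "
                f"{check.tolerance:.0%} of expected {check.expected_mm:.1f} mm"
            )
    center = 0.5 * (x_left + x_right)
    seg = seg.shifted(-center)
    trimmed = trim_profile(seg, *trim)
    smoothed = smooth_profile(trimmed, smooth_window)
    mono = extract_monotone(smoothed)
    mono, flipped = orient_decreasing(mono)
    oriented_trimmed = smoothed.mirrored() if flipped else smoothed
    return WedgeExtraction(profile=mono, trimmed=oriented_trimmed,
                           edges_idx=(left, right), center_mm=float(center),
                           length_check=check, flipped=flipped, warnings=notes)


def _linear_response_fit(points: list[CalibrationPoint], n_fixed: float):
    """Fast (a, b) estimate: the response is linear in (a, b) for fixed n."""
    x = np.array([p.netod for p in points], dtype=float)
    y = np.array([p.dose_gy for p in points], dtype=float)
    design = np.column_stack([x, np.power(x, n_fixed)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(coef[0]), float(coef[1])


def registration_bias_mm(a: float, b: float, n: float, ref: WedgeReference,
                         d_cax_gy: float, spacing_mm: float,
                         presmooth_window: int = 5) -> float:
    """Systematic edge-midpoint shift of the detector on a model netOD profile.

    The gradient-peak edges of a netOD profile are displaced asymmetrically by
    the nonlinear film response, so their midpoint is a biased CAX estimate.
    The displacement is predicted by mapping the reference dose profile
    through the current calibration estimate and running the identical edge
    detector on the resulting model profile; subtracting the model's midpoint
    (true CAX at 0) removes the bias.  Returns 0 when the current estimate is
    not invertible (non-monotone response).
    """
    if a <= 0 or d_cax_gy <= 0:
        return 0.0
    lo, hi = ref.positions_mm[0], ref.positions_mm[-1]
    pos = np.arange(lo, hi + spacing_mm / 2, spacing_mm)
    dose = d_cax_gy * np.interp(pos, ref.positions_mm, ref.dose_rel)
    from .calibration import invert_dose_response

    try:
        netod = invert_dose_response(a, b, n, dose)
    except Exception:
        return 0.0
    model = NetODProfile(pos, netod, np.zeros_like(netod))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RotationWarning)
            x_left, x_right = segment_field_positions(
                model, presmooth_window=presmooth_window)
    except (SegmentationError, DimensionError):
        return 0.0
    return 0.5 * (x_left + x_right)


@dataclass
class WedgeCalibrationResult:
    curve: CalibrationCurve
    points: list[CalibrationPoint]
    extractions: list[WedgeExtraction]


def wedge_calibration(exposures: list[WedgeExposure], ref: WedgeReference,
                      n_fixed: float = 2.5, n_lines: int = 25,
                      trim: tuple[float, float] = (0.2, 0.8),
                      smooth_window: int = 11,
                      weighted: bool = False) -> WedgeCalibrationResult:
    """Fit a calibration curve from one or more wedge exposures.

    Each exposure runs the full chain (reduction, netOD map, profile
    extraction, dose pairing); points are pooled across exposures, sorted by
    netOD and fitted with the exponent fixed.  The returned curve carries the
    netOD domain of the pooled points.
    """
    if len(exposures) < 1:
        raise DomainError("need at least one wedge exposure")
    from dataclasses import replace as dc_replace

    extractions = []
    raw: list[tuple[WedgeExposure, WedgeExtraction]] = []
    for expo in exposures:
        u = reduce_scan_stack(expo.unexposed)
        e = reduce_scan_stack(expo.exposed)
        b = reduce_scan_stack(expo.background)
        nmap = netod_map(u, e, b)
        ext = extract_wedge_profile(nmap, geometry=ref.geometry, axis=expo.axis,
                                    n_lines=n_lines, trim=trim,
                                    smooth_window=smooth_window)
        raw.append((expo, ext))

    def paired(bias: dict[int, float]) -> list[CalibrationPoint]:
        pts: list[CalibrationPoint] = []
        for i, (expo, ext) in enumerate(raw):
            dose = DoseProfile(ref.positions_mm, ref.dose_rel * expo.d_cax_gy)
            prof = ext.profile.shifted(bias.get(i, 0.0))
            pts.extend(pair_profiles(dose, prof))
        return pts

    # Remove the systematic edge-midpoint registration bias: predict the
    # detector's midpoint shift on a model netOD profile built from the
    # current calibration estimate, shift the film profile accordingly,
    # and iterate once (the prediction is insensitive to the remaining
    # parameter error, so two passes converge).
    bias: dict[int, float] = {}
    spacing = {i: float(np.mean(np.diff(ext.profile.positions_mm)))
               for i, (_, ext) in enumerate(raw)}
    for _ in range(2):
        a_est, b_est = _linear_response_fit(paired(bias), n_fixed)
        bias = {i: registration_bias_mm(a_est, b_est, n_fixed, ref,
                                        expo.d_cax_gy, spacing[i])
                for i, (expo, _) in enumerate(raw)}

    all_points = sorted(paired(bias), key=lambda p: p.netod)
    for i, (_, ext) in enumerate(raw):
        shift = bias.get(i, 0.0)
        extractions.append(dc_replace(
            ext,
            profile=ext.profile.shifted(shift),
            trimmed=ext.trimmed.shifted(shift),
            center_mm=ext.center_mm - shift,
            registration_bias_mm=shift,
        ))
    curve = fit_calibration(all_points, n_fixed=n_fixed, weighted=weighted)
    return WedgeCalibrationResult(curve=curve, points=all_points,
                                  extractions=extractions)


def compare_to_benchmark(curve: CalibrationCurve,
                         bc_points: list[CalibrationPoint]):
    """Per-point deviation (%) of the wedge curve from benchmark dose points.

    Returns (deviations, extrapolated): for each benchmark point, the relative
    deviation of the curve's dose prediction at the point's netOD from the
    point's benchmark dose, and whether that netOD lies outside the curve's
    fitted domain.
    """
    netods = np.array([p.netod for p in bc_points], dtype=float)
    d_bc = np.array([p.dose_gy for p in bc_points], dtype=float)
    d_pw = dose_from_netod(curve, netods)
    dev = deviation_pct(d_bc, d_pw)
    extrapolated = curve.is_extrapolated(netods)
    return np.atleast_1d(dev), np.atleast_1d(extrapolated)
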