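"""Calibration-curve fitting, dose conversion and uncertainty budgets.

The netOD -> dose response of the film batch is modelled by the polynomial
analytical form

    D(netOD) = a * netOD + b * netOD^n

with a, b free parameters (Gy) and the exponent n fixed (n = 2.5 for this
film/scanner combination).  The fit uses Levenberg-Marquardt least squares
on the (netOD, dose) pairs; parameter uncertainties sigma_a, sigma_b come
from the fit covariance.

The relative dose uncertainty splits into an experimental part, driven by
the netOD reading uncertainty through the curve slope,

    sigma_D_exp(%) = sqrt( (a + n b netOD^(n-1))^2 sigma_netOD^2 ) / D * 100

a fit part, driven by the parameter uncertainties,

    sigma_D_fit(%) = sqrt( netOD^2 sigma_a^2 + netOD^(2n) sigma_b^2 ) / D * 100

and a total combined in quadrature.  Deviations between two dose
determinations of the same point are expressed relative to the benchmark:
|D_BC - D_PW| / D_BC * 100 %.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import DomainError, FitError
from .densitometry import netod_from_rois
from .scan_io import ScanImage, reduce_scan_stack, roi_mean


@dataclass
class CalibrationPoint:
    netod: float
    sigma_netod: float
    dose_gy: float

    def __post_init__(self):
        if self.dose_gy < 0:
            raise DomainError("dose must be >= 0")
        if self.sigma_netod < 0:
            raise DomainError("sigma_netod must be >= 0")


@dataclass
class CalibrationCurve:
    """Fitted response D = a*netOD + b*netOD^n with parameter uncertainties."""

    a: float
    b: float
    n: float
    sigma_a: float
    sigma_b: float
    netod_domain: tuple[float, float]
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n <= 1:
            raise DomainError("exponent n must be > 1")
        if self.sigma_a < 0 or self.sigma_b < 0:
            raise DomainError("parameter uncertainties must be >= 0")
        lo, hi = self.netod_domain
        if not lo < hi:
            raise DomainError("netod_domain must satisfy min < max")
        self.netod_domain = (float(lo), float(hi))

    def dose(self, netod):
        return dose_from_netod(self, netod)

    def is_extrapolated(self, netod):
        lo, hi = self.netod_domain
        out = (np.asarray(netod, dtype=float) < lo) | (np.asarray(netod, dtype=float) > hi)
        return bool(out) if out.ndim == 0 else out

    def to_json(self, path=None) -> str:
        payload = {
            "a": self.a, "b": self.b, "n": self.n,
            "sigma_a": self.sigma_a, "sigma_b": self.sigma_b,
            "netod_domain": list(self.netod_domain),
            "fit_meta": self.fit_meta,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "CalibrationCurve":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(a=payload["a"], b=payload["b"], n=payload["n"],
                   sigma_a=payload["sigma_a"], sigma_b=payload["sigma_b"],
                   netod_domain=tuple(payload["netod_domain"]),
                   fit_meta=payload.get("fit_meta", {}))


@dataclass
class UncertaintyBudget:
    """Relative dose uncertainty components (%), combined in quadrature."""

    sigma_exp_pct: float
    sigma_fit_pct: float
    sigma_total_pct: float

    def __post_init__(self):
        for v in (self.sigma_exp_pct, self.sigma_fit_pct, self.sigma_total_pct):
            if v < 0:
                raise DomainError("uncertainty components must be >= 0")


def dose_response(netod, a, b, n):
    netod = np.asarray(netod, dtype=float)
    return a * netod + b * np.power(netod, n)


def dose_from_netod(curve: CalibrationCurve, netod):
    """Evaluate the calibration curve. netOD must be >= 0.

    Evaluation outside ``curve.netod_domain`` is permitted (extrapolation);
    use :meth:`CalibrationCurve.is_extrapolated` to flag such points.
    """
    arr = np.asarray(netod, dtype=float)
    if np.any(arr < 0):
        raise DomainError("netOD must be >= 0")
    out = dose_response(arr, curve.a, curve.b, curve.n)
    return float(out) if out.ndim == 0 else out


def response_slope(curve: CalibrationCurve, netod):
    """dD/dnetOD = a + n*b*netOD^(n-1)."""
    arr = np.asarray(netod, dtype=float)
    return curve.a + curve.n * curve.b * np.power(arr, curve.n - 1.0)


def fit_calibration(points: list[CalibrationPoint], n_fixed: float = 2.5,
                    weighted: bool = False) -> CalibrationCurve:
    """Least-squares fit of (a, b) with the exponent held fixed.

    Unweighted residuals in dose by default; with ``weighted=True`` points
    are weighted by the dose-equivalent of their netOD uncertainty (computed
    from a preliminary unweighted fit).  Initialisation is deterministic:
    a0 = slope of the chord through the two lowest-netOD points, b0 = 0.
    """
    if len(points) < 3:
        raise FitError(f"need >= 3 calibration points, got {len(points)}")
    x = np.array([p.netod for p in points], dtype=float)
    y = np.array([p.dose_gy for p in points], dtype=float)
    sx = np.array([p.sigma_netod for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise FitError("rank-deficient design: all netOD values equal")
    if n_fixed <= 1:
        raise DomainError("n_fixed must be > 1")

    order = np.argsort(x)
    x0, x1 = x[order[0]], x[order[1]]
    if x1 > x0:
        a0 = (y[order[1]] - y[order[0]]) / (x1 - x0)
    else:
        a0 = float(np.mean(y) / max(np.mean(x), 1e-12))
    p0 = (a0, 0.0)

    def model(xv, a, b):
        return dose_response(xv, a, b, n_fixed)

    def run(sigma):
        return curve_fit(model, x, y, p0=p0, sigma=sigma, method="lm",
                         maxfev=10000, xtol=1e-12, ftol=1e-12)

    try:
        popt, pcov = run(None)
        if weighted:
            prelim = CalibrationCurve(a=popt[0], b=popt[1], n=n_fixed,
                                      sigma_a=0.0, sigma_b=0.0,
                                      netod_domain=(x.min(), x.max() + 1e-15))
            sd = np.abs(response_slope(prelim, x)) * sx
            sd = np.where(sd > 0, sd, np.max(sd) if np.max(sd) > 0 else 1.0)
            popt, pcov = run(sd)
    except RuntimeError as exc:
        raise FitError(f"calibration fit did not converge: {exc}") from exc
    if not np.all(np.isfinite(popt)) or not np.all(np.isfinite(pcov)):
        raise FitError("calibration fit returned non-finite parameters/covariance")
    sigma_a, sigma_b = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    resid = y - model(x, *popt)
    return CalibrationCurve(
        a=float(popt[0]), b=float(popt[1]), n=float(n_fixed),
        sigma_a=float(sigma_a), sigma_b=float(sigma_b),
        netod_domain=(float(x.min()), float(x.max())),
        fit_meta={
            "n_points": len(points),
            "weighted": bool(weighted),
            "rms_residual_gy": float(np.sqrt(np.mean(resid**2))),
        },
    )


def experimental_uncertainty_pct(curve: CalibrationCurve, netod, sigma_netod):
    """Relative experimental dose uncertainty (%) from the netOD reading."""
    d = dose_from_netod(curve, netod)
    if np.any(np.asarray(d) <= 0):
        raise DomainError("experimental uncertainty undefined at zero dose")
    slope = response_slope(curve, netod)
    out = np.sqrt(slope**2 * np.asarray(sigma_netod, dtype=float) ** 2) / d * 100.0
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def fit_uncertainty_pct(curve: CalibrationCurve, netod):
    """Relative fit dose uncertainty (%) from sigma_a, sigma_b."""
    d = dose_from_netod(curve, netod)
    if np.any(np.asarray(d) <= 0):
        raise DomainError("fit uncertainty undefined at zero dose")
    x = np.asarray(netod, dtype=float)
    out = np.sqrt(x**2 * curve.sigma_a**2 + np.power(x, 2 * curve.n) * curve.sigma_b**2) / d * 100.0
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def total_uncertainty_pct(sigma_exp_pct, sigma_fit_pct):
    """Quadrature sum of the experimental and fit components (%)."""
    e = np.asarray(sigma_exp_pct, dtype=float)
    f = np.asarray(sigma_fit_pct, dtype=float)
    if np.any(e < 0) or np.any(f < 0):
        raise DomainError("uncertainty components must be >= 0")
    out = np.sqrt(e**2 + f**2)
    return float(out) if out.ndim == 0 else out


def uncertainty_budget(curve: CalibrationCurve, netod, sigma_netod) -> UncertaintyBudget:
    e = experimental_uncertainty_pct(curve, netod, sigma_netod)
    f = fit_uncertainty_pct(curve, netod)
    return UncertaintyBudget(sigma_exp_pct=e, sigma_fit_pct=f,
                             sigma_total_pct=total_uncertainty_pct(e, f))


def deviation_pct(d_bc, d_pw):
    """Relative deviation |D_BC - D_PW| / D_BC * 100 of a dose pair (%)."""
    bc = np.asarray(d_bc, dtype=float)
    pw = np.asarray(d_pw, dtype=float)
    if np.any(bc <= 0):
        raise DomainError("benchmark dose must be > 0")
    out = np.abs(bc - pw) / bc * 100.0
    return float(out) if out.ndim == 0 else out


def invert_dose_response(a: float, b: float, n: float, dose, tol: float = 1e-10,
                         max_iter: int = 200):
    """netOD solving a*netOD + b*netOD^n = dose, by bisection (a, b > 0).

    Vectorised; dose 0 maps to netOD 0 exactly.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise DomainError("dose must be >= 0")
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    lo = np.zeros_like(d)
    hi = np.ones_like(d)
    fwd = lambda x: a * x + b * np.power(x, n)
    grow = 0
    while np.any(fwd(hi) < d):
        hi = np.where(fwd(hi) < d, hi * 2.0, hi)
        grow += 1
        if grow > 60:
            raise DomainError("dose out of invertible range")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        below = fwd(mid) < d
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
        if np.max(hi - lo) < tol:
            break
    out = 0.5 * (lo + hi)
    out[d == 0] = 0.0
    return float(out[0]) if scalar else out


def netod_from_dose(curve: CalibrationCurve, dose, tol: float = 1e-10):
    """Invert the fitted curve (monotone for a, b > 0) by bisection."""
    return invert_dose_response(curve.a, curve.b, curve.n, dose, tol=tol)


@dataclass
class BenchmarkExposure:
    """One uniform-field calibration strip: repeat-scan stacks plus nominal dose."""

    unexposed: list[ScanImage]
    exposed: list[ScanImage]
    background: list[ScanImage]
    dose_gy: float


@dataclass
class BenchmarkResult:
    curve: CalibrationCurve
    points: list[CalibrationPoint]
    budgets: list[UncertaintyBudget]


def benchmark_calibration(strip_sets: list[BenchmarkExposure], n_fixed: float = 2.5,
                          roi_mm=(1.0, 1.0), center_mm=None,
                          weighted: bool = False) -> BenchmarkResult:
    """Full uniform-field calibration chain.

    Each strip set is reduced (median -> average -> Wiener), the 1x1 mm ROI at
    the field centre (raster centre by default) yields a netOD reading with
    uncertainty, and the pooled (netOD, nominal dose) points are fitted.
    Returns the curve plus the per-point uncertainty budgets evaluated on it.
    """
    points = []
    for s in strip_sets:
        u = reduce_scan_stack(s.unexposed)
        e = reduce_scan_stack(s.exposed)
        b = reduce_scan_stack(s.background)
        if center_mm is None:
            nrows, ncols = u.shape
            c = ((ncols // 2) * u.mm_per_px, (nrows // 2) * u.mm_per_px)
        else:
            c = center_mm
        val = netod_from_rois(roi_mean(u, c, roi_mm), roi_mean(e, c, roi_mm),
                              roi_mean(b, c, roi_mm))
        points.append(CalibrationPoint(netod=val.netod, sigma_netod=val.sigma_netod,
                                       dose_gy=s.dose_gy))
    curve = fit_calibration(points, n_fixed=n_fixed, weighted=weighted)
    budgets = [uncertainty_budget(curve, p.netod, p.sigma_netod) for p in points]
    return BenchmarkResult(curve=curve, points=points, budgets=budgets)


def points_to_csv(points: list[CalibrationPoint], path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"netod": [p.netod for p in points],
         "sigma_netod": [p.sigma_netod for p in points],
         "dose_gy": [p.dose_gy for p in points]}
    ).to_csv(path, index=False)


def points_from_csv(path) -> list[CalibrationPoint]:
    import pandas as pd

    df = pd.read_csv(path)
    return [CalibrationPoint(netod=r.netod, sigma_netod=r.sigma_netod, dose_gy=r.dose_gy)
            for r in df.itertuples()]
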