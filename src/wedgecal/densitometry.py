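"""Net optical density (netOD) with first-order uncertainty propagation.

The film's dose-response signal is the net optical density

    netOD = OD_exp - OD_unexp = log10((PV_unexp - PV_bckg) / (PV_exp - PV_bckg))

where PV_unexp / PV_exp are background-corrected pixel values of the film
before / after exposure and PV_bckg is the zero-light (opaque strip) reading.
Its one-standard-deviation uncertainty follows from Gaussian error
propagation of the three pixel-value readings:

    sigma_netOD = (1/ln 10) * sqrt( (s_u^2 + s_b^2) / (PV_u - PV_b)^2
                                  + (s_e^2 + s_b^2) / (PV_e - PV_b)^2 )

The sigma of an ROI reading is taken as the standard deviation of the pixels
inside the ROI (not sd/sqrt(n)) — the conservative convention of the film
dosimetry protocol this pipeline follows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DimensionError, DomainError
from .scan_io import RoiStat, ScanImage, round_half_away

LN10 = float(np.log(10.0))


@dataclass
class NetODValue:
    netod: float
    sigma_netod: float

    def __post_init__(self):
        if not np.isfinite(self.netod):
            raise DomainError("netOD must be finite")
        if self.sigma_netod < 0:
            raise DomainError("sigma_netod must be >= 0")


@dataclass
class NetODProfile:
    """1-D netOD profile along the wedge axis.

    positions_mm are strictly increasing; once the field centre is known they
    are CAX-centred (0 at the beam axis).
    """

    positions_mm: np.ndarray
    netod: np.ndarray
    sigma_netod: np.ndarray

    def __post_init__(self):
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.netod = np.asarray(self.netod, dtype=float)
        self.sigma_netod = np.asarray(self.sigma_netod, dtype=float)
        if not (len(self.positions_mm) == len(self.netod) == len(self.sigma_netod)):
            raise DimensionError("profile arrays must have equal length")
        if len(self.positions_mm) > 1 and not np.all(np.diff(self.positions_mm) > 0):
            raise DimensionError("profile positions must be strictly increasing")
        if np.any(self.sigma_netod < 0):
            raise DomainError("sigma_netod must be >= 0")

    def __len__(self):
        return len(self.positions_mm)

    def slice(self, start: int, stop: int) -> "NetODProfile":
        return NetODProfile(self.positions_mm[start:stop], self.netod[start:stop],
                            self.sigma_netod[start:stop])

    def shifted(self, offset_mm: float) -> "NetODProfile":
        return NetODProfile(self.positions_mm + offset_mm, self.netod, self.sigma_netod)

    def mirrored(self) -> "NetODProfile":
        """Flip the spatial axis (x -> -x), keeping positions increasing."""
        return NetODProfile((-self.positions_mm)[::-1], self.netod[::-1],
                            self.sigma_netod[::-1])

    def to_csv(self, path) -> None:
        pd.DataFrame({"position_mm": self.positions_mm, "netod": self.netod,
                      "sigma_netod": self.sigma_netod}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "NetODProfile":
        df = pd.read_csv(path)
        return cls(df["position_mm"].to_numpy(), df["netod"].to_numpy(),
                   df["sigma_netod"].to_numpy())


@dataclass
class NetODMap:
    """2-D netOD raster with per-pixel uncertainty and validity mask."""

    netod: np.ndarray
    sigma_netod: np.ndarray
    dpi: float
    valid: np.ndarray

    @property
    def mm_per_px(self) -> float:
        return 25.4 / self.dpi

    @property
    def shape(self):
        return self.netod.shape


def net_optical_density(pv_unexp, pv_exp, pv_bckg):
    """netOD of background-corrected pixel values (scalar or array).

    Raises DomainError when either background-corrected value is <= 0
    (saturated or over-dark film, or a bad background reading).
    """
    num = np.asarray(pv_unexp, dtype=float) - np.asarray(pv_bckg, dtype=float)
    den = np.asarray(pv_exp, dtype=float) - np.asarray(pv_bckg, dtype=float)
    if np.any(num <= 0) or np.any(den <= 0):
        raise DomainError(
            "background-corrected pixel values must be positive "
            f"(got numerator {np.min(num)}, denominator {np.min(den)})"
        )
    out = np.log10(num / den)
    return float(out) if out.ndim == 0 else out


def netod_uncertainty(pv_unexp, sd_unexp, pv_exp, sd_exp, pv_bckg, sd_bckg):
    """One-sigma netOD uncertainty from the three PV readings and their sds."""
    pv_unexp = np.asarray(pv_unexp, dtype=float)
    pv_exp = np.asarray(pv_exp, dtype=float)
    pv_bckg = np.asarray(pv_bckg, dtype=float)
    sd_unexp = np.asarray(sd_unexp, dtype=float)
    sd_exp = np.asarray(sd_exp, dtype=float)
    sd_bckg = np.asarray(sd_bckg, dtype=float)
    if np.any(sd_unexp < 0) or np.any(sd_exp < 0) or np.any(sd_bckg < 0):
        raise DomainError("standard deviations must be >= 0")
    num = pv_unexp - pv_bckg
    den = pv_exp - pv_bckg
    if np.any(num <= 0) or np.any(den <= 0):
        raise DomainError("background-corrected pixel values must be positive")
    out = (1.0 / LN10) * np.sqrt(
        (sd_unexp**2 + sd_bckg**2) / num**2 + (sd_exp**2 + sd_bckg**2) / den**2
    )
    return float(out) if out.ndim == 0 else out


def netod_from_rois(unexp: RoiStat, exp: RoiStat, bckg: RoiStat) -> NetODValue:
    """netOD value with uncertainty from three ROI statistics."""
    return NetODValue(
        netod=net_optical_density(unexp.mean_pv, exp.mean_pv, bckg.mean_pv),
        sigma_netod=netod_uncertainty(unexp.mean_pv, unexp.sd_pv, exp.mean_pv,
                                      exp.sd_pv, bckg.mean_pv, bckg.sd_pv),
    )


def local_sd(pixels: np.ndarray, size: int) -> np.ndarray:
    """Per-pixel standard deviation over a square neighbourhood (reflect padded)."""
    a = np.asarray(pixels, dtype=float)
    mean = ndimage.uniform_filter(a, size=size, mode="reflect")
    sqmean = ndimage.uniform_filter(a * a, size=size, mode="reflect")
    return np.sqrt(np.maximum(sqmean - mean * mean, 0.0))


def netod_map(unexp: ScanImage, exp: ScanImage, bckg: ScanImage,
              roi_mm: float = 1.0) -> NetODMap:
    """Element-wise netOD raster with per-pixel uncertainty.

    Pixels violating the netOD domain (e.g. saturated film, PV_exp <= PV_bckg)
    are masked as invalid (NaN), not fatal: wedge extraction only needs the
    central band of the strip and this keeps the pipeline robust to dust and
    scratch artefacts.  Per-pixel sigma uses the local ROI standard deviation
    over a ``roi_mm`` x ``roi_mm`` neighbourhood of each reduced raster.
    """
    if unexp.shape != exp.shape or unexp.shape != bckg.shape:
        raise DimensionError(
            f"raster shapes differ: {unexp.shape}, {exp.shape}, {bckg.shape}"
        )
    if not (unexp.dpi == exp.dpi == bckg.dpi):
        raise DimensionError("raster dpi differ")
    num = unexp.pixels - bckg.pixels
    den = exp.pixels - bckg.pixels
    valid = (num > 0) & (den > 0)
    netod = np.full(unexp.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        netod[valid] = np.log10(num[valid] / den[valid])

    w = max(1, round_half_away(roi_mm / unexp.mm_per_px))
    s_u = local_sd(unexp.pixels, w)
    s_e = local_sd(exp.pixels, w)
    s_b = local_sd(bckg.pixels, w)
    sigma = np.full(unexp.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma[valid] = (1.0 / LN10) * np.sqrt(
            (s_u[valid] ** 2 + s_b[valid] ** 2) / num[valid] ** 2
            + (s_e[valid] ** 2 + s_b[valid] ** 2) / den[valid] ** 2
        )
    return NetODMap(netod=netod, sigma_netod=sigma, dpi=unexp.dpi, valid=valid)
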