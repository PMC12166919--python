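"""Reading, writing and reduction of flatbed-scanner film images.

Film strips are digitised in transmission mode as RGB TIFF images (16 bits
per channel, typically 127 dpi).  Only one colour channel — red for EBT3-type
film — carries the dosimetric signal.  A scan *stack* (the same strip scanned
several times in a row) is reduced to a single clean raster by per-scan
median filtering, pixel-wise averaging across the stack and a final adaptive
Wiener filter, after which small regions of interest are summarised by their
mean and standard deviation.

Package-wide pixel/position convention: ``position_mm = index * 25.4 / dpi``,
0-based, origin at the raster corner; x runs along columns, y along rows.
Beam-centred (CAX) coordinates are obtained downstream by subtracting the
detected field centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .errors import BoundsError, DimensionError, DomainError, FormatError

MM_PER_INCH = 25.4
PV_MAX = 65535

CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}
ROLES = ("unexposed", "exposed", "background")


def round_half_away(x):
    """Round to nearest integer, halves away from zero (dpi-exact at 127 dpi)."""
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    if out.ndim == 0:
        return int(out)
    return out.astype(int)


@dataclass
class ScanImage:
    """Single-channel scanner raster with resolution metadata.

    Pixel values are stored as floats internally (stack averaging is done in
    floating point); they are rounded to 16-bit integers only when written
    back to disk.
    """

    pixels: np.ndarray
    dpi: float
    channel: str = "red"
    role: str = "exposed"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise DimensionError(
                f"raster must be 2-D with >= 2 rows and columns, got shape {self.pixels.shape}"
            )
        if self.dpi <= 0:
            raise FormatError(f"dpi must be positive, got {self.dpi}")
        if self.channel not in CHANNEL_INDEX:
            raise FormatError(f"unknown channel {self.channel!r}")
        if self.role not in ROLES:
            raise FormatError(f"unknown role {self.role!r}")
        if np.nanmin(self.pixels) < 0 or np.nanmax(self.pixels) > PV_MAX:
            raise FormatError("pixel values outside the 16-bit range [0, 65535]")

    @property
    def mm_per_px(self) -> float:
        return MM_PER_INCH / self.dpi

    @property
    def shape(self):
        return self.pixels.shape

    def positions_mm(self, axis: str = "x") -> np.ndarray:
        """Physical coordinates of pixel centres along ``axis`` ('x' = columns)."""
        n = self.pixels.shape[1] if axis == "x" else self.pixels.shape[0]
        return np.arange(n) * self.mm_per_px


@dataclass
class RoiStat:
    """Mean/standard deviation summary of the pixel values inside an ROI."""

    mean_pv: float
    sd_pv: float
    n_px: int

    def __post_init__(self):
        if self.sd_pv < 0 or self.n_px < 1:
            raise DomainError(f"invalid ROI statistic {self}")


def load_scan(path, channel: str = "red", role: str = "exposed",
              fallback_dpi: float | None = None) -> ScanImage:
    """Load one colour channel of an RGB TIFF scan.

    dpi is read from the TIFF resolution tags; ``fallback_dpi`` is used when
    the file carries no resolution metadata.  8-bit files are promoted to the
    16-bit scale by multiplying with 257.
    """
    path = Path(path)
    if channel not in CHANNEL_INDEX:
        raise FormatError(f"unknown channel {channel!r}")
    if not path.exists():
        raise FormatError(f"scan file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            arr = page.asarray()
            dpi = _dpi_from_tags(page)
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"not a readable TIFF: {path} ({exc})") from exc
    if arr.ndim != 3 or arr.shape[-1] < 3:
        raise FormatError(f"expected an RGB TIFF, got array shape {arr.shape}")
    plane = arr[..., CHANNEL_INDEX[channel]]
    if plane.dtype == np.uint8:
        plane = plane.astype(float) * 257.0
    else:
        plane = plane.astype(float)
    if dpi is None:
        dpi = fallback_dpi
    if dpi is None:
        raise FormatError(f"no resolution metadata in {path} and no fallback dpi given")
    return ScanImage(pixels=plane, dpi=float(dpi), channel=channel, role=role)


def _dpi_from_tags(page) -> float | None:
    tags = page.tags
    if "XResolution" not in tags:
        return None
    num, den = tags["XResolution"].value
    if den == 0:
        return None
    res = num / den
    unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else 2
    unit = int(unit)
    if unit == 1:  # RESUNIT.NONE: resolution undefined
        return None
    if unit == 3:  # pixels per centimetre
        res *= 2.54
    if res <= 1:  # placeholder written by some encoders
        return None
    return float(res)


def save_scan(image: ScanImage, path) -> None:
    """Write a ScanImage as a 16-bit RGB TIFF (channel replicated to all planes).

    Floating-point pixel values are rounded to the nearest 16-bit integer at
    this point only.
    """
    path = Path(path)
    pv = np.clip(np.rint(image.pixels), 0, PV_MAX).astype(np.uint16)
    rgb = np.stack([pv, pv, pv], axis=-1)
    tifffile.imwrite(
        path,
        rgb,
        photometric="rgb",
        resolution=(image.dpi, image.dpi),
        resolutionunit="INCH",
    )


def wiener_filter(pixels: np.ndarray, size: int = 7) -> np.ndarray:
    """Adaptive (local linear MMSE) Wiener filter with reflect border padding.

    Local mean/variance are estimated over a ``size`` x ``size`` window; the
    noise power is the spatial average of the local variances, as in the
    classical adaptive Wiener filter.  Reflect padding avoids the border
    darkening that zero padding would imprint on strip edges.
    """
    if size < 1 or size % 2 == 0:
        raise DimensionError(f"Wiener window must be odd and >= 1, got {size}")
    a = np.asarray(pixels, dtype=float)
    mean = ndimage.uniform_filter(a, size=size, mode="reflect")
    sqmean = ndimage.uniform_filter(a * a, size=size, mode="reflect")
    var = np.maximum(sqmean - mean * mean, 0.0)
    noise = var.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        gain = np.where(var > noise, (var - noise) / np.where(var > 0, var, 1.0), 0.0)
    return mean + gain * (a - mean)


def reduce_scan_stack(scans: list[ScanImage], median_size: int = 3,
                      wiener_size: int = 7) -> ScanImage:
    """Reduce repeat scans of one strip to a single clean raster.

    Each scan is 3x3 median filtered (impulse noise), the stack is averaged
    pixel-wise, and the average is passed through an adaptive Wiener filter
    with a 7x7 window.  All filters use reflect padding.
    """
    if len(scans) < 1:
        raise DimensionError("empty scan stack")
    first = scans[0]
    for s in scans[1:]:
        if s.shape != first.shape:
            raise DimensionError(f"scan shape mismatch: {s.shape} vs {first.shape}")
        if s.dpi != first.dpi or s.channel != first.channel or s.role != first.role:
            raise DimensionError("scan stack mixes dpi/channel/role")
    med = [ndimage.median_filter(s.pixels, size=median_size, mode="reflect") for s in scans]
    avg = np.mean(med, axis=0)
    out = wiener_filter(avg, size=wiener_size)
    out = np.clip(out, 0, PV_MAX)
    return replace(first, pixels=out)


def roi_bounds_px(image: ScanImage, center_mm, roi_mm):
    """Convert an mm-specified ROI to pixel slices (row_slice, col_slice).

    The centre is snapped to the nearest pixel centre and the ROI size is
    rounded to whole pixels (half away from zero, minimum 1).  Even-sized
    windows keep the extra pixel on the low-index side.
    """
    cx_mm, cy_mm = center_mm
    w_mm, h_mm = roi_mm
    px = image.mm_per_px
    cx = round_half_away(cx_mm / px)
    cy = round_half_away(cy_mm / px)
    w = max(1, round_half_away(w_mm / px))
    h = max(1, round_half_away(h_mm / px))
    c0 = cx - w // 2
    r0 = cy - h // 2
    nrows, ncols = image.shape
    if r0 < 0 or c0 < 0 or r0 + h > nrows or c0 + w > ncols:
        raise BoundsError(
            f"ROI rows {r0}:{r0 + h}, cols {c0}:{c0 + w} outside raster {image.shape}"
        )
    return slice(r0, r0 + h), slice(c0, c0 + w)


def roi_mean(image: ScanImage, center_mm, roi_mm) -> RoiStat:
    """Mean and (population) standard deviation of PV over an mm-specified ROI."""
    rs, cs = roi_bounds_px(image, center_mm, roi_mm)
    block = image.pixels[rs, cs]
    return RoiStat(mean_pv=float(block.mean()), sd_pv=float(block.std()),
                   n_px=int(block.size))


def image_to_csv(image: ScanImage, path) -> None:
    """Export a raster as long-format CSV with columns x_mm, y_mm, pv."""
    nrows, ncols = image.shape
    x = image.positions_mm("x")
    y = image.positions_mm("y")
    xx, yy = np.meshgrid(x, y)
    pd.DataFrame(
        {"x_mm": xx.ravel(), "y_mm": yy.ravel(), "pv": image.pixels.ravel()}
    ).to_csv(path, index=False)
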