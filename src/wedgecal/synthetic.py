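"""Synthetic film-scan study generator.

Emulates the full experimental study this pipeline is built for: EBT3-type
film strips exposed to 6 MV 15x15 cm2 open uniform fields (1-5.5 Gy, the
benchmark calibration) and to 60 degree physical-wedge fields (CAX doses
1-5 Gy), each strip scanned five times before and after irradiation on a
127 dpi flatbed scanner together with zero-light background scans.

The generator owns a ground-truth netOD->dose curve (same polynomial form
the pipeline fits), a parametric wedge profile, a repeat-scan Gaussian noise
model and a low-frequency film-sensitivity nonuniformity field, so every
pipeline stage can be validated against a configured truth.  All randomness
flows through one seeded generator: equal seeds give byte-identical output.

The wedge profile is a parametric stand-in, not a replica of any measured
water-tank profile: an exponential lateral transmission factor (uniform
wedge material, thickness linear in x) with penumbral sigmoid roll-offs and
a scatter floor outside the field.  Its dynamic range across the trimmed
central 60 % of the field defaults to 3, so a single 5 Gy exposure spans
roughly 2.9-8.7 Gy.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .calibration import BenchmarkExposure, dose_response, invert_dose_response
from .errors import ConfigError, DimensionError
from .scan_io import MM_PER_INCH, PV_MAX, ScanImage, load_scan, save_scan
from .wedge import FieldGeometry, WedgeExposure, WedgeReference

BENCHMARK_DOSES_GY = tuple(np.round(np.arange(1.0, 5.51, 0.5), 3))
WEDGE_DCAX_GY = (1.0, 2.0, 3.0, 4.0, 5.0)


@dataclass
class GroundTruthConfig:
    """Full ground truth of a simulated study.

    Noise defaults are tuned to the uncertainty regime of a well-warmed-up
    flatbed scanner and five repeat scans, where the benchmark total dose
    uncertainty stays below 2 % above 1 Gy.
    """

    true_a: float = 10.0          # Gy, linear response coefficient
    true_b: float = 40.0          # Gy, power-term coefficient
    true_n: float = 2.5           # fixed exponent
    pv_unexp_mean: float = 40000.0
    pv_bckg_mean: float = 1000.0
    pixel_noise_rel: float = 0.005      # per-scan Gaussian sd as fraction of PV
    film_nonuniformity_rel: float = 0.003  # sd of the correlated base-PV field
    nonuniformity_corr_mm: float = 50.0    # correlation length of that field
    n_repeat_scans: int = 5
    dpi: float = 127.0
    seed: int = 0
    geometry: FieldGeometry = field(default_factory=FieldGeometry)
    attenuation_cax: float = 0.2654
    penumbra_mm: float = 5.0            # 80-20 % penumbra width
    scatter_floor_rel: float = 0.02     # out-of-field dose fraction of CAX
    wedge_dynamic_range: float = 3.0    # profile ratio across the trimmed 60 %
    strip_width_mm: float = 25.4
    strip_length_mm: float = 203.2
    benchmark_doses_gy: tuple = BENCHMARK_DOSES_GY
    wedge_doses_gy: tuple = WEDGE_DCAX_GY

    def __post_init__(self):
        if self.true_a <= 0 or self.true_b <= 0:
            raise ConfigError("true_a and true_b must be > 0")
        if self.true_n <= 1:
            raise ConfigError("true_n must be > 1")
        if not 0 < self.attenuation_cax < 1:
            raise ConfigError("attenuation_cax must lie in (0, 1)")
        if self.pixel_noise_rel < 0 or self.film_nonuniformity_rel < 0:
            raise ConfigError("noise levels must be >= 0")
        if self.dpi <= 0:
            raise ConfigError("dpi must be > 0")

    @property
    def mm_per_px(self) -> float:
        return MM_PER_INCH / self.dpi

    def raster_shape(self) -> tuple[int, int]:
        nrows = int(round(self.strip_width_mm / self.mm_per_px))
        ncols = int(round(self.strip_length_mm / self.mm_per_px))
        return nrows, ncols

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"] = self.geometry.to_dict()
        d["benchmark_doses_gy"] = [float(v) for v in self.benchmark_doses_gy]
        d["wedge_doses_gy"] = [float(v) for v in self.wedge_doses_gy]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthConfig":
        d = dict(d)
        d["geometry"] = FieldGeometry.from_dict(d["geometry"])
        d["benchmark_doses_gy"] = tuple(d["benchmark_doses_gy"])
        d["wedge_doses_gy"] = tuple(d["wedge_doses_gy"])
        return cls(**d)


def truth_dose_from_netod(cfg: GroundTruthConfig, netod):
    return dose_response(netod, cfg.true_a, cfg.true_b, cfg.true_n)


def truth_netod_from_dose(cfg: GroundTruthConfig, dose, tol: float = 1e-10):
    """Invert the ground-truth response by bisection (0 maps to 0 exactly)."""
    return invert_dose_response(cfg.true_a, cfg.true_b, cfg.true_n, dose, tol=tol)


def wedge_profile_rel(cfg: GroundTruthConfig, x_mm):
    """Normalised lateral wedge dose profile p(x), p(0) = 1.

    Inside the field, transmission falls exponentially toward the thick end
    (+x) of the wedge; the field borders roll off as logistic sigmoids with
    the configured 80-20 penumbra width; outside, a flat scatter floor
    remains.
    """
    x = np.asarray(x_mm, dtype=float)
    span = cfg.geometry.projected_span_mm
    half = span / 2.0
    k = np.log(cfg.wedge_dynamic_range) / (0.6 * span)
    s = cfg.penumbra_mm / (2.0 * np.log(4.0))
    wedge = np.exp(-k * x)
    env = _sigmoid((x + half) / s) * _sigmoid((half - x) / s)
    prof = wedge * env + cfg.scatter_floor_rel * (1.0 - env)
    cax = 1.0 * _sigmoid(half / s) ** 2 + cfg.scatter_floor_rel * (1.0 - _sigmoid(half / s) ** 2)
    out = prof / cax
    return float(out) if out.ndim == 0 else out


def open_profile_rel(cfg: GroundTruthConfig, x_mm):
    """Normalised open (unwedged) field profile: flat top with penumbra."""
    x = np.asarray(x_mm, dtype=float)
    span = cfg.geometry.projected_span_mm
    half = span / 2.0
    s = cfg.penumbra_mm / (2.0 * np.log(4.0))
    env = _sigmoid((x + half) / s) * _sigmoid((half - x) / s)
    prof = env + cfg.scatter_floor_rel * (1.0 - env)
    cax = _sigmoid(half / s) ** 2 + cfg.scatter_floor_rel * (1.0 - _sigmoid(half / s) ** 2)
    out = prof / cax
    return float(out) if out.ndim == 0 else out


def _sigmoid(t):
    return 1.0 / (1.0 + np.exp(-np.asarray(t, dtype=float)))


def make_reference(cfg: GroundTruthConfig, step_mm: float = 0.5) -> WedgeReference:
    """Emit the generator's own wedge profile as the measured reference.

    The grid extends a little beyond the strip so any strip position can be
    interpolated.
    """
    half_support = cfg.strip_length_mm / 2.0 + 2.0
    n = int(np.floor(half_support / step_mm))
    pos = np.arange(-n, n + 1) * step_mm
    return WedgeReference(positions_mm=pos, dose_rel=wedge_profile_rel(cfg, pos),
                          attenuation_cax=cfg.attenuation_cax,
                          geometry=cfg.geometry)


def _strip_x_mm(cfg: GroundTruthConfig, translation_mm: float = 0.0) -> np.ndarray:
    """CAX-centred x of each column; the CAX sits exactly on the centre pixel."""
    _, ncols = cfg.raster_shape()
    center_col = ncols // 2
    return (np.arange(ncols) - center_col) * cfg.mm_per_px - translation_mm


def wedge_dose_field(cfg: GroundTruthConfig, d_cax_gy: float,
                     translation_mm: float = 0.0):
    """2-D wedge dose raster plus the exact 1-D reference profile it uses.

    The gradient runs along columns (x); the transverse direction is flat
    because the narrow strip sits well inside the field.  ``translation_mm``
    shifts the field along the strip (film positioning error).
    """
    nrows, ncols = cfg.raster_shape()
    span = cfg.geometry.projected_span_mm
    if cfg.strip_length_mm < span * 0.6 + 2 * cfg.penumbra_mm:
        raise DimensionError("strip too short to cover the field's usable region")
    x = _strip_x_mm(cfg, translation_mm)
    prof = d_cax_gy * wedge_profile_rel(cfg, x)
    raster = np.tile(prof, (nrows, 1))
    return raster, make_reference(cfg)


def open_dose_field(cfg: GroundTruthConfig, dose_gy: float,
                    translation_mm: float = 0.0) -> np.ndarray:
    """2-D uniform-field dose raster (flat top, penumbral edges)."""
    nrows, ncols = cfg.raster_shape()
    x = _strip_x_mm(cfg, translation_mm)
    prof = dose_gy * open_profile_rel(cfg, x)
    return np.tile(prof, (nrows, 1))


def _nonuniformity_field(cfg: GroundTruthConfig, shape,
                         rng: np.random.Generator) -> np.ndarray:
    """Correlated zero-mean Gaussian field with sd = film_nonuniformity_rel."""
    if cfg.film_nonuniformity_rel == 0:
        return np.zeros(shape)
    sigma_px = 0.5 * cfg.nonuniformity_corr_mm / cfg.mm_per_px
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=sigma_px, mode="reflect")
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return smooth / sd * cfg.film_nonuniformity_rel


def render_scan_triplet(cfg: GroundTruthConfig, dose_raster: np.ndarray,
                        rng: np.random.Generator | None = None):
    """Render (unexposed, exposed, background) repeat-scan stacks for one film.

    The film's base optical density varies smoothly across each strip (the
    correlated nonuniformity field multiplies the unexposed pixel value);
    because the same film is scanned before and after irradiation, this base
    variation largely cancels in netOD — which is the rationale of the
    before/after protocol.  Each repeat scan adds independent Gaussian noise
    with sd = pixel_noise_rel * PV, clipped to the 16-bit range.  Pixel
    values stay floating point in memory; quantisation to integers happens
    when the rasters are written to TIFF.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    dose_raster = np.asarray(dose_raster, dtype=float)
    nonuni = _nonuniformity_field(cfg, dose_raster.shape, rng)
    base = cfg.pv_unexp_mean * (1.0 + nonuni)
    netod_true = truth_netod_from_dose(cfg, dose_raster)
    exposed_clean = cfg.pv_bckg_mean + (base - cfg.pv_bckg_mean) * 10.0 ** (-netod_true)
    bckg_clean = np.full(dose_raster.shape, cfg.pv_bckg_mean)

    def scans(clean, role):
        out = []
        for _ in range(cfg.n_repeat_scans):
            pv = clean + rng.normal(0.0, cfg.pixel_noise_rel * clean)
            pv = np.clip(pv, 0.0, PV_MAX)
            out.append(ScanImage(pixels=pv, dpi=cfg.dpi, channel="red", role=role))
        return out

    return scans(base, "unexposed"), scans(exposed_clean, "exposed"), scans(bckg_clean, "background")


@dataclass
class StudyDataset:
    """One simulated study: benchmark strips, wedge strips, reference, truth."""

    config: GroundTruthConfig
    benchmark: list[BenchmarkExposure]
    wedge: list[WedgeExposure]
    reference: WedgeReference


def simulate_study(cfg: GroundTruthConfig, out_dir=None) -> StudyDataset:
    """Generate the full study (10 benchmark + 5 wedge strips by default).

    With ``out_dir`` given, the dataset is also written to disk: TIFF scan
    triplets, the reference profile as CSV + YAML sidecar, and a JSON
    manifest holding the complete ground-truth configuration.
    """
    rng = np.random.default_rng(cfg.seed)
    reference = make_reference(cfg)
    benchmark = []
    for dose in cfg.benchmark_doses_gy:
        u, e, b = render_scan_triplet(cfg, open_dose_field(cfg, dose), rng)
        benchmark.append(BenchmarkExposure(unexposed=u, exposed=e, background=b,
                                           dose_gy=float(dose)))
    wedge = []
    for d_cax in cfg.wedge_doses_gy:
        raster, _ = wedge_dose_field(cfg, d_cax)
        u, e, b = render_scan_triplet(cfg, raster, rng)
        wedge.append(WedgeExposure(unexposed=u, exposed=e, background=b,
                                   d_cax_gy=float(d_cax), axis="x"))
    ds = StudyDataset(config=cfg, benchmark=benchmark, wedge=wedge,
                      reference=reference)
    if out_dir is not None:
        write_study(ds, out_dir)
    return ds


def _write_stack(scans, directory: Path, stem: str):
    paths = []
    for i, s in enumerate(scans, start=1):
        p = directory / f"{stem}_{i:02d}.tif"
        save_scan(s, p)
        paths.append(p.name)
    return paths


def write_study(ds: StudyDataset, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": ds.config.to_dict(),
                "reference": {"csv": "reference.csv", "yaml": "reference.yaml"},
                "benchmark": [], "wedge": []}
    ds.reference.to_files(out / "reference.csv", out / "reference.yaml")
    for expo in ds.benchmark:
        sub = out / "benchmark" / f"d{expo.dose_gy:.1f}"
        sub.mkdir(parents=True, exist_ok=True)
        entry = {"dose_gy": expo.dose_gy, "dir": str(sub.relative_to(out))}
        for role, scans in (("unexposed", expo.unexposed), ("exposed", expo.exposed),
                            ("background", expo.background)):
            entry[role] = _write_stack(scans, sub, role)
        manifest["benchmark"].append(entry)
    for expo in ds.wedge:
        sub = out / "wedge" / f"d{expo.d_cax_gy:.1f}"
        sub.mkdir(parents=True, exist_ok=True)
        entry = {"d_cax_gy": expo.d_cax_gy, "axis": expo.axis,
                 "dir": str(sub.relative_to(out))}
        for role, scans in (("unexposed", expo.unexposed), ("exposed", expo.exposed),
                            ("background", expo.background)):
            entry[role] = _write_stack(scans, sub, role)
        manifest["wedge"].append(entry)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


def load_study(directory) -> StudyDataset:
    """Load a study dataset previously written by :func:`write_study`."""
    root = Path(directory)
    with open(root / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg = GroundTruthConfig.from_dict(manifest["config"])
    reference = WedgeReference.from_files(root / manifest["reference"]["csv"],
                                          root / manifest["reference"]["yaml"])

    def stack(entry, role):
        sub = root / entry["dir"]
        return [load_scan(sub / name, channel="red", role=role,
                          fallback_dpi=cfg.dpi) for name in entry[role]]

    benchmark = [BenchmarkExposure(unexposed=stack(e, "unexposed"),
                                   exposed=stack(e, "exposed"),
                                   background=stack(e, "background"),
                                   dose_gy=e["dose_gy"])
                 for e in manifest["benchmark"]]
    wedge = [WedgeExposure(unexposed=stack(e, "unexposed"),
                           exposed=stack(e, "exposed"),
                           background=stack(e, "background"),
                           d_cax_gy=e["d_cax_gy"], axis=e.get("axis", "x"))
             for e in manifest["wedge"]]
    return StudyDataset(config=cfg, benchmark=benchmark, wedge=wedge,
                        reference=reference)
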