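# wedgecal

Radiochromic-film calibration from physical-wedge dose gradients.

## The problem

Film dosimetry with radiochromic film (EBT3-class) needs a fresh calibration
for every batch — conventionally ten or more strips exposed one by one to
uniform fields at known doses, scanned, and fitted. A physical wedge (PW)
offers a shortcut: one exposure under a 60° wedge imprints a known lateral
dose gradient on a single strip, providing hundreds of calibration points at
once. If the wedge's normalised dose profile p(x) (p(0) = 1 on the central
axis) and its CAX transmission are measured once in reference conditions,
the dose at every film position is simply D_CAX·p(x).

`wedgecal` implements the complete chain for both routes and validates the
wedge route against the conventional benchmark on a synthetic study replica:

* **scan_io** — RGB TIFF scan I/O (16 bit, dpi metadata), stack reduction
  (per-scan 3×3 median → average → adaptive 7×7 Wiener), mm-specified ROIs;
* **densitometry** — net optical density
  `netOD = log10((PV_unexp−PV_bckg)/(PV_exp−PV_bckg))` with first-order
  uncertainty propagation, as values, maps and profiles;
* **calibration** — the response `D = a·netOD + b·netOD^n` (n fixed at 2.5)
  fitted by Levenberg–Marquardt; experimental/fit/total relative dose
  uncertainty budgets; benchmark deviation `|D_BC−D_PW|/D_BC·100 %`;
* **wedge** — profile extraction (central-line averaging, gradient-based
  field-edge segmentation, divergence-aware length check, 20–80 % penumbra
  trim, moving-mean smoothing, monotone extraction), registration to the
  reference profile, dose pairing, single-/multi-gradient and extrapolated
  calibration, wedge transmission and MU bookkeeping;
* **synthetic** — a seeded study-replica generator (film strips, repeat-scan
  noise, base-density nonuniformity, wedge and open fields) so every stage
  is testable against a configured ground truth;
* **cli** — the `wedgecal` command-line tool.

See `docs/methods.md` for the model, numerical choices and limitations.

## Worked example

```bash
# 1. generate a synthetic study (10 benchmark + 5 wedge strips)
wedgecal simulate --out study --seed 7

# 2. fit the benchmark calibration
wedgecal calibrate-benchmark --dataset study --out bench

# 3. fit a wedge calibration from the 1, 2 and 5 Gy gradients and
#    compare it with the benchmark
wedgecal calibrate-wedge --dataset study --out pw --exposures 1,2,5 \
    --benchmark bench/benchmark_curve.json
```

Logged output of steps 2–3 (abridged):

```
benchmark fit: a=9.9917 Gy b=40.0449 Gy n=2.50
wedge fit on 1428 points: a=10.0110 Gy b=39.8552 Gy
max deviation from benchmark: 0.127 % (in-domain: 0.127 %)
```

The benchmark fit recovers the generator's ground truth (a = 10 Gy,
b = 40 Gy) from the ten uniform-field strips; the wedge fit reaches the same
curve from three strips' pooled gradient points (`wedge_points.csv`), and
`deviation_report.csv` lists the per-point deviation at the ten benchmark
netOD values with an `extrapolated` flag for points outside the fitted
netOD range. Python API equivalents live in `wedgecal.study`
(`simulate_study` → `analyze_study` → `benchmark_reference_points` /
`compare_to_benchmark`).

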