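# adlsfc — anti-diffraction light-sheet flow cytometry

`adlsfc` is a toolkit for a flow-cytometry modality in which the laser
interrogation point is not a focused spot but a thin, wide **anti-diffraction
light sheet** built from an array of Bessel–Gaussian beams. A particle
carried through the sheet by a hydrodynamically focused jet produces a
fluorescence pulse whose duration encodes its size: for a sheet of thickness
`ds` and a particle of diameter `dp` moving at speed `up`, the pulse
full width at half maximum is `τ = (dp + ds)/up`, so

```
dp = up · τ − ds          (sizing inversion)
up = k · Qall / (h · wch) (jet speed; Qall = Qj + 2 Qs)
Re = ρ · Um · Dh / μ      (channel Reynolds number, Dh = 2 h wch /(h + wch))
```

This lets a cytometer with a 0.8 µm sheet and 500 kHz sampling size objects
from O(100 nm) to ~10 µm from a single PMT trace — information a
conventional forward/side-scatter instrument discards.

The package covers the full chain, each stage usable on its own:

| stage | module | what it does |
|---|---|---|
| optics | `adlsfc.optics` | SLM phase synthesis (blazed grating + axicon, stripe-split multiplexing), vector/scalar Debye focusing by FFT, sheet FWHM metrology, axicon calibration |
| microfluidics | `adlsfc.microfluidics` | Reynolds number, jet speed models, FWHM→diameter inversion |
| simulation | `adlsfc.simulate` | seeded synthetic PMT traces: Poisson arrivals, flat-top/Gaussian pulses, PMT gain, 16-bit ADC with saturation, noise |
| detection | `adlsfc.pipeline` | five-step pulse pipeline: band-pass + threshold → moving-average smoothing + peak search → edge-interpolated FWHM → width gate → per-event diameter |
| population | `adlsfc.population` | 2D probability density over (dp, Ifp), two-population ratio β, detection efficiency δ, size-fraction tables |
| orchestration | `adlsfc.config`, `adlsfc.cli` | YAML run configs, end-to-end runs, `adls` command-line verbs |

## Worked example

Sizing two measured pulse widths at the default bench point
(Qj = Qs = 1 µL/h in a 10 × 50 µm chamber, 0.8 µm sheet):

```sh
$ python examples/flow_and_sizing.py
hydraulic diameter : 16.67 um
mean velocity      : 1.667 mm/s
Reynolds number    : 2.778e-02  (laminar)
pulse FWHM 1.13 ms -> particle diameter 1.08 um
pulse FWHM 3.46 ms -> particle diameter 4.97 um
```

The Reynolds number ~2.8×10⁻² confirms laminar flow; the 1.13 ms pulse is a
~1.1 µm micropillar and the 3.46 ms pulse a ~5 µm microsphere.

A full simulate→detect round trip (`examples/simulate_and_detect.py`):

```
injected 178 micropillars into a 20 s trace (10000000 samples)
detected 178 pulses -> efficiency 100.0%
mean diameter: true 0.647 um, estimated 0.670 um
```

Sheet synthesis (`examples/synthesize_sheet.py`) calibrates the axicon
slope so the single-beam Bessel core is 0.8 µm wide, then builds the
nine-beam stripe-multiplexed sheet:

```
calibrated axicon slope tan(alpha) = 2.941e-03
core FWHM variation over the Gaussian-doubling range: 9.4%
(an equal-waist Gaussian focus broadens by 100%)
sheet: 14.4 um wide, 0.95 um thick (SD 0.42 um) across the sampled z-range
```

The core width changes by under 10% over an axial range in which an
ordinary Gaussian focus of the same waist doubles — the anti-diffraction
property that lets one thin sheet span the whole jet.

Other examples: `mixture_analysis.py` (β-ratio recovery of a
pillar/sphere mixture with ADC saturation), `resolution_sweep.py`
(minimum resolvable pulse interval → maximum count rate ≥ 10⁴ events/s).

## Command line

```sh
adls optics   --config run.yaml --out sheet_out/     # phase map + metrics
adls simulate --config run.yaml --out trace.h5       # synthetic trace
adls detect   --trace trace.h5  --out events.csv     # pulse pipeline
adls analyze  --events events.csv --out report.json  # population stats
adls run      --config run.yaml                      # end-to-end
adls resolve-dt                                      # Δτ sweep
```

An empty config file means "all defaults"; every run writes a manifest
with the seed and effective configuration for reproducibility.

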