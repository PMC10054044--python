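# Methods

This note records the models implemented in `adlsfc`, the defaults chosen
where the physical system leaves freedom, and what the synthetic-data tests
do and do not demonstrate.

## Optical model

### Pupil and focusing

The sheet is synthesized on a phase-only SLM conjugate to the objective
pupil. The pupil grid (default 512², aperture radius R = 2.5 mm occupying
one quarter of the grid half-width, i.e. fourfold zero padding) maps pupil
radius r to a convergence angle θ = arcsin(r·NA/(R·nt)) and to transverse
wavenumber kr = k·sinθ, k = 2π·nt/λ. Per axial plane z the focused field is
the inverse FFT of

    P = A · e^{iΦ} · p(θ) · e^{i kz z} / cosθ ,   kz = √(k² − kr²),

the Fourier form of the Debye integral. Defaults: λ = 473 nm, NA = 0.4
(20× air objective, nt = 1), aplanatic apodization p(θ) = √cosθ; a scalar
mode (p ≡ 1, obliquity dropped) reduces to plain Fourier optics and is
verified in tests against a directly coded DFT. A vectorial mode with the
linear-x Richards–Wolf basis is available; all shipped defaults are scalar,
adequate at NA 0.4 where the vectorial corrections are small. FFTs use
orthonormal normalization so pupil and focal energies agree exactly
(Parseval), and pure-phase defocus leaves per-plane energy invariant.

### Phase vocabulary

* **Blazed grating** — a ramp Φ₁ = −(kx·Δx + ky·Δy) displaces the focus by
  (Δx, Δy). In pupil coordinates this equals 2π(x′Δx + y′Δy)/(λf) with the
  sine-condition focal length f = R·nt/NA, which supplies the dimensional
  normalization; the sign convention is fixed so +Δx moves the focus
  towards +x, and shifts beyond the unaliased half field of view raise.
* **Axicon** — the conical phase Φ₂ = 2π·r·tanα/λ. Because it is linear in
  the *pupil* coordinate, the focal-plane field is a ring of radius
  c = R·tanα·nt/NA and the narrow Bessel core exists in an axial zone
  displaced from the nominal focus, where the local cone angle satisfies
  sin θcone ≈ c/z. All sheet metrology therefore happens at a configurable
  **working plane** z_w (default 85 µm). The apex-angle parameter is not
  fixed a priori: `calibrate_axicon` tunes tanα so the single-beam
  central-lobe FWHM at z_w equals a target thickness (default 0.8 µm) and
  records the tuned value (≈ 2.94×10⁻³ at the defaults).
* **Pupil envelope** — a Gaussian amplitude envelope (default waist 0.6 R)
  makes the beams Bessel–Gaussian rather than hard-edged Bessel; it
  suppresses the axial intensity oscillation of a sharply truncated axicon
  and is what keeps the core FWHM variation over the working range near
  10%.
* **Stripe-split multiplexing** — the pupil rows are divided into
  horizontal stripes (default width 1 row) assigned cyclically to the
  beams; each stripe carries the full Φ₁+Φ₂ of its beam. Periodic stripe
  sampling necessarily spawns replica orders; with beams offset along x
  and stripes stacked along y′, the replicas fall along the y focal axis
  at multiples of N·dx/(n_beams·stripe width) (≈ 8.4 µm at the defaults)
  and are excluded by the metrology region-of-interest crop. This is a
  deliberate simplification of published stripe-partitioning schemes; the
  exact stripe geometry of the hardware implementation is not public.
* **Beam spacing** — default 1.5 µm for nine beams, spanning ≈ 12 µm. An
  8λ spacing (≈ 3.8 µm) is sometimes quoted for such arrays but is
  mutually inconsistent with a 12 µm total width; it is available by
  passing `spacing=8*wavelength`. Closely spaced coherent Bessel lobes
  interfere through their rings, so the multiplexed sheet is rippled and
  its median thickness (≈ 0.95 µm) modestly exceeds the single-beam
  calibration target; peak-position fidelity of multiplexing is tested
  with non-axicon beams at 3 µm spacing where ring overlap is negligible.

### Metrology

`measure_sheet` takes an intensity stack ordered (z, y, x), y the thin
axis. Thickness is the half-max width along y at every (z, x) column whose
peak exceeds 30% of the stack maximum, walking outward from the peak so
ring structure is ignored, with linear interpolation between bracketing
samples; the median and SD over columns are reported. Width and height are
outermost half-max spans of max-projected envelopes. The anti-diffraction
check compares the Bessel–Gaussian core FWHM over |z − z_w| ≤ √3·z_R
(z_R from the equal-FWHM Gaussian waist, the range in which that Gaussian
focus doubles) and requires < 15% variation; measured ≈ 9%.

## Flow and sizing

Channel defaults: 10 × 50 µm cross-section, 15 µm jet, water
(ρ = 1000 kg/m³, μ = 10⁻³ Pa·s), Qj = Qs = 1 µL/h. The hydraulic diameter
is 16.67 µm and Re ≈ 2.8×10⁻², deep in the laminar regime. Two velocity
models are provided: the mean channel velocity Um = Qall/(h·wch)
(default — it reproduces the documented worked sizing examples) and the
empirically corrected up = k·Um with k = 0.83 from bench calibration. The
two disagree by 17%; the choice is explicit configuration, never silent.
Sub-resolution inversions (τ < ds/up, possible under noise) clamp to zero
diameter with a flag rather than failing.

## Synthetic traces

A particle of diameter dp at speed up crossing a sheet of Gaussian
thickness profile (FWHM ds) is rendered as a **flat top of duration dp/up
with Gaussian flanks of FWHM ds/up attached at the plateau edges**, so the
pulse FWHM is exactly (dp + ds)/up — the width the sizing inversion
dp = up·τ − ds assumes — and the dp → 0 limit is a pure Gaussian of FWHM
ds/up. (A literal
convolution of a top-hat with the sheet profile has FWHM ≈ max(dp, ds)/up
and would not be invertible by dp = up·τ − ds; the flat-top construction is
the shape consistent with the sizing model.)

Arrivals are a Poisson process of rate C·Qj; overlapping pulses are allowed
and resolvability is tested separately. Size presets: micropillars
log-uniform over 0.4–1.0 µm (their 0.3–0.6 µm widths are not modelled —
attitude effects are out of scope), microspheres normal 5 µm with 5% CV.
Per-event speed jitter defaults to 15% relative SD, the measured jet
fluctuation. Brightness scales with dp² (a cross-section proxy, a modelling
choice) and is expressed in ADC counts above baseline at medium gain,
with gain levels ×10⁵/10⁶/10⁷ acting as ×0.1/×1/×10 multipliers. The scale
(1.16×10⁴ counts/µm² at medium gain) and white-noise SD (350 counts on a
2000-count baseline) are set so that a 1.1 µm pillar at medium gain peaks
near 1.4×10⁴ counts, a 0.39 µm pillar has raw peak SNR ≈ 5 (the smallest
size the method distinguishes), and a 5 µm sphere saturates the 16-bit ADC
at medium gain but not at low gain — reproducing the saturation-driven
size overestimate seen when mixtures are measured at a single gain.
Optional slow sinusoidal baseline drift and single-sample spikes are off by
default. Traces are deterministic given the config seed.

What the generator does **not** emulate: photon shot noise, the true
(uncharacterized) instrument noise spectrum, particle agglomeration,
sedimentation losses, and optical collection geometry. Passing round-trip
tests therefore demonstrates correctness of the *pipeline* under the
stated noise model, not instrument-level accuracy on real samples.

## Pulse pipeline

1. **Detection**: order-2 Butterworth band-pass (default 20 Hz–25 kHz,
   derived from the expected FWHM range via pass 1/(10·τmax)…5/τmin),
   applied forward–backward (`sosfiltfilt`) so it is zero-phase. Candidate
   regions are runs above `threshold_sigma` (default 5) times the filtered
   trace's MAD-based noise SD, padded by twice the run length.
2. **Baseline**: median of the samples *outside* all candidate regions
   (a global median is biased upward by the pulse duty cycle).
3. **Peaks**: centred moving average (default 5 samples) of the
   baseline-subtracted raw trace; `scipy.signal.find_peaks` with height and
   prominence at the detection threshold; saturation plateaus resolve
   deterministically to the plateau centre; maxima not separated by a dip
   below half of the lower one are merged (noise wiggles on one flat top
   are one pulse).
4. **Width**: the half-max level uses a peak value estimated as the median
   of a window centred on the mid-point between the provisional half-max
   crossings (quarter-FWHM half-width) — immune to the max-of-noise bias a
   single maximal sample carries. Edge crossings are then re-estimated by
   a local quadratic regression (window = half the expected sheet-crossing
   flank, one re-centring iteration); on noise-free input this path reduces
   exactly to linear interpolation between bracketing samples. These three
   de-biasing choices (excluded-region baseline, windowed peak median,
   regression crossings) are what keep the median sizing error below one
   sample period (≈ 3 nm at the 1 µL/h bench point) down to peak SNR 5;
   naive max/first-crossing estimators leave 5–60 sample biases.
5. **Validation and sizing**: pulses outside the width gate (time-domain
   min/max FWHM — the reading of the "second band-pass validation" step as
   a width gate) are rejected and logged; survivors are sized by
   dp = up·τ − ds and tabulated with time, τ, Ifp, and saturation and
   sub-resolution flags.

Measurement deliberately avoids the band-pass path: corners that pass the
pulse energy still sag multi-millisecond pulses by ~1%, which would bias τ
by tens of samples. The band-pass filter selects regions; widths are
measured on the smoothed raw signal.

The interpolation order for edge crossings is not prescribed by the
hardware description; linear bracketing interpolation is used in the
noise-free path and quadratic local regression under noise.

## Population analysis

The 2D probability density over (dp, log₁₀ Ifp) uses 64² bins by default
(log intensity because gains span two decades); it sums to one and its
marginals match independently computed 1D histograms. Populations are
split at a fixed diameter boundary (default 2 µm) — deterministic and
adequate for the strongly bimodal pillar/sphere case; model-based
clustering is future work. β = N(dp < 2 µm)/N(dp ≥ 2 µm). Detection
efficiency δ = 100·measured/theoretical is kept at full precision
internally and rounded to one decimal only in reports. Size fractions use
0.2 µm bins over 0.2–1.0 µm with explicit under/overflow bins.

## Problem sizes used in the checks

Quantitative acceptance checks run at sizes chosen to give adequate
statistics on a single core: arrival statistics over 200 seeds; β-recovery
over 24 seeded mixtures (three ratios × eight seeds) of ≈ 2400 events each
at the 20 µL/h bench point, where ~60 events/s keeps pulse overlap near 2%;
sizing bias from 4 × 150 fixed-size pulses per diameter; optics checks on
512² grids. At ≈ 2400 events the binomial noise floor of a single β = 3
estimate is ≈ 4.7%, so the 10%-in-90%-of-runs requirement has margin
without averaging away realization noise.

## Known limitations

* The multiplexed-sheet thickness is measured through coherent inter-lobe
  ripple; its SD (≈ 0.4 µm) reflects that ripple, not instrument noise.
* The exact bench values that depend on unpublished calibrations (absolute
  sphere-cluster position under saturation, e.g. the ~6.7 µm apparent
  mode) are reproduced mechanistically, not numerically.
* Doublet deconvolution, matched filtering, spectral unmixing,
  aberrations, scattering and SLM hardware control are out of scope.
* FCS export is not provided; event tables are CSV/HDF5/JSON.
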