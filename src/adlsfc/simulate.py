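"""Seeded synthetic PMT-trace generator.

Particles arrive in the jet as a Poisson process with rate C * Qj
(concentration times jet flow rate).  A particle of diameter dp crossing a
sheet of thickness ds at speed up produces a pulse with a flat top of
duration dp/up (the interval during which the particle spans the sheet)
and Gaussian flanks whose shape follows the sheet's Gaussian thickness
profile; the flanks are attached so the pulse FWHM is exactly
(dp + ds) / up, the width the sizing inversion dp = up*tau - ds assumes.

The detector model applies a selectable PMT gain (x1e5 / 1e6 / 1e7, acting
as a linear multiplier on fluorescence flux), adds white Gaussian noise,
optional slow baseline drift and single-sample spikes, then quantizes to an
N-bit ADC with saturation.  Brightness presets scale with dp^2 (a
cross-section proxy) and are expressed in ADC counts above baseline at
medium gain; they are calibrated so a 1.09 um particle at medium gain peaks
near 1.4e4 counts and a 5 um sphere saturates a 16-bit converter at medium
gain but not at low gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np

from .microfluidics import ChannelGeometry, FlowConfig, particle_speed
from .units import UM

GainLevel = Literal["low", "medium", "high"]

GAIN_MULTIPLIER = {"low": 1e5, "medium": 1e6, "high": 1e7}
#: gain level at which brightness presets are expressed
_REFERENCE_GAIN = 1e6
#: counts above baseline at medium gain for a 1 um particle
BRIGHTNESS_PER_UM2 = 1.16e4


@dataclass(frozen=True)
class TraceConfig:
    """Acquisition settings for one simulated PMT trace."""

    sampling_rate: float = 5e5
    duration: float = 1.0
    gain: GainLevel = "medium"
    adc_bits: int = 16
    baseline: float = 2000.0
    noise_sigma: float = 350.0
    drift_amplitude: float = 0.0
    drift_period: float = 1.0
    spike_rate: float = 0.0
    spike_amplitude: float = 5000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 8 <= self.adc_bits <= 24:
            raise ValueError("adc_bits must be within 8..24")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def adc_max(self) -> int:
        return 2**self.adc_bits - 1

    @property
    def gain_factor(self) -> float:
        """Multiplier applied to brightness (expressed at medium gain)."""
        return GAIN_MULTIPLIER[self.gain] / _REFERENCE_GAIN


@dataclass(frozen=True)
class ParticleEvent:
    """Ground-truth particle crossing."""

    arrival_time: float
    diameter: float
    brightness: float
    velocity: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("particle diameter must be positive")


@dataclass
class Trace:
    """Quantized ADC samples with the generating config and ground truth.

    The ground-truth event list rides along for validation only; the
    detection pipeline never reads it.
    """

    samples: np.ndarray
    config: TraceConfig
    events: list[ParticleEvent] = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.config.dt


def default_brightness(dp: float) -> float:
    """Brightness preset: counts above baseline at medium gain, ~ dp^2."""
    return BRIGHTNESS_PER_UM2 * (dp / UM) ** 2


def pulse_shape(
    dp: float,
    up: float,
    ds: float,
    brightness: float,
    sampling_rate: float = 5e5,
) -> np.ndarray:
    """Render one pulse at the trace sampling rate.

    Flat top of duration dp/up with Gaussian flanks of FWHM ds/up attached
    at the plateau edges, so the full width at half maximum is exactly
    (dp + ds)/up; the dp -> 0 limit is a pure Gaussian of FWHM ds/up.
    Peak amplitude equals ``brightness``.
    """
    if min(dp, up, ds, sampling_rate) <= 0:
        raise ValueError("dp, up, ds and sampling_rate must be positive")
    plateau_half = 0.5 * dp / up
    sigma = (ds / up) / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    half_support = plateau_half + 5.0 * sigma
    dt = 1.0 / sampling_rate
    n_half = int(np.ceil(half_support / dt))
    t = np.arange(-n_half, n_half + 1) * dt
    excess = np.maximum(np.abs(t) - plateau_half, 0.0)
    return brightness * np.exp(-(excess**2) / (2.0 * sigma**2))


def sample_population(
    concentration: float,
    flow: FlowConfig,
    duration: float,
    size_dist: Callable[[np.random.Generator], float] | str = "micropillar",
    seed: int | np.random.Generator = 0,
    geom: ChannelGeometry | None = None,
    velocity_jitter: float = 0.15,
    brightness_fn: Callable[[float], float] = default_brightness,
    label: str = "",
) -> list[ParticleEvent]:
    """Draw particle arrivals over ``duration`` seconds.

    Arrivals follow a Poisson process with rate ``concentration * Qj``
    (concentration in m^-3, jet rate in m^3/s).  Sizes are i.i.d. from
    ``size_dist`` — a callable, or a preset name:

    * ``"micropillar"`` — log-uniform lengths over 0.4–1.0 um;
    * ``"microsphere"`` — normal, mean 5 um, 5% coefficient of variation.

    Per-event velocity is jittered with a relative SD of
    ``velocity_jitter`` (default 15%, the measured jet fluctuation).
    """
    if concentration < 0 or duration < 0:
        raise ValueError("concentration and duration must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    geom = geom or ChannelGeometry()
    up0 = particle_speed(flow, geom)
    dist = _resolve_size_dist(size_dist)
    rate = concentration * flow.jet_rate
    n = rng.poisson(rate * duration)
    times = np.sort(rng.uniform(0.0, duration, size=n))
    events = []
    for t in times:
        dp = dist(rng)
        up = up0 * max(0.05, 1.0 + velocity_jitter * rng.standard_normal())
        events.append(
            ParticleEvent(
                arrival_time=float(t),
                diameter=float(dp),
                brightness=float(brightness_fn(dp)),
                velocity=float(up),
                label=label or (size_dist if isinstance(size_dist, str) else "custom"),
            )
        )
    return events


def _resolve_size_dist(
    size_dist: Callable[[np.random.Generator], float] | str,
) -> Callable[[np.random.Generator], float]:
    if callable(size_dist):
        return size_dist
    if size_dist == "micropillar":
        lo, hi = np.log(0.4 * UM), np.log(1.0 * UM)
        return lambda rng: float(np.exp(rng.uniform(lo, hi)))
    if size_dist == "microsphere":
        return lambda rng: float(max(0.5 * UM, rng.normal(5.0 * UM, 0.25 * UM)))
    raise ValueError(f"unknown size distribution preset {size_dist!r}")


def generate_trace(
    events: Sequence[ParticleEvent],
    cfg: TraceConfig,
    sheet_thickness: float = 0.8 * UM,
) -> Trace:
    """Render events into a quantized ADC trace; deterministic under the seed."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.sampling_rate))
    signal = np.zeros(n)
    ds = sheet_thickness
    for ev in events:
        if ev.arrival_time < 0 or ev.arrival_time > cfg.duration:
            raise ValueError("event outside trace duration")
        pulse = pulse_shape(ev.diameter, ev.velocity, ds, ev.brightness, cfg.sampling_rate)
        if pulse.size > n:
            raise ValueError("pulse longer than the trace")
        center = int(round(ev.arrival_time * cfg.sampling_rate))
        half = pulse.size // 2
        lo, hi = center - half, center - half + pulse.size
        plo, phi = max(0, -lo), pulse.size - max(0, hi - n)
        lo, hi = max(0, lo), min(n, hi)
        signal[lo:hi] += pulse[plo:phi]
    analog = cfg.baseline + signal * cfg.gain_factor
    if cfg.noise_sigma > 0:
        analog = analog + rng.normal(0.0, cfg.noise_sigma, size=n)
    if cfg.drift_amplitude > 0:
        t = np.arange(n) / cfg.sampling_rate
        analog = analog + cfg.drift_amplitude * np.sin(
            2.0 * np.pi * t / cfg.drift_period + rng.uniform(0, 2 * np.pi)
        )
    if cfg.spike_rate > 0:
        n_spikes = rng.poisson(cfg.spike_rate * cfg.duration)
        idx = rng.integers(0, n, size=n_spikes)
        analog[idx] += cfg.spike_amplitude
    quantized = np.clip(np.rint(analog), 0, cfg.adc_max).astype(np.uint16 if cfg.adc_bits <= 16 else np.uint32)
    return Trace(samples=quantized, config=cfg, events=list(events))


def simulate_population(
    concentration: float,
    flow: FlowConfig,
    cfg: TraceConfig,
    size_dist: Callable[[np.random.Generator], float] | str = "micropillar",
    geom: ChannelGeometry | None = None,
    velocity_jitter: float = 0.15,
    sheet_thickness: float = 0.8 * UM,
) -> Trace:
    """Sample one population and render it into a trace (one-call helper)."""
    events = sample_population(
        concentration,
        flow,
        cfg.duration,
        size_dist=size_dist,
        seed=np.random.default_rng(cfg.seed),
        geom=geom,
        velocity_jitter=velocity_jitter,
    )
    return generate_trace(events, cfg, sheet_thickness)


def simulate_mixture(
    beta: float,
    total_concentration: float,
    flow: FlowConfig,
    duration: float,
    cfg: TraceConfig,
    seed: int | None = None,
    geom: ChannelGeometry | None = None,
    velocity_jitter: float = 0.15,
    sheet_thickness: float = 0.8 * UM,
) -> Trace:
    """Micropillar/microsphere mixture with number-density ratio beta.

    The pillar concentration is beta/(1+beta) of the total and the sphere
    concentration 1/(1+beta); both populations are rendered into a single
    trace with ground-truth labels retained.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    seed = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng_pillar, rng_sphere = (np.random.default_rng(s) for s in ss.spawn(2))
    c_pillar = total_concentration * beta / (1.0 + beta)
    c_sphere = total_concentration / (1.0 + beta)
    pillars = sample_population(
        c_pillar, flow, duration, "micropillar", rng_pillar, geom, velocity_jitter,
        label="micropillar",
    )
    spheres = sample_population(
        c_sphere, flow, duration, "microsphere", rng_sphere, geom, velocity_jitter,
        label="microsphere",
    )
    events = sorted(pillars + spheres, key=lambda e: e.arrival_time)
    cfg = replace(cfg, duration=duration, seed=seed)
    return generate_trace(events, cfg, sheet_thickness)
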