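"""Five-step pulse detection and sizing.

1. The raw trace is band-pass filtered (zero-phase, forward-backward) and
   thresholded to pick candidate pulse regions.
2. Candidate regions of the baseline-subtracted raw trace are smoothed with
   a centred moving average and local maxima are searched.
3. Rising/falling half-max edges are located; pulses whose width falls
   outside a time-domain width gate are rejected (the width gate is the
   second, validation pass of the band filter re-expressed in the time
   domain).
4. Edge crossings are linearly interpolated for sub-sample FWHM (tau).
5. Event diameters follow from dp = up * tau - ds and are tabulated.

The band-pass stage is used for *detection* only; tau and the peak value
Ifp are measured on the smoothed baseline-subtracted raw signal, so the
filter's pass-band droop cannot bias the widths.  The peak value is
estimated by a quadratic fit through the top tenth of the pulse (which on
flat-topped pulses averages the plateau), keeping the half-max level, and
therefore tau, unbiased by noise on a single maximal sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .microfluidics import (
    ChannelGeometry,
    FlowConfig,
    SizingParams,
    particle_diameter,
    particle_speed,
)


@dataclass(frozen=True)
class FilterConfig:
    """Detection/validation settings.

    ``threshold_sigma`` scales the noise SD (median absolute deviation
    estimate) into the detection threshold.  ``band`` is the (low, high)
    corner pair in Hz of the zero-phase band-pass; ``width_gate`` is the
    accepted (min, max) pulse FWHM in seconds.
    """

    threshold_sigma: float = 5.0
    band: tuple[float, float] = (20.0, 2.5e4)
    ma_window: int = 5
    width_gate: tuple[float, float] = (1.0e-5, 2.0e-2)
    region_pad: int = 40

    def __post_init__(self) -> None:
        if not (0 < self.band[0] < self.band[1]):
            raise ValueError("band corners must satisfy 0 < low < high")
        if self.ma_window < 1 or self.ma_window % 2 == 0:
            raise ValueError("ma_window must be an odd integer >= 1")
        if not (0 <= self.width_gate[0] < self.width_gate[1]):
            raise ValueError("width gate must satisfy 0 <= min < max")


#: half-width of the edge-regression window, in units of the flank sigma;
#: 0.5 keeps the quadratic edge model locally valid while averaging noise
EDGE_WINDOW_FACTOR = 0.5


def corners_from_tau(tau_min: float, tau_max: float) -> tuple[float, float]:
    """Band corners from the expected FWHM range: 1/(10 tau_max) .. 5/tau_min."""
    return (1.0 / (10.0 * tau_max), 5.0 / tau_min)


@dataclass
class Pulse:
    """One detected pulse with sub-sample FWHM."""

    start_index: int
    end_index: int
    peak_index: int
    peak_value: float  # Ifp, ADC counts above ADC zero
    fwhm: float  # tau, seconds
    saturated: bool = False
    rejected: str = ""

    def __post_init__(self) -> None:
        if not self.start_index <= self.peak_index <= self.end_index:
            raise ValueError("pulse indices out of order")


@dataclass
class EventTable:
    """Validated events with derived diameters plus run metadata."""

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class DenoiseResult:
    filtered: np.ndarray
    baseline: float
    noise_sigma: float
    regions: list[tuple[int, int]]


def _mad_sigma(x: np.ndarray) -> float:
    med = np.median(x)
    return 1.4826 * float(np.median(np.abs(x - med)))


def denoise(samples: np.ndarray, cfg: FilterConfig, sampling_rate: float) -> DenoiseResult:
    """Zero-phase band-pass filtering and candidate-region extraction.

    Regions are maximal runs of the filtered signal above
    ``threshold_sigma`` times its noise SD, padded by ``region_pad``
    samples (and by twice the run length) so each region contains the full
    pulse down past its half-maximum; overlapping padded regions merge.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty trace")
    nyq = sampling_rate / 2.0
    if cfg.band[1] >= nyq:
        raise ValueError(f"high corner {cfg.band[1]} Hz is at or above Nyquist {nyq} Hz")
    sos = sps.butter(2, cfg.band, btype="bandpass", fs=sampling_rate, output="sos")
    filt = sps.sosfiltfilt(sos, x)
    sigma = _mad_sigma(filt)
    baseline = float(np.median(x))
    # absolute floor guards against numerically-zero noise on flat traces
    floor = 1e-6 * max(1.0, float(np.max(np.abs(x))))
    thr = max(cfg.threshold_sigma * sigma, floor)
    above = filt > thr
    regions: list[tuple[int, int]] = []
    if above.any():
        idx = np.flatnonzero(above)
        splits = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.concatenate([[idx[0]], idx[splits + 1]])
        run_ends = np.concatenate([idx[splits], [idx[-1]]])
        for s, e in zip(run_starts, run_ends):
            pad = max(cfg.region_pad, 2 * (e - s + 1))
            lo, hi = max(0, s - pad), min(x.size, e + pad + 1)
            if regions and lo <= regions[-1][1]:
                regions[-1] = (regions[-1][0], hi)
            else:
                regions.append((int(lo), int(hi)))
        # second pass: re-estimate the baseline from pulse-free samples only,
        # removing the upward bias the pulse duty cycle puts on the global median
        keep = np.ones(x.size, dtype=bool)
        for lo, hi in regions:
            keep[lo:hi] = False
        if keep.sum() > max(1000, x.size // 10):
            baseline = float(np.median(x[keep]))
    return DenoiseResult(filt, baseline, sigma, regions)


def smooth(samples: np.ndarray, ma_window: int) -> np.ndarray:
    """Centred moving average of odd window length."""
    if ma_window == 1:
        return np.asarray(samples, dtype=float)
    return uniform_filter1d(np.asarray(samples, dtype=float), ma_window, mode="nearest")


def smooth_and_peaks(
    samples: np.ndarray,
    regions: Sequence[tuple[int, int]],
    cfg: FilterConfig,
    baseline: float,
) -> tuple[np.ndarray, list[tuple[int, tuple[int, int]]]]:
    """Moving-average smoothing and local-maxima search inside regions.

    Returns the smoothed baseline-subtracted trace and a list of
    (peak_index, region) candidates.  Peaks must clear the detection
    threshold of the smoothed signal and be prominent against their
    surroundings; saturation plateaus of equal samples resolve
    deterministically to the plateau centre.
    """
    y = smooth(np.asarray(samples, dtype=float) - baseline, cfg.ma_window)
    sigma_s = _mad_sigma(y)
    thr = cfg.threshold_sigma * sigma_s if sigma_s > 0 else 0.0
    candidates: list[tuple[int, tuple[int, int]]] = []
    for lo, hi in regions:
        seg = y[lo:hi]
        if seg.size < 3:
            continue
        prominence = max(thr, 0.0) or None
        peaks, _ = sps.find_peaks(seg, height=thr or None, prominence=prominence)
        if peaks.size == 0:
            j = int(np.argmax(seg))
            if seg[j] > thr:
                candidates.append((lo + j, (lo, hi)))
            continue
        for p in _merge_peaks(seg, peaks):
            candidates.append((lo + int(p), (lo, hi)))
    return y, candidates


def _merge_peaks(seg: np.ndarray, peaks: np.ndarray) -> list[int]:
    """Collapse peaks that are not separated by a genuine valley.

    Two local maxima count as distinct pulses only if the signal between
    them falls below half of the lower maximum — the same half-maximum
    criterion the width measurement uses.  Noise wiggles on a flat pulse
    top therefore collapse to a single peak (the tallest).
    """
    merged: list[int] = []
    for p in sorted(int(q) for q in peaks):
        if not merged:
            merged.append(p)
            continue
        last = merged[-1]
        valley = seg[last : p + 1].min()
        if valley > 0.5 * min(seg[last], seg[p]):
            if seg[p] > seg[last]:
                merged[-1] = p
        else:
            merged.append(p)
    return merged


def fwhm(
    smoothed: np.ndarray,
    peak_index: int,
    region: tuple[int, int],
    sampling_rate: float,
    baseline: float = 0.0,
    raw: np.ndarray | None = None,
    adc_max: int | None = None,
    noise_sigma: float = 0.0,
    flank_sigma: float | None = None,
) -> Pulse:
    """Half-max width of one pulse with linearly interpolated edges.

    ``smoothed`` is baseline-subtracted; the half-max level is half the
    fitted peak value.  The search walks outward from the peak to the
    nearest crossing on each side (or the valley before a neighbouring
    pulse) and interpolates linearly between the bracketing samples.  An
    edge that never crosses half maximum inside the region rejects the
    pulse with an ``edge`` flag.
    """
    lo, hi = region
    if not lo <= peak_index < hi:
        raise ValueError("peak outside region")
    seg = smoothed[lo:hi]
    j = peak_index - lo
    peak_val = _fit_peak_value(seg, j, noise_sigma)
    half = peak_val / 2.0
    dt = 1.0 / sampling_rate

    a = j
    while a > 0 and seg[a] > half:
        if seg[a] < seg[j] * 0.05:
            break
        a -= 1
    b = j
    while b < seg.size - 1 and seg[b] > half:
        if seg[b] < seg[j] * 0.05:
            break
        b += 1
    rejected = ""
    if seg[a] > half or seg[b] > half:
        rejected = "edge"
        tau = max((b - a) * dt, dt)
    else:
        if flank_sigma is not None:
            w = max(3, int(round(EDGE_WINDOW_FACTOR * flank_sigma)))
        else:
            w = max(2, max(j - a, b - j) // 4)
        xa = _edge_crossing(seg, a, half, w, noise_sigma)
        xb = _edge_crossing(seg, b, half, w, noise_sigma)
        tau = (xb - xa) * dt
    saturated = False
    if raw is not None and adc_max is not None:
        saturated = bool(np.any(np.asarray(raw[lo:hi]) >= adc_max))
    return Pulse(
        start_index=lo + a,
        end_index=lo + b,
        peak_index=peak_index,
        peak_value=float(peak_val + baseline),
        fwhm=float(tau),
        saturated=saturated,
        rejected=rejected,
    )


def _edge_crossing(
    seg: np.ndarray, c: int, half: float, w: int, noise_sigma: float
) -> float:
    """Sub-sample position where the edge crosses the half-max level.

    ``c`` is the provisional bracketing sample from the outward walk.  With
    noise, the first sample below half is systematically inside the true
    crossing (an extreme-value effect), so the crossing is re-estimated by
    a local quadratic regression over +-w samples around the provisional
    crossing (w of order the flank length), iterated once to re-centre the
    window; the noise-free path reduces to plain linear interpolation
    between the bracketing samples.
    """
    if noise_sigma <= 0 or w < 2:
        lo = max(0, c - 1)
        hi = min(seg.size - 1, c + 1)
        for p, q in ((lo, lo + 1), (hi - 1, hi)):
            v0, v1 = seg[p], seg[q]
            if (v0 - half) * (v1 - half) <= 0 and v0 != v1:
                return p + (half - v0) / (v1 - v0)
        return float(c)
    x = float(c)
    for _ in range(2):
        a = max(0, int(round(x)) - w)
        b = min(seg.size - 1, int(round(x)) + w)
        idx = np.arange(a, b + 1)
        if idx.size < 5:
            return float(c)
        coef = np.polyfit(idx - x, seg[a : b + 1], 2) - np.array([0.0, 0.0, half])
        roots = np.roots(coef)
        roots = roots[np.isreal(roots)].real + x
        roots = roots[(roots >= a - 2) & (roots <= b + 2)]
        if roots.size == 0:
            slope, intercept = np.polyfit(idx, seg[a : b + 1], 1)
            if slope == 0:
                return float(c)
            x_new = (half - intercept) / slope
        else:
            x_new = roots[np.argmin(np.abs(roots - x))]
        if not a - w <= x_new <= b + w:
            return float(c)
        x = float(x_new)
    return x


def _provisional_halfspan(seg: np.ndarray, j: int) -> tuple[int, int]:
    """Bracketing half-of-max crossing samples around the peak (provisional)."""
    half = seg[j] / 2.0
    a = j
    while a > 0 and seg[a] > half:
        a -= 1
    b = j
    while b < seg.size - 1 and seg[b] > half:
        b += 1
    return a, b


def _fit_peak_value(seg: np.ndarray, j: int, noise_sigma: float = 0.0) -> float:
    """Peak estimate from a quadratic fit through the top of the pulse.

    The fit window spans a quarter of the provisional half-max width on
    each side of the peak sample — wide enough to average noise, narrow
    enough that the pulse top is locally quadratic (or flat).  The fitted
    curve is evaluated at the window centre (not its vertex, whose
    extremum is itself noise-biased upward), which keeps the half-max
    level, and therefore tau, free of the positive max-of-noise bias; on
    saturated flat tops the fit degenerates to the plateau value.
    """
    vmax = float(seg[j])
    if noise_sigma <= 0:
        return vmax
    pa, pb = _provisional_halfspan(seg, j)
    m = (pa + pb) // 2  # pulse centre, not the (noise-selected) argmax
    w = max(2, (pb - pa) // 8)
    a, b = max(0, m - w), min(seg.size - 1, m + w)
    if b - a + 1 < 5:
        return vmax
    # median over the central top window: immune both to the single-sample
    # max-of-noise excess and to the local noise bump that made j the argmax
    fitted = float(np.median(seg[a : b + 1]))
    if vmax - 5.0 * noise_sigma <= fitted <= vmax + noise_sigma:
        return fitted
    return vmax


def validate(pulses: Sequence[Pulse], width_gate: tuple[float, float]) -> tuple[list[Pulse], dict]:
    """Discard pulses whose tau falls outside the width gate; log rejections."""
    tmin, tmax = width_gate
    kept: list[Pulse] = []
    log = {"input": len(pulses), "edge": 0, "too_narrow": 0, "too_wide": 0, "kept": 0}
    for p in pulses:
        if p.rejected == "edge":
            log["edge"] += 1
            continue
        if p.fwhm < tmin:
            log["too_narrow"] += 1
        elif p.fwhm > tmax:
            log["too_wide"] += 1
        else:
            kept.append(p)
    log["kept"] = len(kept)
    return kept, log


def size_events(
    pulses: Sequence[Pulse],
    sizing: SizingParams,
    flow: FlowConfig,
    geom: ChannelGeometry,
    sampling_rate: float,
    metadata: dict | None = None,
) -> EventTable:
    """Per-event diameters dp = up tau - ds tabulated with peaks and flags."""
    up = particle_speed(flow, geom)
    rows = []
    for p in pulses:
        res = particle_diameter(up, p.fwhm, sizing.sheet_thickness)
        rows.append(
            {
                "time_s": p.peak_index / sampling_rate,
                "tau_s": p.fwhm,
                "ifp": p.peak_value,
                "dp_m": res.diameter,
                "saturated": p.saturated,
                "sub_resolution": res.sub_resolution,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["time_s", "tau_s", "ifp", "dp_m", "saturated", "sub_resolution"]
    )
    meta = {
        "velocity_model": flow.velocity_model,
        "particle_speed_m_s": up,
        "sheet_thickness_m": sizing.sheet_thickness,
        "count": len(frame),
    }
    if metadata:
        meta.update(metadata)
    return EventTable(frame, meta)


def detect(
    samples: np.ndarray,
    cfg: FilterConfig,
    sizing: SizingParams,
    flow: FlowConfig,
    geom: ChannelGeometry,
    sampling_rate: float,
    adc_max: int | None = None,
) -> tuple[EventTable, dict]:
    """Run the full five-step chain on a raw trace.

    Returns the event table and a per-stage log of counts in/out.
    """
    den = denoise(samples, cfg, sampling_rate)
    y, candidates = smooth_and_peaks(samples, den.regions, cfg, den.baseline)
    sigma_s = _mad_sigma(y)
    # expected flank length in samples: the sheet-crossing time ds / up
    up = particle_speed(flow, geom)
    flank = sizing.sheet_thickness / up / (2.0 * np.sqrt(2.0 * np.log(2.0))) * sampling_rate
    pulses = [
        fwhm(y, pk, reg, sampling_rate, den.baseline, raw=samples, adc_max=adc_max,
             noise_sigma=sigma_s, flank_sigma=flank)
        for pk, reg in candidates
    ]
    kept, log = validate(pulses, cfg.width_gate)
    log = {
        "regions": len(den.regions),
        "candidates": len(candidates),
        **log,
        "noise_sigma": den.noise_sigma,
        "baseline": den.baseline,
    }
    table = size_events(kept, sizing, flow, geom, sampling_rate, metadata={"log": log})
    return table, log


def min_resolvable_interval(
    cfg: FilterConfig,
    sampling_rate: float = 5e5,
    pulse_fwhm: float = 4.5e-5,
    amplitude: float = 1.4e4,
    baseline: float = 2000.0,
    noise_sigma: float = 350.0,
    separations: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[float, dict[float, int]]:
    """Sweep the separation of two identical pulses; report the minimum
    interval at which both are still detected.

    Scans from the largest separation downward and returns the smallest
    separation below which (and including which) detection no longer
    yields two events — i.e. the resolution limit of the configured
    pipeline at the given pulse width.
    """
    if separations is None:
        separations = np.arange(2e-5, 3.1e-4, 1e-5)
    rng = np.random.default_rng(seed)
    dt = 1.0 / sampling_rate
    sigma = pulse_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    results: dict[float, int] = {}
    for sep in sorted(separations):
        n = int((10 * pulse_fwhm + sep) / dt) + 400
        t = np.arange(n) * dt
        c0 = t[n // 2] - sep / 2.0
        x = baseline + amplitude * (
            np.exp(-((t - c0) ** 2) / (2 * sigma**2))
            + np.exp(-((t - c0 - sep) ** 2) / (2 * sigma**2))
        )
        if noise_sigma > 0:
            x = x + rng.normal(0, noise_sigma, n)
        x = np.clip(np.rint(x), 0, 65535)
        den = denoise(x, cfg, sampling_rate)
        _, cands = smooth_and_peaks(x, den.regions, cfg, den.baseline)
        results[float(sep)] = len(cands)
    min_sep = np.inf
    for s in sorted(results, reverse=True):
        if results[s] >= 2:
            min_sep = s
        else:
            break
    return float(min_sep), results
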