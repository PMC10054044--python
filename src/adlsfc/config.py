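"""Run configuration (YAML) and the end-to-end orchestration.

One YAML file drives every stage; bench units (uL/h, um, ms) at the
boundary, SI internally.  Unknown keys are rejected so typos fail loudly,
and the effective configuration is echoed into every run's manifest.
"""

from __future__ import annotations

import dataclasses
import logging
import platform
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .microfluidics import (
    ChannelGeometry,
    FlowConfig,
    FluidProps,
    SizingParams,
    hydraulic_diameter,
    mean_velocity,
    particle_speed,
    reynolds,
)
from .pipeline import FilterConfig, detect
from .population import density2d, detection_efficiency, size_fractions, split_and_ratio
from .simulate import TraceConfig, simulate_mixture, simulate_population
from .units import MS, UM, ul_per_h_to_m3s

logger = logging.getLogger(__name__)


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OpticsSection(_Section):
    enabled: bool = False
    wavelength_nm: float = Field(473.0, gt=0)
    numerical_aperture: float = Field(0.4, gt=0, lt=1.5)
    refractive_index: float = Field(1.0, gt=0)
    grid_size: int = Field(512, ge=64)
    pupil_radius_mm: float = Field(2.5, gt=0)
    envelope_frac: float | None = Field(0.6, description="Gaussian pupil waist / R")
    target_thickness_um: float = Field(0.8, gt=0)
    z_working_um: float = 85.0
    n_beams: int = Field(9, ge=1)
    spacing_um: float = Field(1.5, gt=0)
    stripe_width: int = Field(1, ge=1)


class ChannelSection(_Section):
    h_um: float = Field(10.0, gt=0)
    w_um: float = Field(50.0, gt=0)
    jet_um: float = Field(15.0, gt=0)


class FluidSection(_Section):
    rho: float = Field(1000.0, gt=0)
    mu: float = Field(1.0e-3, gt=0)


class FlowSection(_Section):
    qj_ul_h: float = Field(1.0, gt=0)
    qs_ul_h: float = Field(1.0, gt=0)
    k: float = Field(0.83, gt=0, le=1)
    velocity_model: Literal["mean_channel", "corrected"] = "mean_channel"


class SimSection(_Section):
    duration_s: float = Field(10.0, gt=0)
    concentration_per_ml: float = Field(1.0e7, gt=0)
    population: Literal["micropillar", "microsphere"] = "micropillar"
    mixture_beta: float | None = Field(None, gt=0)
    sampling_rate_hz: float = Field(5.0e5, gt=0)
    gain: Literal["low", "medium", "high"] = "medium"
    adc_bits: int = Field(16, ge=8, le=24)
    baseline: float = Field(2000.0, ge=0)
    noise_sigma: float = Field(350.0, ge=0)
    drift_amplitude: float = Field(0.0, ge=0)
    drift_period_s: float = Field(1.0, gt=0)
    spike_rate_hz: float = Field(0.0, ge=0)
    velocity_jitter: float = Field(0.15, ge=0)
    sheet_thickness_um: float = Field(0.8, gt=0)


class PipelineSection(_Section):
    threshold_sigma: float = Field(5.0, gt=0)
    band_low_hz: float = Field(20.0, gt=0)
    band_high_hz: float = Field(2.5e4, gt=0)
    ma_window: int = Field(5, ge=1)
    gate_min_ms: float = Field(0.01, ge=0)
    gate_max_ms: float = Field(20.0, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "PipelineSection":
        if self.band_low_hz >= self.band_high_hz:
            raise ValueError("band_low_hz must be below band_high_hz")
        if self.gate_min_ms >= self.gate_max_ms:
            raise ValueError("gate_min_ms must be below gate_max_ms")
        return self


class AnalysisSection(_Section):
    boundary_um: float = Field(2.0, gt=0)
    bins: int = Field(64, ge=4)
    theoretical_count: float | None = Field(None, gt=0)


class RunConfig(_Section):
    """Validated umbrella configuration for an end-to-end run."""

    seed: int = 0
    outdir: str = "adls_out"
    log_level: str = "INFO"
    optics: OpticsSection = OpticsSection()
    channel: ChannelSection = ChannelSection()
    fluid: FluidSection = FluidSection()
    flow: FlowSection = FlowSection()
    sim: SimSection = SimSection()
    pipeline: PipelineSection = PipelineSection()
    analysis: AnalysisSection = AnalysisSection()

    # -- converters to the library's SI dataclasses -------------------------

    def channel_geometry(self) -> ChannelGeometry:
        return ChannelGeometry(
            height=self.channel.h_um * UM,
            width=self.channel.w_um * UM,
            jet_width=self.channel.jet_um * UM,
        )

    def fluid_props(self) -> FluidProps:
        return FluidProps(density=self.fluid.rho, viscosity=self.fluid.mu)

    def flow_config(self) -> FlowConfig:
        return FlowConfig.from_ul_per_h(
            self.flow.qj_ul_h,
            self.flow.qs_ul_h,
            k=self.flow.k,
            velocity_model=self.flow.velocity_model,
        )

    def trace_config(self) -> TraceConfig:
        s = self.sim
        return TraceConfig(
            sampling_rate=s.sampling_rate_hz,
            duration=s.duration_s,
            gain=s.gain,
            adc_bits=s.adc_bits,
            baseline=s.baseline,
            noise_sigma=s.noise_sigma,
            drift_amplitude=s.drift_amplitude,
            drift_period=s.drift_period_s,
            spike_rate=s.spike_rate_hz,
            seed=self.seed,
        )

    def filter_config(self) -> FilterConfig:
        p = self.pipeline
        return FilterConfig(
            threshold_sigma=p.threshold_sigma,
            band=(p.band_low_hz, p.band_high_hz),
            ma_window=p.ma_window,
            width_gate=(p.gate_min_ms * MS, p.gate_max_ms * MS),
        )

    def sizing_params(self) -> SizingParams:
        return SizingParams(sheet_thickness=self.sim.sheet_thickness_um * UM)


def load_config(path: str | Path) -> RunConfig:
    """Parse, default and validate a YAML run configuration.

    An empty file yields all documented defaults; unknown keys and
    out-of-range values raise with a clear message.
    """
    raw = yaml.safe_load(Path(path).read_text())
    return RunConfig.model_validate(raw or {})


def save_config(path: str | Path, cfg: RunConfig) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))


def run_end_to_end(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute (optics ->) simulate -> detect -> analyze; write artifacts.

    Returns the report dictionary; the trace, event table, report and a
    manifest sufficient to reproduce the run are written to ``outdir``.
    """
    from . import io as adls_io

    out = Path(outdir if outdir is not None else cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    geom = cfg.channel_geometry()
    fluid = cfg.fluid_props()
    flow = cfg.flow_config()
    sizing = cfg.sizing_params()

    dh = hydraulic_diameter(geom)
    um = mean_velocity(flow, geom)
    report["flow"] = {
        "hydraulic_diameter_um": dh / UM,
        "mean_velocity_mm_s": um * 1e3,
        "particle_speed_mm_s": particle_speed(flow, geom) * 1e3,
        "reynolds": reynolds(fluid, um, dh),
    }

    if cfg.optics.enabled:
        report["optics"] = _run_optics_stage(cfg, out)
        sizing = SizingParams(sheet_thickness=report["optics"]["thickness_um"] * UM)

    try:
        trace = _run_sim_stage(cfg, flow, geom, sizing)
    except Exception as err:  # pragma: no cover - defensive
        raise RuntimeError(f"simulate stage failed: {err}") from err
    adls_io.write_trace_h5(out / "trace.h5", trace)

    try:
        table, log = detect(
            trace.samples,
            cfg.filter_config(),
            sizing,
            flow,
            geom,
            trace.config.sampling_rate,
            adc_max=trace.config.adc_max,
        )
    except Exception as err:
        raise RuntimeError(f"detect stage failed: {err}") from err
    adls_io.write_events_csv(out / "events.csv", table)
    adls_io.write_json(out / "rejections.json", log)

    report["detection"] = {"count": len(table), "log": log}
    if len(table):
        summary = split_and_ratio(table, cfg.analysis.boundary_um * UM)
        dens = density2d(table, bins=cfg.analysis.bins)
        report["analysis"] = {
            "beta": summary.beta,
            "count_small": summary.count_small,
            "count_large": summary.count_large,
            "size_fractions": size_fractions(table),
        }
        theo = cfg.analysis.theoretical_count
        if theo is None:
            theo = (
                cfg.sim.concentration_per_ml
                * 1e6
                * ul_per_h_to_m3s(cfg.flow.qj_ul_h)
                * cfg.sim.duration_s
            ) or None
        if theo:
            report["analysis"]["theoretical_count"] = theo
            report["analysis"]["efficiency_pct"] = round(
                detection_efficiency(len(table), theo), 1
            )
        np.save(out / "pd_grid.npy", dens.pd)

    manifest = {
        "package": "adlsfc",
        "version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "config": cfg.model_dump(),
    }
    adls_io.write_json(out / "report.json", report)
    adls_io.write_json(out / "manifest.json", manifest)
    return report


def _run_optics_stage(cfg: RunConfig, out: Path) -> dict:
    from . import optics as opt

    o = cfg.optics
    spec = opt.PupilSpec(
        wavelength=o.wavelength_nm * 1e-9,
        numerical_aperture=o.numerical_aperture,
        refractive_index=o.refractive_index,
        pupil_radius=o.pupil_radius_mm * 1e-3,
        grid_size=o.grid_size,
        envelope_waist=(
            None if o.envelope_frac is None else o.envelope_frac * o.pupil_radius_mm * 1e-3
        ),
    )
    z_w = o.z_working_um * UM
    tan_alpha = opt.calibrate_axicon(spec, o.target_thickness_um * UM, z_w)
    beams = opt.sheet_beams(o.n_beams, o.spacing_um * UM, tan_alpha)
    pm = opt.ssp_multiplex(beams, spec, o.stripe_width)
    zs = z_w + np.linspace(-5.0, 5.0, 11) * UM
    fld = opt.debye_focus(pm, spec, zs)
    stack = fld.intensity()
    metrics = opt.measure_sheet(
        stack,
        (float(zs[1] - zs[0]), spec.focal_sampling, spec.focal_sampling),
        roi_halfwidth=2.5 * UM,
    )
    from . import io as adls_io

    adls_io.write_phase_png(out / "phase.png", pm)
    adls_io.write_phase_h5(out / "phase.h5", pm, spec)
    adls_io.write_stack_h5(
        out / "sheet.h5",
        stack,
        (float(zs[1] - zs[0]), spec.focal_sampling, spec.focal_sampling),
        z_planes=zs,
    )
    return {
        "tan_alpha": tan_alpha,
        "thickness_um": metrics.thickness_fwhm / UM,
        "thickness_sd_um": metrics.thickness_sd / UM,
        "width_um": metrics.width / UM,
        "height_um": metrics.height / UM,
    }


def _run_sim_stage(cfg: RunConfig, flow, geom, sizing) -> "object":
    s = cfg.sim
    tcfg = cfg.trace_config()
    conc = s.concentration_per_ml * 1e6  # to m^-3
    if s.mixture_beta is not None:
        return simulate_mixture(
            s.mixture_beta,
            conc,
            flow,
            s.duration_s,
            tcfg,
            seed=cfg.seed,
            geom=geom,
            velocity_jitter=s.velocity_jitter,
            sheet_thickness=sizing.sheet_thickness,
        )
    return simulate_population(
        conc,
        flow,
        tcfg,
        size_dist=s.population,
        geom=geom,
        velocity_jitter=s.velocity_jitter,
        sheet_thickness=sizing.sheet_thickness,
    )
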