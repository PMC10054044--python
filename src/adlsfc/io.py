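"""File I/O: HDF5 traces and stacks, CSV traces and event tables, PNG
phase maps, JSON reports."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .optics import PhaseMap, PupilSpec
from .pipeline import EventTable
from .simulate import ParticleEvent, Trace, TraceConfig


def write_trace_h5(path: str | Path, trace: Trace) -> None:
    """Trace samples + config echo + ground-truth events (if any) to HDF5."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("samples", data=trace.samples, compression="gzip")
        for key, val in dataclasses.asdict(trace.config).items():
            d.attrs[key] = val
        if trace.events:
            ev = np.array(
                [
                    (e.arrival_time, e.diameter, e.brightness, e.velocity, e.label)
                    for e in trace.events
                ],
                dtype=[
                    ("arrival_time", "f8"),
                    ("diameter", "f8"),
                    ("brightness", "f8"),
                    ("velocity", "f8"),
                    ("label", "S24"),
                ],
            )
            f.create_dataset("truth", data=ev)


def read_trace_h5(path: str | Path) -> Trace:
    with h5py.File(path, "r") as f:
        d = f["samples"]
        attrs = {k: v for k, v in d.attrs.items()}
        if "gain" in attrs:
            attrs["gain"] = str(attrs["gain"])
        for key in ("adc_bits", "seed"):
            if key in attrs:
                attrs[key] = int(attrs[key])
        cfg = TraceConfig(**attrs)
        samples = d[...]
        events = []
        if "truth" in f:
            for row in f["truth"][...]:
                events.append(
                    ParticleEvent(
                        arrival_time=float(row["arrival_time"]),
                        diameter=float(row["diameter"]),
                        brightness=float(row["brightness"]),
                        velocity=float(row["velocity"]),
                        label=row["label"].decode(),
                    )
                )
    return Trace(samples=samples, config=cfg, events=events)


def write_trace_csv(path: str | Path, trace: Trace) -> None:
    """Two-column (time_s, adc_counts) interchange format."""
    pd.DataFrame(
        {"time_s": trace.times, "adc_counts": trace.samples}
    ).to_csv(path, index=False)


def read_trace_csv(path: str | Path, config: TraceConfig | None = None) -> Trace:
    """Read a two-column trace; sampling rate inferred from the time column
    unless a config is supplied."""
    df = pd.read_csv(path)
    t, x = df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy()
    if config is None:
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 2e-6
        config = TraceConfig(sampling_rate=1.0 / dt, duration=len(x) * dt)
    return Trace(samples=np.asarray(x), config=config)


def write_events_csv(path: str | Path, table: EventTable) -> None:
    table.frame.to_csv(path, index=False)


def read_events_csv(path: str | Path) -> EventTable:
    return EventTable(pd.read_csv(path))


def write_phase_png(path: str | Path, pm: PhaseMap) -> None:
    """8-bit grayscale export, 0..255 mapped onto phase 0..2 pi, for SLM upload."""
    from PIL import Image

    phase8 = np.round(pm.wrapped() / (2.0 * np.pi) * 255.0).astype(np.uint8)
    Image.fromarray(phase8, mode="L").save(path)


def write_phase_h5(path: str | Path, pm: PhaseMap, spec: PupilSpec) -> None:
    """Lossless float phase + amplitude with the optical constants attached."""
    with h5py.File(path, "w") as f:
        f.create_dataset("phase", data=pm.phase, compression="gzip")
        f.create_dataset("amplitude", data=pm.amplitude, compression="gzip")
        f.attrs["wavelength"] = spec.wavelength
        f.attrs["numerical_aperture"] = spec.numerical_aperture
        f.attrs["refractive_index"] = spec.refractive_index
        f.attrs["pupil_radius"] = spec.pupil_radius
        f.attrs["grid_size"] = spec.grid_size


def write_stack_h5(
    path: str | Path,
    stack: np.ndarray,
    sampling: tuple[float, float, float],
    z_planes: np.ndarray | None = None,
) -> None:
    """Intensity stack with axis order and sampling recorded as attributes."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("intensity", data=stack, compression="gzip")
        d.attrs["axes"] = "zyx"
        d.attrs["sampling_m"] = sampling
        if z_planes is not None:
            f.create_dataset("z_planes", data=z_planes)


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj
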