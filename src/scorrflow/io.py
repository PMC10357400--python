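"""Configuration files, trace I/O and provenance records."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .flowsim import SimulationConfig
from .scorr import LaserGeometry
from .trace import Trace


@dataclass
class InstrumentConfig:
    """Laser layout and acquisition settings of the flow analyzer.

    ``laser_positions_um`` orders the channels along the flow axis
    (smaller = upstream); pairwise colocalization geometry for any
    ordered channel pair derives from it together with
    ``beam_widths_um``.
    """

    beam_widths_um: dict = field(default_factory=lambda: {"red": 1.0, "blue": 1.0})
    laser_positions_um: dict = field(default_factory=lambda: {"red": 0.0, "blue": 15.0})
    sample_rate: float = 10_000.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if set(self.beam_widths_um) != set(self.laser_positions_um):
            raise ValueError("beam_widths_um and laser_positions_um must name the same channels")
        for ch, w in self.beam_widths_um.items():
            if w <= 0:
                raise ValueError(f"beam width for channel '{ch}' must be positive")

    @property
    def channels(self) -> list[str]:
        """Channel names ordered upstream to downstream."""
        return sorted(self.laser_positions_um, key=self.laser_positions_um.get)

    def geometry(self, upstream: str, downstream: str) -> LaserGeometry:
        """Two-beam geometry for one ordered channel pair."""
        for ch in (upstream, downstream):
            if ch not in self.laser_positions_um:
                raise ValueError(f"channel '{ch}' not in instrument configuration")
        dx3 = self.laser_positions_um[downstream] - self.laser_positions_um[upstream]
        if dx3 <= 0:
            raise ValueError(f"channel '{downstream}' is not downstream of '{upstream}'")
        return LaserGeometry(
            dx1=self.beam_widths_um[downstream],
            dx2=self.beam_widths_um[upstream],
            dx3=dx3,
        )

    def channel_pairs(self) -> list[tuple[str, str]]:
        """All ordered (upstream, downstream) pairs, e.g. three for 3 colors."""
        chs = self.channels
        return [(chs[i], chs[j]) for i in range(len(chs)) for j in range(i + 1, len(chs))]


def _load_mapping(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at the top level")
    return data


def load_simulation_config(path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from YAML or JSON.

    Unknown keys are an error (listed by name) so typos never silently
    fall back to defaults.
    """
    data = _load_mapping(path)
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown simulation config key(s): {', '.join(unknown)}")
    return SimulationConfig(**data)


def load_instrument_config(path) -> InstrumentConfig:
    data = _load_mapping(path)
    known = {f.name for f in dataclasses.fields(InstrumentConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown instrument config key(s): {', '.join(unknown)}")
    return InstrumentConfig(**data)


def write_traces_hdf5(traces: dict[str, Trace], path) -> None:
    """One dataset per channel with sample-rate/start-time attributes."""
    with h5py.File(path, "w") as f:
        for name, trace in traces.items():
            ds = f.create_dataset(name, data=trace.values)
            ds.attrs["sample_rate_hz"] = trace.sample_rate
            ds.attrs["start_time_ms"] = trace.start_time
            ds.attrs["duration_s"] = trace.duration_ms / 1000.0


def read_traces_hdf5(path) -> dict[str, Trace]:
    traces: dict[str, Trace] = {}
    with h5py.File(path, "r") as f:
        for name in f:
            ds = f[name]
            traces[name] = Trace(
                channel=name,
                sample_rate=float(ds.attrs["sample_rate_hz"]),
                values=ds[()],
                start_time=float(ds.attrs.get("start_time_ms", 0.0)),
            )
    return traces


def write_trace_csv(trace: Trace, path) -> None:
    pd.DataFrame({"time_ms": trace.times_ms, "intensity": trace.values}).to_csv(path, index=False)


def read_trace_csv(path, channel: str = "trace") -> Trace:
    df = pd.read_csv(path)
    for col in ("time_ms", "intensity"):
        if col not in df.columns:
            raise ValueError(f"trace CSV is missing required column '{col}'")
    t = df["time_ms"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("trace CSV needs at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("trace CSV is not uniformly sampled")
    return Trace(
        channel=channel,
        sample_rate=1000.0 / float(dt[0]),
        values=df["intensity"].to_numpy(dtype=float),
        start_time=float(t[0]),
    )


def write_provenance(path, payload: dict) -> None:
    """Write a sidecar provenance record (inputs, parameters, version)."""
    from . import __version__

    record = dict(payload)
    record["scorrflow_version"] = __version__
    blob = json.dumps(record, sort_keys=True, default=str)
    record["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
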