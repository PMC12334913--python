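"""Step/ramp voltage-clamp protocols: representation, generation and I/O.

A protocol is an ordered list of segments, each a constant-voltage step or a
linear ramp, with durations in ms and voltages in mV.  Segment semantics are
half-open: a segment owns times in [start, start + duration), so a sample
falling exactly on a boundary takes the voltage of the *next* segment.

Every designed protocol is book-ended by a common head (leak ramp + large
activation step for conductance estimation) and tail (reversal ramp sequence
plus a closing step at -120 mV), so that leak, conductance and selectivity
can be checked per cell and the channel state is reset between protocols.

The module also implements the square-wave voltage family

    V(t) = b + sum_i a_i * sign(sin(w_i t + phi_i)),

with sign(0) = 0, and its exact conversion to a step list for hardware that
only accepts step/ramp commands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Segment",
    "Protocol",
    "SquareWaveSpec",
    "common_head",
    "common_tail",
    "with_head_and_tail",
    "square_wave_voltage",
    "square_wave_to_segments",
    "read_protocol",
    "write_protocol",
    "HARDWARE_MAX_COMMANDS",
]

#: Maximum number of commands (steps or ramps) a single protocol may use on
#: the automated patch platform the designs target.
HARDWARE_MAX_COMMANDS = 64

#: Default hard voltage range for designed segments, mV.
DESIGN_VOLTAGE_RANGE = (-120.0, 60.0)


@dataclass(frozen=True)
class Segment:
    """One protocol command: a constant step or a linear ramp.

    ``duration`` in ms (> 0); voltages in mV.  For a step, ``v_start`` must
    equal ``v_end``.
    """

    kind: str
    duration: float
    v_start: float
    v_end: float

    def __post_init__(self) -> None:
        if self.kind not in ("step", "ramp"):
            raise ValueError(f"segment kind must be 'step' or 'ramp', got {self.kind!r}")
        if not (np.isfinite(self.duration) and self.duration > 0):
            raise ValueError(f"segment duration must be > 0 ms, got {self.duration}")
        if not (np.isfinite(self.v_start) and np.isfinite(self.v_end)):
            raise ValueError("segment voltages must be finite")
        if self.kind == "step" and self.v_start != self.v_end:
            raise ValueError(
                f"step segment must have v_start == v_end, got {self.v_start} != {self.v_end}")

    @staticmethod
    def step(duration: float, voltage: float) -> "Segment":
        return Segment("step", duration, voltage, voltage)

    @staticmethod
    def ramp(duration: float, v_start: float, v_end: float) -> "Segment":
        return Segment("ramp", duration, v_start, v_end)


@dataclass(frozen=True)
class Protocol:
    """An ordered sequence of segments defining V(t) on [0, total_duration)."""

    segments: tuple[Segment, ...]
    name: str = "protocol"

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if len(self.segments) == 0:
            raise ValueError("protocol must contain at least one segment")

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative segment start times plus the final end time (ms)."""
        return np.concatenate([[0.0], np.cumsum([s.duration for s in self.segments])])

    def voltage_at(self, t: float) -> float:
        """Command voltage at time t (ms), half-open segment semantics."""
        total = self.total_duration
        if not (0.0 <= t < total):
            raise ValueError(f"t={t} ms outside protocol range [0, {total}) ms")
        b = self.boundaries
        i = int(np.searchsorted(b, t, side="right")) - 1
        seg = self.segments[i]
        if seg.kind == "step":
            return seg.v_start
        frac = (t - b[i]) / seg.duration
        return seg.v_start + frac * (seg.v_end - seg.v_start)

    def voltage_trace(self, times: np.ndarray) -> np.ndarray:
        """Vectorised V(t) for times within [0, total_duration)."""
        times = np.asarray(times, dtype=float)
        total = self.total_duration
        if times.size and (times.min() < 0 or times.max() >= total):
            raise ValueError("times outside protocol range")
        b = self.boundaries
        idx = np.searchsorted(b, times, side="right") - 1
        v0 = np.array([s.v_start for s in self.segments])
        v1 = np.array([s.v_end for s in self.segments])
        dur = np.array([s.duration for s in self.segments])
        frac = (times - b[idx]) / dur[idx]
        return v0[idx] + frac * (v1[idx] - v0[idx])

    def concat(self, *others: "Protocol", name: str | None = None) -> "Protocol":
        segs = list(self.segments)
        for p in others:
            segs.extend(p.segments)
        return Protocol(tuple(segs), name or self.name)

    def validate_for_hardware(self, max_commands: int = HARDWARE_MAX_COMMANDS) -> None:
        """Raise if the protocol cannot be programmed on the target platform."""
        if len(self) > max_commands:
            raise ValueError(
                f"protocol {self.name!r} uses {len(self)} commands, exceeding the "
                f"{max_commands}-command hardware limit")


@dataclass(frozen=True)
class SquareWaveSpec:
    """Sum-of-signed-sines square wave: offset b plus components (a_i, w_i, phi_i).

    Amplitudes a_i in mV, angular frequencies w_i in rad/ms, phases in rad.
    """

    offset: float
    amplitudes: tuple[float, ...]
    frequencies: tuple[float, ...]
    phases: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.amplitudes)
        if n < 1:
            raise ValueError("square wave needs at least one component")
        if not (len(self.frequencies) == len(self.phases) == n):
            raise ValueError("amplitudes, frequencies and phases must align")
        if any(a <= 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be positive")

    @property
    def n_components(self) -> int:
        return len(self.amplitudes)


def square_wave_voltage(spec: SquareWaveSpec, t) -> np.ndarray | float:
    """Evaluate the square-wave voltage at time(s) t in ms.

    sign(0) = 0 exactly, so at a component's zero crossing that component
    contributes nothing.
    """
    t = np.asarray(t, dtype=float)
    v = np.full_like(t, spec.offset, dtype=float)
    for a, w, phi in zip(spec.amplitudes, spec.frequencies, spec.phases):
        v = v + a * np.sign(np.sin(w * t + phi))
    return float(v) if v.ndim == 0 else v


def square_wave_to_segments(spec: SquareWaveSpec, total_duration: float,
                            name: str = "squarewave",
                            max_segments: int = 10_000) -> Protocol:
    """Convert a square-wave spec to an equivalent piecewise-constant Protocol.

    Breakpoints are the union of all component zero crossings
    t = (k*pi - phi)/w inside (0, total_duration), deduplicated within
    1e-9 ms.  Between breakpoints every component sign is constant, so each
    emitted step equals the closed form everywhere except the measure-zero
    switching instants themselves.
    """
    if total_duration <= 0:
        raise ValueError("total_duration must be > 0 ms")
    crossings: list[float] = []
    for w, phi in zip(spec.frequencies, spec.phases):
        k_lo = math.ceil(phi / math.pi)
        k_hi = math.floor((w * total_duration + phi) / math.pi)
        for k in range(k_lo, k_hi + 1):
            t = (k * math.pi - phi) / w
            if 1e-9 < t < total_duration - 1e-9:
                crossings.append(t)
    crossings.sort()
    breaks = [0.0]
    for t in crossings:
        if t - breaks[-1] > 1e-9:
            breaks.append(t)
    breaks.append(total_duration)
    if len(breaks) - 1 > max_segments:
        raise ValueError(
            f"square wave conversion would need {len(breaks) - 1} segments "
            f"(> max_segments={max_segments})")
    segments = []
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        v = float(square_wave_voltage(spec, 0.5 * (lo + hi)))
        segments.append(Segment.step(hi - lo, v))
    return Protocol(tuple(segments), name)


def common_head() -> Protocol:
    """Common initial clamp section: leak ramp and conductance/activation step.

    Rows: 250 ms @ -80; 50 ms @ -120; 400 ms ramp -120 -> -80; 200 ms @ -80;
    1000 ms @ +40; 500 ms @ -120; 1000 ms @ -80 (total 3400 ms).
    """
    return Protocol((
        Segment.step(250.0, -80.0),
        Segment.step(50.0, -120.0),
        Segment.ramp(400.0, -120.0, -80.0),
        Segment.step(200.0, -80.0),
        Segment.step(1000.0, 40.0),
        Segment.step(500.0, -120.0),
        Segment.step(1000.0, -80.0),
    ), "common_head")


def common_tail() -> Protocol:
    """Common end clamp section: reversal-ramp sequence and closing step.

    Rows: 1000 ms @ -80; 500 ms @ +40; 10 ms @ -70; 100 ms ramp -70 -> -110;
    390 ms @ -120; 500 ms @ -80 (total 2500 ms).
    """
    return Protocol((
        Segment.step(1000.0, -80.0),
        Segment.step(500.0, 40.0),
        Segment.step(10.0, -70.0),
        Segment.ramp(100.0, -70.0, -110.0),
        Segment.step(390.0, -120.0),
        Segment.step(500.0, -80.0),
    ), "common_tail")


def with_head_and_tail(body: Protocol, name: str | None = None) -> Protocol:
    """Wrap a designed body with the common head and tail sections."""
    return common_head().concat(body, common_tail(), name=name or body.name)


def write_protocol(protocol: Protocol, path: str | Path) -> None:
    """Write a protocol as delimited text (kind, duration_ms, v_start_mV, v_end_mV)."""
    df = pd.DataFrame({
        "kind": [s.kind for s in protocol.segments],
        "duration_ms": [s.duration for s in protocol.segments],
        "v_start_mV": [s.v_start for s in protocol.segments],
        "v_end_mV": [s.v_end for s in protocol.segments],
    })
    df.to_csv(path, sep="\t", index=False)


def read_protocol(path: str | Path, name: str | None = None) -> Protocol:
    """Read a protocol file written by :func:`write_protocol`.

    Malformed rows are reported with their (1-based, header-exclusive) line
    numbers; step rows with differing start/end voltages are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = ["kind", "duration_ms", "v_start_mV", "v_end_mV"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    segments = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            segments.append(Segment(str(row.kind), float(row.duration_ms),
                                    float(row.v_start_mV), float(row.v_end_mV)))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, row {i}: {exc}") from None
    return Protocol(tuple(segments), name or path.stem)
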