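"""Self-contained fixture protocols and synthetic current data.

Everything here is generated programmatically from published step tables or
from clearly-labelled approximations — no downloads, and every dataset is
regenerable bit-identically from its seed.

The ``staircase_like`` protocol is a *synthetic approximation* of the
manually designed staircase protocol family (whose exact step tables are
distributed in a supplementary spreadsheet): a rising then falling ladder
of 500 ms steps spanning the design voltage range.  It exercises the same
activation/deactivation/inactivation dynamics and is good enough for
solver cross-checks and parameter-recovery exercises, but it is not the
published protocol row-for-row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gating import GatingModel
from .parameters import KineticParameters
from .protocols import (
    Protocol,
    Segment,
    SquareWaveSpec,
    common_head,
    common_tail,
    square_wave_to_segments,
    with_head_and_tail,
)
from .simulation import simulate

__all__ = [
    "paper_squarewave_spec",
    "squarewave_protocol",
    "staircase_like_protocol",
    "toy_3step_protocol",
    "fixture_protocols",
    "SyntheticCurrent",
    "make_synthetic_current",
]

#: Default synthetic measurement noise, nA (typical RMS noise of an
#: automated patch recording at ~1 kHz sampling).
DEFAULT_NOISE_SD = 0.05


def paper_squarewave_spec() -> SquareWaveSpec:
    """The published 3-component square-wave conversion of the sinusoidal
    protocol: amplitudes 54/26/10 mV, angular frequencies 0.007/0.037/0.19
    rad/ms, zero phases, offset -30 mV."""
    return SquareWaveSpec(offset=-30.0, amplitudes=(54.0, 26.0, 10.0),
                          frequencies=(0.007, 0.037, 0.19),
                          phases=(0.0, 0.0, 0.0))


def squarewave_protocol(duration: float = 680.0,
                        with_common: bool = True) -> Protocol:
    """Square-wave fixture converted to steps.

    The published body duration is not printed; the 680 ms default yields a
    51-step body, i.e. 64 commands once the common head and tail are added.
    """
    body = square_wave_to_segments(paper_squarewave_spec(), duration,
                                   name="squarewave")
    return with_head_and_tail(body, name="squarewave") if with_common else body


def staircase_like_protocol(with_common: bool = True) -> Protocol:
    """Approximate (synthetic) staircase protocol: 500 ms ladder steps
    from -120 mV up to +40 mV and back down.  See the module docstring for
    what this is and is not."""
    up = [Segment.step(500.0, v) for v in np.arange(-120.0, 41.0, 20.0)]
    down = [Segment.step(500.0, v) for v in np.arange(20.0, -101.0, -20.0)]
    body = Protocol(tuple(up + down), "staircase_like")
    return with_head_and_tail(body, name="staircase_like") if with_common else body


def toy_3step_protocol() -> Protocol:
    """Minimal 3-step body (activate, tail, re-polarise) for fast tests."""
    return Protocol((Segment.step(500.0, 40.0),
                     Segment.step(500.0, -40.0),
                     Segment.step(500.0, -80.0)), "toy_3step")


def fixture_protocols() -> dict[str, Protocol]:
    """All named fixture protocols, regenerated on each call."""
    return {
        "table2_head": common_head(),
        "table2_tail": common_tail(),
        "squarewave_paper": squarewave_protocol(),
        "staircase_like": staircase_like_protocol(),
        "toy_3step": toy_3step_protocol(),
    }


@dataclass(frozen=True)
class SyntheticCurrent:
    """A noisy synthetic current trace with its generating ground truth."""

    times: np.ndarray
    observed: np.ndarray
    true_current: np.ndarray
    protocol: Protocol
    model_name: str
    true_params: KineticParameters
    noise_sd: float
    seed: int


def make_synthetic_current(model: GatingModel, protocol: Protocol,
                           noise_sd: float = DEFAULT_NOISE_SD,
                           seed: int = 0, dt_out: float = 1.0) -> SyntheticCurrent:
    """Simulate a current and add iid Gaussian measurement noise.

    The ground-truth parameters are stored alongside the trace so recovery
    exercises can score themselves.  Identical (model, protocol, noise_sd,
    seed) inputs give bit-identical traces.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    res = simulate(model, protocol, dt_out=dt_out)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=res.current.size) if noise_sd > 0 \
        else np.zeros_like(res.current)
    return SyntheticCurrent(res.times, res.current + noise, res.current,
                            protocol, model.name, model.params, noise_sd, seed)
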