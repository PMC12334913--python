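"""Protocol and current figures (voltage panel above simulated currents)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .gating import GatingModel
from .protocols import Protocol
from .simulation import simulate

__all__ = ["plot_protocol_and_currents"]


def plot_protocol_and_currents(protocol: Protocol, models: list[GatingModel],
                               out_dir: str | Path, dt_out: float = 1.0,
                               prefix: str | None = None) -> list[Path]:
    """Render the voltage waveform with each model's simulated current.

    Writes ``<prefix or protocol.name>.png`` into ``out_dir`` and returns
    the written paths (deterministic naming).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fig, (ax_v, ax_i) = plt.subplots(2, 1, sharex=True, figsize=(9, 5),
                                     height_ratios=[1, 1.4])
    first = models[0] if models else None
    times = None
    for model in models:
        res = simulate(model, protocol, dt_out=dt_out)
        times = res.times
        ax_i.plot(times / 1e3, res.current, lw=0.8, label=model.name)
    if times is None:
        from .simulation import output_grid
        times = output_grid(protocol, dt_out)
    ax_v.plot(times / 1e3, protocol.voltage_trace(times), color="k", lw=0.9)
    ax_v.set_ylabel("voltage (mV)")
    ax_i.set_ylabel("current (nA)")
    ax_i.set_xlabel("time (s)")
    if models:
        ax_i.legend(frameon=False, fontsize=8)
    fig.suptitle(protocol.name)
    fig.tight_layout()
    path = out_dir / f"{prefix or protocol.name}.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return [path]
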