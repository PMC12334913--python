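"""Protocol-scoring objective functions used by the automated designers.

Five families are implemented, all operating on one 3-step design unit
appended to a fixed *context* protocol (the common head plus previously
accepted units):

* ``local_sens`` — normalised local parameter sensitivity over the unit's
  third step: S_i = int |dI/dp_i p_i| dt / sum_k int |dI/dp_k p_k| dt.
  Integrating only the last step lets the first two steps prime the channel
  into whatever state makes the third step informative.
* ``sobol`` — first-order Sobol index Var_{p_i}(E(I|p_i))/Var(I) of the
  current, estimated Saltelli-style over the fitted parameter ranges and
  averaged over the third-step samples.
* ``brute_rmsd`` — output spread over M parameter draws:
  S = 2/M^2 * sum_{j<k} RMSD(I_j, I_k), evaluated over all three steps.
* ``discrim`` — RMSD between the currents of two candidate models at their
  default parameters, over all three steps.
* ``spacefill`` — number of previously unvisited boxes of the discretised
  (a, r, V) phase-voltage space entered by the trajectory, sampled at 1 ms.

The scoring window choice (third step for the sensitivity objectives, all
three steps for the comparison objectives) is exposed via ``window=``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .gating import GatingModel
from .parameters import ParameterRanges
from .protocols import Protocol, Segment
from .simulation import (
    local_sensitivities,
    output_grid,
    rmsd,
    simulate,
    simulate_hh_gates,
)

__all__ = [
    "DesignUnit",
    "PhaseGrid",
    "ParameterSampleSet",
    "sample_parameters",
    "local_sensitivity_objective",
    "sobol_first_order_indices",
    "sobol_first_order_objective",
    "brute_force_spread_objective",
    "model_discrimination_objective",
    "phase_coverage",
    "OBJECTIVE_NAMES",
]

OBJECTIVE_NAMES = ("local_sens", "sobol", "brute_rmsd", "discrim", "spacefill")


@dataclass(frozen=True)
class DesignUnit:
    """One 3-step design block: voltages (mV) and durations (ms).

    ``free_mask`` marks which of the six scalars (V1..V3, dt1..dt3) an
    optimiser may move; frozen entries hold Gibbs-style random draws.
    """

    voltages: tuple[float, float, float]
    durations: tuple[float, float, float]
    free_mask: tuple[bool, bool, bool, bool, bool, bool] = (True,) * 6

    def __post_init__(self) -> None:
        if len(self.voltages) != 3 or len(self.durations) != 3:
            raise ValueError("a design unit has exactly 3 steps")
        if any(d <= 0 for d in self.durations):
            raise ValueError("step durations must be > 0 ms")

    @property
    def segments(self) -> tuple[Segment, Segment, Segment]:
        return tuple(Segment.step(d, v)
                     for v, d in zip(self.voltages, self.durations))

    def as_protocol(self, name: str = "unit") -> Protocol:
        return Protocol(self.segments, name)

    @property
    def total_duration(self) -> float:
        return float(sum(self.durations))


def _unit_windows(context: Protocol, unit: DesignUnit, dt_out: float):
    """Sample-index windows of the appended unit on the combined output grid.

    Returns (protocol, full_window, third_step_window) where the windows are
    slices into ``output_grid(protocol, dt_out)``.
    """
    protocol = context.concat(unit.as_protocol(), name=context.name)
    times = output_grid(protocol, dt_out)
    t_ctx = context.total_duration
    t_third = t_ctx + unit.durations[0] + unit.durations[1]
    t_end = t_ctx + unit.total_duration
    full = slice(np.searchsorted(times, t_ctx - 1e-9),
                 np.searchsorted(times, t_end - 1e-9))
    third = slice(np.searchsorted(times, t_third - 1e-9),
                  np.searchsorted(times, t_end - 1e-9))
    return protocol, full, third


def _window_slice(full: slice, third: slice, window: str) -> slice:
    if window == "third_step":
        return third
    if window == "unit":
        return full
    raise ValueError(f"unknown window {window!r}")


# ---------------------------------------------------------------------------
# Local sensitivity
# ---------------------------------------------------------------------------

def local_sensitivity_objective(i: int, unit: DesignUnit, context: Protocol,
                                model: GatingModel, delta_frac: float = 1e-3,
                                dt_out: float = 1.0,
                                include_conductance: bool = False,
                                window: str = "third_step") -> float:
    """Normalised scaled-sensitivity share of parameter i over the window.

    Lies in [0, 1]; the shares of all parameters over the same window sum
    to one.  Returns 0 (with a warning) when no parameter moves the current
    at all in the window.
    """
    n_params = len(model.params) + int(include_conductance)
    if not 0 <= i < n_params:
        raise IndexError(f"parameter index {i} out of range for {n_params} parameters")
    protocol, full, third = _unit_windows(context, unit, dt_out)
    sens = local_sensitivities(model, protocol, delta_frac, dt_out,
                               include_conductance=include_conductance)
    win = _window_slice(full, third, window)
    integrals = np.abs(sens.matrix[win]).sum(axis=0) * dt_out
    total = integrals.sum()
    if total < 1e-300:
        warnings.warn("no current sensitivity in the scoring window; objective is 0",
                      stacklevel=2)
        return 0.0
    return float(integrals[i] / total)


# ---------------------------------------------------------------------------
# Sobol first-order indices (Saltelli estimator)
# ---------------------------------------------------------------------------

def saltelli_sample(lower: np.ndarray, upper: np.ndarray, n_base: int,
                    seed: int, scale: str = "linear") -> np.ndarray:
    """Saltelli cross-sampling design: returns (n_base*(d+2), d) points.

    Rows are ordered [A; B; AB_1; ...; AB_d] where AB_i is A with column i
    replaced from B.  Quasi-random (scrambled Sobol') base sample of 2d
    columns; deterministic given the seed.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    d = lower.size
    sampler = qmc.Sobol(d=2 * d, scramble=True, seed=seed)
    base = sampler.random(n_base)
    if scale == "log":
        lo, hi = np.log(lower), np.log(upper)
    elif scale == "linear":
        lo, hi = lower, upper
    else:
        raise ValueError(f"unknown scale {scale!r}")
    A = lo + base[:, :d] * (hi - lo)
    B = lo + base[:, d:] * (hi - lo)
    blocks = [A, B]
    for i in range(d):
        AB = A.copy()
        AB[:, i] = B[:, i]
        blocks.append(AB)
    out = np.vstack(blocks)
    return np.exp(out) if scale == "log" else out


def sobol_first_order_indices(outputs: np.ndarray, n_base: int, d: int) -> np.ndarray:
    """First-order indices from model outputs on a Saltelli design.

    ``outputs`` has shape (n_base*(d+2), T) in block order [A; B; AB_1..AB_d].
    Returns (d, T) per-output-time indices (Saltelli-2010 estimator),
    un-clipped so estimator noise is visible to callers.
    """
    outputs = np.atleast_2d(np.asarray(outputs, dtype=float))
    if outputs.shape[0] != n_base * (d + 2):
        raise ValueError("outputs do not match the Saltelli block structure")
    fA = outputs[:n_base]
    fB = outputs[n_base:2 * n_base]
    var = np.var(np.vstack([fA, fB]), axis=0)
    indices = np.empty((d, outputs.shape[1]))
    for i in range(d):
        fABi = outputs[(2 + i) * n_base:(3 + i) * n_base]
        indices[i] = np.mean(fB * (fABi - fA), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        indices = np.where(var > 0, indices / var, 0.0)
    return indices


def sobol_first_order_objective(i: int, unit: DesignUnit, context: Protocol,
                                model: GatingModel,
                                ranges: ParameterRanges | None = None,
                                n_base: int = 256, seed: int = 0,
                                scale: str = "log", dt_out: float = 1.0,
                                window: str = "third_step") -> float:
    """Time-averaged first-order Sobol index of parameter i over the window.

    Parameter draws span the fitted ranges (log-uniform by default — several
    span multiple decades).  Clipped to [0, 1]; returns 0 with a warning if
    the current does not vary over the window at all.
    """
    ranges = ranges if ranges is not None else model.ranges
    if ranges is None:
        raise ValueError("model has no parameter ranges; pass ranges explicitly")
    d = len(ranges)
    if not 0 <= i < d:
        raise IndexError(f"parameter index {i} out of range")
    protocol, full, third = _unit_windows(context, unit, dt_out)
    win = _window_slice(full, third, window)
    samples = saltelli_sample(ranges.lower, ranges.upper, n_base, seed, scale)
    outputs = np.empty((samples.shape[0], win.stop - win.start))
    for j, values in enumerate(samples):
        m = model.with_params(model.params.with_values(values))
        outputs[j] = simulate(m, protocol, dt_out=dt_out).current[win]
    var = np.var(outputs[:2 * n_base], axis=0)
    if np.all(var < 1e-300):
        warnings.warn("current does not vary over the window; Sobol objective is 0",
                      stacklevel=2)
        return 0.0
    indices = sobol_first_order_indices(outputs, n_base, d)
    keep = var > 1e-300
    return float(np.clip(np.mean(indices[i, keep]), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Sampled-parameter output spread (brute force) and model discrimination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterSampleSet:
    """M kinetic-parameter draws from a prior over the fitted ranges."""

    values: np.ndarray  # (M, d)
    scale: str
    seed: int

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[0] < 2:
            raise ValueError("need at least M=2 parameter samples")

    @property
    def m(self) -> int:
        return self.values.shape[0]


def sample_parameters(ranges: ParameterRanges, m: int, seed: int,
                      scale: str = "log") -> ParameterSampleSet:
    """Draw M parameter vectors from the ranges (log-uniform by default)."""
    if m < 2:
        raise ValueError("M must be >= 2")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=(m, len(ranges)))
    if scale == "log":
        lo, hi = np.log(ranges.lower), np.log(ranges.upper)
        values = np.exp(lo + u * (hi - lo))
    elif scale == "linear":
        values = ranges.lower + u * (ranges.upper - ranges.lower)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return ParameterSampleSet(values, scale, seed)


def pairwise_rmsd_spread(currents: np.ndarray) -> float:
    """Eq.-style spread 2/M^2 * sum_{j<k} RMSD(I_j, I_k) for rows of currents."""
    currents = np.atleast_2d(np.asarray(currents, dtype=float))
    m, t = currents.shape
    if m < 2:
        raise ValueError("need at least two traces")
    gram = currents @ currents.T
    sq = np.diag(gram)
    msd = (sq[:, None] + sq[None, :] - 2.0 * gram) / t
    d = np.sqrt(np.maximum(msd, 0.0))
    return float(d[np.triu_indices(m, k=1)].sum() * 2.0 / m ** 2)


def brute_force_spread_objective(unit: DesignUnit, context: Protocol,
                                 model: GatingModel,
                                 samples: ParameterSampleSet,
                                 dt_out: float = 1.0,
                                 window: str = "unit") -> float:
    """Mean pairwise-RMSD spread of the current over M parameter draws."""
    protocol, full, third = _unit_windows(context, unit, dt_out)
    win = _window_slice(full, third, window)
    currents = np.empty((samples.m, win.stop - win.start))
    for j, values in enumerate(samples.values):
        m = model.with_params(model.params.with_values(values))
        currents[j] = simulate(m, protocol, dt_out=dt_out).current[win]
    return pairwise_rmsd_spread(currents)


def model_discrimination_objective(unit: DesignUnit, context: Protocol,
                                   model_a: GatingModel, model_b: GatingModel,
                                   dt_out: float = 1.0,
                                   window: str = "unit") -> float:
    """RMSD between two models' currents over the unit window (symmetric)."""
    protocol, full, third = _unit_windows(context, unit, dt_out)
    win = _window_slice(full, third, window)
    ia = simulate(model_a, protocol, dt_out=dt_out).current[win]
    ib = simulate(model_b, protocol, dt_out=dt_out).current[win]
    return rmsd(ia, ib)


# ---------------------------------------------------------------------------
# Phase-voltage space coverage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseGrid:
    """Box discretisation of the (a, r, V) phase-voltage space."""

    bounds: tuple[tuple[float, float], ...] = ((0.0, 1.0), (0.0, 1.0), (-120.0, 60.0))
    subdivisions: tuple[int, ...] = (6, 6, 6)

    def __post_init__(self) -> None:
        if len(self.bounds) != len(self.subdivisions):
            raise ValueError("bounds and subdivisions must align")
        if any(hi <= lo for lo, hi in self.bounds):
            raise ValueError("bounds must be ordered")
        if any(n < 1 for n in self.subdivisions):
            raise ValueError("subdivisions must be >= 1")

    @property
    def n_boxes(self) -> int:
        return int(np.prod(self.subdivisions))

    def box_indices(self, points: np.ndarray) -> np.ndarray:
        """Flat box index per point; the top edge of the last bin is closed.

        Points outside the bounds are clamped into the edge bins (the
        voltage may touch the bounds exactly) with a warning.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        flat = np.zeros(points.shape[0], dtype=np.int64)
        stride = 1
        out_of_bounds = False
        for dim in range(len(self.bounds) - 1, -1, -1):
            lo, hi = self.bounds[dim]
            n = self.subdivisions[dim]
            x = points[:, dim]
            if np.any((x < lo) | (x > hi)):
                out_of_bounds = True
            idx = np.floor((x - lo) / (hi - lo) * n).astype(np.int64)
            idx = np.clip(idx, 0, n - 1)
            flat += idx * stride
            stride *= n
        if out_of_bounds:
            warnings.warn("trajectory samples outside the phase grid bounds "
                          "were clamped into edge bins", stacklevel=2)
        return flat


def phase_coverage(trajectory: np.ndarray, grid: PhaseGrid,
                   already_visited: set[int] | None = None) -> tuple[int, set[int]]:
    """Count newly visited boxes and return the updated visited set.

    ``trajectory`` is an (n, 3) array of (a, r, V) samples (1 ms sampling in
    the published design runs).
    """
    visited = set() if already_visited is None else set(already_visited)
    boxes = set(int(b) for b in grid.box_indices(trajectory))
    new = boxes - visited
    return len(new), visited | new


def beattie_phase_trajectory(model: GatingModel, protocol: Protocol,
                             dt_out: float = 1.0,
                             initial: tuple[float, float] | None = None) -> np.ndarray:
    """(a, r, V) samples of the 4-state model's HH gates under a protocol."""
    times, a, r = simulate_hh_gates(model.params, protocol, initial, dt_out)
    v = protocol.voltage_trace(times)
    return np.column_stack([a, r, v])
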