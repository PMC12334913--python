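"""Automated protocol designers: iterative 3-step CMA-ES optimisation,
Gibbs variants, phase-space-filling run selection, and the 9-parameter
square-wave discrimination design.

A designed protocol body consists of N units of three constant-voltage
steps.  Units are optimised sequentially: unit i is scored with the common
head and all previously accepted units as fixed context, so each objective
evaluation only needs to advance the model from the cached context-end
state through the three candidate steps.  For the 4-state model this uses
the closed-form Hodgkin-Huxley relaxation; other models use the exact
matrix-exponential (eigendecomposition) propagator with per-voltage
caching.  The cached fast path samples the same global 1 ms output grid as
the reference simulator, so a stored unit score equals re-evaluation of the
public objective function on the exported protocol.

Optimised scalars are rounded to 0.1 ms / 0.1 mV (the practical hardware
resolution) *before* restart winners are compared, so the reported score is
the score of the shipped, rounded protocol.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .cmaes import cmaes_minimize
from .gating import DEFAULT_E_REV, GatingModel, get_model, steady_state
from .objectives import (
    DesignUnit,
    ParameterSampleSet,
    PhaseGrid,
    beattie_phase_trajectory,
    pairwise_rmsd_spread,
    saltelli_sample,
    sample_parameters,
    sobol_first_order_indices,
)
from .protocols import Protocol, common_head, with_head_and_tail
from .simulation import hh_batch_currents, rmsd, simulate
from .protocols import Segment, SquareWaveSpec, square_wave_to_segments

logger = logging.getLogger(__name__)

__all__ = [
    "DesignConfig",
    "DesignResult",
    "SpacefillSelection",
    "SquareWaveDesignResult",
    "iterative_design",
    "spacefill_design",
    "squarewave_discrimination_design",
]

_PER_PARAMETER_OBJECTIVES = ("local_sens", "sobol")


@dataclass(frozen=True)
class DesignConfig:
    """Configuration of one iterative 3-step design run."""

    objective: str = "spacefill"
    model: str = "beattie"
    model_b: str = "wang"             # second model for discrimination
    n_units: int | None = None        # default: #parameters or 17
    v_bounds: tuple[float, float] = (-120.0, 60.0)
    dt_bounds: tuple[float, float] = (50.0, 1000.0)
    n_restarts: int = 10
    seed: int = 0
    rounding: float = 0.1             # ms and mV resolution
    gibbs_mode: str = "none"          # none | random_dt | random_v | alternating
    random_dt_range: tuple[float, float] = (50.0, 1000.0)
    random_v_range: tuple[float, float] = (-120.0, 60.0)
    dt_out: float = 1.0
    e_rev: float = DEFAULT_E_REV
    include_conductance: bool = False
    delta_frac: float = 1e-3
    sobol_n_base: int = 64
    sample_m: int = 100
    sample_scale: str = "log"
    popsize: int | None = None
    max_iter: int = 100
    sigma0: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        if self.n_units is not None and self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.v_bounds[0] >= self.v_bounds[1] or self.dt_bounds[0] >= self.dt_bounds[1]:
            raise ValueError("bounds must be ordered")
        if self.gibbs_mode not in ("none", "random_dt", "random_v", "alternating"):
            raise ValueError(f"unknown gibbs_mode {self.gibbs_mode!r}")


@dataclass(frozen=True)
class DesignResult:
    """Outcome of one design run: the protocol and per-unit bookkeeping."""

    config: DesignConfig
    units: tuple[DesignUnit, ...]
    unit_scores: tuple[float, ...]
    body: Protocol
    protocol: Protocol          # head + body + tail

    @property
    def n_commands(self) -> int:
        return len(self.protocol)


# ---------------------------------------------------------------------------
# Cached-context steppers
# ---------------------------------------------------------------------------

def _window_offsets(t_ctx: float, durations, dt_out: float) -> np.ndarray:
    """Global-grid sample times in [t_ctx, t_ctx+sum(durations)), as offsets."""
    total = float(np.sum(durations))
    k0 = int(np.ceil(t_ctx / dt_out - 1e-9))
    k1 = int(np.ceil((t_ctx + total) / dt_out - 1e-9))
    return np.arange(k0, k1) * dt_out - t_ctx


def _segment_masks(offsets: np.ndarray, durations) -> list[np.ndarray]:
    cum = np.concatenate([[0.0], np.cumsum(durations)])
    return [(offsets >= cum[j] - 1e-9) & (offsets < cum[j + 1] - 1e-9)
            for j in range(len(durations))]


def _hh_gate_rates_batch(P: np.ndarray, V: float):
    """Vectorised (a_inf, tau_a, r_inf, tau_r) for rows of a (M, 8) matrix."""
    k1 = P[:, 0] * np.exp(P[:, 1] * V)
    k2 = P[:, 2] * np.exp(-P[:, 3] * V)
    k3 = P[:, 4] * np.exp(P[:, 5] * V)
    k4 = P[:, 6] * np.exp(-P[:, 7] * V)
    return k1 / (k1 + k2), 1.0 / (k1 + k2), k4 / (k3 + k4), 1.0 / (k3 + k4)


class HHBatchStepper:
    """Analytic two-gate stepper for (a batch of) 4-state parameter vectors."""

    def __init__(self, param_matrix: np.ndarray, conductance, context: Protocol,
                 e_rev: float = DEFAULT_E_REV, dt_out: float = 1.0):
        self.P = np.atleast_2d(np.asarray(param_matrix, dtype=float))  # (M, 8)
        self.g = np.broadcast_to(np.asarray(conductance, dtype=float),
                                 (self.P.shape[0],)).copy()
        self.e_rev = e_rev
        self.dt_out = dt_out
        a_inf, _, r_inf, _ = self._gate_rates(-80.0)
        self.a, self.r = a_inf, r_inf
        self.t_ctx = 0.0
        for seg in context.segments:
            self._advance_segment(seg)
        self.t_ctx = context.total_duration

    def _gate_rates(self, V: float):
        return _hh_gate_rates_batch(self.P, V)

    def _advance_segment(self, seg) -> None:
        if seg.kind == "step":
            a_inf, tau_a, r_inf, tau_r = self._gate_rates(seg.v_start)
            self.a = a_inf + (self.a - a_inf) * np.exp(-seg.duration / tau_a)
            self.r = r_inf + (self.r - r_inf) * np.exp(-seg.duration / tau_r)
        else:
            m = self.P.shape[0]
            slope = (seg.v_end - seg.v_start) / seg.duration

            def rhs(tau, y):
                a, r = y[:m], y[m:]
                a_inf, tau_a, r_inf, tau_r = self._gate_rates(seg.v_start + slope * tau)
                return np.concatenate([(a_inf - a) / tau_a, (r_inf - r) / tau_r])

            sol = solve_ivp(rhs, (0.0, seg.duration),
                            np.concatenate([self.a, self.r]),
                            rtol=1e-8, atol=1e-10, method="LSODA")
            if not sol.success:
                raise RuntimeError(f"gate batch ODE failed: {sol.message}")
            self.a = np.clip(sol.y[:m, -1], 0.0, 1.0)
            self.r = np.clip(sol.y[m:, -1], 0.0, 1.0)

    def run(self, voltages, durations):
        """Simulate the candidate steps without mutating the cached state.

        Returns (current (M, T), open (M, T), v_trace (T,), offsets (T,)).
        """
        offsets = _window_offsets(self.t_ctx, durations, self.dt_out)
        masks = _segment_masks(offsets, durations)
        m, t = self.P.shape[0], offsets.size
        a_traj = np.empty((m, t))
        r_traj = np.empty((m, t))
        v_trace = np.empty(t)
        a, r = self.a, self.r
        cum = 0.0
        for V, dt, mask in zip(voltages, durations, masks):
            a_inf, tau_a, r_inf, tau_r = self._gate_rates(V)
            rel = offsets[mask] - cum
            ea = np.exp(-rel[None, :] / tau_a[:, None])
            er = np.exp(-rel[None, :] / tau_r[:, None])
            a_traj[:, mask] = a_inf[:, None] + (a - a_inf)[:, None] * ea
            r_traj[:, mask] = r_inf[:, None] + (r - r_inf)[:, None] * er
            v_trace[mask] = V
            a = a_inf + (a - a_inf) * np.exp(-dt / tau_a)
            r = r_inf + (r - r_inf) * np.exp(-dt / tau_r)
            cum += dt
        open_prob = a_traj * r_traj
        current = self.g[:, None] * open_prob * (v_trace[None, :] - self.e_rev)
        return current, open_prob, v_trace, offsets

    def advance(self, voltages, durations) -> None:
        for V, dt in zip(voltages, durations):
            self._advance_segment(Segment.step(dt, V))
        self.t_ctx += float(np.sum(durations))


class MarkovStepper:
    """Exact-propagator stepper for a general gating model (single params)."""

    def __init__(self, model: GatingModel, context: Protocol,
                 e_rev: float = DEFAULT_E_REV, dt_out: float = 1.0):
        self.model = model
        self.e_rev = e_rev
        self.dt_out = dt_out
        self.x = steady_state(model, -80.0)
        self._eig_cache: dict[float, tuple] = {}
        self.t_ctx = 0.0
        for seg in context.segments:
            self._advance_segment(seg)
        self.t_ctx = context.total_duration

    def _eig(self, V: float):
        hit = self._eig_cache.get(V)
        if hit is None:
            A = self.model.matrix_builder(V, self.model.params)
            lam, S = np.linalg.eig(A)
            hit = (lam, S, np.linalg.inv(S))
            self._eig_cache[V] = hit
        return hit

    def _step_states(self, V: float, x0: np.ndarray, taus: np.ndarray) -> np.ndarray:
        lam, S, Sinv = self._eig(V)
        return ((np.exp(np.outer(taus, lam)) * (Sinv @ x0)) @ S.T).real

    def _advance_segment(self, seg) -> None:
        if seg.kind == "step":
            self.x = self._step_states(seg.v_start, self.x, np.array([seg.duration]))[0]
        else:
            slope = (seg.v_end - seg.v_start) / seg.duration

            def rhs(tau, x):
                A = self.model.matrix_builder(seg.v_start + slope * tau,
                                              self.model.params)
                return A @ x

            sol = solve_ivp(rhs, (0.0, seg.duration), self.x,
                            rtol=1e-8, atol=1e-10, method="LSODA")
            if not sol.success:
                raise RuntimeError(f"context ramp integration failed: {sol.message}")
            self.x = sol.y[:, -1]

    def run(self, voltages, durations):
        """Returns (current (T,), open (T,), v_trace (T,), offsets (T,))."""
        offsets = _window_offsets(self.t_ctx, durations, self.dt_out)
        masks = _segment_masks(offsets, durations)
        states = np.empty((offsets.size, self.model.n_states))
        v_trace = np.empty(offsets.size)
        x = self.x
        cum = 0.0
        for V, dt, mask in zip(voltages, durations, masks):
            rel = offsets[mask] - cum
            states[mask] = self._step_states(V, x, rel)
            x = self._step_states(V, x, np.array([dt]))[0]
            v_trace[mask] = V
            cum += dt
        open_prob = states[:, self.model.open_state_index]
        current = (self.model.params.conductance * open_prob
                   * (v_trace - self.e_rev))
        return current, open_prob, v_trace, offsets

    def advance(self, voltages, durations) -> None:
        for V, dt in zip(voltages, durations):
            self.x = self._step_states(V, self.x, np.array([dt]))[0]
        self.t_ctx += float(np.sum(durations))


def _make_stepper(model: GatingModel, context: Protocol, e_rev: float,
                  dt_out: float):
    if model.name == "beattie":
        return HHBatchStepper(model.params.values[None, :],
                              model.params.conductance, context, e_rev, dt_out)
    return MarkovStepper(model, context, e_rev, dt_out)


def _run_single(stepper, voltages, durations):
    """Current trace (T,) from either stepper flavour."""
    current = stepper.run(voltages, durations)[0]
    return current[0] if current.ndim == 2 else current


# ---------------------------------------------------------------------------
# Unit evaluators (all maximise)
# ---------------------------------------------------------------------------

class _SpacefillEvaluator:
    """New-box count in the (a, r, V) phase grid, cumulative across units."""

    def __init__(self, model: GatingModel, context: Protocol, cfg: DesignConfig):
        if model.name != "beattie":
            raise ValueError("the space-filling objective uses the 4-state model's HH gates")
        self.grid = PhaseGrid()
        self.stepper = HHBatchStepper(model.params.values[None, :],
                                      model.params.conductance, context,
                                      cfg.e_rev, cfg.dt_out)
        traj = beattie_phase_trajectory(model, context, cfg.dt_out)
        self.visited = np.zeros(self.grid.n_boxes, dtype=bool)
        self.visited[self.grid.box_indices(traj)] = True

    def set_unit_index(self, i: int) -> None:
        pass

    def evaluate(self, voltages, durations) -> float:
        stepper = self.stepper
        offsets = _window_offsets(stepper.t_ctx, durations, stepper.dt_out)
        masks = _segment_masks(offsets, durations)
        a, r = stepper.a[0], stepper.r[0]
        boxes = np.zeros(offsets.size, dtype=np.int64)
        cum = 0.0
        for V, dt, mask in zip(voltages, durations, masks):
            a_inf, tau_a, r_inf, tau_r = stepper._gate_rates(V)
            a_inf, tau_a = a_inf[0], tau_a[0]
            r_inf, tau_r = r_inf[0], tau_r[0]
            rel = offsets[mask] - cum
            aa = a_inf + (a - a_inf) * np.exp(-rel / tau_a)
            rr = r_inf + (r - r_inf) * np.exp(-rel / tau_r)
            boxes[mask] = self.grid.box_indices(
                np.column_stack([aa, rr, np.full(aa.size, V)]))
            a = a_inf + (a - a_inf) * np.exp(-dt / tau_a)
            r = r_inf + (r - r_inf) * np.exp(-dt / tau_r)
            cum += dt
        return float(np.count_nonzero(~self.visited[np.unique(boxes)]))

    def accept(self, voltages, durations) -> None:
        stepper = self.stepper
        offsets = _window_offsets(stepper.t_ctx, durations, stepper.dt_out)
        masks = _segment_masks(offsets, durations)
        a, r = stepper.a[0], stepper.r[0]
        cum = 0.0
        for V, dt, mask in zip(voltages, durations, masks):
            a_inf, tau_a, r_inf, tau_r = (x[0] for x in stepper._gate_rates(V))
            rel = offsets[mask] - cum
            aa = a_inf + (a - a_inf) * np.exp(-rel / tau_a)
            rr = r_inf + (r - r_inf) * np.exp(-rel / tau_r)
            self.visited[self.grid.box_indices(
                np.column_stack([aa, rr, np.full(aa.size, V)]))] = True
            a = a_inf + (a - a_inf) * np.exp(-dt / tau_a)
            r = r_inf + (r - r_inf) * np.exp(-dt / tau_r)
            cum += dt
        stepper.advance(voltages, durations)

    @property
    def coverage(self) -> int:
        return int(self.visited.sum())


class _LocalSensEvaluator:
    """Third-step normalised sensitivity share for the unit's target parameter."""

    def __init__(self, model: GatingModel, context: Protocol, cfg: DesignConfig):
        self.cfg = cfg
        self.d = len(model.params)
        self.target = 0
        self.include_g = cfg.include_conductance
        rows = []
        for i in range(self.d):
            for sign in (+1.0, -1.0):
                values = model.params.values.copy()
                values[i] *= 1.0 + sign * cfg.delta_frac
                rows.append(values)
        if model.name == "beattie":
            self.steppers = [HHBatchStepper(np.vstack(rows), model.params.conductance,
                                            context, cfg.e_rev, cfg.dt_out)]
            self.base = (HHBatchStepper(model.params.values[None, :],
                                        model.params.conductance, context,
                                        cfg.e_rev, cfg.dt_out)
                         if self.include_g else None)
        else:
            self.steppers = [MarkovStepper(model.with_params(model.params.with_values(v)),
                                           context, cfg.e_rev, cfg.dt_out)
                             for v in rows]
            self.base = (MarkovStepper(model, context, cfg.e_rev, cfg.dt_out)
                         if self.include_g else None)

    def set_unit_index(self, i: int) -> None:
        self.target = i % (self.d + int(self.include_g))

    def _columns(self, voltages, durations) -> np.ndarray:
        """Scaled sensitivity columns over the third step, (T3, d[+1])."""
        dt3_start = durations[0] + durations[1]
        if len(self.steppers) == 1:
            currents = self.steppers[0].run(voltages, durations)[0]  # (2d, T)
        else:
            currents = np.vstack([_run_single(s, voltages, durations)
                                  for s in self.steppers])
        offsets = _window_offsets(self.steppers[0].t_ctx, durations,
                                  self.cfg.dt_out)
        third = offsets >= dt3_start - 1e-9
        cols = [(currents[2 * i][third] - currents[2 * i + 1][third])
                / (2.0 * self.cfg.delta_frac) for i in range(self.d)]
        if self.include_g:
            cols.append(_run_single(self.base, voltages, durations)[third])
        return np.column_stack(cols)

    def evaluate(self, voltages, durations) -> float:
        cols = self._columns(voltages, durations)
        integrals = np.abs(cols).sum(axis=0) * self.cfg.dt_out
        total = integrals.sum()
        return float(integrals[self.target] / total) if total > 1e-300 else 0.0

    def accept(self, voltages, durations) -> None:
        for s in self.steppers:
            s.advance(voltages, durations)
        if self.base is not None:
            self.base.advance(voltages, durations)


class _SobolEvaluator:
    """Time-averaged first-order Sobol index over the third step."""

    def __init__(self, model: GatingModel, context: Protocol, cfg: DesignConfig):
        self.cfg = cfg
        ranges = model.ranges
        if ranges is None:
            raise ValueError("model has no parameter ranges for Sobol sampling")
        self.d = len(ranges)
        self.n_base = cfg.sobol_n_base
        self.target = 0
        self.samples = saltelli_sample(ranges.lower, ranges.upper,
                                       self.n_base, cfg.seed, cfg.sample_scale)
        self.model = model
        if model.name == "beattie":
            self.steppers = [HHBatchStepper(self.samples, model.params.conductance,
                                            context, cfg.e_rev, cfg.dt_out)]
        else:
            self.steppers = [MarkovStepper(model.with_params(model.params.with_values(v)),
                                           context, cfg.e_rev, cfg.dt_out)
                             for v in self.samples]

    def set_unit_index(self, i: int) -> None:
        self.target = i % self.d

    def evaluate(self, voltages, durations) -> float:
        dt3_start = durations[0] + durations[1]
        if len(self.steppers) == 1:
            currents = self.steppers[0].run(voltages, durations)[0]
            t_ctx = self.steppers[0].t_ctx
        else:
            currents = np.vstack([_run_single(s, voltages, durations)
                                  for s in self.steppers])
            t_ctx = self.steppers[0].t_ctx
        offsets = _window_offsets(t_ctx, durations, self.cfg.dt_out)
        third = offsets >= dt3_start - 1e-9
        outputs = currents[:, third]
        var = np.var(outputs[:2 * self.n_base], axis=0)
        keep = var > 1e-300
        if not np.any(keep):
            return 0.0
        indices = sobol_first_order_indices(outputs, self.n_base, self.d)
        return float(np.clip(np.mean(indices[self.target, keep]), 0.0, 1.0))

    def accept(self, voltages, durations) -> None:
        for s in self.steppers:
            s.advance(voltages, durations)


class _BruteForceEvaluator:
    """Pairwise-RMSD spread of the current over M sampled parameter vectors."""

    def __init__(self, model: GatingModel, context: Protocol, cfg: DesignConfig,
                 samples: ParameterSampleSet | None = None):
        ranges = model.ranges
        if ranges is None:
            raise ValueError("model has no parameter ranges for prior sampling")
        self.samples = samples if samples is not None else sample_parameters(
            ranges, cfg.sample_m, cfg.seed, cfg.sample_scale)
        if model.name == "beattie":
            self.steppers = [HHBatchStepper(self.samples.values,
                                            model.params.conductance, context,
                                            cfg.e_rev, cfg.dt_out)]
        else:
            self.steppers = [MarkovStepper(model.with_params(model.params.with_values(v)),
                                           context, cfg.e_rev, cfg.dt_out)
                             for v in self.samples.values]

    def set_unit_index(self, i: int) -> None:
        pass

    def evaluate(self, voltages, durations) -> float:
        if len(self.steppers) == 1:
            currents = self.steppers[0].run(voltages, durations)[0]
        else:
            currents = np.vstack([_run_single(s, voltages, durations)
                                  for s in self.steppers])
        return pairwise_rmsd_spread(currents)

    def accept(self, voltages, durations) -> None:
        for s in self.steppers:
            s.advance(voltages, durations)


class _DiscriminationEvaluator:
    """RMSD between the currents of two candidate models (default parameters)."""

    def __init__(self, model_a: GatingModel, model_b: GatingModel,
                 context: Protocol, cfg: DesignConfig):
        self.stepper_a = _make_stepper(model_a, context, cfg.e_rev, cfg.dt_out)
        self.stepper_b = _make_stepper(model_b, context, cfg.e_rev, cfg.dt_out)

    def set_unit_index(self, i: int) -> None:
        pass

    def evaluate(self, voltages, durations) -> float:
        ia = _run_single(self.stepper_a, voltages, durations)
        ib = _run_single(self.stepper_b, voltages, durations)
        return rmsd(ia, ib)

    def accept(self, voltages, durations) -> None:
        self.stepper_a.advance(voltages, durations)
        self.stepper_b.advance(voltages, durations)


def _make_evaluator(cfg: DesignConfig, context: Protocol):
    model = get_model(cfg.model)
    if cfg.objective == "spacefill":
        return _SpacefillEvaluator(model, context, cfg)
    if cfg.objective == "local_sens":
        return _LocalSensEvaluator(model, context, cfg)
    if cfg.objective == "sobol":
        return _SobolEvaluator(model, context, cfg)
    if cfg.objective == "brute_rmsd":
        return _BruteForceEvaluator(model, context, cfg)
    if cfg.objective == "discrim":
        return _DiscriminationEvaluator(model, get_model(cfg.model_b), context, cfg)
    raise ValueError(f"unknown objective {cfg.objective!r}")


# ---------------------------------------------------------------------------
# Unit optimisation and the iterative designer
# ---------------------------------------------------------------------------

def _unit_free_mask(cfg: DesignConfig, unit_index: int) -> tuple[bool, ...]:
    """Which of (V1,V2,V3,dt1,dt2,dt3) are optimised for this unit."""
    mode = cfg.gibbs_mode
    if mode == "alternating":
        # 1-based odd units optimise voltages; even units optimise durations
        mode = "random_dt" if unit_index % 2 == 0 else "random_v"
    if mode == "none":
        return (True,) * 6
    if mode == "random_dt":
        return (True, True, True, False, False, False)
    return (False, False, False, True, True, True)


def optimise_unit(evaluator, cfg: DesignConfig, rng: np.random.Generator,
                  unit_index: int = 0) -> tuple[DesignUnit, float]:
    """CMA-ES optimisation of one 3-step unit with restarts and rounding.

    Frozen (Gibbs) scalars are drawn once per unit from their configured
    uniform ranges and rounded to the hardware resolution; each restart's
    winner is rounded and re-scored before restart winners are compared.
    """
    free = _unit_free_mask(cfg, unit_index)
    r = cfg.rounding
    frozen_v = np.round(rng.uniform(*cfg.random_v_range, size=3) / r) * r
    frozen_dt = np.round(rng.uniform(*cfg.random_dt_range, size=3) / r) * r
    full_lower = np.array([cfg.v_bounds[0]] * 3 + [cfg.dt_bounds[0]] * 3)
    full_upper = np.array([cfg.v_bounds[1]] * 3 + [cfg.dt_bounds[1]] * 3)
    idx_free = [i for i in range(6) if free[i]]
    lower, upper = full_lower[idx_free], full_upper[idx_free]

    def assemble(x_free: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        full = np.concatenate([frozen_v, frozen_dt])
        full[idx_free] = x_free
        return full[:3], full[3:]

    def neg_score(x_free: np.ndarray) -> float:
        vs, dts = assemble(x_free)
        return -evaluator.evaluate(vs, dts)

    best_x = None
    best_score = -np.inf
    for _ in range(cfg.n_restarts):
        x0 = rng.uniform(lower, upper)
        res = cmaes_minimize(neg_score, x0, cfg.sigma0, lower, upper, rng,
                             popsize=cfg.popsize, max_iter=cfg.max_iter)
        x_round = np.clip(np.round(res.x / r) * r, lower, upper)
        score = -neg_score(x_round)
        if score > best_score:
            best_score = score
            best_x = x_round
    vs, dts = assemble(best_x)
    unit = DesignUnit(tuple(vs), tuple(dts), free)
    return unit, float(best_score)


def iterative_design(cfg: DesignConfig) -> DesignResult:
    """Sequentially optimise N three-step units after the common head.

    For the per-parameter objectives (``local_sens``, ``sobol``) the default
    number of units equals the number of kinetic parameters and unit i
    targets parameter i; otherwise 17 units give a 51-step body (64 commands
    with the common head and tail).  Fully reproducible from ``cfg.seed``.
    """
    model = get_model(cfg.model)
    if cfg.n_units is not None:
        n_units = cfg.n_units
    elif cfg.objective in _PER_PARAMETER_OBJECTIVES:
        n_units = len(model.params) + int(cfg.include_conductance)
    else:
        n_units = 17
    rng = np.random.default_rng(cfg.seed)
    context = common_head()
    evaluator = _make_evaluator(cfg, context)
    units: list[DesignUnit] = []
    scores: list[float] = []
    for i in range(n_units):
        evaluator.set_unit_index(i)
        unit, score = optimise_unit(evaluator, cfg, rng, unit_index=i)
        evaluator.accept(unit.voltages, unit.durations)
        units.append(unit)
        scores.append(score)
        logger.info("unit %d/%d: score %.6g, V=%s mV, dt=%s ms",
                    i + 1, n_units, score, unit.voltages, unit.durations)
    body = Protocol(tuple(s for u in units for s in u.segments),
                    f"{cfg.objective}_design")
    full = with_head_and_tail(body, name=body.name)
    return DesignResult(cfg, tuple(units), tuple(scores), body, full)


# ---------------------------------------------------------------------------
# Space-filling run selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpacefillSelection:
    """All space-filling runs plus the best run under each selection criterion."""

    results: tuple[DesignResult, ...]
    coverages: tuple[int, ...]            # boxes visited by the full protocol
    discrimination: tuple[float, ...]     # RMSD between the two models' currents
    spread: tuple[float, ...]             # sampled-parameter spread score
    best_by_coverage: int
    best_by_discrimination: int
    best_by_spread: int


def spacefill_design(cfg: DesignConfig, n_runs: int = 5) -> SpacefillSelection:
    """Run the space-filling designer ``n_runs`` times and rank the runs.

    Selection criteria (ties broken by run index): (1) phase-grid coverage
    of the full protocol, (2) RMSD between the two candidate models'
    currents, (3) the sampled-parameter spread score for the design model.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    cfg = replace(cfg, objective="spacefill")
    model = get_model(cfg.model)
    model_b = get_model(cfg.model_b)
    grid = PhaseGrid()
    samples = sample_parameters(model.ranges, cfg.sample_m, cfg.seed,
                                cfg.sample_scale)
    results, coverages, discrim, spread = [], [], [], []
    for run in range(n_runs):
        run_cfg = replace(cfg, seed=int(cfg.seed + run))
        res = iterative_design(run_cfg)
        results.append(res)
        traj = beattie_phase_trajectory(model, res.protocol, cfg.dt_out)
        coverages.append(int(np.unique(grid.box_indices(traj)).size))
        ia = simulate(model, res.protocol, dt_out=cfg.dt_out, e_rev=cfg.e_rev).current
        ib = simulate(model_b, res.protocol, dt_out=cfg.dt_out, e_rev=cfg.e_rev).current
        discrim.append(rmsd(ia, ib))
        spread.append(_full_protocol_spread(model, samples, res.protocol,
                                            cfg.e_rev, cfg.dt_out))
        logger.info("spacefill run %d: coverage=%d, discrim=%.4g, spread=%.4g",
                    run, coverages[-1], discrim[-1], spread[-1])
    return SpacefillSelection(
        tuple(results), tuple(coverages), tuple(discrim), tuple(spread),
        int(np.argmax(coverages)), int(np.argmax(discrim)), int(np.argmax(spread)))


def _full_protocol_spread(model: GatingModel, samples: ParameterSampleSet,
                          protocol: Protocol, e_rev: float, dt_out: float) -> float:
    """Sampled-parameter pairwise-RMSD spread over a whole protocol."""
    if model.name == "beattie":
        currents = hh_batch_currents(samples.values, model.params.conductance,
                                     protocol, dt_out, e_rev)
    else:
        currents = np.vstack([
            simulate(model.with_params(model.params.with_values(v)), protocol,
                     dt_out=dt_out, e_rev=e_rev).current
            for v in samples.values])
    return pairwise_rmsd_spread(currents)


# ---------------------------------------------------------------------------
# Automated square-wave discrimination design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SquareWaveDesignResult:
    spec: SquareWaveSpec
    score: float                     # RMSD between the two models' currents
    boundary_hit: bool               # any optimised parameter on a bound
    protocol: Protocol               # head + converted body + tail
    body: Protocol


def squarewave_discrimination_design(
        cfg: DesignConfig,
        duration: float = 1000.0,
        offset: float = -30.0,
        amplitude_bounds: tuple[float, float] = (0.5, 30.0),
        frequency_bounds: tuple[float, float] = (1e-3, 0.5),
        phase_bounds: tuple[float, float] = (0.0, 2.0 * np.pi),
        n_components: int = 3,
        max_segments: int = 4000) -> SquareWaveDesignResult:
    """Optimise square-wave components to separate two candidate models.

    The offset voltage is fixed (default -30 mV); the 3N free scalars are
    the component amplitudes (mV), angular frequencies (rad/ms) and phases.
    With per-component amplitudes capped at 30 mV the waveform stays inside
    the [-120, 60] mV hardware window.  If any optimised parameter lands on
    a bound a warning is emitted: such designs tend to be extremely
    high-frequency/high-amplitude and likely impractical to record.
    """
    model_a = get_model(cfg.model)
    model_b = get_model(cfg.model_b)
    context = common_head()
    stepper_a = _make_stepper(model_a, context, cfg.e_rev, cfg.dt_out)
    stepper_b = _make_stepper(model_b, context, cfg.e_rev, cfg.dt_out)
    rng = np.random.default_rng(cfg.seed)
    lower = np.array([amplitude_bounds[0]] * n_components
                     + [frequency_bounds[0]] * n_components
                     + [phase_bounds[0]] * n_components)
    upper = np.array([amplitude_bounds[1]] * n_components
                     + [frequency_bounds[1]] * n_components
                     + [phase_bounds[1]] * n_components)

    def make_spec(x: np.ndarray) -> SquareWaveSpec:
        return SquareWaveSpec(offset, tuple(x[:n_components]),
                              tuple(x[n_components:2 * n_components]),
                              tuple(x[2 * n_components:]))

    def score(x: np.ndarray) -> float:
        body = square_wave_to_segments(make_spec(x), duration,
                                       max_segments=max_segments)
        vs = [s.v_start for s in body.segments]
        dts = [s.duration for s in body.segments]
        ia = _run_single(stepper_a, vs, dts)
        ib = _run_single(stepper_b, vs, dts)
        return rmsd(ia, ib)

    best_x, best = None, -np.inf
    for _ in range(cfg.n_restarts):
        x0 = rng.uniform(lower, upper)
        res = cmaes_minimize(lambda x: -score(x), x0, cfg.sigma0, lower, upper,
                             rng, popsize=cfg.popsize, max_iter=cfg.max_iter)
        if -res.fun > best:
            best, best_x = -res.fun, res.x
    final_score = score(best_x)
    tol = 1e-6 * (upper - lower)
    boundary_hit = bool(np.any(best_x <= lower + tol) or np.any(best_x >= upper - tol))
    if boundary_hit:
        warnings.warn(
            "square-wave optimum lies on the parameter bounds; the resulting "
            "high-frequency/high-amplitude protocol is likely impractical",
            stacklevel=2)
    spec = make_spec(best_x)
    body = square_wave_to_segments(spec, duration, max_segments=max_segments)
    full = with_head_and_tail(body, name="maxdiff_squarewave")
    return SquareWaveDesignResult(spec, float(final_score), boundary_hit, full, body)
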