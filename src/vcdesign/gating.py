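"""Markov gating models of the hERG (Kv11.1) channel.

Two published structures are shipped:

* a symmetric 4-state model (states C, I, IC, O) equivalent to a two-gate
  Hodgkin-Huxley formulation with an activation gate ``a`` and an
  inactivation/recovery gate ``r`` whose product is the open probability;
* a sequential 5-state model (C1 - C2 - C3 - O - I) with one
  voltage-independent closed-closed transition pair (kf, kb).

Both are continuous-time Markov chains x' = A(V) x where every column of
A sums to zero (probability conservation) and off-diagonal entries are the
non-negative transition rates.  Rates follow Eyring-style exponential
voltage dependence, r(V) = r0 * exp(±s V), with prefactors in ms^-1 and
slopes in mV^-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .parameters import (
    KineticParameters,
    ParameterRanges,
    beattie_default_parameters,
    beattie_default_ranges,
    wang_default_parameters,
    wang_default_ranges,
)

__all__ = [
    "GatingModel",
    "HHGateState",
    "beattie_rates",
    "wang_rates",
    "beattie_model",
    "wang_model",
    "transition_matrix",
    "steady_state",
    "hh_gate_rates",
    "hh_steady_state",
]

#: Default reversal potential for the ohmic current I = g * P(open) * (V - E_rev),
#: in mV.  A room-temperature K+ Nernst-style value; override per call site.
DEFAULT_E_REV = -88.0


def _check_voltage(V) -> np.ndarray:
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError(f"voltage must be finite, got {V!r}")
    return V


def beattie_rates(V, p: KineticParameters) -> dict[str, np.ndarray]:
    """Voltage-dependent rates k1..k4 (ms^-1) of the 4-state model.

    k1 = p1*exp(p2*V) and k3 = p5*exp(p6*V) increase with voltage
    (activation and inactivation); k2 = p3*exp(-p4*V) and k4 = p7*exp(-p8*V)
    decrease with voltage (deactivation and recovery).
    """
    V = _check_voltage(V)
    if len(p) != 8:
        raise ValueError(f"expected 8 kinetic parameters, got {len(p)}")
    p1, p2, p3, p4, p5, p6, p7, p8 = p.values
    return {
        "k1": p1 * np.exp(p2 * V),
        "k2": p3 * np.exp(-p4 * V),
        "k3": p5 * np.exp(p6 * V),
        "k4": p7 * np.exp(-p8 * V),
    }


def wang_rates(V, q: KineticParameters) -> dict[str, np.ndarray]:
    """Rates of the 5-state model (ms^-1), plus voltage-independent kf, kb.

    a1, aa0, aa1 increase with voltage; ba1, b1, ba0 decrease with it.
    """
    V = _check_voltage(V)
    if len(q) != 14:
        raise ValueError(f"expected 14 kinetic parameters, got {len(q)}")
    kb, kf, q1, q2, q3, q4, q5, q6, q7, q8, q9, q10, q11, q12 = q.values
    ones = np.ones_like(V)
    return {
        "a1": q1 * np.exp(q2 * V),
        "aa0": q3 * np.exp(q4 * V),
        "aa1": q5 * np.exp(q6 * V),
        "ba1": q7 * np.exp(-q8 * V),
        "b1": q9 * np.exp(-q10 * V),
        "ba0": q11 * np.exp(-q12 * V),
        "kf": kf * ones,
        "kb": kb * ones,
    }


def _beattie_matrix(V: float, p: KineticParameters) -> np.ndarray:
    r = beattie_rates(V, p)
    k1, k2, k3, k4 = (float(r[k]) for k in ("k1", "k2", "k3", "k4"))
    # State order [C, I, IC, O].
    return np.array([
        [-k1 - k3, 0.0, k4, k2],
        [0.0, -k2 - k4, k1, k3],
        [k3, k2, -k1 - k4, 0.0],
        [k1, k4, 0.0, -k2 - k3],
    ])


def _wang_matrix(V: float, q: KineticParameters) -> np.ndarray:
    r = wang_rates(V, q)
    a1, aa0, aa1, ba1, b1, ba0, kf, kb = (
        float(r[k]) for k in ("a1", "aa0", "aa1", "ba1", "b1", "ba0", "kf", "kb"))
    # State order [C1, C2, C3, O, I].
    return np.array([
        [-aa0, ba0, 0.0, 0.0, 0.0],
        [aa0, -ba0 - kf, kb, 0.0, 0.0],
        [0.0, kf, -kb - aa1, ba1, 0.0],
        [0.0, 0.0, aa1, -ba1 - a1, b1],
        [0.0, 0.0, 0.0, a1, -b1],
    ])


@dataclass(frozen=True)
class GatingModel:
    """A named linear gating ODE system x' = A(V) x with an open state."""

    name: str
    state_names: tuple[str, ...]
    open_state_index: int
    rate_law: Callable[[np.ndarray, KineticParameters], dict[str, np.ndarray]]
    matrix_builder: Callable[[float, KineticParameters], np.ndarray]
    params: KineticParameters
    ranges: ParameterRanges | None = None

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def rates(self, V) -> dict[str, np.ndarray]:
        return self.rate_law(V, self.params)

    def with_params(self, params: KineticParameters) -> "GatingModel":
        return GatingModel(self.name, self.state_names, self.open_state_index,
                           self.rate_law, self.matrix_builder, params, self.ranges)


def beattie_model(params: KineticParameters | None = None) -> GatingModel:
    """The 4-state hERG model with default room-temperature parameters."""
    return GatingModel(
        name="beattie",
        state_names=("C", "I", "IC", "O"),
        open_state_index=3,
        rate_law=beattie_rates,
        matrix_builder=_beattie_matrix,
        params=params if params is not None else beattie_default_parameters(),
        ranges=beattie_default_ranges(),
    )


def wang_model(params: KineticParameters | None = None) -> GatingModel:
    """The 5-state hERG model with default room-temperature parameters."""
    return GatingModel(
        name="wang",
        state_names=("C1", "C2", "C3", "O", "I"),
        open_state_index=3,
        rate_law=wang_rates,
        matrix_builder=_wang_matrix,
        params=params if params is not None else wang_default_parameters(),
        ranges=wang_default_ranges(),
    )


def get_model(name: str) -> GatingModel:
    """Look up a shipped model by name ('beattie' or 'wang')."""
    try:
        return {"beattie": beattie_model, "wang": wang_model}[name.lower()]()
    except KeyError:
        raise ValueError(f"unknown model {name!r}; expected 'beattie' or 'wang'") from None


def transition_matrix(model: GatingModel, V: float) -> np.ndarray:
    """Transition-rate matrix A(V) in ms^-1 (columns sum to zero)."""
    V = float(_check_voltage(V))
    return model.matrix_builder(V, model.params)


def steady_state(model: GatingModel, V: float) -> np.ndarray:
    """Equilibrium state occupancy at a constant voltage.

    Solves A(V) x = 0 subject to sum(x) = 1 via the null space of A.
    Raises if the null space is not one-dimensional (reducible chain) or the
    resulting occupancy is not a probability vector.
    """
    A = transition_matrix(model, V)
    # Null space via SVD; a proper CTMC has exactly one zero singular value.
    _, s, vt = np.linalg.svd(A)
    tol = max(A.shape) * np.finfo(float).eps * s[0]
    null_dim = int(np.sum(s < max(tol, 1e-12 * s[0])))
    if null_dim != 1:
        raise np.linalg.LinAlgError(
            f"transition matrix at V={V} mV has a {null_dim}-dimensional null "
            "space; steady state undefined")
    x = vt[-1]
    x = x / x.sum()
    if np.any(x < -1e-12):
        raise np.linalg.LinAlgError(
            f"steady state at V={V} mV has negative entries; matrix is degenerate")
    return np.clip(x, 0.0, None) / np.clip(x, 0.0, None).sum()


# ---------------------------------------------------------------------------
# Hodgkin-Huxley two-gate equivalence of the 4-state model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HHGateState:
    """Activation (a) and inactivation-recovery (r) gate open fractions."""

    a: float
    r: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.a <= 1.0 and 0.0 <= self.r <= 1.0):
            raise ValueError(f"gate fractions must lie in [0, 1], got a={self.a}, r={self.r}")


def hh_gate_rates(V, p: KineticParameters):
    """Steady states and time constants of the two HH gates at voltage V.

    da/dt = k1 (1 - a) - k2 a  ->  a_inf = k1/(k1+k2), tau_a = 1/(k1+k2)
    dr/dt = k4 (1 - r) - k3 r  ->  r_inf = k4/(k3+k4), tau_r = 1/(k3+k4)

    Returns (a_inf, tau_a, r_inf, tau_r), vectorised over V.
    """
    r = beattie_rates(V, p)
    ka = r["k1"] + r["k2"]
    kr = r["k3"] + r["k4"]
    return r["k1"] / ka, 1.0 / ka, r["k4"] / kr, 1.0 / kr


def hh_steady_state(V: float, p: KineticParameters) -> HHGateState:
    """Gate fixed point at a constant voltage."""
    a_inf, _, r_inf, _ = hh_gate_rates(V, p)
    return HHGateState(float(a_inf), float(r_inf))
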