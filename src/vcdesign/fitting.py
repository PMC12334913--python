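"""Sum-of-squares parameter fitting of a gating model to a current trace.

The misfit is the RMSD between the simulated and observed current on the
observation grid.  Search runs on log-transformed parameters (all rate
prefactors, slopes and the conductance are positive and the prefactors
span decades), with a derivative-free CMA-ES global stage followed by a
Levenberg-Marquardt least-squares polish for tight local convergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .cmaes import cmaes_minimize
from .gating import DEFAULT_E_REV, GatingModel
from .parameters import KineticParameters
from .protocols import Protocol
from .simulation import hh_batch_currents, rmsd, simulate

__all__ = ["FitResult", "fit_model", "fit_conductance"]


def fit_conductance(model: GatingModel, protocol: Protocol,
                    observed: np.ndarray, dt_out: float = 1.0,
                    e_rev: float = DEFAULT_E_REV) -> float:
    """Least-squares conductance with kinetics frozen (closed form).

    The current is linear in g, so the optimum is the projection
    <u, y> / <u, u> of the observation y onto the unit-conductance
    prediction u.
    """
    observed = np.asarray(observed, dtype=float)
    unit = simulate(model, protocol, dt_out=dt_out, e_rev=e_rev).current \
        / model.params.conductance
    denom = float(unit @ unit)
    if denom == 0.0:
        raise ValueError("protocol elicits no current; conductance unidentifiable")
    return float(unit @ observed) / denom


@dataclass(frozen=True)
class FitResult:
    params: KineticParameters
    rmsd: float
    n_evaluations: int
    converged: bool


def _predict(model: GatingModel, theta: np.ndarray, protocol: Protocol,
             dt_out: float, e_rev: float) -> np.ndarray:
    values, g = np.exp(theta[:-1]), float(np.exp(theta[-1]))
    if model.name == "beattie":
        return hh_batch_currents(values[None, :], g, protocol, dt_out, e_rev)[0]
    m = model.with_params(model.params.with_values(values, conductance=g))
    return simulate(m, protocol, dt_out=dt_out, e_rev=e_rev).current


def fit_model(model: GatingModel, protocol: Protocol, observed: np.ndarray,
              restarts: int = 1, seed: int = 0,
              initial: KineticParameters | None = None,
              log_radius: float = 1.0, dt_out: float = 1.0,
              e_rev: float = DEFAULT_E_REV, max_iter: int = 150,
              popsize: int | None = None) -> FitResult:
    """Fit kinetic parameters and conductance to an observed current.

    Parameters
    ----------
    observed : current samples aligned with the protocol's ``dt_out`` grid.
    restarts : number of CMA-ES starts; the first uses ``initial`` (default:
        the model's current parameters), later ones draw log-uniformly
        within ``log_radius`` natural-log units around it.
    log_radius : half-width of the log-space search box around the initial
        guess (1.0 spans roughly x/e .. x*e per parameter).

    Returns the best parameters found; if neither stage converged the
    best-so-far estimate is still returned with ``converged=False``.
    """
    observed = np.asarray(observed, dtype=float)
    init = initial if initial is not None else model.params
    theta0 = np.concatenate([np.log(init.values), [np.log(init.conductance)]])
    lower = theta0 - log_radius
    upper = theta0 + log_radius
    rng = np.random.default_rng(seed)

    n_eval = 0

    def objective(theta: np.ndarray) -> float:
        try:
            pred = _predict(model, theta, protocol, dt_out, e_rev)
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            return 1e6  # unsimulable parameter draw
        return rmsd(pred, observed)

    best_theta, best_f, converged = theta0, objective(theta0), False
    n_eval += 1
    for k in range(restarts):
        x0 = theta0 if k == 0 else rng.uniform(lower, upper)
        res = cmaes_minimize(objective, x0, 1.0 / 6.0, lower, upper, rng,
                             popsize=popsize, max_iter=max_iter)
        n_eval += res.n_evaluations
        if res.fun < best_f:
            best_theta, best_f = res.x, res.fun
            converged = res.converged

    def residuals(theta: np.ndarray) -> np.ndarray:
        try:
            return _predict(model, theta, protocol, dt_out, e_rev) - observed
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            return np.full(observed.size, 1e3)

    polish = least_squares(residuals, best_theta, method="lm",
                           xtol=1e-12, ftol=1e-12)
    n_eval += polish.nfev
    polished_f = float(np.sqrt(np.mean(polish.fun ** 2)))
    if polished_f < best_f:
        best_theta, best_f = polish.x, polished_f
        converged = converged or polish.success
    values, g = np.exp(best_theta[:-1]), float(np.exp(best_theta[-1]))
    params = model.params.with_values(values, conductance=g)
    return FitResult(params, float(best_f), n_eval, converged)
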