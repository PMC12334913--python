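"""A compact (mu/mu_w, lambda) covariance-matrix-adaptation evolution strategy.

Minimisation with box constraints handled by clipping sampled candidates to
the feasible box before evaluation (no penalty).  Deterministic given the
random generator passed in.  Defaults follow the standard published CMA-ES
parameterisation (rank-mu update, cumulative step-size adaptation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["CMAESResult", "cmaes_minimize"]


@dataclass
class CMAESResult:
    x: np.ndarray
    fun: float
    n_evaluations: int
    n_iterations: int
    converged: bool


def cmaes_minimize(func: Callable[[np.ndarray], float], x0: np.ndarray,
                   sigma0: float, lower: np.ndarray, upper: np.ndarray,
                   rng: np.random.Generator, popsize: int | None = None,
                   max_iter: int = 200, ftol: float = 1e-11,
                   sigma_stop: float = 1e-12) -> CMAESResult:
    """Minimise ``func`` over the box [lower, upper].

    Parameters are internally normalised to [0, 1] per dimension so a single
    ``sigma0`` (as a fraction of each range) is meaningful for mixed units
    (mV vs ms).
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    span = upper - lower
    if np.any(span <= 0):
        raise ValueError("upper bounds must exceed lower bounds")
    n = lower.size

    def denorm(z: np.ndarray) -> np.ndarray:
        return lower + z * span

    m = np.clip((np.asarray(x0, dtype=float) - lower) / span, 0.0, 1.0)
    sigma = float(sigma0)

    lam = popsize if popsize is not None else 4 + int(3 * np.log(n))
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mu_eff = 1.0 / np.sum(w ** 2)

    cc = (4 + mu_eff / n) / (n + 4 + 2 * mu_eff / n)
    cs = (mu_eff + 2) / (n + mu_eff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mu_eff)
    cmu = min(1 - c1, 2 * (mu_eff - 2 + 1 / mu_eff) / ((n + 2) ** 2 + mu_eff))
    damps = 1 + 2 * max(0.0, np.sqrt((mu_eff - 1) / (n + 1)) - 1) + cs
    chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n ** 2))

    pc = np.zeros(n)
    ps = np.zeros(n)
    C = np.eye(n)
    best_x = denorm(m)
    best_f = func(best_x)
    n_eval = 1
    converged = False

    for it in range(max_iter):
        # Eigendecomposition of C (n is small here; every iteration is fine).
        evals, B = np.linalg.eigh(C)
        evals = np.maximum(evals, 1e-20)
        D = np.sqrt(evals)

        z = rng.standard_normal((lam, n))
        y = z * D @ B.T          # ~ N(0, C)
        x = np.clip(m + sigma * y, 0.0, 1.0)
        y = (x - m) / sigma      # effective mutation after clipping
        f = np.array([func(denorm(xi)) for xi in x])
        n_eval += lam

        order = np.argsort(f)
        if f[order[0]] < best_f:
            best_f = float(f[order[0]])
            best_x = denorm(x[order[0]])

        y_sel = y[order[:mu]]
        y_w = w @ y_sel
        m = np.clip(m + sigma * y_w, 0.0, 1.0)

        inv_sqrt = B @ np.diag(1.0 / D) @ B.T
        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mu_eff) * (inv_sqrt @ y_w)
        h_sig = (np.linalg.norm(ps) /
                 np.sqrt(1 - (1 - cs) ** (2 * (it + 1))) / chi_n) < 1.4 + 2 / (n + 1)
        pc = (1 - cc) * pc + h_sig * np.sqrt(cc * (2 - cc) * mu_eff) * y_w

        rank_mu = (y_sel * w[:, None]).T @ y_sel
        C = ((1 - c1 - cmu) * C
             + c1 * (np.outer(pc, pc) + (not h_sig) * cc * (2 - cc) * C)
             + cmu * rank_mu)
        C = 0.5 * (C + C.T)

        sigma *= np.exp((cs / damps) * (np.linalg.norm(ps) / chi_n - 1))

        if sigma < sigma_stop or (f.max() - f.min()) < ftol:
            converged = True
            break

    return CMAESResult(best_x, best_f, n_eval, it + 1, converged)
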