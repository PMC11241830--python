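"""Global-best particle swarm optimization over a box.

Used to tune the variable weights and the two LS-SVM hyperparameters
against the monitoring set, but written as a generic minimizer.  The
velocity update is the standard constriction form

    v <- inertia * v + cognitive * r1 * (pbest - x) + social * r2 * (gbest - x)

with positions clipped to the bounds after each move.  Runs are seeded and
fully reproducible; the global-best trace is non-increasing by
construction, and a particle whose objective evaluates non-finite is
treated as +inf (and counted) rather than propagating NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class PSOConfig:
    bounds_lo: np.ndarray = field(default_factory=lambda: np.zeros(1))
    bounds_hi: np.ndarray = field(default_factory=lambda: np.ones(1))
    n_particles: int = 100
    n_iterations: int = 100
    inertia: float = 0.729
    cognitive: float = 1.494
    social: float = 1.494
    seed: int = 0

    def __post_init__(self):
        self.bounds_lo = np.asarray(self.bounds_lo, dtype=float)
        self.bounds_hi = np.asarray(self.bounds_hi, dtype=float)
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if self.bounds_lo.shape != self.bounds_hi.shape:
            raise ValueError("bound arrays must share a shape")
        if not (np.all(np.isfinite(self.bounds_lo)) and np.all(np.isfinite(self.bounds_hi))):
            raise ValueError("bounds must be finite")
        if np.any(self.bounds_hi <= self.bounds_lo):
            raise ValueError("upper bounds must exceed lower bounds")
        if min(self.inertia, self.cognitive, self.social) <= 0:
            raise ValueError("coefficients must be positive")

    @property
    def dim(self) -> int:
        return self.bounds_lo.size


def pso_optimize(
    objective: Callable[[np.ndarray], float], config: PSOConfig
) -> tuple[np.ndarray, float, list[float]]:
    """Minimize ``objective`` over the box; returns (best x, best value, gbest trace).

    The trace holds the global best after initialization and after each
    iteration.  Ties never displace the incumbent global best (first-found
    wins), so reruns with one seed are bit-identical.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds_lo, config.bounds_hi
    span = hi - lo
    n, d = config.n_particles, config.dim

    x = lo + rng.uniform(size=(n, d)) * span
    v = np.zeros((n, d))

    def evaluate(row: np.ndarray) -> float:
        val = float(objective(row))
        if not np.isfinite(val):
            log.warning("non-finite objective at %s; treated as +inf", row)
            return np.inf
        return val

    fitness = np.array([evaluate(x[i]) for i in range(n)])
    pbest, pbest_val = x.copy(), fitness.copy()
    g = int(np.argmin(fitness))  # argmin ties -> first particle
    gbest, gbest_val = x[g].copy(), float(fitness[g])
    trace = [gbest_val]

    for _ in range(config.n_iterations):
        r1 = rng.uniform(size=(n, d))
        r2 = rng.uniform(size=(n, d))
        v = (
            config.inertia * v
            + config.cognitive * r1 * (pbest - x)
            + config.social * r2 * (gbest[None, :] - x)
        )
        x = np.clip(x + v, lo, hi)
        fitness = np.array([evaluate(x[i]) for i in range(n)])
        improved = fitness < pbest_val
        pbest[improved] = x[improved]
        pbest_val[improved] = fitness[improved]
        g = int(np.argmin(pbest_val))
        if pbest_val[g] < gbest_val:
            gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])
        trace.append(gbest_val)

    return gbest, gbest_val, trace
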