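"""Differential Evolution (rand/1/bin) with bound reflection.

The calibration problems in this package are low-dimensional (4–13
parameters) but multimodal and built on ODE solves, so a derivative-free
global optimizer is used throughout.  The scheme is the classic
Storn–Price rand/1/bin:

* mutation: ``v = a + F * (b - c)`` over three distinct population
  members, none equal to the target;
* binomial crossover at rate CR with one guaranteed gene;
* greedy selection (a trial replaces its target only when strictly
  better, so an optimal warm start is never displaced by ties);
* out-of-bounds genes are reflected back into the box.

Runs are bit-reproducible given a seed; an explicit initial population
(or a single warm-start point) can be injected, which the profile and
bootstrap stages use for continuation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["DEConfig", "FitResult", "differential_evolution"]


@dataclass(frozen=True)
class DEConfig:
    """Hyperparameters of the optimizer.

    ``pop_size=None`` means 10x the problem dimension (with a floor of
    4, the minimum rand/1/bin needs).  ``tol`` is the absolute
    population cost spread below which iteration stops.
    """

    pop_size: int | None = None
    F: float = 0.5
    CR: float = 0.9
    max_gen: int = 300
    tol: float = 1e-8
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pop_size is not None and self.pop_size < 4:
            raise ValueError("population size must be >= 4")
        if not (0 < self.F <= 2):
            raise ValueError("F must be in (0, 2]")
        if not (0 <= self.CR <= 1):
            raise ValueError("CR must be in [0, 1]")

    def resolved_pop(self, dim: int) -> int:
        return max(self.pop_size or 10 * dim, 4)


@dataclass
class FitResult:
    """Outcome of one optimization run.

    ``params`` maps parameter names to the best values found; ``x`` is
    the same vector in bound order.  ``converged`` is True when the
    population cost spread fell below tolerance before the generation
    budget ran out.
    """

    params: dict[str, float]
    cost: float
    n_gen: int
    converged: bool
    bounds: dict[str, tuple[float, float]]
    n_evals: int = 0
    names: tuple[str, ...] = field(default_factory=tuple)

    @property
    def x(self) -> np.ndarray:
        return np.array([self.params[k] for k in self.names])

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "cost": self.cost,
            "n_gen": self.n_gen,
            "converged": self.converged,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "n_evals": self.n_evals,
        }


def jittered_population(x0: np.ndarray, bounds, npop: int, jitter: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Initial population clustered around a warm-start point.

    Rows are ``x0`` plus Gaussian jitter of ``jitter`` times each
    coordinate's bound range, reflected into the box; row 0 is ``x0``
    verbatim.  Used by the profile continuation and the bootstrap
    replicates, where the optimum is known to be near ``x0``.
    """
    if isinstance(bounds, dict):
        pairs = list(bounds.values())
    else:
        pairs = list(bounds)
    lo = np.array([p[0] for p in pairs], dtype=float)
    hi = np.array([p[1] for p in pairs], dtype=float)
    x0 = np.asarray(x0, dtype=float)
    pop = x0 + jitter * (hi - lo) * rng.standard_normal((npop, x0.size))
    pop = np.array([_reflect(row, lo, hi) for row in pop])
    pop[0] = _reflect(x0, lo, hi)
    return pop


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Reflect out-of-bounds coordinates into [lo, hi]."""
    span = hi - lo
    y = x.copy()
    for _ in range(100):
        below = y < lo
        above = y > hi
        if not (below.any() or above.any()):
            return y
        y = np.where(below, 2 * lo - y, y)
        y = np.where(above, 2 * hi - y, y)
    # pathological F could bounce forever; fall back to clipping
    return np.clip(y, lo, hi)


def differential_evolution(
    cost_fn: Callable[[np.ndarray], float],
    bounds: dict[str, tuple[float, float]] | Sequence[tuple[float, float]],
    cfg: DEConfig = DEConfig(),
    *,
    x0: np.ndarray | Sequence[float] | None = None,
    init: np.ndarray | None = None,
) -> FitResult:
    """Minimize ``cost_fn`` over a box by rand/1/bin DE.

    Parameters
    ----------
    cost_fn : callable
        Maps a parameter vector to a finite cost (may return large
        penalty values for failed evaluations).
    bounds : dict or sequence
        Per-parameter (low, high); a dict keys the result by name.
    x0 : array, optional
        Warm-start point injected verbatim as the first population member.
    init : array (pop, dim), optional
        Full initial population (overrides the uniform draw; ``x0`` still
        replaces the first row).  Rows are reflected into bounds.
    """
    if isinstance(bounds, dict):
        names = tuple(bounds)
        pairs = [bounds[k] for k in names]
    else:
        pairs = list(bounds)
        names = tuple(f"p{i}" for i in range(len(pairs)))
    lo = np.array([p[0] for p in pairs], dtype=float)
    hi = np.array([p[1] for p in pairs], dtype=float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi)) and np.all(lo < hi)):
        raise ValueError("bounds must be finite with low < high")
    dim = lo.size
    npop = cfg.resolved_pop(dim)
    rng = np.random.default_rng(cfg.seed)

    if init is not None:
        pop = np.array([_reflect(np.asarray(row, float), lo, hi) for row in init])
        if pop.shape != (npop, dim):
            raise ValueError(f"init must have shape {(npop, dim)}")
        pop = pop.copy()
    else:
        pop = lo + rng.random((npop, dim)) * (hi - lo)
    if x0 is not None:
        pop[0] = _reflect(np.asarray(x0, dtype=float), lo, hi)

    costs = np.array([float(cost_fn(ind)) for ind in pop])
    n_evals = npop
    best_i = int(np.argmin(costs))
    best_x, best_c = pop[best_i].copy(), costs[best_i]

    converged = False
    gen = 0
    for gen in range(1, cfg.max_gen + 1):
        if costs.max() - costs.min() < cfg.tol:
            converged = True
            gen -= 1
            break
        for i in range(npop):
            idx = rng.choice(npop - 1, size=3, replace=False)
            idx[idx >= i] += 1  # distinct from the target
            a, b, c = pop[idx]
            mutant = _reflect(a + cfg.F * (b - c), lo, hi)
            cross = rng.random(dim) < cfg.CR
            cross[rng.integers(dim)] = True  # guaranteed gene
            trial = np.where(cross, mutant, pop[i])
            tc = float(cost_fn(trial))
            n_evals += 1
            if tc < costs[i]:
                pop[i], costs[i] = trial, tc
                if tc < best_c:
                    best_x, best_c = trial.copy(), tc
    else:
        gen = cfg.max_gen

    return FitResult(
        params={k: float(v) for k, v in zip(names, best_x)},
        cost=float(best_c),
        n_gen=gen,
        converged=converged,
        bounds={k: (float(l), float(h)) for k, l, h in zip(names, lo, hi)},
        n_evals=n_evals,
        names=names,
    )
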