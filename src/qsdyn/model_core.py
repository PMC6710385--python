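"""Single-culture AI-2 quorum-sensing model and its integration.

The model couples three observables of an *E. coli* batch culture:

* ``X(t)`` — cell density (OD600), a closed-form Gompertz curve (never
  numerically integrated);
* ``A(t)`` — extracellular AI-2 activity, produced by the cells in a
  density-dependent (Hill) fashion, consumed basally through the PTS and,
  once the *lsr* operon is expressed, through the LsrACDB transporters;
* ``L(t)`` — *lsr* operon expression (beta-galactosidase reporter units),
  driven by AI-2 internalisation and repressed by LsrR.

The two dynamic states obey

    dA/dt = mu_A - mu_XA - mu_LA
    dL/dt = mu_L + mu_AL - mu_R

with the six rate terms defined in :func:`rate_terms`.  Every negative
term in dA/dt carries a factor A and every negative term in dL/dt a
factor L, so the non-negative orthant is forward-invariant up to solver
round-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import GrowthParams, QSParams

__all__ = [
    "ModelState",
    "RateTerms",
    "Trajectory",
    "IntegrationError",
    "gompertz_growth",
    "rate_terms",
    "model_rhs",
    "simulate",
    "DEFAULT_RTOL",
    "DEFAULT_ATOL",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
#: reported A or L below -100*atol is treated as model misuse, not round-off
NEGATIVITY_FACTOR = 100.0


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the solver diagnostic message."""


@dataclass(frozen=True)
class ModelState:
    """Dynamic state (A, L); both must be non-negative."""

    A: float
    L: float

    def __post_init__(self) -> None:
        if self.A < 0 or self.L < 0:
            raise ValueError(f"state must be non-negative, got {(self.A, self.L)}")


@dataclass(frozen=True)
class RateTerms:
    """The six instantaneous rates (activity/h for the A terms,
    beta-gal/h for the L terms)."""

    muA: float
    muXA: float
    muLA: float
    muL: float
    muAL: float
    muR: float


def gompertz_growth(t, gp: GrowthParams):
    """Gompertz cell density X(t) = X0 + C*exp(-exp(-B*(t - M))).

    Defined for all real t; vectorised over ``t``.  Monotone
    non-decreasing, with X(-inf) = X0 and X(+inf) = X0 + C.
    """
    z = -gp.B * (np.asarray(t, dtype=float) - gp.M)
    # exp overflows past ~709; the double exponential is then exactly 0
    inner = np.exp(np.clip(z, None, 700.0))
    return gp.X0 + gp.C * np.exp(-inner)


def _hill(x: float, km: float, n: float) -> float:
    """x^n / (x^n + km^n), evaluated in log space for robustness."""
    if x == 0.0:
        return 0.0
    # log form keeps large exponents from overflowing x**n
    t = n * math.log(km / x)
    if t > 700.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(t))


def rate_terms(X: float, state: ModelState | tuple[float, float],
               qp: QSParams) -> RateTerms:
    """Evaluate the six rate terms at cell density X and state (A, L).

    mu_A  = kA * X^n1 / (X^n1 + km1^n1)          (AI-2 production)
    mu_XA = kXA * X^n2 / (X^n2 + km2^n2) * A     (basal PTS uptake)
    mu_LA = kLA * (X / Xdelta) * A * L           (LsrACDB uptake)
    mu_L  = kL * X^n3 / (X^n3 + km3^n3) * A      (PTS-driven expression)
    mu_AL = kAL * (X / Xdelta) * A * L           (feedback expression)
    mu_R  = kR * L                               (LsrR repression)

    Raises
    ------
    ValueError
        If X, A or L is negative.
    """
    if isinstance(state, ModelState):
        A, L = state.A, state.L
    else:
        A, L = state
        if A < 0 or L < 0:
            raise ValueError(f"state must be non-negative, got {(A, L)}")
    if X < 0:
        raise ValueError(f"cell density must be non-negative, got {X}")
    xdl = X / qp.Xdelta * A * L
    return RateTerms(
        muA=qp.kA * _hill(X, qp.km1, qp.n1),
        muXA=qp.kXA * _hill(X, qp.km2, qp.n2) * A,
        muLA=qp.kLA * xdl,
        muL=qp.kL * _hill(X, qp.km3, qp.n3) * A,
        muAL=qp.kAL * xdl,
        muR=qp.kR * L,
    )


def model_rhs(t: float, state, gp: GrowthParams, qp: QSParams) -> tuple[float, float]:
    """Time derivatives (dA/dt, dL/dt) with X taken from the growth curve."""
    X = float(gompertz_growth(t, gp))
    r = rate_terms(X, state, qp)
    return (r.muA - r.muXA - r.muLA, r.muL + r.muAL - r.muR)


@dataclass(frozen=True)
class Trajectory:
    """Dense simulated time courses.

    ``times`` is strictly increasing; ``X`` is the closed-form Gompertz
    evaluation (exact, never integrated); ``A`` and ``L`` come from the
    ODE solver and are clipped to 0 when within solver round-off below
    zero.  ``X_ko`` is present only for co-culture simulations.
    """

    times: np.ndarray
    X: np.ndarray
    A: np.ndarray
    L: np.ndarray
    X_ko: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("X", "A", "L"):
            if len(getattr(self, name)) != n:
                raise ValueError("trajectory columns must share one length")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def peak_A(self) -> float:
        return float(np.max(self.A))

    @property
    def peak_L(self) -> float:
        return float(np.max(self.L))

    def values(self, variable: str) -> np.ndarray:
        return getattr(self, variable)

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.times, "X": self.X, "A": self.A, "L": self.L}
        if self.X_ko is not None:
            cols["X_ko"] = self.X_ko
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(
            times=df["time"].to_numpy(float),
            X=df["X"].to_numpy(float),
            A=df["A"].to_numpy(float),
            L=df["L"].to_numpy(float),
            X_ko=df["X_ko"].to_numpy(float) if "X_ko" in df else None,
        )


def _integrate(rhs, t_grid: np.ndarray, init, rtol: float, atol: float,
               method: str) -> np.ndarray:
    """Run solve_ivp on a grid, enforcing the negativity contract."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("t_grid must be non-empty")
    if t_grid.size > 1 and not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be strictly increasing")
    y0 = [init.A, init.L] if isinstance(init, ModelState) else list(init)
    t0, t1 = float(t_grid[0]), float(t_grid[-1])
    if t0 == t1:
        return np.array([y0]).T
    sol = solve_ivp(rhs, (t0, t1), y0, t_eval=t_grid, method=method,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    y = sol.y
    floor = -NEGATIVITY_FACTOR * atol
    if np.any(y < floor):
        raise IntegrationError(
            f"state fell below the round-off floor {floor:g} "
            f"(min {y.min():g}); the model is being driven outside its domain")
    return np.clip(y, 0.0, None)


def simulate(gp: GrowthParams, qp: QSParams,
             t_grid: Sequence[float] | np.ndarray,
             init: ModelState = ModelState(0.0, 0.0), *,
             rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
             method: str = "LSODA") -> Trajectory:
    """Integrate the single-culture model on ``t_grid``.

    The growth column is the exact Gompertz evaluation; only (A, L) are
    integrated, with an adaptive-step stiff-capable method (LSODA by
    default).  A and L within round-off below zero are clipped to 0;
    larger negativity raises :class:`IntegrationError`.
    """

    def rhs(t, y):
        X = float(gompertz_growth(t, gp))
        A, L = max(y[0], 0.0), max(y[1], 0.0)
        r = rate_terms(X, (A, L), qp)
        return (r.muA - r.muXA - r.muLA, r.muL + r.muAL - r.muR)

    t_grid = np.asarray(t_grid, dtype=float)
    y = _integrate(rhs, t_grid, init, rtol, atol, method)
    return Trajectory(times=t_grid, X=np.asarray(gompertz_growth(t_grid, gp)),
                      A=y[0], L=y[1])
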