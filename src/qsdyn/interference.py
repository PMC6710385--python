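"""Co-culture interference: wild type sharing medium with a LuxS- strain.

The knockout cannot synthesise AI-2 but still imports it through the
PTS and the LsrACDB transporters, so it acts as a signal scavenger.
Both strains share the medium's carrying capacity: the wild strain grows
to ``wild_fraction * C`` and the knockout to the complement, each along
a Gompertz curve with the shared X0, B and M.  A pre-culture head start
of ``tau`` hours advances the knockout along its curve (the mixed medium
starts AI-2-free — the knockout produces none, and any pre-culture
supernatant is discarded).

AI-2 production comes from the wild strain only; uptake sums the PTS
and LsrACDB terms of both strains, the knockout's LsrACDB term using
the shared operon-expression variable L (interpreted as the wild
strain's expression level).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model_core import (
    ModelState,
    Trajectory,
    _integrate,
    gompertz_growth,
    rate_terms,
    DEFAULT_RTOL,
    DEFAULT_ATOL,
)
from .params import GrowthParams, QSParams

__all__ = [
    "CoCultureConfig",
    "cocult_growth",
    "cocult_rhs",
    "simulate_cocult",
    "sweep_fractions",
    "sweep_preculture",
    "DEFAULT_FRACTIONS",
    "DEFAULT_TAUS",
    "DEFAULT_SUPPRESSION_THRESHOLD",
]

DEFAULT_FRACTIONS = (0.1, 0.3, 0.5, 0.7, 0.9)
DEFAULT_TAUS = (0.0, 2.0, 3.0, 4.0, 5.0)
DEFAULT_SUPPRESSION_THRESHOLD = 0.10


@dataclass(frozen=True)
class CoCultureConfig:
    """Medium sharing and scheduling of the two strains.

    ``wild_fraction`` is the share of the carrying capacity C taken by
    the wild strain (the knockout takes the complement, so
    C_w + C_ko = C exactly); ``preculture_hours`` is the knockout's
    head start.
    """

    wild_fraction: float
    preculture_hours: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.wild_fraction < 1):
            raise ValueError("wild_fraction must lie in (0, 1)")
        if self.preculture_hours < 0:
            raise ValueError("preculture_hours must be >= 0")

    def capacities(self, gp: GrowthParams) -> tuple[float, float]:
        cw = self.wild_fraction * gp.C
        return cw, gp.C - cw


def cocult_growth(t, gp: GrowthParams,
                  cfg: CoCultureConfig) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form strain densities (X_w, X_ko) at time(s) t.

    The knockout's Gompertz argument is shifted by +preculture_hours to
    encode the head start.
    """
    cw, cko = cfg.capacities(gp)
    xw = gompertz_growth(t, GrowthParams(gp.X0, cw, gp.B, gp.M))
    shifted = np.asarray(t, dtype=float) + cfg.preculture_hours
    xko = gompertz_growth(shifted, GrowthParams(gp.X0, cko, gp.B, gp.M))
    return xw, xko


def cocult_rhs(t: float, state, gp: GrowthParams, qp: QSParams,
               cfg: CoCultureConfig) -> tuple[float, float]:
    """Derivatives (dA/dt, dL/dt) of the shared-medium co-culture.

    Production uses the wild density only; consumption sums the PTS and
    LsrACDB terms evaluated at the wild and knockout densities, the
    knockout's LsrACDB term multiplying the shared L.  The operon
    equation follows the single-culture form with X = X_w.
    """
    xw, xko = cocult_growth(t, gp, cfg)
    rw = rate_terms(float(xw), state, qp)
    rko = rate_terms(float(xko), state, qp)
    dA = rw.muA - (rw.muXA + rko.muXA + rw.muLA + rko.muLA)
    dL = rw.muL + rw.muAL - rw.muR
    return dA, dL


def simulate_cocult(gp: GrowthParams, qp: QSParams, cfg: CoCultureConfig,
                    t_grid: Sequence[float] | np.ndarray,
                    init: ModelState = ModelState(0.0, 0.0), *,
                    rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
                    method: str = "LSODA") -> Trajectory:
    """Integrate the co-culture on ``t_grid``.

    Returns a :class:`Trajectory` whose ``X`` column is the wild strain
    and ``X_ko`` the knockout (both closed-form).
    """

    def rhs(t, y):
        A, L = max(y[0], 0.0), max(y[1], 0.0)
        return cocult_rhs(t, (A, L), gp, qp, cfg)

    t_grid = np.asarray(t_grid, dtype=float)
    y = _integrate(rhs, t_grid, init, rtol, atol, method)
    xw, xko = cocult_growth(t_grid, gp, cfg)
    return Trajectory(times=t_grid, X=np.asarray(xw), A=y[0], L=y[1],
                      X_ko=np.asarray(xko))


def _default_grid() -> np.ndarray:
    return np.linspace(0.0, 12.0, 1201)


def sweep_fractions(gp: GrowthParams, qp: QSParams,
                    fractions: Sequence[float] = DEFAULT_FRACTIONS,
                    t_grid: Sequence[float] | None = None,
                    init: ModelState = ModelState(0.0, 0.0)) -> pd.DataFrame:
    """Peak responses across wild-strain capacity shares.

    Returns one row per fraction with columns ``fraction``, ``peak_A``,
    ``peak_L`` and ``L_ratio`` — the peak L relative to the
    single-culture (full-capacity wild strain) peak computed once with
    the same parameters, grid and initial state.
    """
    if len(fractions) == 0:
        raise ValueError("fractions must be non-empty")
    from .model_core import simulate

    t_grid = _default_grid() if t_grid is None else np.asarray(t_grid, float)
    mono = simulate(gp, qp, t_grid, init)
    rows = []
    for f in fractions:
        traj = simulate_cocult(gp, qp, CoCultureConfig(f), t_grid, init)
        rows.append({"fraction": f, "peak_A": traj.peak_A,
                     "peak_L": traj.peak_L,
                     "L_ratio": traj.peak_L / mono.peak_L})
    return pd.DataFrame(rows)


def sweep_preculture(gp: GrowthParams, qp: QSParams,
                     taus: Sequence[float] = DEFAULT_TAUS,
                     t_grid: Sequence[float] | None = None,
                     init: ModelState = ModelState(0.0, 0.0),
                     suppression_threshold: float = DEFAULT_SUPPRESSION_THRESHOLD,
                     ) -> tuple[pd.DataFrame, float | None]:
    """Peak L across knockout pre-culture head starts at a 50/50 split.

    A head start counts as suppressing when the co-culture peak L falls
    below ``suppression_threshold`` times the single-culture peak L.
    Returns the sweep table (columns ``tau_h``, ``peak_L``,
    ``suppressed``) and the smallest suppressing tau of the tested set
    (None when none suppresses).
    """
    if len(taus) == 0:
        raise ValueError("taus must be non-empty")
    if not (0 < suppression_threshold < 1):
        raise ValueError("suppression_threshold must lie in (0, 1)")
    if any(tau < 0 for tau in taus):
        raise ValueError("taus must be >= 0")
    from .model_core import simulate

    t_grid = _default_grid() if t_grid is None else np.asarray(t_grid, float)
    mono_peak = simulate(gp, qp, t_grid, init).peak_L
    rows = []
    for tau in taus:
        traj = simulate_cocult(gp, qp, CoCultureConfig(0.5, tau), t_grid, init)
        rows.append({"tau_h": tau, "peak_L": traj.peak_L,
                     "suppressed": traj.peak_L < suppression_threshold * mono_peak})
    table = pd.DataFrame(rows)
    hit = table.loc[table["suppressed"], "tau_h"]
    return table, (float(hit.min()) if not hit.empty else None)
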