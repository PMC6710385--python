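"""Synthetic datasets with the sampling structure of batch QS assays.

The generator integrates the model from a chosen truth, samples OD600
and AI-2 activity on a regular dense grid and the beta-gal series on a
sparser one (expression assays are more laborious, so real L series
carry fewer points), then applies multiplicative Gaussian observation
noise, value * (1 + CV * z), clipped at zero.  Multiplicative noise is
the natural choice for optical-density and luminescence readouts whose
magnitudes span decades.

``default_truth`` returns the published best-fit parameter set used as
the canonical ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import Series, TimeSeriesDataset
from .model_core import ModelState, simulate
from .params import GrowthParams, QSParams

__all__ = ["DesignSpec", "generate_dataset", "default_truth"]


@dataclass(frozen=True)
class DesignSpec:
    """Sampling design and noise model of a synthetic experiment.

    ``dt_xa`` is the sampling interval of the X and A series, ``dt_l``
    the (no smaller) interval of the L series, both in hours over
    ``t_span``.  ``cv`` gives the per-variable coefficient of variation
    of the multiplicative Gaussian noise (a scalar applies to all
    three).
    """

    t_span: tuple[float, float] = (0.0, 10.0)
    dt_xa: float = 0.5
    dt_l: float = 1.5
    cv: float | dict[str, float] = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt_xa <= 0 or self.dt_l <= 0:
            raise ValueError("sampling intervals must be positive")
        if self.dt_l < self.dt_xa:
            raise ValueError("the L series must not be denser than X/A")
        for v in (self.cv.values() if isinstance(self.cv, dict) else [self.cv]):
            if v < 0:
                raise ValueError("coefficients of variation must be >= 0")

    def cv_for(self, variable: str) -> float:
        if isinstance(self.cv, dict):
            return float(self.cv.get(variable, 0.0))
        return float(self.cv)

    def grid(self, dt: float) -> np.ndarray:
        t0, t1 = self.t_span
        n = int(np.floor((t1 - t0) / dt + 1e-9))
        return t0 + dt * np.arange(n + 1)


def default_truth() -> tuple[GrowthParams, QSParams]:
    """The published best-fit parameter set (growth and kinetics)."""
    gp = GrowthParams(X0=0.064, C=5.8828, B=0.6384, M=3.2823)
    qp = QSParams(kA=1561.68, km1=1.5793, n1=2.9302,
                  kXA=343.98, km2=5.8205, n2=8.9542,
                  kLA=0.0044, Xdelta=5.7953,
                  kL=0.5825, km3=3.9128, n3=0.0017,
                  kAL=0.0028, kR=0.1037)
    return gp, qp


def generate_dataset(gp: GrowthParams, qp: QSParams,
                     design: DesignSpec = DesignSpec(),
                     init: ModelState = ModelState(0.0, 0.0)) -> TimeSeriesDataset:
    """Simulate, sample and corrupt a three-variable dataset.

    With all CVs zero the dataset equals the simulation at the sample
    times exactly.  The generating parameters are recorded on the
    dataset (and serialized as ``# truth:`` headers by its CSV writer).
    """
    grid_xa = design.grid(design.dt_xa)
    grid_l = design.grid(design.dt_l)
    union = np.unique(np.concatenate([grid_xa, grid_l]))
    traj = simulate(gp, qp, union, init)
    rng = np.random.default_rng(design.seed)

    series: dict[str, Series] = {}
    for name, grid in (("X", grid_xa), ("A", grid_xa), ("L", grid_l)):
        idx = np.searchsorted(union, grid)
        clean = traj.values(name)[idx]
        cv = design.cv_for(name)
        noisy = clean * (1.0 + cv * rng.standard_normal(clean.size)) if cv else clean.copy()
        noisy = np.clip(noisy, 0.0, None)
        if name == "X":
            noisy = np.maximum(noisy, 1e-12)  # OD must stay positive
        series[name] = Series(grid, noisy)

    truth = {**gp.to_dict(), **qp.to_dict()}
    return TimeSeriesDataset(series, truth=truth)
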