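"""Model/Results front end tying the calibration stages together.

:class:`QSModel` wraps a :class:`~qsdyn.datasets.TimeSeriesDataset` and
exposes the two-stage calibration as a single ``fit()``;
:class:`QSResults` carries the estimates and gives access to
simulation, profile-likelihood scans, bootstrap intervals and a text
summary.  The functional modules (:mod:`~qsdyn.estimation`,
:mod:`~qsdyn.identifiability`, :mod:`~qsdyn.uncertainty`) do the work.

>>> from qsdyn import QSModel, synthetic
>>> gp, qp = synthetic.default_truth()
>>> data = synthetic.generate_dataset(gp, qp, synthetic.DesignSpec(seed=0))
>>> res = QSModel(data).fit(seed=1)         # doctest: +SKIP
>>> print(res.summary())                    # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import TimeSeriesDataset
from .estimation import (
    DEFAULT_FIXED,
    fit_growth,
    fit_qs,
)
from .identifiability import ProfileResult, profile_likelihood
from .model_core import ModelState, Trajectory, simulate
from .optimize import DEConfig, FitResult
from .params import GrowthParams, QSParams
from .uncertainty import BootstrapResult, weighted_bootstrap

__all__ = ["QSModel", "QSResults"]


class QSModel:
    """AI-2 quorum-sensing model bound to a dataset.

    Parameters
    ----------
    dataset : TimeSeriesDataset
        Observed (or synthetic) X/A/L time courses.
    fixed : dict, optional
        Kinetic parameters to clamp in stage two (default: n3 and
        Xdelta at their published values).
    bounds : dict, optional
        Overrides of the default search boxes.
    """

    def __init__(self, dataset: TimeSeriesDataset,
                 fixed: dict[str, float] | None = None,
                 bounds: dict[str, tuple[float, float]] | None = None):
        self.dataset = dataset
        self.fixed = DEFAULT_FIXED.copy() if fixed is None else dict(fixed)
        self.bounds = bounds

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "QSModel":
        """Build from a long-format frame (columns variable,time,value)."""
        return cls(TimeSeriesDataset.from_frame(df), **kw)

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "QSModel":
        return cls(TimeSeriesDataset.from_csv(path), **kw)

    def fit(self, *, growth_cfg: DEConfig | None = None,
            qs_cfg: DEConfig | None = None,
            seed: int | None = None,
            x0: dict[str, float] | None = None) -> "QSResults":
        """Two-stage calibration: growth first, kinetics second.

        ``seed`` derives both stages' optimizer seeds; per-stage
        configurations override the defaults.
        """
        if growth_cfg is None:
            growth_cfg = DEConfig(max_gen=200,
                                  seed=None if seed is None else seed)
        if qs_cfg is None:
            qs_cfg = DEConfig(seed=None if seed is None else seed + 1)
        growth_fit = fit_growth(self.dataset, cfg=growth_cfg)
        gp = GrowthParams(**growth_fit.params)
        qs_fit = fit_qs(self.dataset, gp, fixed=self.fixed,
                        bounds=self.bounds, cfg=qs_cfg, x0=x0)
        return QSResults(model=self, growth_fit=growth_fit, qs_fit=qs_fit)


@dataclass
class QSResults:
    """Estimates and diagnostics of a fitted quorum-sensing model."""

    model: QSModel
    growth_fit: FitResult
    qs_fit: FitResult

    @property
    def growth(self) -> GrowthParams:
        return GrowthParams(**self.growth_fit.params)

    @property
    def qs(self) -> QSParams:
        full = dict(self.qs_fit.params)
        full.update(self.model.fixed)
        return QSParams(**full)

    @property
    def sswr(self) -> float:
        return self.qs_fit.cost

    def simulate(self, t_grid=None,
                 init: ModelState = ModelState(0.0, 0.0)) -> Trajectory:
        """Trajectory of the fitted model (default grid: [0, 12] h)."""
        if t_grid is None:
            t_grid = np.linspace(0.0, 12.0, 481)
        return simulate(self.growth, self.qs, t_grid, init)

    def profile(self, param: str, **kw) -> ProfileResult:
        """Profile-likelihood scan of one fitted kinetic parameter."""
        return profile_likelihood(self.model.dataset, self.qs_fit, param,
                                  self.growth, bounds=self.model.bounds, **kw)

    def bootstrap(self, n_reps: int = 500, **kw) -> BootstrapResult:
        """Weighted-bootstrap confidence intervals for the kinetics."""
        return weighted_bootstrap(self.model.dataset, self.growth,
                                  self.qs_fit, n_reps=n_reps,
                                  fixed=self.model.fixed,
                                  bounds=self.model.bounds, **kw)

    def summary(self) -> str:
        """Human-readable account of both stages."""
        lines = ["Quorum-sensing model fit (two-stage SSWR / DE)",
                 "=" * 48,
                 "Growth stage (Gompertz, closed form)",
                 f"  cost {self.growth_fit.cost:.6g}   "
                 f"generations {self.growth_fit.n_gen}   "
                 f"converged {self.growth_fit.converged}"]
        for k, v in self.growth_fit.params.items():
            lines.append(f"  {k:>8s} = {v:.6g}")
        lines += ["Kinetic stage (A, L ODEs; growth frozen)",
                  f"  cost {self.qs_fit.cost:.6g}   "
                  f"generations {self.qs_fit.n_gen}   "
                  f"converged {self.qs_fit.converged}"]
        for k, v in self.qs_fit.params.items():
            lo, hi = self.qs_fit.bounds[k]
            lines.append(f"  {k:>8s} = {v:<12.6g} in [{lo:g}, {hi:g}]")
        if self.model.fixed:
            fx = ", ".join(f"{k}={v:g}" for k, v in self.model.fixed.items())
            lines.append(f"  fixed: {fx}")
        return "\n".join(lines)

    def plot(self, t_grid=None, ax=None):
        """Quick-look figure: data points and fitted curves."""
        import matplotlib.pyplot as plt

        traj = self.simulate(t_grid)
        if ax is None:
            _, ax = plt.subplots(3, 1, sharex=True, figsize=(6, 8))
        labels = {"X": "OD600", "A": "AI-2 activity", "L": "beta-gal"}
        for a, v in zip(ax, ("X", "A", "L")):
            a.plot(traj.times, traj.values(v), "-", label="model")
            if v in self.model.dataset:
                s = self.model.dataset[v]
                a.plot(s.times, s.values, "o", ms=4, label="data")
            a.set_ylabel(labels[v])
            a.legend(frameon=False)
        ax[-1].set_xlabel("time (h)")
        return ax
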