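"""Weighted-bootstrap confidence intervals and parameter dependency.

Each bootstrap replicate draws i.i.d. Exponential(1) weights (mean and
variance one), attaches one weight to every data point's squared
normalised residual in the cost, and re-runs the stage-two fit from a
warm start at the baseline optimum with a reduced optimizer budget.
The 95% confidence interval of each parameter is the (2.5%, 97.5%)
quantile pair of the replicate estimates, with linear interpolation
between order statistics (type-7 — quantile conventions differ, so the
rule is stated).  Pairwise Pearson correlation of the replicate matrix
summarises parameter dependency.

Replicate r derives its RNG stream from ``seed + r``, making the full
result bit-reproducible under a fixed master seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import TimeSeriesDataset
from .estimation import DEFAULT_FIXED, PENALTY_COST, fit_qs
from .optimize import DEConfig, FitResult
from .params import GrowthParams

__all__ = ["BootstrapResult", "draw_weights", "weighted_bootstrap",
           "parameter_dependency"]

#: abort when more than this fraction of replicates fails
MAX_FAILURE_FRACTION = 0.20


def draw_weights(n: int, seed: int | np.random.Generator | None = None) -> np.ndarray:
    """n i.i.d. Exponential(1) weights (mean 1, variance 1)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return rng.exponential(1.0, size=n)


@dataclass
class BootstrapResult:
    """Replicate estimates and their quantile intervals.

    ``replicates`` has one row per successful replicate and one column
    per fitted parameter; ``sswr`` the per-replicate cost.
    """

    replicates: pd.DataFrame
    sswr: np.ndarray
    seed: int | None
    n_failures: int = 0

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.replicates.columns)

    def ci(self, lo: float = 2.5, hi: float = 97.5) -> pd.DataFrame:
        """Per-parameter quantile interval (percent levels)."""
        q = self.replicates.quantile([lo / 100, hi / 100],
                                     interpolation="linear")
        out = q.T
        out.columns = [f"q{lo}", f"q{hi}"]
        return out

    def median(self) -> pd.Series:
        return self.replicates.median()

    def to_csv(self, path: str | Path) -> None:
        df = self.replicates.copy()
        df["sswr"] = self.sswr
        df.to_csv(path, index=False)

    def summary(self) -> pd.DataFrame:
        ci = self.ci()
        ci.insert(0, "median", self.median())
        return ci


def weighted_bootstrap(dataset: TimeSeriesDataset, gp: GrowthParams,
                       baseline: FitResult, *,
                       n_reps: int = 500,
                       fixed: dict[str, float] | None = None,
                       bounds: dict[str, tuple[float, float]] | None = None,
                       cfg: DEConfig | None = None,
                       seed: int | None = None,
                       jitter: float = 0.05,
                       unit_weights: bool = False) -> BootstrapResult:
    """Re-fit the kinetic stage under exponential residual weights.

    Parameters
    ----------
    baseline : FitResult
        The stage-two fit to warm-start every replicate from.
    cfg : DEConfig
        Per-replicate optimizer budget; default halves the generation
        budget relative to the global fit and shrinks the population,
        relying on the warm start.
    unit_weights : bool
        Force every weight to 1 (degenerate bootstrap: with a baseline
        at an exact cost minimum, every replicate returns the baseline
        and all intervals have zero width).

    Raises
    ------
    RuntimeError
        If more than 20% of replicates fail.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    fixed = DEFAULT_FIXED.copy() if fixed is None else dict(fixed)
    work = dataset
    n_points = {v: len(work[v]) for v in ("A", "L") if v in work}
    cfg = cfg or DEConfig(pop_size=max(4, 3 * len(baseline.params)),
                          max_gen=150)

    rows, costs = [], []
    n_failures = 0
    base = seed if seed is not None else 0
    for r in range(n_reps):
        rep_seed = (base + r) % (2**31 - 1)
        rng = np.random.default_rng(rep_seed)
        weighted = work
        for v, n in n_points.items():
            w = np.ones(n) if unit_weights else draw_weights(n, rng)
            weighted = weighted.replace_series(v, weighted[v].with_weights(w))
        try:
            sub_cfg = DEConfig(pop_size=cfg.pop_size, F=cfg.F, CR=cfg.CR,
                               max_gen=cfg.max_gen, tol=cfg.tol, seed=rep_seed)
            res = fit_qs(weighted, gp, fixed=fixed, bounds=bounds,
                         cfg=sub_cfg, x0=baseline.params, jitter=jitter,
                         equalize=False)
            if res.cost >= PENALTY_COST:
                raise RuntimeError("replicate stuck at the failure penalty")
        except Exception:
            n_failures += 1
            continue
        rows.append(res.params)
        costs.append(res.cost)
    if n_failures > MAX_FAILURE_FRACTION * n_reps:
        raise RuntimeError(
            f"{n_failures}/{n_reps} bootstrap replicates failed")
    return BootstrapResult(replicates=pd.DataFrame(rows),
                           sswr=np.asarray(costs),
                           seed=seed, n_failures=n_failures)


def parameter_dependency(result: BootstrapResult) -> pd.DataFrame:
    """Pearson correlation matrix of the replicate estimates.

    Raises
    ------
    ValueError
        With fewer than 10 successful replicates, or when a parameter
        column is constant (zero variance makes the correlation
        undefined).
    """
    reps = result.replicates
    if len(reps) < 10:
        raise ValueError("dependency analysis needs >= 10 replicates")
    sd = reps.std(ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant replicate columns: {constant}")
    corr = np.corrcoef(reps.to_numpy(float), rowvar=False)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=reps.columns, columns=reps.columns)
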