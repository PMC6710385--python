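"""Profile-likelihood identifiability analysis.

A parameter's profile is the re-optimized cost as the parameter is
clamped over a scan around its fitted value: all other free parameters
are re-fitted at every scan point.  A concave profile that rises on
both sides of the optimum marks an identifiable parameter; a profile
that stays within a cost-increase threshold ``delta`` of the minimum on
one or both sides marks practical non-identifiability in that
direction.

Scan points are solved by continuation: each point's optimizer
population is seeded around the previous point's solution, which cuts
the re-optimization budget substantially.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .datasets import TimeSeriesDataset
from .estimation import default_qs_bounds, fit_qs, PENALTY_COST
from .optimize import DEConfig, FitResult
from .params import GrowthParams

__all__ = [
    "ProfileResult",
    "profile_likelihood",
    "classify_identifiability",
    "IDENTIFIABLE",
    "FLAT_LEFT",
    "FLAT_RIGHT",
    "FLAT",
]

IDENTIFIABLE = "identifiable"
FLAT_LEFT = "practically non-identifiable (flat left)"
FLAT_RIGHT = "practically non-identifiable (flat right)"
FLAT = "practically non-identifiable (flat)"

#: relative tolerance for the profile-lower-envelope invariant
ENVELOPE_RTOL = 1e-6


@dataclass
class ProfileResult:
    """Scanned profile of one parameter.

    ``scan_values`` are increasing; ``sswr`` holds the re-optimized cost
    at each, with failed scan points recorded as NaN rather than
    aborting the scan.
    """

    param: str
    scan_values: np.ndarray
    sswr: np.ndarray
    best_value: float
    best_sswr: float
    label: str | None = None
    failures: int = 0

    def classify(self, delta: float | None = None, **kw) -> str:
        self.label = classify_identifiability(self, delta=delta, **kw)
        return self.label

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"param": self.param,
                             "scan_value": self.scan_values,
                             "sswr": self.sswr})


def _scan_grid(center: float, lo: float, hi: float, n_points: int,
               span: float, linear: bool) -> np.ndarray:
    """Scan grid around the fitted value, clipped to the bounds."""
    if linear or center <= 0:
        lo_s, hi_s = center / span, center * span
        grid = np.linspace(max(lo_s, lo), min(hi_s, hi), n_points)
    else:
        lo_s = max(center / span, lo)
        hi_s = min(center * span, hi)
        grid = np.geomspace(lo_s, hi_s, n_points)
    return np.unique(grid)


def profile_likelihood(dataset: TimeSeriesDataset, fitted: FitResult,
                       param: str, gp: GrowthParams, *,
                       n_points: int = 21, span: float = 5.0,
                       linear: bool = False,
                       bounds: dict[str, tuple[float, float]] | None = None,
                       cfg: DEConfig | None = None,
                       jitter: float = 0.05,
                       seed: int | None = None) -> ProfileResult:
    """Profile one kinetic parameter by clamp-and-refit.

    Parameters
    ----------
    fitted : FitResult
        The stage-two fit whose free parameters define the profile's
        re-optimization space; ``param`` must be one of them.
    n_points, span : int, float
        Scan design: ``n_points`` values over [value/span, value*span],
        log-spaced unless ``linear`` (exponents near zero profile more
        naturally on a linear scale).
    cfg : DEConfig
        Re-optimization budget per scan point (reduced relative to the
        global fit; continuation keeps this cheap).
    jitter : float
        Relative spread (of each bound range) of the warm-start
        population around the previous solution.
    """
    if param not in fitted.params:
        raise ValueError(f"{param!r} is not a free parameter of the fit")
    all_bounds = default_qs_bounds()
    if bounds:
        all_bounds.update(bounds)
    lo, hi = all_bounds[param]
    center = fitted.params[param]
    grid = _scan_grid(center, lo, hi, n_points, span, linear)

    other = tuple(k for k in fitted.params if k != param)
    fixed_base = _held_fixed(fitted)
    cfg = cfg or DEConfig(pop_size=max(4, 2 * len(other)), max_gen=40)
    rng = np.random.default_rng(seed)

    profile = np.full(grid.size, np.nan)
    solutions: list[dict[str, float] | None] = [None] * grid.size
    failures = 0

    def refit(i: int, warm: dict[str, float]) -> None:
        nonlocal failures
        fixed = dict(fixed_base)
        fixed[param] = float(grid[i])
        try:
            sub_cfg = DEConfig(pop_size=cfg.pop_size, F=cfg.F, CR=cfg.CR,
                               max_gen=cfg.max_gen, tol=cfg.tol,
                               seed=int(rng.integers(2**31 - 1)))
            res = fit_qs(dataset, gp, fixed=fixed,
                         bounds=all_bounds, cfg=sub_cfg, x0=warm,
                         jitter=jitter)
            if res.cost >= PENALTY_COST:
                raise RuntimeError("all evaluations failed integration")
        except Exception:
            failures += 1
            return
        if not np.isfinite(profile[i]) or res.cost < profile[i]:
            profile[i] = res.cost
            solutions[i] = res.params

    # continuation: start at the scan point nearest the optimum, walk
    # outward in both directions warm-starting from the neighbour, then
    # sweep back inward from each edge and keep the pointwise best —
    # the reverse pass irons out isolated re-optimization spikes
    nearest = int(np.argmin(np.abs(grid - center)))
    start = {k: fitted.params[k] for k in other}
    for idx_range in (range(nearest, grid.size),
                      range(nearest - 1, -1, -1)):
        prev = start
        for i in idx_range:
            refit(i, prev)
            prev = solutions[i] or prev
    for idx_range in (range(grid.size - 1, nearest - 1, -1),
                      range(0, nearest)):
        prev = None
        for i in idx_range:
            if prev is not None:
                refit(i, prev)
            prev = solutions[i] or prev
    return ProfileResult(param=param, scan_values=grid, sswr=profile,
                         best_value=center, best_sswr=fitted.cost,
                         failures=failures)


def _held_fixed(fitted: FitResult) -> dict[str, float]:
    """Kinetic parameters absent from the fit (held at defaults)."""
    from .estimation import DEFAULT_FIXED
    return {k: v for k, v in DEFAULT_FIXED.items() if k not in fitted.params}


def classify_identifiability(profile: ProfileResult,
                             delta: float | None = None, *,
                             n_obs: int | None = None) -> str:
    """Label a profile as identifiable or flat left/right/both.

    A side counts as rising when some scan point on that side of the
    profile minimum exceeds ``min + delta``; the parameter is
    identifiable only when both sides rise within the scanned span.

    ``delta=None`` uses a pointwise 95% chi-square threshold on the
    weighted-residual scale, ``best * chi2_95(1) / (n_obs - p)``, with
    ``n_obs`` the number of residuals behind the cost (falls back to
    the number of scan points if not given — pass it for a calibrated
    threshold).  ``delta=inf`` classifies everything non-identifiable.
    """
    ok = np.isfinite(profile.sswr)
    if ok.sum() < 5:
        raise ValueError("profile must contain >= 5 successful points")
    vals = profile.scan_values[ok]
    cost = profile.sswr[ok]
    i_min = int(np.argmin(cost))
    best = cost[i_min]
    if delta is None:
        dof = max((n_obs or cost.size) - 1, 1)
        delta = best * chi2.ppf(0.95, 1) / dof
    rises_left = bool(np.any(cost[:i_min] > best + delta))
    rises_right = bool(np.any(cost[i_min + 1:] > best + delta))
    if rises_left and rises_right:
        return IDENTIFIABLE
    if rises_left:
        return FLAT_RIGHT
    if rises_right:
        return FLAT_LEFT
    return FLAT
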