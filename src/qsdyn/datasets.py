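"""Observed (or synthetic) time-series containers and their CSV formats.

A dataset holds up to three variables — ``X`` (OD600 growth), ``A``
(extracellular AI-2 activity) and ``L`` (*lsr* expression, beta-gal
units) — each on its own time grid; the L series is typically sparser
than the other two.  On disk the long format is::

    variable,time,value
    X,0.0,0.064
    ...

optionally preceded by ``#`` comment lines; synthetic datasets carry
their generating parameters in ``# truth: key=value`` headers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Series", "TimeSeriesDataset", "VARIABLES"]

VARIABLES = ("X", "A", "L")


@dataclass(frozen=True)
class Series:
    """One variable's observations: increasing times, values, and
    optional positive per-point weights (default 1)."""

    times: np.ndarray
    values: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D of equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != t.shape:
                raise ValueError("weights must match times in length")
            if np.any(w <= 0):
                raise ValueError("weights must be positive")
            object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.times.size

    def with_weights(self, weights: np.ndarray) -> "Series":
        return Series(self.times, self.values, weights)


@dataclass(frozen=True)
class TimeSeriesDataset:
    """Per-variable time courses with possibly different grids.

    Attributes
    ----------
    series : dict
        Maps a subset of ``{"X", "A", "L"}`` to :class:`Series`.
    truth : dict or None
        Generating parameters, when the dataset is synthetic.
    """

    series: dict[str, Series]
    truth: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for name, s in self.series.items():
            if name not in VARIABLES:
                raise ValueError(f"unknown variable {name!r}")
            if name == "X" and np.any(s.values <= 0):
                raise ValueError("X (OD600) values must be positive")
            if name in ("A", "L") and np.any(s.values < 0):
                raise ValueError(f"{name} values must be non-negative")

    def __contains__(self, name: str) -> bool:
        return name in self.series

    def __getitem__(self, name: str) -> Series:
        return self.series[name]

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(v for v in VARIABLES if v in self.series)

    def replace_series(self, name: str, s: Series) -> "TimeSeriesDataset":
        new = dict(self.series)
        new[name] = s
        return TimeSeriesDataset(new, self.truth)

    def union_times(self, variables: tuple[str, ...] | None = None) -> np.ndarray:
        """Sorted union of the observation times of the given variables."""
        variables = variables or self.variables
        times = np.unique(np.concatenate(
            [self.series[v].times for v in variables if v in self.series]))
        return times

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.variables:
            s = self.series[v]
            rows.append(pd.DataFrame(
                {"variable": v, "time": s.times, "value": s.values}))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        header = ""
        if self.truth:
            header = "".join(f"# truth: {k}={v!r}\n" for k, v in self.truth.items())
        path.write_text(header + self.to_frame().to_csv(index=False))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TimeSeriesDataset":
        path = Path(path)
        truth: dict[str, float] = {}
        for line in path.read_text().splitlines():
            if line.startswith("# truth:"):
                key, _, val = line[len("# truth:"):].strip().partition("=")
                truth[key.strip()] = float(val)
            elif not line.startswith("#"):
                break
        df = pd.read_csv(path, comment="#")
        return cls.from_frame(df, truth=truth or None)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   truth: dict[str, float] | None = None) -> "TimeSeriesDataset":
        """Build from a long-format frame with columns variable,time,value."""
        required = {"variable", "time", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"long format needs columns {sorted(required)}")
        series = {}
        for v, sub in df.groupby("variable"):
            sub = sub.sort_values("time")
            series[str(v)] = Series(sub["time"].to_numpy(float),
                                    sub["value"].to_numpy(float))
        return cls(series, truth=truth)
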