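"""Parameter containers for the AI-2 quorum-sensing model.

Two parameter groups are kept separate because they are estimated in two
stages: the Gompertz growth constants (fitted first against OD600 data,
then frozen) and the thirteen kinetic constants of the AI-2 / lsr-operon
equations.  Both round-trip losslessly through flat JSON or YAML maps
keyed by the conventional symbol names::

    X0, C, B, M, kA, km1, n1, kXA, km2, n2, kLA, Xdelta, kL, km3, n3, kAL, kR
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, fields, asdict
from pathlib import Path

import yaml

__all__ = [
    "GrowthParams",
    "QSParams",
    "GROWTH_NAMES",
    "QS_NAMES",
    "save_params",
    "load_params",
]

GROWTH_NAMES = ("X0", "C", "B", "M")
QS_NAMES = (
    "kA", "km1", "n1", "kXA", "km2", "n2", "kLA",
    "Xdelta", "kL", "km3", "n3", "kAL", "kR",
)


@dataclass(frozen=True)
class GrowthParams:
    """Gompertz growth-curve constants, X(t) = X0 + C*exp(-exp(-B*(t-M))).

    Parameters
    ----------
    X0 : float
        Initial cell density (OD600), > 0.
    C : float
        Maximum additional cell density, the sigmoid asymptote (OD600), > 0.
    B : float
        Growth rate (1/h), > 0.
    M : float
        Inflection time (h), >= 0.
    """

    X0: float
    C: float
    B: float
    M: float

    def __post_init__(self) -> None:
        if not (self.X0 > 0):
            raise ValueError(f"X0 must be > 0, got {self.X0}")
        if not (self.C > 0):
            raise ValueError(f"C must be > 0, got {self.C}")
        if not (self.B > 0):
            raise ValueError(f"B must be > 0, got {self.B}")
        if not (self.M >= 0):
            raise ValueError(f"M must be >= 0, got {self.M}")

    def to_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in asdict(self).items()}


@dataclass(frozen=True)
class QSParams:
    """Kinetic constants of the AI-2 / lsr-operon rate equations.

    Parameters
    ----------
    kA : float
        AI-2 production velocity (activity/h).
    km1 : float
        Cell density at half-maximal AI-2 production (OD600).
    n1 : float
        Hill exponent of the production term.
    kXA : float
        Basal AI-2 uptake rate through the PTS (1/h).
    km2 : float
        Cell density at half-maximal PTS uptake (OD600).
    n2 : float
        Hill exponent of the PTS uptake term.
    kLA : float
        AI-2 uptake rate through the LsrACDB transporters (1/(beta-gal*h)).
    Xdelta : float
        Cell density scaling the LsrACDB terms (OD600); expected near the
        late-exponential density (a value above X0 + C only triggers a
        warning, not an error).
    kL : float
        Operon expression rate (beta-gal/(activity*h)).
    km3 : float
        Cell density at half-maximal PTS-driven expression (OD600).
    n3 : float
        Hill exponent of the expression term.
    kAL : float
        Feedback operon expression rate (1/(activity*h)).
    kR : float
        Operon repression rate by LsrR (1/h).
    """

    kA: float
    km1: float
    n1: float
    kXA: float
    km2: float
    n2: float
    kLA: float
    Xdelta: float
    kL: float
    km3: float
    n3: float
    kAL: float
    kR: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v > 0):
                raise ValueError(f"{f.name} must be > 0, got {v}")

    def warn_if_inconsistent(self, gp: GrowthParams) -> None:
        """Warn when Xdelta exceeds the attainable density X0 + C."""
        if self.Xdelta > gp.X0 + gp.C:
            warnings.warn(
                f"Xdelta={self.Xdelta} exceeds the growth asymptote "
                f"X0 + C = {gp.X0 + gp.C}; the LsrACDB terms then never "
                "reach their nominal scale",
                stacklevel=2,
            )

    def to_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in asdict(self).items()}

    def replace(self, **kwargs: float) -> "QSParams":
        d = self.to_dict()
        d.update(kwargs)
        return QSParams(**d)


def save_params(path: str | Path, gp: GrowthParams | None = None,
                qp: QSParams | None = None) -> None:
    """Write parameters as a flat JSON or YAML map (by file extension)."""
    payload: dict[str, float] = {}
    if gp is not None:
        payload.update(gp.to_dict())
    if qp is not None:
        payload.update(qp.to_dict())
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2))


def load_params(path: str | Path) -> tuple[GrowthParams | None, QSParams | None]:
    """Read a flat parameter map; returns whichever groups are complete."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    gp = qp = None
    if all(k in data for k in GROWTH_NAMES):
        gp = GrowthParams(**{k: float(data[k]) for k in GROWTH_NAMES})
    if all(k in data for k in QS_NAMES):
        qp = QSParams(**{k: float(data[k]) for k in QS_NAMES})
    if gp is None and qp is None:
        raise ValueError(f"{path} contains neither a complete growth nor "
                         "a complete kinetic parameter set")
    return gp, qp
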