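"""Core domain types shared across the pipeline.

Axis convention (right-handed, fixed to the laboratory / goalkeeper):

* X — transversal (mediolateral), positive toward the right dive side
* Y — sagittal (anteroposterior), positive forward
* Z — longitudinal (vertical), positive up

Positions are meters, forces newtons, time seconds from trial start.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

G = 9.81
"""Gravitational acceleration used for weight normalization, m/s^2."""


class Rule(str, Enum):
    """Goalkeeper feet-positioning rule at the penalty kick."""

    OLD = "old"
    NEW = "new"


class Side(str, Enum):
    """Dive direction (or lower-limb dominance side)."""

    LEFT = "left"
    RIGHT = "right"


class Quality(str, Enum):
    OK = "ok"
    DISCARDED = "discarded"


@dataclass
class UniformSeries:
    """A uniformly sampled signal: one axis (1-D) or three axes (N x 3).

    Parameters
    ----------
    t0 : float
        Time of the first sample, seconds.
    rate : float
        Sampling rate, Hz. Must be positive.
    values : ndarray
        Shape (n,) for a single channel or (n, 3) for a 3-axis signal.
    """

    t0: float
    rate: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (1, 2):
            raise ValueError("values must be 1-D or 2-D")
        if self.values.ndim == 2 and self.values.shape[1] != 3:
            raise ValueError(
                f"2-D series must have 3 columns, got {self.values.shape[1]}"
            )

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def t(self) -> np.ndarray:
        """Sample times, seconds."""
        return self.t0 + np.arange(len(self)) / self.rate

    def time_at(self, i: int) -> float:
        return self.t0 + i / self.rate

    def column(self, j: int) -> "UniformSeries":
        """Single-axis view of column ``j`` of a 3-axis series."""
        return UniformSeries(self.t0, self.rate, self.values[:, j])

    def with_values(self, values: np.ndarray) -> "UniformSeries":
        return UniformSeries(self.t0, self.rate, values)


# Canonical ordering of the 14 outcome variables, as reported.
VARIABLE_NAMES = (
    "VD", "MLD", "APD", "RD", "AV", "PV",
    "VPF", "MLPF", "APPF", "RPF", "VI", "MLI", "API", "RI",
)

VARIABLE_UNITS = {
    "VD": "m", "MLD": "m", "APD": "m", "RD": "m",
    "AV": "m/s", "PV": "m/s",
    "VPF": "xBW", "MLPF": "xBW", "APPF": "xBW", "RPF": "xBW",
    "VI": "xBW.s", "MLI": "xBW.s", "API": "xBW.s", "RI": "xBW.s",
}


@dataclass
class DiveVariables:
    """The 14 per-trial outcome variables.

    Displacements in meters, velocities in m/s, peak forces in multiples of
    body weight (xBW), impulses in xBW.s.
    """

    VD: float
    MLD: float
    APD: float
    RD: float
    AV: float
    PV: float
    VPF: float
    MLPF: float
    APPF: float
    RPF: float
    VI: float
    MLI: float
    API: float
    RI: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def as_array(self) -> np.ndarray:
        d = self.as_dict()
        return np.array([d[k] for k in VARIABLE_NAMES])


@dataclass
class TrialRecord:
    """One dive trial: metadata plus the two sampled channels."""

    trial_id: str
    subject_id: str
    body_mass_kg: float
    rule: Rule
    side: Side
    iplag_score: int
    quality: Quality = Quality.OK
    cm: Optional[UniformSeries] = None
    grf: Optional[UniformSeries] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.body_mass_kg <= 0:
            raise ValueError(f"body mass must be positive, got {self.body_mass_kg}")
        if not 1 <= int(self.iplag_score) <= 5:
            raise ValueError(f"IPLAG score must be in 1..5, got {self.iplag_score}")
        self.rule = Rule(self.rule)
        self.side = Side(self.side)
        self.quality = Quality(self.quality)
        if self.quality is Quality.OK:
            if self.cm is not None and len(self.cm) == 0:
                raise ValueError("cm series empty for quality=ok trial")
            if self.grf is not None and len(self.grf) == 0:
                raise ValueError("grf series empty for quality=ok trial")
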