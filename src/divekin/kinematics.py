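"""Dive-window detection and displacement/velocity outcomes from the CM path.

The dive window runs from the global minimum of the vertical CM coordinate
(countermovement bottom) to its global maximum (flight apex).  Displacements
are reported as absolute per-axis coordinate differences between the window
ends, so left and right dives are directly comparable; the resultant is
their Euclidean norm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal import differentiate
from .types import UniformSeries

__all__ = [
    "DiveWindow",
    "NoRisingPhaseError",
    "detect_dive_window",
    "displacement_components",
    "resultant_displacement",
    "average_velocity",
    "peak_velocity",
    "kinematic_outcomes",
]

# column indices in a 3-axis CM series
_X, _Y, _Z = 0, 1, 2  # transversal (ML), sagittal (AP), longitudinal (V)


class NoRisingPhaseError(ValueError):
    """The vertical minimum occurs at or after the maximum: no dive."""


@dataclass(frozen=True)
class DiveWindow:
    i_start: int
    i_end: int
    t_start: float
    t_end: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def detect_dive_window(cm: UniformSeries) -> DiveWindow:
    """Locate the dive window on a (filtered) CM series.

    First occurrence wins on exact ties.  Raises
    :class:`NoRisingPhaseError` if the vertical minimum does not precede
    the maximum.
    """
    if cm.values.ndim != 2:
        raise ValueError("CM series must have 3 axes")
    if len(cm) < 3:
        raise ValueError(f"CM series too short ({len(cm)} samples)")
    z = cm.values[:, _Z]
    i_min = int(np.argmin(z))
    i_max = int(np.argmax(z))
    if i_min >= i_max:
        raise NoRisingPhaseError(
            f"no rising phase: vertical minimum (sample {i_min}) does not "
            f"precede maximum (sample {i_max})"
        )
    return DiveWindow(i_min, i_max, cm.time_at(i_min), cm.time_at(i_max))


def displacement_components(
    cm: UniformSeries, w: DiveWindow
) -> tuple[float, float, float]:
    """(VD, MLD, APD): absolute per-axis displacement across the window, m."""
    delta = np.abs(cm.values[w.i_end] - cm.values[w.i_start])
    return float(delta[_Z]), float(delta[_X]), float(delta[_Y])


def resultant_displacement(VD: float, MLD: float, APD: float) -> float:
    """Euclidean norm of the three displacement components, m."""
    return float(np.sqrt(VD**2 + MLD**2 + APD**2))


def average_velocity(RD: float, w: DiveWindow) -> float:
    """Resultant displacement over window duration, m/s."""
    if w.duration <= 0:
        raise ValueError("dive window has non-positive duration")
    return RD / w.duration


def peak_velocity(cm: UniformSeries, w: DiveWindow,
                  mode: str = "resultant") -> float:
    """Peak instantaneous CM speed within the dive window, m/s.

    ``mode='resultant'`` (default) takes the maximum of the Euclidean norm
    of the per-axis derivative; ``mode='per_axis'`` the maximum absolute
    single-axis velocity.
    """
    v = differentiate(cm).values[w.i_start: w.i_end + 1]
    if mode == "resultant":
        speed = np.linalg.norm(v, axis=1)
    elif mode == "per_axis":
        speed = np.abs(v).max(axis=1)
    else:
        raise ValueError(f"unknown peak-velocity mode {mode!r}")
    return float(speed.max())


def kinematic_outcomes(cm: UniformSeries, pv_mode: str = "resultant") -> dict:
    """All six kinematic outcomes of one (filtered) CM series."""
    w = detect_dive_window(cm)
    VD, MLD, APD = displacement_components(cm, w)
    RD = resultant_displacement(VD, MLD, APD)
    return {
        "VD": VD, "MLD": MLD, "APD": APD, "RD": RD,
        "AV": average_velocity(RD, w),
        "PV": peak_velocity(cm, w, mode=pv_mode),
        "window": w,
    }
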