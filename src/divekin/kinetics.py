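"""Impulse-phase detection and weight-normalized force/impulse outcomes.

The force plate reports the ground reaction force of the lower limb
ipsilateral to the dive; outcomes are normalized by body weight
(``m * 9.81``): peaks in xBW, trapezoid-integrated impulses in xBW.s.

The push-off phase starts where the vertical force last rises through
``onset_factor`` x body weight before its terminal peak, and ends at the
first subsequent sample below the foot-off contact threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import G, UniformSeries

__all__ = [
    "ImpulsePhase",
    "ImpulseDetectionError",
    "detect_impulse_phase",
    "peak_forces",
    "impulses",
    "kinetic_outcomes",
]

_X, _Y, _Z = 0, 1, 2  # ML, AP, vertical force components


class ImpulseDetectionError(ValueError):
    """No impulse onset or no takeoff could be located."""


@dataclass(frozen=True)
class ImpulsePhase:
    i_on: int
    i_off: int
    t_on: float
    t_off: float

    @property
    def duration(self) -> float:
        return self.t_off - self.t_on


def detect_impulse_phase(
    grf: UniformSeries,
    body_mass_kg: float,
    onset_factor: float = 1.05,
    contact_threshold_n: float = 10.0,
) -> ImpulsePhase:
    """Locate the terminal push-off on a (filtered) force series.

    ``i_on`` is the first sample of the last up-crossing of
    ``onset_factor * body weight`` before the global vertical-force peak;
    ``i_off`` the first sample after the peak with vertical force below
    ``contact_threshold_n`` (foot-off).
    """
    if body_mass_kg <= 0:
        raise ValueError("body mass must be positive")
    if grf.values.ndim != 2:
        raise ValueError("force series must have 3 axes")
    fz = grf.values[:, _Z]
    thr = onset_factor * body_mass_kg * G
    i_pk = int(np.argmax(fz))
    if fz[i_pk] < thr:
        raise ImpulseDetectionError(
            f"no impulse detected: vertical force never exceeds "
            f"{thr:.1f} N (max {fz[i_pk]:.1f} N)"
        )
    below = np.nonzero(fz[:i_pk] < thr)[0]
    # Onset: first sample after the last sub-threshold sample before the
    # peak; if force is above threshold from the start, onset is sample 0.
    i_on = int(below[-1]) + 1 if len(below) else 0
    off = np.nonzero(fz[i_pk:] < contact_threshold_n)[0]
    if len(off) == 0:
        raise ImpulseDetectionError(
            f"no takeoff detected: vertical force never falls below "
            f"{contact_threshold_n:.1f} N after its peak"
        )
    i_off = i_pk + int(off[0])
    return ImpulsePhase(i_on, i_off, grf.time_at(i_on), grf.time_at(i_off))


def peak_forces(
    grf: UniformSeries, phase: ImpulsePhase, body_mass_kg: float
) -> tuple[float, float, float, float]:
    """(VPF, MLPF, APPF, RPF) in xBW over the impulse phase.

    The resultant peak is the maximum of the sample-wise Euclidean norm of
    the force vector (norm-then-max), not a combination of per-axis peaks.
    """
    bw = body_mass_kg * G
    f = grf.values[phase.i_on: phase.i_off + 1]
    per_axis = np.abs(f).max(axis=0) / bw
    rpf = float(np.linalg.norm(f, axis=1).max() / bw)
    return float(per_axis[_Z]), float(per_axis[_X]), float(per_axis[_Y]), rpf


def impulses(
    grf: UniformSeries,
    phase: ImpulsePhase,
    body_mass_kg: float,
    signed: bool = False,
) -> tuple[float, float, float, float]:
    """(VI, MLI, API, RI) in xBW.s: trapezoidal force-time integrals over
    the impulse phase, normalized by body weight.

    Per-axis integrands are absolute force by default (``signed=False``),
    so dive direction does not flip signs; the resultant integrand is the
    sample-wise force-vector magnitude (norm-then-integrate).
    """
    bw = body_mass_kg * G
    f = grf.values[phase.i_on: phase.i_off + 1]
    t = grf.t[phase.i_on: phase.i_off + 1]
    integrand = f if signed else np.abs(f)
    per_axis = np.trapezoid(integrand, t, axis=0) / bw
    if signed:
        per_axis = np.abs(per_axis)
    ri = float(np.trapezoid(np.linalg.norm(f, axis=1), t) / bw)
    return float(per_axis[_Z]), float(per_axis[_X]), float(per_axis[_Y]), ri


def kinetic_outcomes(
    grf: UniformSeries,
    body_mass_kg: float,
    onset_factor: float = 1.05,
    contact_threshold_n: float = 10.0,
    signed_impulses: bool = False,
) -> dict:
    """All eight kinetic outcomes of one (filtered) force series."""
    phase = detect_impulse_phase(grf, body_mass_kg, onset_factor,
                                 contact_threshold_n)
    VPF, MLPF, APPF, RPF = peak_forces(grf, phase, body_mass_kg)
    VI, MLI, API, RI = impulses(grf, phase, body_mass_kg,
                                signed=signed_impulses)
    return {
        "VPF": VPF, "MLPF": MLPF, "APPF": APPF, "RPF": RPF,
        "VI": VI, "MLI": MLI, "API": API, "RI": RI,
        "phase": phase,
    }
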