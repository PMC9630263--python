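"""Mechanistic synthetic dive generator with an analytic truth channel.

A dive is modeled as a continuous-time center-of-mass (CM) path through four
phases — quiet stance, countermovement, push-off impulse, ballistic flight —
built from piecewise polynomials with continuous position and velocity
(acceleration is continuous everywhere except at most the takeoff boundary,
where the ground reaction force reaches exactly zero by construction).

While the foot is on the ground the reaction force is Newtonian,
``F(t) = m (a(t) + g ez)``; after takeoff it is identically zero and the CM
acceleration is ``(0, 0, -g)``.

Every outcome variable the processing pipeline later estimates from sampled,
noisy signals is also computed here exactly from the continuous model
(polynomial extrema and integrals in closed form; the resultant-force
integral by adaptive quadrature at ~1e-12 tolerance), so that recovery error
is attributable to the pipeline alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numpy.polynomial import Polynomial
from scipy.integrate import quad

from .types import (
    G,
    DiveVariables,
    Quality,
    Rule,
    Side,
    TrialRecord,
    UniformSeries,
)

__all__ = [
    "SimParams",
    "SyntheticGroundTruth",
    "SubjectConfig",
    "SessionConfig",
    "default_params",
    "default_session_config",
    "simulate_dive",
    "simulate_session",
    "simulate_outcome_table",
]

# Default apex height chosen so the rise time sqrt(2 h / g) = 0.175 s, which
# puts the flight apex of the default parameter set exactly on the 400 Hz
# kinematic sample grid (discretization-free event recovery on clean trials).
_DEFAULT_APEX_M = G * 0.175**2 / 2.0


@dataclass
class SimParams:
    """Parameters of one synthetic dive.

    All durations in seconds, lengths in meters, rates in Hz.
    ``frontal_step_m`` is the new-rule handle: the extra anteroposterior CM
    excursion produced by projecting the foot forward; it must be 0 under
    the old rule.
    """

    body_mass_kg: float = 80.0
    rule: Rule = Rule.OLD
    side: Side = Side.RIGHT
    stance_duration_s: float = 0.5
    countermovement_depth_m: float = 0.3
    countermovement_duration_s: float = 0.45
    impulse_duration_s: float = 0.33
    flight_apex_height_m: float = _DEFAULT_APEX_M
    lateral_reach_m: float = 1.4
    frontal_step_m: float = 0.0
    ap_drift_m: float = 0.25
    takeoff_reach_fraction: float = 0.55
    stance_height_m: float = 1.0
    bottom_accel_ms2: float = 6.0
    flight_padding_s: float = 0.2
    kin_rate_hz: float = 400.0
    force_rate_hz: float = 2000.0
    noise_sd_pos_m: float = 0.0
    noise_sd_force_n: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.rule = Rule(self.rule)
        self.side = Side(self.side)
        if self.body_mass_kg <= 0:
            raise ValueError("body_mass_kg must be positive")
        if self.rule is Rule.OLD and self.frontal_step_m != 0.0:
            raise ValueError(
                "frontal_step_m must be 0 under the old rule "
                f"(got {self.frontal_step_m})"
            )
        for name in ("kin_rate_hz", "force_rate_hz", "impulse_duration_s",
                     "countermovement_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.flight_apex_height_m <= 0:
            raise ValueError(
                f"flight_apex_height_m must be positive, got "
                f"{self.flight_apex_height_m} (no airborne phase)"
            )
        for name in ("stance_duration_s", "countermovement_depth_m",
                     "lateral_reach_m", "frontal_step_m", "ap_drift_m",
                     "flight_padding_s", "noise_sd_pos_m", "noise_sd_force_n"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 <= self.takeoff_reach_fraction <= 1:
            raise ValueError("takeoff_reach_fraction must be in [0, 1]")


def default_params(rule: Rule | str, side: Side | str, **overrides) -> SimParams:
    """Default parameter set for a rule/side condition.

    The new rule adds a 0.25 m frontal-step anteroposterior excursion
    unless overridden.
    """
    rule = Rule(rule)
    if rule is Rule.NEW:
        overrides.setdefault("frontal_step_m", 0.25)
    return SimParams(rule=rule, side=Side(side), **overrides)


@dataclass
class SyntheticGroundTruth:
    """Exact outcome values and event times of the continuous model."""

    variables: DiveVariables
    t_bottom: float
    t_takeoff: float
    t_apex: float
    t_onset: float
    takeoff_velocity: tuple[float, float, float]

    def as_dict(self) -> dict:
        d = self.variables.as_dict()
        d.update(
            t_bottom=self.t_bottom,
            t_takeoff=self.t_takeoff,
            t_apex=self.t_apex,
            t_onset=self.t_onset,
        )
        return d


# ----------------------------------------------------------------------
# polynomial helpers (all in a piece's local time)

def _hermite_quintic(T, p0, v0, a0, p1, v1, a1) -> Polynomial:
    """Unique quintic with prescribed position/velocity/acceleration ends."""
    M = np.zeros((6, 6))
    M[0, 0] = 1.0
    M[1, 1] = 1.0
    M[2, 2] = 2.0
    M[3] = [T**k for k in range(6)]
    M[4] = [k * T ** (k - 1) if k >= 1 else 0.0 for k in range(6)]
    M[5] = [k * (k - 1) * T ** (k - 2) if k >= 2 else 0.0 for k in range(6)]
    coef = np.linalg.solve(M, np.array([p0, v0, a0, p1, v1, a1], dtype=float))
    return Polynomial(coef)


def _real_roots(poly: Polynomial, lo: float, hi: float) -> np.ndarray:
    c = poly.coef
    if np.allclose(c, 0.0):
        return np.array([])
    r = poly.roots()
    r = r[np.abs(r.imag) < 1e-9].real
    eps = 1e-12 * max(1.0, abs(hi))
    return r[(r >= lo - eps) & (r <= hi + eps)].clip(lo, hi)


def _poly_abs_max(poly: Polynomial, lo: float, hi: float) -> float:
    cand = [lo, hi] + list(_real_roots(poly.deriv(), lo, hi))
    return float(np.max(np.abs(poly(np.array(cand)))))


def _poly_abs_integral(poly: Polynomial, lo: float, hi: float) -> float:
    """Integral of |poly| on [lo, hi], split exactly at sign changes."""
    pts = np.unique(np.concatenate([[lo, hi], _real_roots(poly, lo, hi)]))
    P = poly.integ()
    total = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        total += abs(P(b) - P(a))
    return float(total)


# ----------------------------------------------------------------------

class _Piece:
    """One phase of the motion: 3 position polynomials in local time."""

    __slots__ = ("t0", "t1", "pos", "vel", "acc")

    def __init__(self, t0: float, t1: float, pos):
        self.t0 = t0
        self.t1 = t1
        self.pos = pos
        self.vel = tuple(p.deriv() for p in pos)
        self.acc = tuple(p.deriv(2) for p in pos)


class _DiveModel:
    """Continuous-time dive built from :class:`SimParams`."""

    def __init__(self, p: SimParams):
        self.p = p
        s = 1.0 if p.side is Side.RIGHT else -1.0
        self.side_sign = s
        z0 = p.stance_height_m
        d = p.countermovement_depth_m
        Ts, Tc, Ti = (p.stance_duration_s, p.countermovement_duration_s,
                      p.impulse_duration_s)
        ab = p.bottom_accel_ms2
        v0z = np.sqrt(2.0 * G * p.flight_apex_height_m)
        t_fl = v0z / G

        frac = p.takeoff_reach_fraction
        x_tot = p.lateral_reach_m
        y_tot = p.ap_drift_m + p.frontal_step_m
        x_to, y_to = frac * x_tot, frac * y_tot
        vx_to = (x_tot - x_to) / t_fl
        vy_to = (y_tot - y_to) / t_fl

        self.t_bottom = Ts + Tc
        self.t_takeoff = Ts + Tc + Ti
        self.t_apex = self.t_takeoff + t_fl
        self.t_end = self.t_apex + p.flight_padding_s
        self.takeoff_velocity = (s * vx_to, vy_to, v0z)

        const = lambda c: Polynomial([c])  # noqa: E731
        stance = _Piece(0.0, Ts, (const(0.0), const(0.0), const(z0)))
        counter = _Piece(Ts, Ts + Tc, (
            const(0.0), const(0.0),
            _hermite_quintic(Tc, z0, 0.0, 0.0, z0 - d, 0.0, ab),
        ))
        impulse = _Piece(self.t_bottom, self.t_takeoff, (
            _hermite_quintic(Ti, 0.0, 0.0, 0.0, s * x_to, s * vx_to, 0.0),
            _hermite_quintic(Ti, 0.0, 0.0, 0.0, y_to, vy_to, 0.0),
            _hermite_quintic(Ti, z0 - d, 0.0, ab, z0, v0z, -G),
        ))
        flight = _Piece(self.t_takeoff, self.t_end, (
            Polynomial([s * x_to, s * vx_to]),
            Polynomial([y_to, vy_to]),
            Polynomial([z0, v0z, -G / 2.0]),
        ))
        self.pieces = [stance, counter, impulse, flight]
        self.contact = self.pieces[:3]
        self._validate()

    # -- evaluation --------------------------------------------------

    def _eval(self, t: np.ndarray, attr: str) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.empty(t.shape + (3,))
        for k, piece in enumerate(self.pieces):
            if k == len(self.pieces) - 1:
                m = t >= piece.t0
            else:
                m = (t >= piece.t0) & (t < piece.t1)
            tau = t[m] - piece.t0
            for j, poly in enumerate(getattr(piece, attr)):
                out[m, j] = poly(tau)
        return out

    def position(self, t: np.ndarray) -> np.ndarray:
        return self._eval(t, "pos")

    def velocity(self, t: np.ndarray) -> np.ndarray:
        return self._eval(t, "vel")

    def force(self, t: np.ndarray) -> np.ndarray:
        """Ground reaction force; identically zero after takeoff."""
        t = np.asarray(t, dtype=float)
        a = self._eval(t, "acc")
        f = self.p.body_mass_kg * (a + np.array([0.0, 0.0, G]))
        f[t >= self.t_takeoff] = 0.0
        return f

    def _force_polys(self, piece: _Piece):
        m = self.p.body_mass_kg
        return (piece.acc[0] * m, piece.acc[1] * m,
                piece.acc[2] * m + Polynomial([m * G]))

    # -- validation --------------------------------------------------

    def _validate(self) -> None:
        t = np.linspace(0.0, self.t_end, 4001)
        pos = self.position(t)
        frc = self.force(t)
        fz_min = frc[t < self.t_takeoff, 2].min()
        if fz_min < -1e-6 * self.p.body_mass_kg * G:
            raise ValueError(
                "non-physical parameter set: vertical ground reaction force "
                f"becomes negative ({fz_min:.1f} N) during contact — the "
                "impulse is too short/shallow for the requested flight"
            )
        z = pos[:, 2]
        z_bottom = self.p.stance_height_m - self.p.countermovement_depth_m
        if z.min() < z_bottom - 1e-9:
            raise ValueError(
                "non-physical parameter set: CM drops below the "
                "countermovement bottom during push-off"
            )
        z_apex = self.p.stance_height_m + self.p.flight_apex_height_m
        if z[t < self.t_takeoff].max() > z_apex - 1e-9:
            raise ValueError(
                "non-physical parameter set: CM exceeds the flight apex "
                "before takeoff"
            )

    # -- analytic ground truth --------------------------------------

    def ground_truth(self, onset_factor: float = 1.05) -> SyntheticGroundTruth:
        p = self.p
        m, bw = p.body_mass_kg, p.body_mass_kg * G
        vx, vy, vz = self.takeoff_velocity

        VD = p.countermovement_depth_m + p.flight_apex_height_m
        MLD = p.lateral_reach_m
        APD = p.ap_drift_m + p.frontal_step_m
        RD = float(np.sqrt(VD**2 + MLD**2 + APD**2))
        window = self.t_apex - self.t_bottom
        AV = RD / window

        # peak resultant speed over [t_bottom, t_apex]; in flight the speed
        # only decreases toward apex, so the flight max is at takeoff, which
        # is an endpoint of the impulse piece.
        imp = self.pieces[2]
        speed2 = imp.vel[0] ** 2 + imp.vel[1] ** 2 + imp.vel[2] ** 2
        cand = [0.0, imp.t1 - imp.t0] + list(
            _real_roots(speed2.deriv(), 0.0, imp.t1 - imp.t0)
        )
        PV = float(np.sqrt(np.max(speed2(np.array(cand)))))

        # impulse-phase bounds on the continuous force
        thr = onset_factor * bw
        t_pk, f_pk = None, -np.inf
        for piece in self.contact:
            fz = self._force_polys(piece)[2]
            hi = piece.t1 - piece.t0
            for tau in [0.0, hi] + list(_real_roots(fz.deriv(), 0.0, hi)):
                v = float(fz(tau))
                if v > f_pk:
                    f_pk, t_pk = v, piece.t0 + tau
        t_on = None
        for piece in self.contact:
            fz = self._force_polys(piece)[2]
            hi = piece.t1 - piece.t0
            for tau in _real_roots(fz - Polynomial([thr]), 0.0, hi):
                t_abs = piece.t0 + tau
                if t_abs <= t_pk and float(fz.deriv()(tau)) > 0:
                    if t_on is None or t_abs > t_on:
                        t_on = t_abs
        if t_on is None:
            raise ValueError(
                "ground truth: vertical force never rises through the onset "
                f"threshold {thr:.1f} N before its peak"
            )
        t_off = self.t_takeoff

        peaks = np.zeros(3)
        imps = np.zeros(3)
        RPF = 0.0
        RI = 0.0
        for piece in self.contact:
            lo = max(t_on, piece.t0) - piece.t0
            hi = min(t_off, piece.t1) - piece.t0
            if hi <= lo:
                continue
            fp = self._force_polys(piece)
            S = fp[0] ** 2 + fp[1] ** 2 + fp[2] ** 2
            for j in range(3):
                peaks[j] = max(peaks[j], _poly_abs_max(fp[j], lo, hi))
                imps[j] += _poly_abs_integral(fp[j], lo, hi)
            cand = [lo, hi] + list(_real_roots(S.deriv(), lo, hi))
            RPF = max(RPF, float(np.sqrt(np.max(S(np.array(cand))))))
            val, _ = quad(lambda u: np.sqrt(S(u)), lo, hi,
                          epsabs=1e-10, epsrel=1e-12, limit=200)
            RI += val

        MLPF, APPF, VPF = peaks / bw
        MLI, API, VI = imps / bw
        variables = DiveVariables(
            VD=VD, MLD=MLD, APD=APD, RD=RD, AV=AV, PV=PV,
            VPF=float(VPF), MLPF=float(MLPF), APPF=float(APPF),
            RPF=float(RPF / bw),
            VI=float(VI), MLI=float(MLI), API=float(API), RI=float(RI / bw),
        )
        return SyntheticGroundTruth(
            variables=variables,
            t_bottom=self.t_bottom,
            t_takeoff=self.t_takeoff,
            t_apex=self.t_apex,
            t_onset=float(t_on),
            takeoff_velocity=self.takeoff_velocity,
        )


# ----------------------------------------------------------------------

def simulate_dive(
    params: SimParams,
    trial_id: str = "trial",
    subject_id: str = "subject",
    iplag_score: int = 5,
    rng: Optional[np.random.Generator] = None,
) -> tuple[TrialRecord, SyntheticGroundTruth]:
    """Generate one sampled dive trial plus its exact ground truth.

    The kinematic and force channels are sampled on independent clocks
    (``kin_rate_hz`` / ``force_rate_hz``) with i.i.d. Gaussian measurement
    noise per channel; the ground truth comes from the continuous model and
    is unaffected by sampling or noise.
    """
    model = _DiveModel(params)
    truth = model.ground_truth()
    if rng is None:
        rng = np.random.default_rng(params.seed)

    n_k = int(np.floor(model.t_end * params.kin_rate_hz)) + 1
    t_k = np.arange(n_k) / params.kin_rate_hz
    cm = model.position(t_k)
    if params.noise_sd_pos_m > 0:
        cm = cm + rng.normal(0.0, params.noise_sd_pos_m, size=cm.shape)

    n_f = int(np.floor(model.t_end * params.force_rate_hz)) + 1
    t_f = np.arange(n_f) / params.force_rate_hz
    grf = model.force(t_f)
    if params.noise_sd_force_n > 0:
        grf = grf + rng.normal(0.0, params.noise_sd_force_n, size=grf.shape)

    record = TrialRecord(
        trial_id=trial_id,
        subject_id=subject_id,
        body_mass_kg=params.body_mass_kg,
        rule=params.rule,
        side=params.side,
        iplag_score=iplag_score,
        quality=Quality.OK,
        cm=UniformSeries(0.0, params.kin_rate_hz, cm),
        grf=UniformSeries(0.0, params.force_rate_hz, grf),
        meta={"params": dataclasses.asdict(params), "truth": truth.as_dict()},
    )
    return record, truth


# ----------------------------------------------------------------------
# sessions

@dataclass
class SubjectConfig:
    subject_id: str
    body_mass_kg: float
    iplag_score: int


@dataclass
class SessionConfig:
    """One collection session: every subject performs ``4 * n_per_cell``
    dives, ``n_per_cell`` per (rule x side) cell, in seed-randomized order.

    ``frontal_step_m`` injects the rule effect (applied to new-rule trials
    only); ``ndll_reach_boost_m`` injects a laterality effect (extra lateral
    reach on dives toward the non-dominant side).  Set both to 0 for null
    simulations.
    """

    subjects: list[SubjectConfig] = field(default_factory=list)
    n_per_cell: int = 5
    base: SimParams = field(default_factory=SimParams)
    frontal_step_m: float = 0.25
    ndll_reach_boost_m: float = 0.0
    subject_scale_sd: float = 0.05
    param_jitter_sd: float = 0.03
    effort_sd: float = 0.05
    var_noise_sd: float = 0.01
    noise_sd_pos_m: float = 0.0
    noise_sd_force_n: float = 0.0
    discard_count: int = 0


def default_session_config(n_subjects: int = 6, **overrides) -> SessionConfig:
    """Six-subject default roster; one left-footed subject, as in typical
    goalkeeper samples."""
    masses = [81.6, 75.0, 88.0, 70.5, 92.3, 79.0, 84.1, 73.2]
    scores = [2, 5, 4, 5, 4, 5, 4, 5]
    subjects = [
        SubjectConfig(f"S{i + 1:02d}", masses[i % len(masses)],
                      scores[i % len(scores)])
        for i in range(n_subjects)
    ]
    return SessionConfig(subjects=subjects, **overrides)


def _dominance_of(iplag: int) -> Side:
    if iplag in (1, 2):
        return Side.LEFT
    if iplag in (4, 5):
        return Side.RIGHT
    raise ValueError(f"IPLAG score {iplag} has no dominance side")


def _trial_params(cfg: SessionConfig, subj: SubjectConfig, rule: Rule,
                  side: Side, scale: float, rng: np.random.Generator,
                  jitter: bool = True) -> SimParams:
    jit = (lambda: float(np.exp(rng.normal(0.0, cfg.param_jitter_sd)))) \
        if jitter and cfg.param_jitter_sd > 0 else (lambda: 1.0)
    reach = cfg.base.lateral_reach_m * scale * jit()
    if cfg.ndll_reach_boost_m and side is not _dominance_of(subj.iplag_score):
        reach += cfg.ndll_reach_boost_m
    step = cfg.frontal_step_m * scale * jit() if rule is Rule.NEW else 0.0
    return replace(
        cfg.base,
        body_mass_kg=subj.body_mass_kg,
        rule=rule,
        side=side,
        lateral_reach_m=reach,
        frontal_step_m=step,
        ap_drift_m=cfg.base.ap_drift_m * scale * jit(),
        flight_apex_height_m=cfg.base.flight_apex_height_m * scale * jit(),
        countermovement_depth_m=cfg.base.countermovement_depth_m * jit(),
        noise_sd_pos_m=cfg.noise_sd_pos_m,
        noise_sd_force_n=cfg.noise_sd_force_n,
    )


def simulate_session(cfg: SessionConfig, seed: int) -> list[TrialRecord]:
    """Simulate a full session; deterministic for equal seeds.

    Returns one :class:`TrialRecord` per dive (ground truth is attached in
    ``record.meta['truth']``).
    """
    if not cfg.subjects:
        raise ValueError("session config names no subjects")
    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    for subj in cfg.subjects:
        scale = float(np.exp(rng.normal(0.0, cfg.subject_scale_sd))) \
            if cfg.subject_scale_sd > 0 else 1.0
        cells = [(r, s) for r in (Rule.OLD, Rule.NEW)
                 for s in (Side.LEFT, Side.RIGHT)
                 for _ in range(cfg.n_per_cell)]
        order = rng.permutation(len(cells))
        for k, idx in enumerate(order):
            rule, side = cells[idx]
            params = _trial_params(cfg, subj, rule, side, scale, rng)
            rec, _ = simulate_dive(
                params,
                trial_id=f"{subj.subject_id}_t{k + 1:02d}",
                subject_id=subj.subject_id,
                iplag_score=subj.iplag_score,
                rng=rng,
            )
            trials.append(rec)
    if cfg.discard_count:
        for i in rng.choice(len(trials), size=cfg.discard_count,
                            replace=False):
            trials[i].quality = Quality.DISCARDED
    return trials


def simulate_outcome_table(cfg: SessionConfig, seed: int):
    """Fast outcome-level session: trial outcomes drawn around the analytic
    ground truth without synthesizing/processing signals.

    Per-trial variation is a shared multiplicative "effort" factor (all 14
    variables move together, as they do physically) plus a small independent
    per-variable jitter; subjects carry a multiplicative scale of their own.
    Intended for large replicate studies (type-I calibration, power), where
    running the full signal pipeline would be needlessly slow; fidelity of
    the signal path itself is covered by the ground-truth recovery tests.

    Returns a pandas DataFrame with one row per trial: metadata plus the 14
    outcome variables.
    """
    import pandas as pd

    from .types import VARIABLE_NAMES

    if not cfg.subjects:
        raise ValueError("session config names no subjects")
    rng = np.random.default_rng(seed)
    cache: dict = {}

    def truth_vec(subj: SubjectConfig, rule: Rule, side: Side) -> np.ndarray:
        ndll = (cfg.ndll_reach_boost_m > 0
                and side is not _dominance_of(subj.iplag_score))
        key = (rule, ndll)
        if key not in cache:
            reach = cfg.base.lateral_reach_m + (
                cfg.ndll_reach_boost_m if ndll else 0.0)
            step = cfg.frontal_step_m if rule is Rule.NEW else 0.0
            p = replace(cfg.base, rule=rule, side=Side.RIGHT,
                        lateral_reach_m=reach, frontal_step_m=step)
            cache[key] = _DiveModel(p).ground_truth().variables.as_array()
        return cache[key]

    rows = []
    for subj in cfg.subjects:
        # additive Gaussian factors keep paired null differences Gaussian,
        # so the paired t-test is exactly calibrated
        s_i = 1.0 + float(rng.normal(0.0, cfg.subject_scale_sd)) \
            if cfg.subject_scale_sd > 0 else 1.0
        cells = [(r, s) for r in (Rule.OLD, Rule.NEW)
                 for s in (Side.LEFT, Side.RIGHT)
                 for _ in range(cfg.n_per_cell)]
        order = rng.permutation(len(cells))
        for k, idx in enumerate(order):
            rule, side = cells[idx]
            base = truth_vec(subj, rule, side)
            effort = float(rng.normal(0.0, cfg.effort_sd))
            jitter = rng.normal(0.0, cfg.var_noise_sd, size=len(base))
            vals = base * s_i * (1.0 + effort + jitter)
            row = {
                "trial_id": f"{subj.subject_id}_t{k + 1:02d}",
                "subject_id": subj.subject_id,
                "body_mass_kg": subj.body_mass_kg,
                "rule": rule.value,
                "side": side.value,
                "iplag_score": subj.iplag_score,
                "quality": "ok",
            }
            row.update(dict(zip(VARIABLE_NAMES, vals)))
            rows.append(row)
    df = pd.DataFrame(rows)
    if cfg.discard_count:
        drop = rng.choice(len(df), size=cfg.discard_count, replace=False)
        df.loc[drop, "quality"] = "discarded"
    return df
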