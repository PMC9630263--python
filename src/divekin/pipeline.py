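"""End-to-end orchestration: simulate -> process -> stats.

All randomness flows from the single seed given to :func:`run_pipeline`;
filter cutoffs, detected windows/phases and every exclusion are logged.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as dio
from .kinematics import NoRisingPhaseError, kinematic_outcomes
from .kinetics import ImpulseDetectionError, kinetic_outcomes
from .signal import butterworth_lowpass, residual_analysis_cutoff
from .stats import run_analysis
from .synthetic import (
    SessionConfig,
    SubjectConfig,
    default_session_config,
    simulate_session,
)
from .types import Quality, TrialRecord, UniformSeries

__all__ = [
    "ProcessConfig",
    "PipelineConfig",
    "process_trial",
    "process_session",
    "run_pipeline",
    "session_config_from_dict",
]

logger = logging.getLogger("divekin.pipeline")


@dataclass
class ProcessConfig:
    """Signal-processing and event-detection settings.

    Cutoffs may be a number (Hz), ``"auto"`` (residual analysis per trial
    per channel) or ``None`` (no filtering).
    """

    filter_order: int = 4
    cm_cutoff_hz: float | str | None = 10.0
    force_cutoff_hz: float | str | None = 10.0
    grid_hz: tuple[float, ...] = tuple(np.arange(1.0, 41.0))
    onset_factor: float = 1.05
    contact_threshold_n: float = 10.0
    signed_impulses: bool = False
    pv_mode: str = "resultant"


def _filtered(series: UniformSeries, cutoff, cfg: ProcessConfig,
              label: str, trial_id: str) -> UniformSeries:
    if cutoff is None:
        return series
    if cutoff == "auto":
        grid = np.asarray([f for f in cfg.grid_hz if f < series.rate / 2.0])
        cutoff = residual_analysis_cutoff(series, grid,
                                          order=cfg.filter_order)
        logger.info("trial=%s channel=%s residual_cutoff_hz=%.3g",
                    trial_id, label, cutoff)
    return butterworth_lowpass(series, float(cutoff),
                               order=cfg.filter_order)


def process_trial(trial: TrialRecord, cfg: Optional[ProcessConfig] = None
                  ) -> dict:
    """Compute all 14 outcome variables for one trial.

    Raises the detection errors of the kinematics/kinetics stages; callers
    that batch trials catch them and exclude the trial.
    """
    cfg = cfg or ProcessConfig()
    if trial.cm is None or trial.grf is None:
        raise ValueError(f"trial {trial.trial_id}: missing channel data")
    cm = _filtered(trial.cm, cfg.cm_cutoff_hz, cfg, "cm", trial.trial_id)
    grf = _filtered(trial.grf, cfg.force_cutoff_hz, cfg, "grf",
                    trial.trial_id)
    kin = kinematic_outcomes(cm, pv_mode=cfg.pv_mode)
    kin.pop("window")
    kin_full = kinetic_outcomes(
        grf, trial.body_mass_kg,
        onset_factor=cfg.onset_factor,
        contact_threshold_n=cfg.contact_threshold_n,
        signed_impulses=cfg.signed_impulses,
    )
    kin_full.pop("phase")
    return {**kin, **kin_full}


def process_session(
    trials: list[TrialRecord],
    cfg: Optional[ProcessConfig] = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Process a batch of trials into a tidy results table.

    Returns (results, exclusions); every excluded trial appears exactly
    once in ``exclusions`` with a machine-readable reason code.
    """
    cfg = cfg or ProcessConfig()
    rows, exclusions = [], []

    def exclude(trial_id: str, reason: str, detail: str = "") -> None:
        exclusions.append(
            {"trial_id": trial_id, "reason": reason, "detail": detail})
        logger.info("excluded trial=%s reason=%s %s", trial_id, reason,
                    detail)

    for trial in trials:
        meta = {
            "trial_id": trial.trial_id,
            "subject_id": trial.subject_id,
            "body_mass_kg": trial.body_mass_kg,
            "rule": trial.rule.value,
            "side": trial.side.value,
            "iplag_score": trial.iplag_score,
            "quality": trial.quality.value,
        }
        if trial.quality is not Quality.OK:
            exclude(trial.trial_id, "quality_discarded")
            continue
        try:
            outcomes = process_trial(trial, cfg)
        except NoRisingPhaseError as exc:
            exclude(trial.trial_id, "no_rising_phase", str(exc))
            continue
        except ImpulseDetectionError as exc:
            exclude(trial.trial_id, "impulse_detection", str(exc))
            continue
        rows.append({**meta, **outcomes})
    logger.info("processed %d trials, excluded %d", len(rows),
                len(exclusions))
    return pd.DataFrame(rows), exclusions


@dataclass
class PipelineConfig:
    session: SessionConfig = field(default_factory=default_session_config)
    process: ProcessConfig = field(default_factory=ProcessConfig)
    pairing_mode: str = "subject_mean"
    d_method: str = "pooled"
    alpha: float = 0.05
    seed: int = 0


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None
                 ) -> pd.DataFrame:
    """simulate -> process -> stats; deterministic given config + seed.

    When ``out_dir`` is given, writes the simulated trial directory plus
    ``results.csv`` and ``report.csv`` there.
    """
    trials = simulate_session(config.session, config.seed)
    results, _ = process_session(trials, config.process)
    report = run_analysis(results, pairing_mode=config.pairing_mode,
                          d_method=config.d_method, alpha=config.alpha)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dio.write_session(trials, out)
        dio.write_results(results, out / "results.csv")
        report.to_csv(out / "report.csv", index=False, float_format="%.17g")
    return report


def session_config_from_dict(d: dict) -> SessionConfig:
    """Build a SessionConfig from a plain JSON-style dict.

    Recognized keys: ``subjects`` (list of subject dicts), ``base``
    (SimParams overrides), and any top-level SessionConfig field.
    """
    from .synthetic import SimParams

    d = dict(d)
    kwargs = {}
    if "subjects" in d:
        kwargs["subjects"] = [SubjectConfig(**s) for s in d.pop("subjects")]
    if "base" in d:
        kwargs["base"] = SimParams(**d.pop("base"))
    valid = {f.name for f in dataclasses.fields(SessionConfig)}
    unknown = set(d) - valid
    if unknown:
        raise ValueError(f"unknown session config keys: {sorted(unknown)}")
    kwargs.update(d)
    cfg = SessionConfig(**kwargs)
    if not cfg.subjects:
        cfg.subjects = default_session_config().subjects
    return cfg
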