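"""Readers and writers: trial directories, results tables, reports.

Canonical on-disk layout of a trial directory::

    DIR/
      trials.json                 # manifest: metadata + channel descriptors
      truth.csv                   # simulator ground truth (when available)
      trials/<trial_id>/cm.csv    # t[s],x[m],y[m],z[m]
      trials/<trial_id>/grf.csv   # t[s],fx[N],fy[N],fz[N]

Column headers double as unit declarations and are checked on read.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    VARIABLE_NAMES,
    VARIABLE_UNITS,
    Quality,
    TrialRecord,
    UniformSeries,
)

__all__ = [
    "write_session",
    "read_trial_dir",
    "write_results",
    "read_results",
    "TrialReadError",
]

logger = logging.getLogger("divekin.io")

_CM_HEADER = "t[s],x[m],y[m],z[m]"
_GRF_HEADER = "t[s],fx[N],fy[N],fz[N]"

_META_COLUMNS = ("trial_id", "subject_id", "body_mass_kg", "rule", "side",
                 "iplag_score", "quality")


class TrialReadError(ValueError):
    """A trial directory or manifest entry could not be validated."""


def _write_series(path: Path, series: UniformSeries, header: str) -> None:
    data = np.column_stack([series.t, series.values])
    np.savetxt(path, data, delimiter=",", header=header, comments="",
               fmt="%.17g")


def _read_series(path: Path, header: str, rate: float, t0: float
                 ) -> UniformSeries:
    if not path.exists():
        raise TrialReadError(f"missing channel file: {path}")
    with open(path) as fh:
        first = fh.readline().strip()
    if first != header:
        raise TrialReadError(
            f"{path}: unit/column header mismatch: expected {header!r}, "
            f"got {first!r}"
        )
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.shape[1] != 4:
        raise TrialReadError(f"{path}: expected 4 columns, got {data.shape[1]}")
    t = data[:, 0]
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise TrialReadError(
                f"{path}: non-monotone time at row {i + 2}")
        if not np.allclose(dt, 1.0 / rate, rtol=1e-6, atol=1e-9):
            raise TrialReadError(
                f"{path}: sample spacing inconsistent with declared rate "
                f"{rate} Hz"
            )
    if abs(t[0] - t0) > 1e-9:
        raise TrialReadError(f"{path}: first timestamp {t[0]} != t0 {t0}")
    return UniformSeries(t0, rate, data[:, 1:4])


def write_session(trials: list[TrialRecord], out_dir: str | Path) -> Path:
    """Write a list of trials as a canonical trial directory.

    Ground truth rows (from ``record.meta['truth']``) are collected into
    ``truth.csv`` when every trial carries them.
    """
    out = Path(out_dir)
    (out / "trials").mkdir(parents=True, exist_ok=True)
    manifest = []
    truth_rows = []
    for rec in trials:
        tdir = out / "trials" / rec.trial_id
        tdir.mkdir(parents=True, exist_ok=True)
        entry = {
            "trial_id": rec.trial_id,
            "subject_id": rec.subject_id,
            "body_mass_kg": rec.body_mass_kg,
            "rule": rec.rule.value,
            "side": rec.side.value,
            "iplag_score": rec.iplag_score,
            "quality": rec.quality.value,
        }
        if rec.cm is not None:
            _write_series(tdir / "cm.csv", rec.cm, _CM_HEADER)
            entry["cm"] = {"path": f"trials/{rec.trial_id}/cm.csv",
                           "rate_hz": rec.cm.rate, "t0_s": rec.cm.t0}
        if rec.grf is not None:
            _write_series(tdir / "grf.csv", rec.grf, _GRF_HEADER)
            entry["grf"] = {"path": f"trials/{rec.trial_id}/grf.csv",
                            "rate_hz": rec.grf.rate, "t0_s": rec.grf.t0}
        manifest.append(entry)
        if "truth" in rec.meta:
            truth_rows.append({"trial_id": rec.trial_id, **rec.meta["truth"]})
    with open(out / "trials.json", "w") as fh:
        json.dump({"trials": manifest}, fh, indent=1)
    if truth_rows and len(truth_rows) == len(trials):
        pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False,
                                        float_format="%.17g")
    return out


def read_trial_dir(path: str | Path) -> list[TrialRecord]:
    """Read a canonical trial directory back into validated records.

    Malformed trials raise :class:`TrialReadError` naming the file; a
    missing manifest is an error.  Discarded trials are loaded (their
    channels too, if present) and keep their quality flag.
    """
    root = Path(path)
    manifest_path = root / "trials.json"
    if not manifest_path.exists():
        raise TrialReadError(f"no trials.json manifest in {root}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    truth = None
    truth_path = root / "truth.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path).set_index("trial_id")
    records = []
    for entry in manifest["trials"]:
        tid = entry.get("trial_id", "<missing id>")
        try:
            cm = grf = None
            if "cm" in entry:
                cm = _read_series(root / entry["cm"]["path"], _CM_HEADER,
                                  entry["cm"]["rate_hz"], entry["cm"]["t0_s"])
            if "grf" in entry:
                grf = _read_series(root / entry["grf"]["path"], _GRF_HEADER,
                                   entry["grf"]["rate_hz"],
                                   entry["grf"]["t0_s"])
            meta = {}
            if truth is not None and tid in truth.index:
                meta["truth"] = truth.loc[tid].to_dict()
            records.append(TrialRecord(
                trial_id=tid,
                subject_id=entry["subject_id"],
                body_mass_kg=entry["body_mass_kg"],
                rule=entry["rule"],
                side=entry["side"],
                iplag_score=entry["iplag_score"],
                quality=Quality(entry.get("quality", "ok")),
                cm=cm,
                grf=grf,
                meta=meta,
            ))
        except (KeyError, ValueError) as exc:
            raise TrialReadError(f"trial {tid!r}: {exc}") from exc
    return records


def _unit_comment(columns) -> str:
    units = []
    for c in columns:
        if c in VARIABLE_UNITS:
            units.append(f"{c}[{VARIABLE_UNITS[c]}]")
        elif c == "body_mass_kg":
            units.append("body_mass_kg[kg]")
    return "# units: " + " ".join(units)


def write_results(rows: pd.DataFrame, path: str | Path) -> Path:
    """Write a tidy per-trial results table (metadata + 14 variables).

    Stable column order; units documented in a ``#`` header comment;
    floats at full precision so the round trip is lossless.
    """
    path = Path(path)
    if len(rows.columns) == 0:
        rows = pd.DataFrame(columns=list(_META_COLUMNS) + list(VARIABLE_NAMES))
    cols = [c for c in _META_COLUMNS if c in rows.columns]
    cols += [c for c in VARIABLE_NAMES if c in rows.columns]
    cols += [c for c in rows.columns if c not in cols]
    df = rows[cols] if len(rows) else pd.DataFrame(columns=cols)
    with open(path, "w") as fh:
        fh.write(_unit_comment(cols) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results (or report) CSV written by :func:`write_results`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, comment="#")
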