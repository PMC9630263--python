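"""Grouping designs and paired statistical comparisons of the 14 outcomes.

Four paired designs are analyzed for every outcome variable:

* ``rule`` — old vs new rule, pooled over sides;
* ``laterality`` — dives toward the dominant (DLL) vs non-dominant (NDLL)
  lower-limb side, pooled over rules;
* ``rule_within_dominant`` / ``rule_within_nondominant`` — old vs new rule
  restricted to one relative side.

The pairing unit is the subject by default (condition means per subject);
``trial_matched`` pairs the k-th valid trial of each condition within a
subject instead, dropping the surplus.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .types import VARIABLE_NAMES, Side

__all__ = [
    "DESIGNS",
    "ComparisonResult",
    "classify_laterality",
    "assign_relative_side",
    "build_pairs",
    "shapiro_wilk",
    "paired_t_test",
    "cohens_d",
    "holm_adjust",
    "run_analysis",
]

logger = logging.getLogger("divekin.stats")

DESIGNS = ("rule", "laterality", "rule_within_dominant",
           "rule_within_nondominant")

# condition labels (a, b) per design, reported in this order
_CONDITIONS = {
    "rule": ("OR", "NR"),
    "laterality": ("DLL", "NDLL"),
    "rule_within_dominant": ("ORD", "NRD"),
    "rule_within_nondominant": ("ORND", "NRND"),
}


class UnclassifiableLateralityError(ValueError):
    """IPLAG score 3: ambidextrous / no preference."""


def classify_laterality(iplag_score: int) -> Side:
    """Map an IPLAG 1-5 score to a dominant lower-limb side.

    1-2 are left-footed, 4-5 right-footed; 3 (no preference) cannot be
    assigned a side and raises.
    """
    score = int(iplag_score)
    if score in (1, 2):
        return Side.LEFT
    if score in (4, 5):
        return Side.RIGHT
    if score == 3:
        raise UnclassifiableLateralityError(
            "IPLAG score 3 (ambidextrous/no preference) has no dominance side"
        )
    raise ValueError(f"IPLAG score must be in 1..5, got {iplag_score}")


def assign_relative_side(trial_side: Side | str, dominance: Side | str) -> str:
    """'DLL' if the dive goes toward the dominant side, else 'NDLL'."""
    return "DLL" if Side(trial_side) is Side(dominance) else "NDLL"


def _prepare(trials: pd.DataFrame) -> pd.DataFrame:
    df = trials.copy()
    n_total = len(df)
    discarded = df["quality"] != "ok"
    for tid in df.loc[discarded, "trial_id"]:
        logger.info("excluded trial=%s reason=quality_discarded", tid)
    df = df[~discarded]
    logger.info("trials: %d total, %d discarded, %d analyzed",
                n_total, int(discarded.sum()), len(df))
    df = df.assign(
        dominance=[classify_laterality(s).value for s in df["iplag_score"]],
    )
    df = df.assign(
        rel_side=[assign_relative_side(s, d)
                  for s, d in zip(df["side"], df["dominance"])],
    )
    return df


def _condition_masks(df: pd.DataFrame, design: str):
    if design == "rule":
        return df["rule"] == "old", df["rule"] == "new"
    if design == "laterality":
        return df["rel_side"] == "DLL", df["rel_side"] == "NDLL"
    if design == "rule_within_dominant":
        sub = df["rel_side"] == "DLL"
        return sub & (df["rule"] == "old"), sub & (df["rule"] == "new")
    if design == "rule_within_nondominant":
        sub = df["rel_side"] == "NDLL"
        return sub & (df["rule"] == "old"), sub & (df["rule"] == "new")
    raise ValueError(f"unknown design {design!r}")


def build_pairs(
    trials: pd.DataFrame,
    variable: str,
    design: str,
    pairing_mode: str = "subject_mean",
) -> tuple[np.ndarray, np.ndarray]:
    """Paired samples (a, b) for one variable under one design.

    ``trials`` is a tidy per-trial table (metadata + outcome columns);
    quality-discarded trials are excluded first.  ``subject_mean`` yields
    one pair of condition means per subject; ``trial_matched`` pairs the
    k-th valid trial of each condition within a subject, dropping and
    logging the surplus.
    """
    return _build_pairs_prepared(_prepare(trials), variable, design,
                                 pairing_mode)


def _build_pairs_prepared(
    df: pd.DataFrame,
    variable: str,
    design: str,
    pairing_mode: str = "subject_mean",
) -> tuple[np.ndarray, np.ndarray]:
    mask_a, mask_b = _condition_masks(df, design)
    a_parts, b_parts = [], []
    for subject, g in df.groupby("subject_id", sort=True):
        xa = g.loc[mask_a.reindex(g.index, fill_value=False), variable].values
        xb = g.loc[mask_b.reindex(g.index, fill_value=False), variable].values
        if len(xa) == 0 or len(xb) == 0:
            logger.info("excluded subject=%s design=%s reason=empty_condition",
                        subject, design)
            continue
        if pairing_mode == "subject_mean":
            a_parts.append(np.array([xa.mean()]))
            b_parts.append(np.array([xb.mean()]))
        elif pairing_mode == "trial_matched":
            k = min(len(xa), len(xb))
            dropped = len(xa) + len(xb) - 2 * k
            if dropped:
                logger.info(
                    "subject=%s design=%s dropped=%d surplus trials",
                    subject, design, dropped)
            a_parts.append(xa[:k])
            b_parts.append(xb[:k])
        else:
            raise ValueError(f"unknown pairing mode {pairing_mode!r}")
    if not a_parts:
        raise ValueError(f"no pairable units for design {design!r}")
    a = np.concatenate(a_parts)
    b = np.concatenate(b_parts)
    if len(a) < 2:
        raise ValueError(
            f"only {len(a)} pair(s) for design {design!r}; paired t-test "
            "needs at least 2"
        )
    return a, b


def shapiro_wilk(x: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p) for 3 <= n <= 5000."""
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    res = sstats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def paired_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired Student t-test on samples of equal length.

    Degenerate cases: all differences zero -> (0, 1); nonzero constant
    differences -> (signed inf, 0) with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, 1.0
        warnings.warn(
            "paired differences are a nonzero constant; t is infinite and "
            "p -> 0 by convention",
            stacklevel=2,
        )
        return float(np.sign(d.mean()) * np.inf), 0.0
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sstats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def cohens_d(a: np.ndarray, b: np.ndarray, method: str = "pooled") -> float:
    """Cohen's d effect size (absolute value).

    ``pooled``: |mean(a) - mean(b)| / pooled SD (the conventional
    0.2 / 0.5 / 0.8 ladder); ``paired_diff``: |mean(a - b)| / SD(a - b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Cohen's d needs at least 2 values per group")
    if method == "pooled":
        na, nb = len(a), len(b)
        s2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) \
            / (na + nb - 2)
        if s2 == 0:
            return 0.0 if a.mean() == b.mean() else float("inf")
        return float(abs(a.mean() - b.mean()) / np.sqrt(s2))
    if method == "paired_diff":
        if a.shape != b.shape:
            raise ValueError("paired_diff requires equal-length samples")
        d = a - b
        sd = d.std(ddof=1)
        if sd == 0:
            return 0.0 if d.mean() == 0 else float("inf")
        return float(abs(d.mean()) / sd)
    raise ValueError(f"unknown Cohen's d method {method!r}")


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


@dataclass
class ComparisonResult:
    variable: str
    design: str
    condition_a: str
    condition_b: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_pairs: int
    shapiro_p_a: float
    shapiro_p_b: float
    t: float
    p: float
    cohens_d: float
    significant: bool


def run_analysis(
    trials: pd.DataFrame,
    pairing_mode: str = "subject_mean",
    d_method: str = "pooled",
    alpha: float = 0.05,
    variables: tuple[str, ...] = VARIABLE_NAMES,
    designs: tuple[str, ...] = DESIGNS,
    normality_gate: bool = False,
) -> pd.DataFrame:
    """Full comparison table: every variable under every design.

    Returns a tidy DataFrame of ``len(variables) * len(designs)`` rows with
    group descriptives, Shapiro-Wilk p per group, paired t, p, Cohen's d, a
    significance flag at ``alpha``, and a Holm-adjusted p column (within
    each design family; provided for transparency, no correction is applied
    to the significance flag).
    """
    prepared = _prepare(trials)
    rows = []
    for design in designs:
        for variable in variables:
            a, b = _build_pairs_prepared(prepared, variable, design,
                                         pairing_mode)
            try:
                _, sp_a = shapiro_wilk(a)
                _, sp_b = shapiro_wilk(b)
            except ValueError:
                sp_a = sp_b = float("nan")
            t, p = paired_t_test(a, b)
            d = cohens_d(a, b, method=d_method)
            if normality_gate and (sp_a < alpha or sp_b < alpha):
                raise ValueError(
                    f"normality gate: Shapiro-Wilk p < {alpha} for "
                    f"{variable} under design {design!r}"
                )
            ca, cb = _CONDITIONS[design]
            rows.append(ComparisonResult(
                variable=variable, design=design,
                condition_a=ca, condition_b=cb,
                mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
                mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
                n_pairs=len(a),
                shapiro_p_a=sp_a, shapiro_p_b=sp_b,
                t=t, p=p, cohens_d=d,
                significant=bool(p <= alpha),
            ))
    report = pd.DataFrame([r.__dict__ for r in rows])
    report["p_holm"] = np.concatenate([
        holm_adjust(report.loc[report["design"] == dsg, "p"].values)
        for dsg in designs
    ])
    report.attrs["pairing_mode"] = pairing_mode
    report.attrs["d_method"] = d_method
    return report
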