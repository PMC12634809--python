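"""Rule-out triage and combined-pathway metrics.

Visits are split into *certain* cases, reported autonomously by the AI
(positive iff the ensemble mean reaches ``ai_threshold``), and *uncertain*
cases referred to the radiologist (positive iff PI-RADS >= 4). Triage is by
a UQ threshold or by a requested autonomous fraction; pathway metrics pool
the two readers' decisions over all visits. The calibrator finds the AI
operating threshold at which the combined pathway attains a non-inferior
specificity target (the radiologist's specificity minus a margin), choosing
the attainable point that maximizes sensitivity subject to the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError

__all__ = [
    "MEANUQ",
    "VARUQ",
    "TriageResult",
    "PathwayMetrics",
    "CalibrationResult",
    "certainty_key",
    "triage_by_threshold",
    "triage_by_fraction",
    "combined_diagnosis",
    "pathway_metrics",
    "calibrate_ai_threshold",
]

MEANUQ = "meanuq"
VARUQ = "varuq"
_METRIC_COLUMN = {MEANUQ: "mean_uq", VARUQ: "var_uq"}


def _normalize_metric(metric: str) -> str:
    m = str(metric).lower().replace("_", "")
    if m not in _METRIC_COLUMN:
        raise ConfigError(f"unknown UQ metric {metric!r}; expected 'meanuq' or 'varuq'")
    return m


def _uq_values(summaries, metric: str) -> np.ndarray:
    col = _METRIC_COLUMN[metric]
    if isinstance(summaries, pd.DataFrame):
        if col not in summaries.columns:
            raise ConfigError(f"summaries frame lacks column {col!r}; "
                              "run uq.add_uq_columns first")
        return summaries[col].to_numpy(dtype=float)
    return np.asarray(summaries, dtype=float)


def certainty_key(summaries, metric: str) -> np.ndarray:
    """Per-visit certainty on a common orientation: larger = more certain.

    This is the single comparator both metrics route through: meanUQ is
    certain when *high*, varUQ when *low*.
    """
    m = _normalize_metric(metric)
    values = _uq_values(summaries, m)
    return values if m == MEANUQ else -values


def triage_by_threshold(summaries, metric: str, tau: float) -> np.ndarray:
    """Certainty flags at a fixed UQ threshold.

    meanUQ: certain iff ``mean_uq >= tau``; varUQ: certain iff
    ``var_uq <= tau``.
    """
    if not math.isfinite(tau):
        # +/- inf are still meaningful boundaries; NaN is not
        if math.isnan(tau):
            raise DomainError("tau must not be NaN")
    m = _normalize_metric(metric)
    values = _uq_values(summaries, m)
    return values >= tau if m == MEANUQ else values <= tau


def triage_by_fraction(
    summaries, metric: str, fraction: float, visit_ids: Optional[Sequence] = None
) -> tuple[float, np.ndarray]:
    """Flag the ``floor(fraction * n)`` most certain visits.

    Visits are ranked most-to-least certain under the metric; ties at the
    cut are broken deterministically by ``visit_ids`` (or input position if
    not given). Returns ``(tau, flags)`` where ``tau`` is the implied UQ
    threshold: the UQ value of the least-certain flagged visit, or the
    empty-set sentinel (``+inf`` for meanUQ, ``-inf`` for varUQ) at
    fraction 0.
    """
    if not (0.0 <= fraction <= 1.0):
        raise DomainError(f"fraction must be in [0,1], got {fraction!r}")
    m = _normalize_metric(metric)
    values = _uq_values(summaries, m)
    n = values.size
    key = values if m == MEANUQ else -values
    if visit_ids is None:
        tiebreak = np.arange(n)
    else:
        tiebreak = np.asarray(visit_ids)
        if tiebreak.size != n:
            raise DomainError("visit_ids must align with summaries")
    # small epsilon guards floor against 0.3 * 10 -> 2.9999...
    k = int(math.floor(fraction * n + 1e-9))
    order = np.lexsort((tiebreak, -key))  # key desc, visit_id asc within ties
    flags = np.zeros(n, dtype=bool)
    flags[order[:k]] = True
    if k == 0:
        tau = math.inf if m == MEANUQ else -math.inf
    else:
        tau = float(values[order[k - 1]])
    return tau, flags


@dataclass(frozen=True)
class TriageResult:
    """Routing and final diagnosis for one visit."""

    visit_id: str
    certain: bool
    reader: str  # "AI" | "radiologist"
    diagnosis: int

    def __post_init__(self) -> None:
        if (self.reader == "AI") != self.certain:
            raise ConfigError("reader must be 'AI' exactly for certain cases")


def combined_diagnosis(
    frame: pd.DataFrame, flags: np.ndarray, ai_threshold: float
) -> pd.DataFrame:
    """Pathway decisions: AI reads certain visits (``mean_pred >=
    ai_threshold``), the radiologist reads the rest (``pirads >= 4``).

    Returns a frame with columns visit_id, certain, reader, diagnosis,
    aligned with the input.
    """
    flags = np.asarray(flags, dtype=bool)
    if flags.size != len(frame):
        raise DomainError("flags must align with records")
    for col in ("mean_pred", "pirads", "visit_id"):
        if col not in frame.columns:
            raise ConfigError(f"cohort frame lacks column {col!r}")
    ai_call = frame["mean_pred"].to_numpy(dtype=float) >= ai_threshold
    rad_call = frame["pirads"].to_numpy() >= 4
    return pd.DataFrame(
        {
            "visit_id": frame["visit_id"].to_numpy(),
            "certain": flags,
            "reader": np.where(flags, "AI", "radiologist"),
            "diagnosis": np.where(flags, ai_call, rad_call).astype(np.int64),
        }
    )


@dataclass(frozen=True)
class PathwayMetrics:
    """Confusion counts and rates of a (possibly mixed-reader) pathway.

    ``sensitivity``/``specificity`` are ``None`` when the corresponding
    denominator is empty — an undefined rate is reported as absent, never
    coerced to 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    n_certain: int
    n_total: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    workload_radiologist: float


def pathway_metrics(diagnosis, truth, flags=None) -> PathwayMetrics:
    """Confusion counts over all visits regardless of reader; workload is
    the fraction of visits the radiologist still reads."""
    if isinstance(diagnosis, pd.DataFrame):
        if flags is None and "certain" in diagnosis.columns:
            flags = diagnosis["certain"].to_numpy(dtype=bool)
        diagnosis = diagnosis["diagnosis"].to_numpy()
    diag = np.asarray(diagnosis).astype(int)
    truth = np.asarray(truth).astype(int)
    if diag.size == 0:
        raise DomainError("pathway_metrics requires at least one visit")
    if diag.size != truth.size:
        raise DomainError("diagnosis and truth must align")
    if flags is None:
        flags = np.zeros(diag.size, dtype=bool)
    flags = np.asarray(flags, dtype=bool)
    tp = int(np.sum((diag == 1) & (truth == 1)))
    fp = int(np.sum((diag == 1) & (truth == 0)))
    tn = int(np.sum((diag == 0) & (truth == 0)))
    fn = int(np.sum((diag == 0) & (truth == 1)))
    n = diag.size
    n_certain = int(flags.sum())
    return PathwayMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        n_certain=n_certain, n_total=n,
        sensitivity=tp / (tp + fn) if (tp + fn) > 0 else None,
        specificity=tn / (tn + fp) if (tn + fp) > 0 else None,
        workload_radiologist=1.0 - n_certain / n,
    )


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of AI-threshold calibration against a specificity target."""

    threshold: float
    attainable: bool
    achieved_specificity: float
    target_specificity: float


def _candidate_cuts(values: np.ndarray) -> np.ndarray:
    """Midpoints between sorted unique values, with -inf/+inf sentinels:
    every achievable decision set is visited exactly once."""
    u = np.unique(values)
    mids = (u[1:] + u[:-1]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def calibrate_ai_threshold(
    frame: pd.DataFrame, flags: np.ndarray, target_specificity: float
) -> CalibrationResult:
    """Smallest AI threshold at which the combined pathway's specificity
    reaches ``target_specificity``.

    Specificity is a non-decreasing step function of the threshold
    (uncertain negatives are fixed radiologist calls; certain negatives flip
    to true negatives as the threshold passes their ensemble mean), so the
    smallest attaining threshold also maximizes sensitivity subject to the
    target. When even an all-negative AI cannot reach the target the result
    is flagged unattainable and carries the maximum achievable specificity.
    """
    if not (0.0 < target_specificity < 1.0):
        raise DomainError(
            f"target_specificity must be in (0,1), got {target_specificity!r}"
        )
    flags = np.asarray(flags, dtype=bool)
    if flags.size != len(frame):
        raise DomainError("flags must align with records")
    truth = frame["truth"].to_numpy().astype(int)
    neg = truth == 0
    n_neg = int(neg.sum())
    if n_neg == 0:
        raise DomainError("calibration requires at least one negative case")
    pirads = frame["pirads"].to_numpy()
    tn_uncertain = int(np.sum(~flags & neg & (pirads < 4)))
    mean_pred = frame["mean_pred"].to_numpy(dtype=float)
    s = np.sort(mean_pred[flags & neg])
    if s.size == 0:
        # specificity is flat in the threshold; 0 maximizes sensitivity
        achieved = tn_uncertain / n_neg
        return CalibrationResult(0.0, achieved >= target_specificity,
                                 achieved, target_specificity)
    # Candidates over all certain scores, not just negatives: between two
    # negative-driven specificity steps, sensitivity still varies with the
    # certain positives, and the smallest attaining cut maximizes it.
    cuts = _candidate_cuts(mean_pred[flags])
    # AI negative call iff mean_pred < cut
    tn_certain = np.searchsorted(s, cuts, side="left")
    spec = (tn_uncertain + tn_certain) / n_neg
    ok = np.flatnonzero(spec >= target_specificity)
    if ok.size == 0:
        return CalibrationResult(math.inf, False, float(spec.max()),
                                 target_specificity)
    i = int(ok[0])
    return CalibrationResult(float(cuts[i]), True, float(spec[i]),
                             target_specificity)
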