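"""Ensemble aggregation and uncertainty-quantification (UQ) metrics.

Two patient-level UQ metrics are computed from the ensemble of submodel
likelihood scores:

* ``meanUQ = |mean(scores) - 0.5|`` — distance of the ensemble mean from the
  maximally ambiguous value 0.5. Higher values indicate a *more certain*
  diagnosis (either confidently benign or confidently malignant).
* ``varUQ = sd(scores)`` — the standard deviation across submodels
  (population divisor by default: the ensemble is the whole population of
  submodels, not a sample). Lower values indicate *more agreement*, hence a
  more certain diagnosis.

All threshold logic elsewhere routes through a single orientation-aware
comparator (see :mod:`uqtriage.triage`) so the opposing orientations of the
two metrics cannot be confused.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = ["EnsembleSummary", "ensemble_mean", "mean_uq", "var_uq",
           "summarize", "add_uq_columns"]


@dataclass(frozen=True)
class EnsembleSummary:
    """Ensemble mean and both UQ metrics for one visit."""

    mean_pred: float
    mean_uq: float
    var_uq: float


def _as_scores(scores) -> np.ndarray:
    arr = np.asarray(getattr(scores, "scores", scores), dtype=float)
    if arr.ndim != 1:
        raise DomainError("scores must be one-dimensional")
    if arr.size == 0:
        raise DomainError("scores must be non-empty")
    if np.any((arr < 0) | (arr > 1)) or np.any(~np.isfinite(arr)):
        raise DomainError("every score must be in [0,1]")
    return arr


def ensemble_mean(scores) -> float:
    """Arithmetic mean of the submodel scores — the final AI prediction."""
    return float(_as_scores(scores).mean())


def mean_uq(scores) -> float:
    """``|mean - 0.5|``; in [0, 0.5], larger = more certain."""
    return abs(ensemble_mean(scores) - 0.5)


def var_uq(scores, ddof: int = 0) -> float:
    """Standard deviation across submodels; smaller = more certain.

    ``ddof=0`` (population SD) by default; pass ``ddof=1`` for the sample
    convention.
    """
    arr = _as_scores(scores)
    if arr.size < 2:
        raise DomainError("var_uq requires at least 2 scores")
    if arr.max() == arr.min():
        return 0.0  # exact zero for constant ensembles, no float residue
    return float(arr.std(ddof=ddof))


def summarize(record, ddof: int = 0) -> EnsembleSummary:
    """Bundle mean prediction, meanUQ and varUQ for one record (a
    :class:`~uqtriage.cohort.PatientRecord` or a bare score sequence)."""
    arr = _as_scores(record)
    if arr.size < 2:
        raise DomainError("summarize requires at least 2 scores")
    m = float(arr.mean())
    sd = 0.0 if arr.max() == arr.min() else float(arr.std(ddof=ddof))
    return EnsembleSummary(m, abs(m - 0.5), sd)


def add_uq_columns(frame: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Return a copy of a cohort frame with ``mean_pred``, ``mean_uq`` and
    ``var_uq`` columns appended (vectorised over all visits)."""
    score_cols = [c for c in frame.columns if c.startswith("score_")]
    if len(score_cols) < 2:
        raise DomainError("cohort frame needs at least 2 score columns")
    scores = frame[score_cols].to_numpy(dtype=float)
    if scores.size and (np.any(scores < 0) or np.any(scores > 1)):
        raise DomainError("every score must be in [0,1]")
    out = frame.copy()
    m = scores.mean(axis=1)
    out["mean_pred"] = m
    out["mean_uq"] = np.abs(m - 0.5)
    sd = scores.std(axis=1, ddof=ddof) if len(out) else np.zeros(0)
    if len(out):
        constant = scores.max(axis=1) == scores.min(axis=1)
        sd = np.where(constant, 0.0, sd)
    out["var_uq"] = sd
    return out
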