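"""ROC machinery, Youden cut-point selection, the DeLong AUROC comparison
and the patient-level permutation test.

The DeLong test uses the structural-components estimator of the AUROC
variance/covariance (DeLong, DeLong & Clarke-Pearson 1988) with the
midrank-based O(n log n) computation; paired mode accounts for the
correlation induced by scoring the same cases, unpaired mode drops the
covariance term (and may compare different case sets).

The permutation test compares the sensitivity of two diagnosis sources on
the same cohort with the *patient* as the resampling unit: under the null
the two sources are exchangeable, so each patient's visits are swapped
between sources together with probability 1/2. The statistic is the
sensitivity difference; because sensitivities are ratios of integer counts
over a fixed positive set, null and observed statistics are compared on the
integer count scale, avoiding floating-point ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

from .errors import ConfigError, DomainError
from .triage import MEANUQ, _candidate_cuts, _normalize_metric, triage_by_threshold

__all__ = [
    "RocCurve",
    "TestResult",
    "auroc",
    "roc_points",
    "youden_threshold",
    "youden_uq_threshold",
    "delong_test",
    "permutation_sensitivity_test",
    "overlap_share",
]


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray  # descending
    sensitivities: np.ndarray
    specificities: np.ndarray
    auroc: float


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_resamples: Optional[int] = None


def _check_two_classes(truth: np.ndarray) -> None:
    if truth.min() == truth.max():
        raise DomainError("truth must contain both classes")


def _as_xy(scores, truth) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth).astype(int)
    if s.size != t.size or s.size == 0:
        raise DomainError("scores and truth must be non-empty and aligned")
    _check_two_classes(t)
    return s, t


def auroc(scores, truth) -> float:
    """AUROC as the Mann-Whitney concordance probability (ties get half
    credit)."""
    s, t = _as_xy(scores, truth)
    return float(roc_auc_score(t, s))


def roc_points(scores, truth) -> RocCurve:
    """Full ROC curve (thresholds descending) plus its area."""
    s, t = _as_xy(scores, truth)
    fpr, tpr, thr = _sk_roc_curve(t, s)
    return RocCurve(thresholds=thr, sensitivities=tpr,
                    specificities=1.0 - fpr, auroc=float(roc_auc_score(t, s)))


def youden_threshold(scores, truth) -> tuple[float, float]:
    """Cut maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are midpoints between sorted unique scores plus +/-inf
    sentinels (positive call iff score >= cut); ties in J are broken toward
    higher specificity, i.e. the larger cut.
    """
    s, t = _as_xy(scores, truth)
    pos = np.sort(s[t == 1])
    neg = np.sort(s[t == 0])
    cuts = _candidate_cuts(s)
    sens = 1.0 - np.searchsorted(pos, cuts, side="left") / pos.size
    spec = np.searchsorted(neg, cuts, side="left") / neg.size
    j = sens + spec - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    i = int(best[-1])  # largest cut among ties -> highest specificity
    return float(cuts[i]), float(j[i])


def youden_uq_threshold(frame: pd.DataFrame, metric: str) -> float:
    """Rule-out threshold for a UQ metric via Youden's index.

    Scans the observed UQ values as candidate rule-out thresholds; for each
    candidate, restricts the cohort to the certain subset and scores the AI
    there by the best Youden J of the ensemble mean on that subset. Returns
    the UQ threshold whose certain subset maximizes that J, requiring at
    least two cases of each class in the subset (so the subset's ROC
    statistics have estimable variance); ties prefer the larger certain
    subset (more rule-out at equal diagnostic quality).

    This is one concretization of selecting "the UQ threshold that maximizes
    csPCa detection at minimal false-positive cost"; the subset-J criterion
    is the package's design choice (see the methods note).
    """
    m = _normalize_metric(metric)
    col = "mean_uq" if m == MEANUQ else "var_uq"
    if col not in frame.columns or "mean_pred" not in frame.columns:
        raise ConfigError("frame lacks UQ columns; run uq.add_uq_columns first")
    truth = frame["truth"].to_numpy().astype(int)
    _check_two_classes(truth)
    uq = frame[col].to_numpy(dtype=float)
    mean_pred = frame["mean_pred"].to_numpy(dtype=float)
    best: tuple[float, int, float] | None = None  # (J, subset size, tau)
    for tau in np.unique(uq):
        flags = triage_by_threshold(uq, m, float(tau))
        sub_t = truth[flags]
        if sub_t.sum() < 2 or (sub_t.size - sub_t.sum()) < 2:
            continue
        _, j = youden_threshold(mean_pred[flags], sub_t)
        size = int(flags.sum())
        # strictly better J wins; near-ties prefer the larger certain subset
        if (best is None or j > best[0] + 1e-12
                or (j >= best[0] - 1e-12 and size > best[1])):
            best = (j, size, float(tau))
    if best is None:
        raise DomainError(
            "no candidate UQ threshold yields a two-class certain subset"
        )
    return best[2]


# ---------------------------------------------------------------------------
# DeLong


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (1-based), averaging over ties."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = x.size
    t = np.zeros(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n, dtype=float)
    out[order] = t
    return out


def _structural_components(scores: np.ndarray, truth: np.ndarray):
    """AUROC plus the per-case structural components V10 (positives) and
    V01 (negatives)."""
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise DomainError("DeLong components require both classes")
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return auc, v10, v01


def delong_variance(scores, truth) -> float:
    """Structural-components variance estimate of a single AUROC."""
    s, t = _as_xy(scores, truth)
    _, v10, v01 = _structural_components(s, t)
    if v10.size < 2 or v01.size < 2:
        raise DomainError("variance needs >= 2 cases per class")
    return float(np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size)


def delong_test(
    scores_a,
    scores_b,
    truth,
    paired: bool = True,
    truth_b=None,
    alternative: str = "two-sided",
) -> TestResult:
    """DeLong comparison of two AUROCs.

    Paired mode requires both score vectors on the identical case set
    (``truth``) and includes the structural-component covariance; unpaired
    mode treats the two samples as independent (``truth_b`` may give a
    different case set for ``scores_b``; defaults to ``truth``).
    """
    sa, ta = _as_xy(scores_a, truth)
    if paired:
        if truth_b is not None and not np.array_equal(
            np.asarray(truth_b).astype(int), ta
        ):
            raise DomainError("paired mode requires identical case sets")
        sb, tb = _as_xy(scores_b, truth)
        if sb.size != sa.size:
            raise DomainError("paired mode requires identical case sets")
    else:
        sb, tb = _as_xy(scores_b, truth if truth_b is None else truth_b)

    auc_a, v10_a, v01_a = _structural_components(sa, ta)
    auc_b, v10_b, v01_b = _structural_components(sb, tb)
    for v in (v10_a, v01_a, v10_b, v01_b):
        if v.size < 2:
            raise DomainError("DeLong test needs >= 2 cases per class")
    var_a = np.var(v10_a, ddof=1) / v10_a.size + np.var(v01_a, ddof=1) / v01_a.size
    var_b = np.var(v10_b, ddof=1) / v10_b.size + np.var(v01_b, ddof=1) / v01_b.size
    if paired:
        cov = (np.cov(v10_a, v10_b, ddof=1)[0, 1] / v10_a.size
               + np.cov(v01_a, v01_b, ddof=1)[0, 1] / v01_a.size)
    else:
        cov = 0.0
    diff = auc_a - auc_b
    sd = math.sqrt(max(var_a + var_b - 2.0 * cov, 0.0))
    if sd == 0.0:
        p = 1.0 if diff == 0.0 else 0.0
    else:
        z = diff / sd
        if alternative == "two-sided":
            p = 2.0 * norm.sf(abs(z))
        elif alternative == "greater":
            p = float(norm.sf(z))
        elif alternative == "less":
            p = float(norm.cdf(z))
        else:
            raise ConfigError(f"unknown alternative {alternative!r}")
    return TestResult(statistic=float(diff), p_value=float(min(p, 1.0)),
                      method="delong-paired" if paired else "delong-unpaired")


# ---------------------------------------------------------------------------
# permutation test


def permutation_sensitivity_test(
    pathway_diag,
    radiologist_diag,
    truth,
    patient_ids,
    n_perm: int = 10_000,
    seed=None,
    alternative: str = "greater",
) -> TestResult:
    """Permutation test of sensitivity(pathway) - sensitivity(radiologist)
    with the patient as the resampling unit.

    Each permutation swaps the two diagnosis sources for all of a patient's
    visits together with probability 1/2. The p-value uses the add-one
    estimator ``(1 + hits) / (1 + n_perm)``. Default alternative is
    one-sided ("greater": the pathway improves sensitivity); "two-sided"
    compares absolute statistics.
    """
    a = np.asarray(pathway_diag).astype(int)
    b = np.asarray(radiologist_diag).astype(int)
    t = np.asarray(truth).astype(int)
    pid = np.asarray(patient_ids)
    if not (a.size == b.size == t.size == pid.size):
        raise DomainError("all vectors must align")
    if n_perm < 1:
        raise DomainError("n_perm must be >= 1")
    if alternative not in ("greater", "two-sided"):
        raise ConfigError(f"unknown alternative {alternative!r}")
    pos = t == 1
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise DomainError("sensitivity undefined: no positive cases")

    # Per-patient net sensitivity contribution on the integer count scale.
    _, inv = np.unique(pid[pos], return_inverse=True)
    d = np.bincount(inv, weights=(a[pos] - b[pos])).astype(np.int64)
    obs = int(d.sum())

    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(int(n_perm), d.size)) * 2 - 1
    null = signs @ d
    if alternative == "greater":
        hits = int(np.sum(null >= obs))
    else:
        hits = int(np.sum(np.abs(null) >= abs(obs)))
    p = (1 + hits) / (1 + int(n_perm))
    return TestResult(statistic=obs / n_pos, p_value=float(p),
                      method=f"permutation-{alternative}",
                      n_resamples=int(n_perm))


def overlap_share(flags_var, flags_mean) -> float:
    """Share of varUQ-certain cases that are also meanUQ-certain."""
    fv = np.asarray(flags_var, dtype=bool)
    fm = np.asarray(flags_mean, dtype=bool)
    if fv.size != fm.size:
        raise DomainError("flag vectors must align")
    nv = int(fv.sum())
    if nv == 0:
        raise DomainError("no varUQ-certain cases; overlap share undefined")
    return float(np.sum(fv & fm) / nv)
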