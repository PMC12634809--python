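"""End-to-end experiment runners and report rendering.

Two experiments, both per center (thresholds, calibration and tests are
computed within center to respect institutional variation):

* Experiment 1 compares meanUQ and varUQ as rule-out criteria: Youden-based
  UQ thresholds, certain-case counts/percentages, AUROC of the ensemble
  mean on each certain subset, an unpaired DeLong comparison of the two
  subset AUROCs, and the share of varUQ-certain cases also meanUQ-certain.

* Experiment 2 sweeps the autonomous fraction in 10% increments for the
  chosen UQ metric, calibrates the AI threshold to a non-inferior
  specificity target (radiologist specificity minus a margin), and tests
  the combined pathway's sensitivity against the radiologist's with a
  patient-level permutation test.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats, triage, uq
from .errors import ConfigError, DomainError

__all__ = ["run_experiment1", "run_experiment2", "render_reports", "round_pct"]

log = logging.getLogger(__name__)

DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))
DEFAULT_MARGINS = (0.05, 0.10)


def round_pct(fraction: float) -> float:
    """Percentage reporting convention: 100x, round-half-even, 2 decimals."""
    return float(np.round(100.0 * fraction, 2))


def _prepared(cohort: pd.DataFrame, ddof: int) -> pd.DataFrame:
    if "mean_pred" in cohort.columns:
        return cohort
    return uq.add_uq_columns(cohort, ddof=ddof)


def run_experiment1(cohort: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Per center: rule-out efficacy of varUQ vs meanUQ.

    Centers whose cohort lacks one of the classes are skipped with a logged
    warning. Returns one row per (center, metric).
    """
    frame = _prepared(cohort, ddof)
    rows = []
    for center_id, sub in frame.groupby("center_id", sort=False):
        truth = sub["truth"].to_numpy().astype(int)
        if truth.min() == truth.max():
            log.warning("center %s skipped: single-class truth", center_id)
            continue
        n_center = len(sub)
        per_metric = {}
        for metric in (triage.VARUQ, triage.MEANUQ):
            tau = stats.youden_uq_threshold(sub, metric)
            flags = triage.triage_by_threshold(sub, metric, tau)
            per_metric[metric] = (tau, flags)
            log.info("center %s: %s rule-out threshold %.4g (%d certain)",
                     center_id, metric, tau, int(flags.sum()))
        mean_pred = sub["mean_pred"].to_numpy(dtype=float)
        flags_var = per_metric[triage.VARUQ][1]
        flags_mean = per_metric[triage.MEANUQ][1]
        try:
            delong_p = stats.delong_test(
                mean_pred[flags_var], mean_pred[flags_mean],
                truth[flags_var], paired=False, truth_b=truth[flags_mean],
            ).p_value
        except DomainError as exc:
            log.warning("center %s: DeLong comparison undefined (%s)",
                        center_id, exc)
            delong_p = float("nan")
        overlap = stats.overlap_share(flags_var, flags_mean)
        for metric in (triage.VARUQ, triage.MEANUQ):
            tau, flags = per_metric[metric]
            n_certain = int(flags.sum())
            rows.append(
                {
                    "center_id": center_id,
                    "metric": metric,
                    "tau": tau,
                    "n_certain": n_certain,
                    "pct_certain": round_pct(n_certain / n_center),
                    "auroc_certain": stats.auroc(mean_pred[flags], truth[flags]),
                    "delong_p": delong_p,
                    "overlap_pct": round_pct(overlap),
                }
            )
    if not rows:
        raise DomainError("no center had both classes present")
    return pd.DataFrame(rows)


def run_experiment2(
    cohort: pd.DataFrame,
    metric: str = triage.VARUQ,
    margins: Sequence[float] = DEFAULT_MARGINS,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    n_perm: int = 10_000,
    seed: int = 0,
    ddof: int = 0,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Workload-reduction sweep: per center x margin x autonomous fraction.

    Each row carries the calibrated AI threshold, the combined pathway's
    operating point and workload, and the permutation p-value of its
    sensitivity against the radiologist's (one-sided by default).
    """
    for m in margins:
        if not (0.0 < m < 1.0):
            raise ConfigError(f"margin must be in (0,1), got {m!r}")
    if list(fractions) != sorted(fractions):
        raise ConfigError("fractions must be sorted ascending")
    frame = _prepared(cohort, ddof)
    rows = []
    invocation = 0
    for center_id, sub in frame.groupby("center_id", sort=False):
        truth = sub["truth"].to_numpy().astype(int)
        if truth.min() == truth.max():
            log.warning("center %s skipped: single-class truth", center_id)
            continue
        pirads = sub["pirads"].to_numpy()
        rad_diag = (pirads >= 4).astype(int)
        rad = triage.pathway_metrics(rad_diag, truth)
        patient_ids = sub["patient_id"].to_numpy()
        visit_ids = sub["visit_id"].to_numpy()
        for margin in margins:
            target = rad.specificity - margin
            for fraction in fractions:
                tau, flags = triage.triage_by_fraction(
                    sub, metric, float(fraction), visit_ids=visit_ids
                )
                cal = triage.calibrate_ai_threshold(sub, flags, target)
                decisions = triage.combined_diagnosis(sub, flags, cal.threshold)
                pm = triage.pathway_metrics(decisions, truth)
                perm = stats.permutation_sensitivity_test(
                    decisions["diagnosis"].to_numpy(), rad_diag, truth,
                    patient_ids, n_perm=n_perm,
                    seed=np.random.SeedSequence([int(seed), invocation]),
                    alternative=alternative,
                )
                invocation += 1
                ruled_out_pirads = pirads[flags]
                p3_share = (
                    float(np.mean(ruled_out_pirads >= 3))
                    if ruled_out_pirads.size else np.nan
                )
                rows.append(
                    {
                        "center_id": center_id,
                        "metric": metric,
                        "fraction_ai": float(fraction),
                        "margin": float(margin),
                        "target_specificity": target,
                        "ai_threshold": cal.threshold,
                        "attainable": cal.attainable,
                        "achieved_specificity": pm.specificity,
                        "pathway_sensitivity": pm.sensitivity,
                        "pathway_specificity": pm.specificity,
                        "radiologist_sensitivity": rad.sensitivity,
                        "radiologist_specificity": rad.specificity,
                        "workload_radiologist": pm.workload_radiologist,
                        "n_certain": pm.n_certain,
                        "p_value": perm.p_value,
                        "pirads3plus_share_ruled_out": p3_share,
                    }
                )
    if not rows:
        raise DomainError("no center had both classes present")
    return pd.DataFrame(rows)


def render_reports(
    exp2_rows: pd.DataFrame,
    outdir: str | Path,
    exp1_rows: pd.DataFrame | None = None,
) -> list[Path]:
    """Write deterministic result tables and a per-center sensitivity-vs-
    autonomous-fraction plot with the radiologist reference line."""
    if exp2_rows is None or len(exp2_rows) == 0:
        raise DomainError("no rows to render")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(frame: pd.DataFrame, name: str) -> None:
        path = outdir / name
        frame.to_csv(path, index=False, float_format="%.6g")
        written.append(path)

    _write(exp2_rows.sort_values(
        ["center_id", "metric", "margin", "fraction_ai"]).reset_index(drop=True),
        "experiment2.csv")
    if exp1_rows is not None and len(exp1_rows):
        _write(exp1_rows.sort_values(
            ["center_id", "metric"]).reset_index(drop=True), "experiment1.csv")

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for center_id, sub in exp2_rows.groupby("center_id", sort=True):
        fig, ax = plt.subplots(figsize=(5.5, 4))
        for margin, msub in sub.groupby("margin", sort=True):
            msub = msub.sort_values("fraction_ai")
            ax.plot(msub["fraction_ai"] * 100, msub["pathway_sensitivity"],
                    marker="o", label=f"pathway (margin {margin:.2f})")
        rad_sens = float(sub["radiologist_sensitivity"].iloc[0])
        ax.axhline(rad_sens, ls="--", color="k", label="radiologist")
        ax.set_xlabel("autonomous AI readings (%)")
        ax.set_ylabel("sensitivity")
        ax.set_ylim(0, 1.02)
        ax.set_title(f"center {center_id}")
        ax.legend(loc="lower left", fontsize=8)
        fig.tight_layout()
        path = outdir / f"sensitivity_vs_fraction_{center_id}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written
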