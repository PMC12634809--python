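"""Synthetic multicenter cohort generation and cohort-file I/O.

The generator emulates a multicenter prostate-MRI cohort for clinically
significant prostate cancer (csPCa, Gleason Grade Group >= 2) detection.
Each visit carries a ground-truth label, a radiologist PI-RADS score (1-5,
with PI-RADS >= 4 being the radiologist's positive call during clinical
practice) and the patient-level likelihood scores of an ensemble of
independently trained AI submodels.

Score model
-----------
Each case draws a latent logit ``z = +/- ai_separation/2 + N(0, latent_sd)``
(sign by true class), and submodel ``k`` reports ``logistic(z + e_k)`` with
``e_k ~ N(0, sd)`` i.i.d. across submodels. The noise scale ``sd`` is one of
two regimes -- a concordant (certain) regime and a discordant (uncertain)
regime -- chosen per case with probability ``uncertain_mix``. This yields
ensembles whose standard deviation separates into a low-dispersion and a
high-dispersion population, the structure the rule-out thresholds act on,
while ``ai_separation`` controls the discriminative ability of the ensemble
mean.

PI-RADS model
-------------
A csPCa case is called positive (PI-RADS 4 or 5, uniform split) with
probability ``rad_sensitivity``; missed csPCa cases receive PI-RADS 3, the
only negative read consistent with a biopsy-confirmed positive (PI-RADS 1-2
cases are not biopsied and are negative by definition). A benign case is
called positive with probability ``1 - rad_specificity``; otherwise it is
PI-RADS 3 with probability ``pirads3_rate_neg`` and PI-RADS 1 or 2 (uniform)
otherwise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError, SchemaError

__all__ = [
    "CenterSpec",
    "CohortSpec",
    "PatientRecord",
    "score_columns",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "records_from_frame",
    "frame_from_records",
    "default_multicenter_spec",
]

#: Columns every cohort table must carry, ahead of the score columns.
BASE_COLUMNS = ("patient_id", "visit_id", "center_id", "truth", "pirads")


def score_columns(n_submodels: int) -> list[str]:
    """Names of the submodel-score columns: ``score_01 .. score_NN``."""
    return [f"score_{k:02d}" for k in range(1, n_submodels + 1)]


def _check_fraction(name: str, value: float, *, open_ends: bool = False) -> None:
    lo_ok = value > 0 if open_ends else value >= 0
    hi_ok = value < 1 if open_ends else value <= 1
    if not (lo_ok and hi_ok):
        kind = "(0,1)" if open_ends else "[0,1]"
        raise ConfigError(f"{name} must be in {kind}, got {value!r}")


@dataclass(frozen=True)
class CenterSpec:
    """Generator parameters for one center.

    Parameters
    ----------
    center_id
        Label, used in ids and as the RNG sub-stream key.
    n_visits
        Number of MRI visits to generate.
    prevalence
        Fraction of visits with csPCa (truth 1).
    rad_sensitivity, rad_specificity
        Radiologist operating point at the PI-RADS >= 4 cut, both strictly
        inside (0, 1).
    pirads3_rate_neg
        Probability that a radiologist-negative benign case reads PI-RADS 3
        (biopsied, benign) rather than PI-RADS 1-2 (not biopsied).
    ai_separation
        Distance between the class means of the latent logit; larger means a
        more discriminative ensemble.
    ensemble_sd_certain, ensemble_sd_uncertain
        Logit-scale submodel noise in the concordant / discordant regimes;
        the discordant scale must be at least the concordant one.
    uncertain_mix
        Probability a case is drawn from the discordant (high-dispersion)
        regime.
    latent_sd
        Scale of the shared per-case latent noise; with ``ai_separation = d``
        the latent AUROC is ``Phi(d / (latent_sd * sqrt(2)))``.
    repeat_visit_fraction
        Probability that a visit belongs to an already-seen patient of the
        same center (repeat visits, e.g. active surveillance).
    """

    center_id: str
    n_visits: int
    prevalence: float
    rad_sensitivity: float
    rad_specificity: float
    pirads3_rate_neg: float = 0.4
    ai_separation: float = 1.5
    ensemble_sd_certain: float = 0.15
    ensemble_sd_uncertain: float = 1.0
    uncertain_mix: float = 0.5
    latent_sd: float = 1.0
    repeat_visit_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_visits <= 0:
            raise ConfigError(f"n_visits must be positive, got {self.n_visits!r}")
        _check_fraction("prevalence", self.prevalence)
        _check_fraction("rad_sensitivity", self.rad_sensitivity, open_ends=True)
        _check_fraction("rad_specificity", self.rad_specificity, open_ends=True)
        _check_fraction("pirads3_rate_neg", self.pirads3_rate_neg)
        _check_fraction("uncertain_mix", self.uncertain_mix)
        _check_fraction("repeat_visit_fraction", self.repeat_visit_fraction)
        if self.ai_separation <= 0:
            raise ConfigError(f"ai_separation must be > 0, got {self.ai_separation!r}")
        if self.ensemble_sd_certain < 0:
            raise ConfigError("ensemble_sd_certain must be >= 0")
        if self.ensemble_sd_uncertain < self.ensemble_sd_certain:
            raise ConfigError(
                "ensemble_sd_uncertain must be >= ensemble_sd_certain, got "
                f"{self.ensemble_sd_uncertain!r} < {self.ensemble_sd_certain!r}"
            )
        if self.latent_sd < 0:
            raise ConfigError("latent_sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """A multicenter cohort: a list of :class:`CenterSpec` plus ensemble size
    and the single integer seed that drives all randomness."""

    centers: Sequence[CenterSpec]
    n_submodels: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.centers) == 0:
            raise ConfigError("centers must be non-empty")
        if self.n_submodels < 2:
            raise ConfigError(
                f"n_submodels must be >= 2 (ensemble SD is undefined for a "
                f"single submodel), got {self.n_submodels!r}"
            )


@dataclass(frozen=True)
class PatientRecord:
    """Row-level view of one MRI visit."""

    patient_id: str
    visit_id: str
    center_id: str
    truth: int
    pirads: int
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.truth not in (0, 1):
            raise ConfigError(f"truth must be 0 or 1, got {self.truth!r}")
        if self.pirads not in (1, 2, 3, 4, 5):
            raise ConfigError(f"pirads must be in 1..5, got {self.pirads!r}")
        if self.pirads <= 2 and self.truth == 1:
            raise ConfigError(
                "pirads <= 2 implies truth 0 (PI-RADS 1-2 cases are not biopsied)"
            )
        if any(not (0.0 <= s <= 1.0) for s in self.scores):
            raise ConfigError("every score must be in [0,1]")


def _center_rng(seed: int, center_id: str) -> np.random.Generator:
    # Sub-stream keyed by a CRC of the center label: reproducible per center
    # regardless of the order centers appear in the spec.
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(center_id.encode("utf-8"))])
    )


def _generate_center(center: CenterSpec, n_submodels: int, seed: int) -> pd.DataFrame:
    rng = _center_rng(seed, center.center_id)
    n = center.n_visits

    truth = (rng.random(n) < center.prevalence).astype(np.int64)

    # Latent case signal and two-regime ensemble noise on the logit scale.
    z = np.where(truth == 1, center.ai_separation / 2, -center.ai_separation / 2)
    z = z + rng.normal(0.0, center.latent_sd, size=n)
    uncertain = rng.random(n) < center.uncertain_mix
    sd = np.where(uncertain, center.ensemble_sd_uncertain, center.ensemble_sd_certain)
    noise = rng.standard_normal((n, n_submodels)) * sd[:, None]
    scores = expit(z[:, None] + noise)

    # Radiologist read at the PI-RADS >= 4 operating point.
    pirads = np.empty(n, dtype=np.int64)
    detected = rng.random(n) < center.rad_sensitivity
    called_pos = rng.random(n) < (1.0 - center.rad_specificity)
    is_p3_neg = rng.random(n) < center.pirads3_rate_neg
    hi = rng.integers(4, 6, size=n)  # uniform over {4, 5}
    lo = rng.integers(1, 3, size=n)  # uniform over {1, 2}
    pos = truth == 1
    pirads[pos] = np.where(detected[pos], hi[pos], 3)
    neg = ~pos
    pirads[neg] = np.where(called_pos[neg], hi[neg], np.where(is_p3_neg[neg], 3, lo[neg]))

    # Patient assignment with optional repeat visits.
    patient_ids: list[str] = []
    n_patients = 0
    repeat_draw = rng.random(n)
    for i in range(n):
        if i > 0 and repeat_draw[i] < center.repeat_visit_fraction:
            patient_ids.append(patient_ids[int(rng.integers(0, i))])
        else:
            n_patients += 1
            patient_ids.append(f"{center.center_id}_P{n_patients:05d}")

    frame = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "visit_id": [f"{center.center_id}_V{i + 1:05d}" for i in range(n)],
            "center_id": center.center_id,
            "truth": truth,
            "pirads": pirads,
        }
    )
    frame[score_columns(n_submodels)] = scores
    return frame


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a multicenter cohort table, deterministically given the seed.

    Returns a DataFrame with columns ``patient_id, visit_id, center_id,
    truth, pirads, score_01 .. score_NN`` and one row per visit, centers in
    spec order.
    """
    seen: set[str] = set()
    for center in spec.centers:
        if center.center_id in seen:
            raise ConfigError(f"duplicate center_id {center.center_id!r}")
        seen.add(center.center_id)
    parts = [_generate_center(c, spec.n_submodels, spec.seed) for c in spec.centers]
    return pd.concat(parts, ignore_index=True)


def default_multicenter_spec(seed: int = 0) -> CohortSpec:
    """Three-center cohort spec with the structure of a European multicenter
    csPCa detection study: 689, 723 and 200 visits; csPCa prevalence 25%,
    25% and 27.5%; radiologist sensitivity/specificity 83%/58%, 86%/54% and
    95%/78% at the PI-RADS >= 4 cut; repeat-visit rates matching 625, 571
    and 200 distinct patients respectively."""
    return CohortSpec(
        centers=(
            CenterSpec("A", 689, 0.25, 0.83, 0.58, repeat_visit_fraction=64 / 689),
            CenterSpec("B", 723, 0.25, 0.86, 0.54, repeat_visit_fraction=152 / 723),
            CenterSpec("C", 200, 0.275, 0.95, 0.78, repeat_visit_fraction=0.0),
        ),
        n_submodels=15,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# record <-> frame converters


def records_from_frame(frame: pd.DataFrame) -> list[PatientRecord]:
    cols = [c for c in frame.columns if c.startswith("score_")]
    return [
        PatientRecord(
            patient_id=str(row.patient_id),
            visit_id=str(row.visit_id),
            center_id=str(row.center_id),
            truth=int(row.truth),
            pirads=int(row.pirads),
            scores=tuple(float(getattr(row, c)) for c in cols),
        )
        for row in frame.itertuples(index=False)
    ]


def frame_from_records(records: Sequence[PatientRecord]) -> pd.DataFrame:
    if len(records) == 0:
        raise ConfigError("records must be non-empty; for empty cohorts build "
                          "an empty frame with score_columns()")
    n_scores = len(records[0].scores)
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "visit_id": r.visit_id,
            "center_id": r.center_id,
            "truth": r.truth,
            "pirads": r.pirads,
        }
        row.update(dict(zip(score_columns(n_scores), r.scores)))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file I/O (comma-separated text, header row, UTF-8, '.' decimal separator)


def write_cohort(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as CSV. ``read_cohort(write_cohort(x)) == x``
    field-for-field (floats round-trip through repr)."""
    _validate_frame(frame)
    frame.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV; schema violations raise
    :class:`SchemaError` naming the column or 1-based data row."""
    frame = pd.read_csv(path)
    if len(frame) == 0:
        # header-only file: normalise dtypes for round-trip equality
        frame = frame.astype(
            {c: (np.int64 if c in ("truth", "pirads") else
                 (np.float64 if c.startswith("score_") else object))
             for c in frame.columns}
        )
    _validate_frame(frame)
    return frame


def _validate_frame(frame: pd.DataFrame) -> None:
    for col in BASE_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"missing column {col!r}")
    score_cols = [c for c in frame.columns if c.startswith("score_")]
    if not score_cols:
        raise SchemaError("missing score columns (score_01 ...)")
    if len(frame) == 0:
        return

    def first_bad(mask: np.ndarray) -> int:
        return int(np.flatnonzero(mask)[0]) + 1  # 1-based data row

    truth = frame["truth"].to_numpy()
    bad = ~np.isin(truth, (0, 1))
    if bad.any():
        raise SchemaError(f"row {first_bad(bad)}: truth must be 0 or 1")
    pirads = frame["pirads"].to_numpy()
    bad = ~np.isin(pirads, (1, 2, 3, 4, 5))
    if bad.any():
        raise SchemaError(f"row {first_bad(bad)}: pirads must be in 1..5")
    bad = (pirads <= 2) & (truth == 1)
    if bad.any():
        raise SchemaError(
            f"row {first_bad(bad)}: pirads <= 2 implies truth 0"
        )
    for col in score_cols:
        s = frame[col].to_numpy(dtype=float)
        bad = ~((s >= 0.0) & (s <= 1.0))
        if bad.any():
            raise SchemaError(
                f"row {first_bad(bad)}: {col} outside [0,1]"
            )
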