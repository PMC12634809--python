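import numpy as np
import pandas as pd
import pytest

from uqtriage import CenterSpec, CohortSpec, add_uq_columns, generate_cohort


@pytest.fixture(scope="session")
def single_center_frame() -> pd.DataFrame:
    """One mid-sized center with UQ columns, shared read-only."""
    spec = CohortSpec(
        centers=(CenterSpec("X", 300, 0.3, 0.85, 0.6),), seed=42
    )
    return add_uq_columns(generate_cohort(spec))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_scored_cohort(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Minimal frame with mean_pred / pirads / truth for triage tests."""
    truth = rng.integers(0, 2, n)
    pirads = np.where(
        truth == 1,
        rng.choice([3, 4, 5], n),
        rng.choice([1, 2, 3, 4, 5], n),
    )
    return pd.DataFrame(
        {
            "visit_id": [f"V{i:03d}" for i in range(n)],
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "truth": truth,
            "pirads": pirads,
            "mean_pred": rng.random(n),
        }
    )
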