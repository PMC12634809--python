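"""ROC statistics, Youden selection, DeLong and the permutation test."""

import numpy as np
import pandas as pd
import pytest

from oracles import (
    auroc_pairwise,
    delong_components_naive,
    delong_variance_naive,
    youden_exhaustive,
)

from uqtriage import (
    CenterSpec,
    CohortSpec,
    DomainError,
    add_uq_columns,
    auroc,
    delong_test,
    generate_cohort,
    overlap_share,
    permutation_sensitivity_test,
    youden_threshold,
    youden_uq_threshold,
)
from uqtriage.stats import delong_variance, roc_points


def test_auroc_trivial_cases():
    truth = np.array([1, 1, 0, 0])
    assert auroc([0.9, 0.8, 0.2, 0.1], truth) == 1.0
    assert auroc([0.5] * 4, truth) == 0.5
    with pytest.raises(DomainError):
        auroc([0.1, 0.2], [1, 1])


def test_auroc_matches_pairwise_oracle(rng):
    scores = rng.choice(np.linspace(0, 1, 11), 20)  # ties likely
    truth = rng.integers(0, 2, 20)
    truth[:2] = [0, 1]
    assert auroc(scores, truth) == pytest.approx(
        auroc_pairwise(scores, truth), abs=1e-12
    )


def test_auroc_complement_symmetry(rng):
    scores = rng.random(50)  # tie-free almost surely
    truth = (rng.random(50) < 0.4).astype(int)
    truth[:2] = [0, 1]
    assert auroc(scores, truth) + auroc(-scores, truth) == pytest.approx(1.0)


def test_roc_points_consistency(rng):
    scores = rng.random(40)
    truth = rng.integers(0, 2, 40)
    truth[:2] = [0, 1]
    curve = roc_points(scores, truth)
    assert curve.auroc == pytest.approx(auroc(scores, truth))
    assert np.all(np.diff(curve.sensitivities) >= 0)
    assert np.all(np.diff(curve.thresholds) <= 0)


def test_youden_separable_and_degenerate():
    truth = np.array([0, 0, 1, 1])
    tau, j = youden_threshold([0.1, 0.2, 0.8, 0.9], truth)
    assert j == 1.0 and tau == pytest.approx(0.5)
    _, j = youden_threshold([0.4] * 4, truth)
    assert j == 0.0


@pytest.mark.parametrize("trial", range(5))
def test_youden_matches_exhaustive_scan(trial):
    rng = np.random.default_rng(900 + trial)
    scores = rng.choice(np.linspace(0, 1, 15), 30)
    truth = rng.integers(0, 2, 30)
    truth[:2] = [0, 1]
    tau, j = youden_threshold(scores, truth)
    o_tau, o_j = youden_exhaustive(scores, truth)
    assert j == pytest.approx(o_j, abs=1e-12)
    assert tau == pytest.approx(o_tau)


def test_youden_invariant_under_monotone_transform(rng):
    scores = rng.random(40)
    truth = rng.integers(0, 2, 40)
    truth[:2] = [0, 1]
    _, j = youden_threshold(scores, truth)
    for f in (lambda s: 2 * s + 1, np.exp, lambda s: s**3):
        _, jt = youden_threshold(f(scores), truth)
        assert jt == pytest.approx(j, abs=1e-12)


def test_youden_uq_threshold_zero_noise_all_certain():
    spec = CohortSpec(
        centers=(CenterSpec("Z", 80, 0.3, 0.8, 0.6,
                            ensemble_sd_certain=0.0,
                            ensemble_sd_uncertain=0.0),),
        seed=5,
    )
    frame = add_uq_columns(generate_cohort(spec))
    tau = youden_uq_threshold(frame, "varuq")
    assert tau == 0.0  # all varUQ zero: everything certain at threshold 0


def test_youden_uq_threshold_excludes_noise_block(rng):
    # low-dispersion block: separable; high-dispersion block: random truth
    n = 60
    mean_pred = np.concatenate([
        np.where(np.arange(n // 2) % 2 == 0, 0.9, 0.1),
        rng.random(n // 2),
    ])
    truth = np.concatenate([
        (np.arange(n // 2) % 2 == 0).astype(int),
        rng.integers(0, 2, n // 2),
    ])
    var_uq = np.concatenate([
        rng.uniform(0.01, 0.05, n // 2), rng.uniform(0.2, 0.4, n // 2)
    ])
    frame = pd.DataFrame(
        {"truth": truth, "mean_pred": mean_pred, "var_uq": var_uq,
         "mean_uq": np.abs(mean_pred - 0.5)}
    )
    tau = youden_uq_threshold(frame, "varuq")
    assert tau < 0.2  # the high-dispersion block is excluded
    # exhaustive check: no observed threshold achieves a higher subset J
    best_j = -1.0
    for cand in np.unique(var_uq):
        sub = frame[frame.var_uq <= cand]
        if sub.truth.nunique() == 2:
            best_j = max(best_j, youden_threshold(sub.mean_pred, sub.truth)[1])
    sub = frame[frame.var_uq <= tau]
    assert youden_threshold(sub.mean_pred, sub.truth)[1] == pytest.approx(best_j)


def test_youden_uq_threshold_meanuq_isolates_extreme_modes(rng):
    n = 40
    mean_pred = np.concatenate([
        rng.uniform(0.0, 0.1, 10), rng.uniform(0.9, 1.0, 10),
        rng.uniform(0.45, 0.55, 20),
    ])
    truth = np.concatenate([
        np.zeros(10, int), np.ones(10, int), rng.integers(0, 2, 20)
    ])
    frame = pd.DataFrame(
        {"truth": truth, "mean_pred": mean_pred,
         "mean_uq": np.abs(mean_pred - 0.5), "var_uq": 0.1}
    )
    tau = youden_uq_threshold(frame, "meanuq")
    flagged = frame[frame.mean_uq >= tau]
    assert set(flagged.index) >= set(range(20))  # both extreme modes kept
    # exhaustive scan: the chosen subset attains the maximal subset J
    j_at = {}
    for cand in np.unique(frame.mean_uq):
        sub = frame[frame.mean_uq >= cand]
        if sub.truth.sum() >= 2 and (1 - sub.truth).sum() >= 2:
            j_at[cand] = youden_threshold(sub.mean_pred, sub.truth)[1]
    assert j_at[tau] == pytest.approx(max(j_at.values()), abs=1e-12)


# ---------------------------------------------------------------------------
# DeLong


def test_delong_identical_scores_p_one(rng):
    scores = rng.random(30)
    truth = rng.integers(0, 2, 30)
    truth[:2] = [0, 1]
    res = delong_test(scores, scores, truth, paired=True)
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_delong_variance_matches_naive_oracle(rng):
    scores = rng.choice(np.linspace(0, 1, 9), 20)
    truth = rng.integers(0, 2, 20)
    truth[:2] = [0, 1]
    assert delong_variance(scores, truth) == pytest.approx(
        delong_variance_naive(scores, truth), abs=1e-10
    )


def test_delong_components_match_naive_oracle(rng):
    scores = rng.random(25)
    truth = rng.integers(0, 2, 25)
    truth[:2] = [0, 1]
    from uqtriage.stats import _structural_components

    auc, v10, v01 = _structural_components(scores, truth)
    o_auc, o_v10, o_v01 = delong_components_naive(scores, truth)
    assert auc == pytest.approx(o_auc, abs=1e-12)
    np.testing.assert_allclose(np.sort(v10), np.sort(o_v10), atol=1e-10)
    np.testing.assert_allclose(np.sort(v01), np.sort(o_v01), atol=1e-10)


def test_delong_variance_shrinks_as_one_over_n():
    rng = np.random.default_rng(77)
    reps = 200
    ratios = []
    for _ in range(reps):
        small = _sample_scores(rng, 50)
        big = _sample_scores(rng, 200)
        ratios.append(delong_variance(*small) / delong_variance(*big))
    assert abs(np.mean(ratios) / 4.0 - 1.0) < 0.3


def _sample_scores(rng, n):
    truth = np.zeros(n, int)
    truth[: n // 2] = 1
    scores = rng.normal(truth * 0.8, 1.0)
    return scores, truth


def test_delong_paired_mismatch_rejected(rng):
    scores = rng.random(10)
    truth = np.array([0, 1] * 5)
    with pytest.raises(DomainError):
        delong_test(scores, rng.random(8), truth, paired=True)


def test_delong_unpaired_allows_different_case_sets(rng):
    sa, ta = _sample_scores(rng, 40)
    sb, tb = _sample_scores(rng, 30)
    res = delong_test(sa, sb, ta, paired=False, truth_b=tb)
    assert 0.0 <= res.p_value <= 1.0
    assert res.method == "delong-unpaired"


# ---------------------------------------------------------------------------
# permutation test


def _simple_cohort(n_pos=30, n_neg=30):
    truth = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
    pids = np.array([f"P{i}" for i in range(truth.size)])
    return truth, pids


def test_permutation_identical_sources_p_one(rng):
    truth, pids = _simple_cohort()
    diag = rng.integers(0, 2, truth.size)
    res = permutation_sensitivity_test(diag, diag, truth, pids, n_perm=200, seed=1)
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_permutation_detects_flipped_false_negatives():
    truth, pids = _simple_cohort(n_pos=60)
    rad = truth.copy()
    rad[:10] = 0  # 10 radiologist false negatives
    pathway = truth.copy()  # pathway recovers them
    res = permutation_sensitivity_test(
        pathway, rad, truth, pids, n_perm=10_000, seed=2
    )
    assert res.statistic == pytest.approx(10 / 60)
    assert res.p_value < 0.05


def test_permutation_patient_is_resampling_unit():
    # both visits of each patient move together: with 2 patients carrying
    # all the signal the null has only 4 equally likely sign patterns
    truth = np.ones(4, int)
    pids = np.array(["P1", "P1", "P2", "P2"])
    pathway = np.array([1, 1, 1, 1])
    rad = np.array([0, 0, 0, 0])
    res = permutation_sensitivity_test(pathway, rad, truth, pids,
                                       n_perm=4000, seed=3)
    # P(null >= obs) = P(both patients keep sign +1) = 1/4
    assert res.p_value == pytest.approx(0.25, abs=0.03)


def test_permutation_requires_positives():
    with pytest.raises(DomainError):
        permutation_sensitivity_test(
            [0, 1], [0, 0], [0, 0], ["a", "b"], n_perm=10
        )


def test_overlap_share_examples():
    assert overlap_share([True, True], [True, True]) == 1.0
    assert overlap_share([True, False], [False, True]) == 0.0
    flags_var = np.zeros(689, bool)
    flags_var[:224] = True
    flags_mean = np.zeros(689, bool)
    flags_mean[:207] = True
    flags_mean[300:500] = True
    assert overlap_share(flags_var, flags_mean) == pytest.approx(207 / 224)
    with pytest.raises(DomainError):
        overlap_share([False, False], [True, True])
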