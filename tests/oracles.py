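"""Independent brute-force oracles used by unit and acceptance tests.

These are deliberately naive re-implementations (O(n^2) loops, exhaustive
scans) kept separate from the library code paths they check.
"""

import numpy as np

from uqtriage.triage import combined_diagnosis, pathway_metrics


def auroc_pairwise(scores, truth):
    """Mann-Whitney concordance by explicit pos x neg comparison."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (pos.size * neg.size)


def candidate_cuts(values):
    u = np.unique(np.asarray(values, dtype=float))
    return np.concatenate(([-np.inf], (u[1:] + u[:-1]) / 2.0, [np.inf]))


def youden_exhaustive(scores, truth):
    """Grid scan over all candidate cut points; ties -> larger cut."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    cuts = candidate_cuts(scores)
    js = []
    for cut in cuts:
        call = scores >= cut
        tp = np.sum(call & (truth == 1))
        fn = np.sum(~call & (truth == 1))
        tn = np.sum(~call & (truth == 0))
        fp = np.sum(call & (truth == 0))
        js.append(tp / (tp + fn) + tn / (tn + fp) - 1.0)
    js = np.asarray(js)
    tied = np.flatnonzero(js >= js.max() - 1e-12)
    i = tied[-1]  # cuts ascend, so the last tie is the largest cut
    return float(cuts[i]), float(js[i])


def delong_components_naive(scores, truth):
    """Structural components by explicit double loops."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    pos = scores[truth == 1]
    neg = scores[truth == 0]

    def psi(x, y):
        return 1.0 if x > y else (0.5 if x == y else 0.0)

    v10 = np.array([np.mean([psi(x, y) for y in neg]) for x in pos])
    v01 = np.array([np.mean([psi(x, y) for x in pos]) for y in neg])
    auc = v10.mean()
    return auc, v10, v01


def delong_variance_naive(scores, truth):
    _, v10, v01 = delong_components_naive(scores, truth)
    return np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size


def calibrate_exhaustive(frame, flags, target):
    """Scan every candidate AI threshold (midpoints of mean_pred plus
    sentinels); return (threshold, achieved_spec, sensitivity) of the
    smallest threshold whose combined-pathway specificity reaches the
    target, or None if unattainable."""
    for thr in candidate_cuts(frame["mean_pred"]):
        decisions = combined_diagnosis(frame, flags, thr)
        pm = pathway_metrics(decisions, frame["truth"].to_numpy())
        if pm.specificity is not None and pm.specificity >= target:
            return thr, pm.specificity, pm.sensitivity
    return None
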