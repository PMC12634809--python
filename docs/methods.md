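# Methods

## Pathway model

One MRI visit carries a biopsy-backed truth label (csPCa = Gleason Grade
Group ≥ 2), a radiologist PI-RADS score, and K submodel likelihoods from a
deep ensemble. The final AI prediction is the ensemble mean `p̄`; two
uncertainty metrics order visits by confidence:

- `meanUQ = |p̄ − 0.5|`, in [0, 0.5], **higher = more certain**;
- `varUQ = sd(scores)`, **lower = more certain**. The standard deviation
  uses the population divisor (ddof = 0) by default — the K submodels are
  the entire ensemble, not a sample from one — and every function accepts
  `ddof=1` for the sample convention; the choice only rescales varUQ by
  `sqrt(K/(K−1))` and cannot change any rank-based triage decision.

Both orientations route through a single comparator
(`triage.certainty_key`), so threshold logic is written once.

The rule-out pathway reads *certain* visits autonomously (positive iff
`p̄ ≥ τ_AI`) and refers *uncertain* visits to the radiologist (positive iff
PI-RADS ≥ 4). Pathway sensitivity/specificity pool both readers' decisions
over all visits; radiologist workload is the uncertain fraction. Rates with
an empty denominator are reported as absent (`None`/`NaN`), never coerced
to 0, and such strata are excluded from test statistics.

## Triage and calibration

- **By threshold:** meanUQ certain iff `mean_uq ≥ τ`; varUQ certain iff
  `var_uq ≤ τ`.
- **By fraction f:** the `⌊f·n⌋` most certain visits are flagged (never
  exceeding the requested autonomous share); ties at the cut break by
  visit id (stable, platform-independent). The implied threshold returned
  is the UQ value of the least certain flagged visit.
- **Operating-point calibration:** the AI threshold is chosen as the
  smallest value at which the *combined* pathway specificity reaches the
  target (radiologist specificity minus the margin). Combined specificity
  is a non-decreasing step function of the threshold, so the smallest
  attaining threshold maximizes sensitivity subject to the target.
  Candidate thresholds are midpoints between sorted unique certain-case
  ensemble means plus ±∞ sentinels — all certain cases, not only certain
  negatives, because sensitivity still varies with the certain positives
  between two specificity steps. An unattainable target is reported as such
  together with the maximum achievable specificity, never silently clamped.

## Rule-out threshold selection (Youden)

For a plain score classifier, `youden_threshold` scans midpoints of sorted
unique scores with ±∞ sentinels (every confusion table visited exactly
once) and maximizes J = sensitivity + specificity − 1, breaking ties toward
higher specificity.

Selecting a *UQ* threshold needs a concretization, because a UQ cut defines
a subset, not a classifier: for each observed UQ value as candidate
threshold, the cohort is restricted to the resulting certain subset and the
ensemble mean is scored there by its best Youden J. The returned UQ
threshold maximizes that subset J; ties prefer the larger certain subset
(more rule-out at equal quality). Candidate subsets must contain at least
two cases of each class — with fewer, the subset AUROC has no estimable
variance and downstream DeLong comparisons are undefined. This subset-J
criterion is one defensible reading of "maximize detection at minimal
false-positive cost" and is deliberately isolated in a single function
(`stats.youden_uq_threshold`) so alternative strategies can be swapped in.

## Inference

- **DeLong test** for AUROC differences, implemented with the
  structural-components variance/covariance estimator and midrank-based
  O(n log n) computation; two-sided normal reference by default. Paired
  mode requires identical case sets and includes the covariance; unpaired
  mode zeroes it and admits different case sets. The experiment-1 runner
  compares the varUQ-certain and meanUQ-certain subsets, which generally
  differ, and therefore uses unpaired mode, logging both subset sizes and
  their overlap.
- **Permutation test** for pathway-vs-radiologist sensitivity with the
  patient as the resampling unit: per permutation, each patient's visits
  swap diagnosis source together with probability 1/2. Because sensitivity
  differences are integer counts over a fixed positive set, observed and
  null statistics are compared exactly on the count scale. The p-value uses
  the add-one estimator `(1 + hits)/(1 + n_perm)`, which cannot return 0.
  Default sidedness is one-sided ("greater"): the scientific claim is
  *superior* sensitivity at a non-inferior specificity; two-sided is
  available by flag. Permutation streams are seeded from the top-level seed
  plus an invocation counter, so every reported p-value is reproducible.
- No multiple-testing correction is applied across centers, margins or
  fractions; rows are reported per stratum and should be read as such.

## Synthetic cohort generator

The generator emulates a three-center cohort (689/723/200 visits; csPCa
prevalence 25/25/27.5%; radiologist sensitivity/specificity 83/58, 86/54,
95/78 at the PI-RADS ≥ 4 cut; repeat-visit rates giving 625/571/200
distinct patients) via `default_multicenter_spec`; all parameters are
per-center and overridable.

Score model: per case, a latent logit `z = ±ai_separation/2 +
N(0, latent_sd)` (sign by class), and submodel scores
`logistic(z + e_k)` with `e_k ~ N(0, sd_regime)` i.i.d. The noise regime is
a two-point mixture — concordant (`ensemble_sd_certain`, default 0.15) vs
discordant (`ensemble_sd_uncertain`, default 1.0), mixed with probability
`uncertain_mix` (default 0.5) — which directly produces the
certain/uncertain dichotomy the rule-out thresholds act on. Defaults:
`ai_separation = 1.5` with `latent_sd = 1.0` puts the latent AUROC at
`Φ(1.5/√2) ≈ 0.86`, a realistic figure for a strong csPCa detector on
external data. The real distribution of submodel disagreement is unknown;
this logit-normal mixture is a stand-in chosen for controllability, not a
fitted model.

PI-RADS model: detected csPCa cases read 4 or 5 (uniform); missed csPCa
cases read PI-RADS 3 — the only negative read consistent with a
biopsy-confirmed positive, since PI-RADS 1–2 cases are not biopsied and are
negative by definition. False-positive benign cases read 4 or 5 (uniform);
the rest read 3 with probability `pirads3_rate_neg` (default 0.4) or 1–2
(uniform). The 4/5 and 1/2 splits are uniform because no downstream
computation distinguishes within those bins.

Randomness: one integer seed; each center draws from a sub-stream keyed by
a CRC of its center id, so center-level output is reproducible regardless
of center order. Identical spec + seed gives byte-identical cohort files.

**What passing tests on synthetic cohorts do not show:** the generator has
no image-quality, scanner, age/PSA or lesion-size structure; submodel
errors are exchangeable given the regime (real ensembles share training
data and correlate in structured ways); the uncertain regime keeps the same
class signal as the certain regime rather than degrading it; and
radiologist errors are independent of AI errors, which inflates the
apparent headroom of the pathway. Results on synthetic cohorts validate the
*machinery* — thresholding, calibration, inference — not clinical
performance, and clinical AUROCs or workload numbers from any real study
are not expected to be reproduced.

## Numerical choices

- Constant ensembles return varUQ exactly 0 (the floating-point residue of
  `std` on a constant vector is snapped), making `varUQ = 0 iff all scores
  equal` exact.
- `⌊f·n⌋` is computed with a 1e-9 guard against binary-fraction artifacts
  (`0.3 × 10 = 2.999…`).
- Percentages in result tables use round-half-even to 2 decimals,
  a single fixed convention so table equality is testable.
- Youden tie-break: among equal-J cuts the largest cut (highest
  specificity) wins; J comparisons use a 1e-12 tolerance.
- Degenerate inputs fail loudly: single-class truth, empty score lists,
  misaligned vectors and unknown metric names raise typed errors
  (`DomainError`, `ConfigError`, `SchemaError`) rather than returning
  defaults; centers with single-class truth are skipped with a logged
  warning by the experiment runners.

## Problem sizes

The test suite and the acceptance script run the full pipeline on the
default 1612-visit cohort with 10 000 permutations, the statistical
calibration suites at 500 replicate null cohorts (n = 200, 999
permutations) and 1000 equal-AUROC replicates (n = 150 per arm), and
parameter recovery at n = 5000 — sizes at which binomial/permutation noise
is well inside the asserted bands while the whole suite stays fast.
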