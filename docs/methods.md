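# Methods

This note documents the statistical model behind `woerisk`, its tunable
parameters and defaults, what the synthetic cohort generator does and does
not emulate, the numerical choices, and the known limitations.

## Model

For a subject with variables `x = (x1, …, xP)` and binary outcome `Y`
(1 = musculoskeletal injury within a year of return to participation), the
risk model estimates the log-odds

    log P(Y=1|x) / P(Y=0|x)  ≈  w0 + Σi wi · WoEi(xi)

and converts it to a probability through the logistic function. `WoEi` is
the Weight-of-Evidence coding of variable i: a step function assigning each
bin of the variable's range (or each group of category levels, or the
missing state) the natural-log ratio of class-conditional bin frequencies
estimated on the training set,

    WoE_bin = ln[ (n_event_bin + s) / (N_event + s·B)
                ÷ (n_nonevent_bin + s) / (N_nonevent + s·B) ],

with pseudo-count `s` per class per bin and `B` the number of bins in the
scheme. Positive WoE is evidence for injury. Setting every `wi = 1` and
`w0` to the log prior odds makes the score exactly the naive Bayes log
posterior odds of the binned data (the independent-evidence limit); the
fitted weights temper that assumption, and this equivalence is verified in
the tests by direct counting.

### Binning

Continuous variables are pre-binned into at most `pre_bins` quantile cells
and then merged into contiguous bins by exact dynamic programming that
maximizes the scheme's Information Value,

    IV = Σ_bins (p_event_bin − p_nonevent_bin) · WoE_bin

(smoothed proportions throughout), subject to a minimum bin occupancy and a
maximum bin count. Because the smoothing denominators depend on the total
number of bins B, the DP is run once per candidate bin count and the best
total wins, so the optimum is exact, not greedy — the tests verify it
against exhaustive enumeration of all contiguous partitions. Categorical
(and binary) variables are ordered by event rate and grouped by the same
DP; restricting groups to be contiguous in that ordering keeps the search
exact while avoiding the exponential cost of unordered set partitions.
Missing values always form their own bin when present in training, which is
how the model "imputes": a missing entry simply contributes that bin's
evidence. WoE monotonicity across bins is intentionally not enforced —
threshold-shaped risk (e.g. elevated risk only below a short recovery time)
is precisely what the method should be free to represent.

Binning parameters (defaults): `min_bin_fraction` 0.05 of the non-missing
training sample per bin, `max_bins` 10, `pre_bins` 20, `smoothing` 0.5
pseudo-counts per class per bin. The smoothing keeps WoE finite in
single-class bins; 0.5 (a Jeffreys-style half count) is small enough to be
negligible in occupied bins.

### Selection and refit

The L1 path minimizes mean logistic loss + λ‖w‖₁ (intercept unpenalized)
over 100 log-spaced penalties from the analytic null threshold
`λ_max = max_j |x_jᵀ(y − ȳ)|/n` down to `10⁻⁴·λ_max`, with warm starts;
coefficients below `10⁻⁸` snap to exactly zero. Each path point is scored
by the corrected Akaike Information Criterion

    AICc = 2·NLL + 2k + 2k(k+1)/(n − k − 1),

and the minimizer (ties: fewer variables, then the larger penalty) defines
the selected support, which is refit with an L2 penalty of strength 1.0
(objective: total logistic loss + ½‖w‖², mild on the log-odds scale of WoE
features; configurable).

**Complexity accounting.** The conventional lasso-IC choice is
`k = nonzero coefficients + 1`. For WoE features that accounting is
systematically too generous: each selected variable's coding is itself a
step function whose ~`B` levels were estimated from the same training
labels, so a selected variable consumes roughly `B` degrees of freedom, not
one. On synthetic cohorts with known ground truth the conventional
accounting retains nearly every variable — a spurious WoE column at
n = 2000 carries enough manufactured in-sample evidence (IV ≈ 0.03,
deviance drop ≈ 11) to beat a penalty of 2 — and the resulting model's
held-out AUC falls ~0.07–0.09 below the generator's Bayes ceiling. The
default is therefore `complexity="effective"`: `k = 1 + Σ_support B_v`.
Under it the same cohorts yield compact supports (the planted informative
variables plus Sport), and held-out AUC within ~0.03–0.045 of the ceiling.
`complexity="support"` restores the conventional accounting; note that with
small samples (n in the low hundreds) the AICc correction term itself
bounds model size under either accounting, which is the regime where the
conventional choice is commonly used.

### Explanation

For a linear model the Shapley value of variable i has the closed form
`φi(x) = wi · (WoEi(xi) − mean reference WoEi)`, with the training set as
the default reference sample. Contributions satisfy local accuracy —
`Σi φi(x) = log-odds(x) − mean reference log-odds` — which the tests assert
to 1e-9 for every subject. Variables are summarized by the mean absolute
contribution `(1/N) Σ |φi|`, descending, ties alphabetical.

### Evaluation

AUC is pairwise concordance with half-credit ties; average precision is the
step-sum `Σ ΔRecall · precision`. An operating point at target
false-positive rate t is the threshold maximizing sensitivity subject to
FPR ≤ t (a zero-FPR target is always feasible at a threshold above every
score; with no positive calls precision is reported as 1 with a flag). The
two outcome groups' log-odds distributions are compared by a two-sided
Mann–Whitney U test (exact enumeration when both groups are small and
untied, asymptotic otherwise; Welch's t available as a switch) — a rank
test was chosen because the comparison is presented on quartile summaries
and no distributional form is assumed.

The split-stability experiment reruns the *entire* pipeline — binning, L1
path, AICc, L2 refit — on each of `n_runs` outcome-stratified splits (run r
uses split seed r; a draw leaving any categorical level only in the test
set is rejected and redrawn within the run, up to 1000 times). It reports
mean±sd test AUC, support sizes, per-variable selection frequency, and two
companion arms: refits on run 0's fixed support, and the pipeline with
sport-tagged variables removed.

### Splitting

Per outcome class with `n_c` members the test set receives
`round(n_c · test_fraction)` members (round half up; this rounding
reproduces a 96/59 | 24/15 partition of 120 events / 74 non-events at
fraction 0.2). The unique-level rejection rule is applied to categorical
*and* binary variables, since a binary level confined to the test set
breaks the WoE lookup identically.

## Synthetic cohort generator

`GeneratorSpec` defaults define the desk-scale preset: 50 variables —
5 informative + 42 noise continuous variables and 3 categorical variables
(Sport plus two generic factors) — on `n_subjects` subjects, 35%
missingness. Structure:

- **Continuous blocks.** Variables come in blocks of 5 sharing a latent
  factor with loading √`block_correlation` (default 0.3), mimicking
  correlated assessment batteries; columns are scaled to mean 10.5, sd 2.
  Measure names repeat across the four timepoints
  (`M03@Asymptomatic` etc.) so difference features have baseline partners.
- **Threshold effects.** Each informative variable shifts the log-odds
  piecewise-constantly at cutpoints {9, 12} by ±`effect_size`
  (default 1.2), alternating sign across variables — the same shape as a
  recovery-time segmentation at "under 9 / 9–12 / over 12 days", and the
  shape optimal binning is supposed to find. The default effect size
  anchors the cohort's attainable (Bayes) AUC near 0.8, the discrimination
  level reported for cohorts of this kind.
- **Sport.** Drawn from a 12-sport collegiate mixture with per-sport injury
  rates from a representative cohort table; each sport contributes
  `logit(rate) − base_log_odds`, so with all other effects off the
  per-sport event rates are exact.
- **Missingness and outcome order.** The MCAR mask is drawn *first*, and
  each subject's latent log-odds is computed from the observed entries (a
  masked informative value contributes `missing_shift`, default 0); the
  outcome is then Bernoulli of the logistic of that latent score. This
  makes `GroundTruth.bayes_auc` — the concordance of the latent score with
  the outcome — the ceiling attainable by a model that sees the masked
  table, which is the right yardstick for parameter-recovery tests. A
  nonzero `missing_shift` gives the informative-missingness mode, where the
  missing bin itself is predictive. The mechanism generating the mask is
  uncharacterized in real cohorts; both modes exist rather than committing
  to either.

What the generator does **not** emulate: clinically realistic score
distributions of specific instruments (error counts, bounded scales),
between-timepoint autocorrelation beyond the shared block factor,
missingness that clusters by visit (a skipped visit blanks a whole
timepoint), and measurement drift. Passing recovery tests therefore show
that the pipeline recovers threshold effects and sport effects under heavy
MCAR missingness at desk scale — not that it would achieve any particular
performance on real clinical data.

## Problem sizes and numerical choices

Tests and the acceptance script run the recovery preset at n = 4000 split
50/50 (train/test 2000 each, 10 generator seeds), the null (permuted-label)
check at the same scale, and the split-stability experiment at n = 1000
with 5 runs; these sizes put Monte-Carlo noise well inside the asserted
tolerances while keeping a full run in minutes on one CPU. Other choices:
continuous bins are half-open `[lo, hi)` with outer bins extended to ±∞;
unseen category levels transform to 0 (neutral evidence); the L1 solver is
scikit-learn's saga with warm starts, tolerance 1e-7, fixed random state; a
non-converged path point is flagged and excluded from selection; AICc is
undefined (treated as +∞) when `n ≤ k + 1`; scheme and model bundles
serialize to JSON with exact float round-trip.

## Limitations

- IV-maximizing binning always manufactures some in-sample evidence; the
  effective-dof AICc controls its effect on selection, but per-variable IV
  values on training data remain optimistically biased (a permuted-label
  run at n = 2000 still shows median IV ≈ 0.03). Audit IV manifests
  against a null permutation when in doubt.
- The categorical optimizer searches only groupings contiguous in the
  event-rate ordering; pathological level structures could in principle
  admit a better unordered grouping.
- Calibration relies on the logistic link and the training prior; under
  strong covariate shift the probabilities, not just the ranking, need
  re-checking.
- With very small samples the 0.05 minimum bin fraction can force coarse
  bins, hiding narrow threshold effects.
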