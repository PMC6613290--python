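# Methods

This note documents the models, rules and numerical choices implemented in
`vrisk`, the assumptions behind them, and what the synthetic corpus does and
does not emulate.

## Problem and analysis unit

The task is prognostic: at 24 hours after the start of a psychiatric
admission, predict from the clinical notes written so far whether the patient
will show violent behavior during the remainder of the first four weeks. The
analysis unit is the *admission*, one contiguous inpatient episode of one
patient.

### Cohort rules

- **Episode merging.** Registration systems split a clinical stay into
  episodes (ward transfers, brief discharges, somatic interludes).
  Consecutive episodes of one patient with a gap of at most 14 days (gap =
  next start − previous end; "at most two weeks" read inclusively) are merged
  into one admission spanning both. Overlapping episodes merge with a warning.
  Merging is idempotent.
- **Predictor window.** The document of an admission concatenates, in
  chronological order, every note with timestamp in
  [start − 28 d, start + 24 h], both boundaries closed. "Four weeks" is
  always 28 calendar days, "24 hours" an exact offset; the source material
  gives durations, not boundary conventions, so the closed boundaries are a
  package decision.
- **Outcome.** Positive iff ≥ 1 incident of category `violence_verbal` or
  `violence_physical` with timestamp in (start + 24 h, start + 28 d]. The
  categories `self_harm`, `substance_use`, `sexual_intimidation` and
  `vandalism` never qualify. Incident severity (SOAS-R, an integer in
  [1, 22]) is carried through but deliberately unused: no severity
  distinction is made. The category taxonomy is an enumeration invented to
  operationalize the inclusion sentence; real deployments remap their codes
  onto it.
- **Documentation exclusion.** Admissions with fewer than 100 words
  registered *after* the first 24 hours are excluded. We read this rule as a
  follow-up-documentation requirement (too little text to have observed the
  outcome period), not as a predictor-window requirement; the alternative
  reading is available via `count_predictor_window=True` in
  `build_labeled_admissions`. Admissions with an empty predictor document are
  likewise excluded, and input = retained + excluded counts is asserted.
- **Tokenizer.** One tokenizer everywhere (word counts, embedding, term
  screening): lowercase, strip punctuation, keep numerals, split on
  whitespace.

## Document embedding

Paragraph vectors trained with negative sampling, implemented in numpy:

- **DBOW (default):** the document vector alone predicts each word occurring
  in the document, against 5 noise words drawn from the unigram distribution
  raised to 3/4.
- **DM:** the document vector is averaged with the input vectors of words in
  a ±5-token context window to predict the center word.

Defaults follow common literature practice — 300 dimensions, context window
5, 20 epochs, minimum term count 5, linearly decaying learning rate
0.025 → 1e-4 — and are all exposed in `EmbeddingConfig`. Training is
label-blind (the API accepts no outcomes) and single-threaded, hence
bit-reproducible for a fixed seed. Vectors for *all* analysis documents,
train-fold and test-fold alike, are produced by inference against the frozen
word matrix (fresh document vector, gradient steps only on it), so no
document is represented differently because of the fold it landed in. Each
document's inference uses an independent sub-seed, making its vector
independent of the batch it is embedded with. A document with no
in-vocabulary token gets the random inference prior plus a warning, and the
pipeline continues. The training corpus may be a superset of the analysis
documents (unsupervised pretraining on a larger note set).

## Risk classifier and operating point

An RBF-kernel SVM (`sklearn.svm.SVC`) on document vectors z-scored with
statistics fit on the training fold only. `cost` (C) and `kernel_width` (γ)
come from the nested CV grid, by default C ∈ {0.1, 1, 10, 100} ×
γ ∈ {scale, 0.001, 0.01, 0.1}, where "scale" is 1/(dim · feature variance).
No class weighting: imbalance is handled at the operating point instead,
which matches the high-specificity / low-sensitivity profile such models
show at single-digit prevalence.

The continuous decision score is dichotomized at the cut minimizing
|FP − FN| over all distinct cut-points of the pooled out-of-fold scores —
the "balance false positives against false negatives" operating philosophy;
the published confusion tables show |FP − FN| ≤ 5 in all four experiments,
and the rule regenerates that near-balance. Ties are broken toward the
smaller FP, then toward the larger threshold, for determinism. Raising the
threshold never increases FP nor decreases FN.

## Validation design

- **Patient-grouped folds.** All admissions of one patient share a fold
  (identity leakage otherwise: later admissions of a patient can reveal the
  earlier ones). Assignment shuffles patients by seed, orders by admission
  count, and greedily fills the smallest fold, so sizes are as balanced as
  grouping permits (exactly n/k for singleton patients with k | n).
- **Nested CV.** 5 outer folds; within each outer-training set, 5 inner
  patient-grouped folds select the grid point with the best mean inner AUC
  (the inner k is a package decision; only "nested" is prescribed). The
  classifier is refit on the outer-training set and scored on the outer-test
  set. Pooled predictions cover every admission exactly once.
- **Headline AUC** = unweighted mean of the 5 outer-fold AUCs. The DeLong
  standard error and 95% CI are computed on the pooled out-of-fold scores —
  pooled predictions are the only single score vector the placement-value
  estimator applies to — and both the fold-mean and pooled AUC are reported
  side by side.
- **DeLong inference.** AUC is the Mann–Whitney statistic (ties count half);
  the variance comes from placement values via midranks. Paired comparisons
  (two models on the same admissions) use the placement covariance; unpaired
  comparisons add the marginal variances. Both are two-sided z-tests with
  significance at P < .01. A reference R implementation evaluates the same
  unpaired statistic against a Welch t distribution instead of the normal;
  the difference appears in the fourth decimal of p at n = 40 and vanishes
  with n.
- **Pooled metrics.** sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
  relative risk = [TP/(TP+FP)] / [FN/(FN+TN)] (risk among predicted-high
  over risk among predicted-low). Zero denominators yield NaN ("undefined"),
  never silent zeros. CIs are Wilson intervals for the proportions and the
  Katz log-scale interval for the relative risk — documented approximations,
  since the upstream CI method for pooled metrics is not fully specified.
- **Subgroups.** Early vs late violence splits positives at first incident
  ≤ 14 days; short vs long admission splits at the cohort median length of
  stay; both cutoffs configurable (the original definitions are not in the
  available material). To keep the two subgroups disjoint — so the unpaired
  DeLong comparison sees independent samples — the label-negative admissions
  of the early/late split are alternated deterministically (by admission id)
  between the subgroups.
- **Transfer.** The exchanged site model is the full frozen pipeline:
  embedding, scaler, SVM refit on all of the site's admissions with the
  hyperparameters most often chosen across its outer folds, and the pooled
  FP/FN-balancing threshold. Target documents are embedded by the *source*
  embedding (out-of-vocabulary tokens drop out naturally), scored, and
  compared against the target's internal pooled predictions with a paired
  DeLong test on the identical admissions. Evaluating a site with its own
  model is, by definition, its internal cross-validated evaluation, and the
  code returns exactly that.

## Term screening

Candidates are unigrams plus adjacent-token bigrams; the top 1000 by
*document* frequency (the binary-variable framing makes document frequency
the natural ranking; raw token count is available as an option) become
binary presence variables. Per term: Pearson χ² on the 2×2 table with 1 df
and *no* continuity correction — chosen so the identity χ² = n·MCC² holds
exactly (a correction is available as an option); MCC carries the direction,
with a 2000-replicate nonparametric bootstrap CI over admissions (no CI
method is prescribed upstream). Stability selection redraws admissions with
replacement 1000 times, recomputes all χ², and marks the top ⌈0.10·k⌉ terms
(ties broken lexicographically); a term's ratio is its inclusion fraction.
Resamples with a single outcome class are redrawn with a warning. Holm's
step-down procedure controls the familywise error rate at α = 0.01;
adjusted p-values are the running maxima of (m − i)·p(i) capped at 1, and
Holm rejections always contain the plain Bonferroni rejections.

## Synthetic two-site corpus

The generator emulates the *register structure* of two psychiatric centers,
with full-scale profiles (`site_profile_1/2`) parameterized to the published
descriptive statistics: 3189 admissions of 2209 patients vs 3253 of 1919;
prevalence 9.1% vs 7.7%; lognormal length of stay with median 16 d
(IQR 6–41) vs 15 d (5–40.5); lognormal predictor-document length with median
2091 words (1541–2981) vs 1961 (1160–3060); 68.4%/9.4% vs 48.8%/6.4% of
incidents in the first four weeks / 24 hours; SOAS-R as a discrete
triangular distribution on [1, 22] with mode 12 vs 11; diagnosis mixtures
from the published tables.

Mechanics and their rationale:

- Admissions per patient ~ 1 + Poisson(rate − 1): one knob reproduces the
  admissions-to-patients ratio. Later admissions start ≥ 15 days after the
  previous discharge so distinct admissions stay distinct under the 14-day
  merge rule.
- Outcome via a latent standard-normal risk score thresholded at the
  prevalence quantile: the marginal is exactly Bernoulli(prevalence) and the
  latent score is recorded as ground truth. Positive admissions redraw
  lengths of stay ≤ 1.1 d (the outcome window must be nonempty); this
  touches ~2.5% of draws.
- Notes are token streams, not language: background tokens from a Zipf-like
  distribution over a configurable vocabulary; per-note Bernoulli occurrence
  of each signal term with logit = logit(0.05) + log-odds·outcome, inserted
  at random positions (1 + Poisson(0.5) copies). A negative log-odds makes a
  term protective. This is the simplest mechanism giving tunable AUC and
  χ²-detectable terms. Signal is planted only in predictor-window notes.
- Every admission gets predictor-window notes, post-24h notes (≥ 110 words
  unless planted as under-documented: `n_underdocumented` admissions get 40
  words, for testing the exclusion rule), and occasionally a stale
  pre-window note.
- Violent incidents attach to positive admissions: one forced index incident
  in the outcome window plus Poisson extras whose window mixture is solved
  analytically so the *overall* 24-hour/4-week timing fractions land on the
  configured targets despite the forced indices. Non-violent incidents
  attach anywhere with the configured mixture. Incidents never fall outside
  [admission start, end].
- Cross-site shift: each site independently replaces each base signal term
  with a site-local synonym (`term_<site>`) with probability `site_shift`,
  mimicking two hospitals wording the same observation differently.

What the generator does **not** emulate: natural language (word order
carries no meaning beyond adjacency), diagnosis- or ward-dependent risk,
correlation of note length with outcome (none is published; they are
independent by default), within-patient document similarity, and violent
incidents outside the outcome window on label-negative admissions. Passing
tests therefore demonstrate that the *pipeline machinery* recovers planted
distributional structure — not that any particular AUC is attainable on real
notes; the published site AUCs require the two centers' undeposited corpora
and are out of reach by design.

### Desk-scale study conditions

Tests and the reproduction script run on `desk_profile_1/2`: all rates as
above but 480 patients (~700 admissions; 700 patients, ~1000 admissions for
null-signal runs), 150-word median documents, 800-term vocabulary, a 48-d /
12-epoch DBOW embedding, and a 2×2 hyperparameter grid — sized so the full
suite runs in minutes on one CPU. Planted conditions: "strong" signal at
log-odds +2.5 (protective −2.0) for signal-recovery and term-screening
checks; "moderate" +2.0/−1.5 with site shift 0.8 for the transfer
experiment; no signal terms for null calibration. Under the null the
cross-validated AUC is checked as a mean over 5 generator seeds against
[0.45, 0.55]: single-seed fold-mean AUCs at ~60 positives carry Monte-Carlo
noise of ±0.03–0.04, and CV on null data is known to sit a hair below 0.5.

## Determinism

One top-level seed drives everything: corpus generation, fold assignment,
embedding initialization and negative sampling, inference sub-seeds, SVM,
bootstrap and stability resampling. Same profile + seed ⇒ byte-identical
corpora; same config + seed ⇒ identical manifests, predictions and metrics.

## Known limitations

- The embedding is a compact reimplementation of paragraph vectors;
  large-corpus performance tuning (hierarchical softmax, frequent-word
  subsampling, threading) is out of scope.
- DeLong p-values are asymptotic; at very small n (tens of admissions) the
  normal approximation is anticonservative by a few tenths of a percent at
  α = 0.01.
- The Wilson/Katz intervals for pooled metrics ignore the fold structure of
  the pooled predictions.
- `relative_risk` is undefined (NaN) when the model predicts no one, or
  everyone, as high risk — the transferred-model example in the README shows
  this happening legitimately.
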