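# Methods

## Model and procedure

The package discovers a "diagnosis pattern": a minimal subset of
continuous biomarkers, plus a boosted-stump classifier over it, separating
two diagnostic classes in a small clinical cohort. The procedure is a
wrapper feature selection driven by a univariate filter:

1. every biomarker is scored with the pooled-variance two-sample *t*
   statistic (positive class minus negative class, so $t>0$ means elevated
   in cases), with $\nu = n_1+n_2-2$ degrees of freedom;
2. the top-10 biomarkers by $|t|$ form the candidate list;
3. each rank-prefix subset of sizes 2–10 (nine subsets) is evaluated by
   stratified 3-fold cross-validation of a discrete AdaBoost ensemble of
   depth-1 weighted decision trees, pooling the held-out predictions of
   all folds into one confusion matrix;
4. the subset with the highest pooled CV accuracy wins; exact ties (the
   pooled correct count is an integer out of $M$) go to the smaller
   subset;
5. the winning subset is refit on the whole cohort, yielding the
   deployable ensemble; its resubstitution confusion matrix is reported,
   clearly labelled, and never used for selection.

Assumptions worth keeping in mind: the *t* filter targets mean shifts, so
biomarkers informative only through variance or through interactions
effectively enter the candidate list by luck; prefix subsets assume the
marginal ranking orders joint usefulness at least roughly; and pooled CV
accuracy on 52 samples has a granularity of ~1.9 points, which is why the
tie rule matters.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `n_rounds` (N) | 50 | maximum boosting rounds; resubstitution accuracy on 52-sample cohorts saturates at 100% well inside this budget |
| `max_depth` | 1 | weak-learner depth; stumps are the canonical AdaBoost weak learner and keep the sweep's capacity low at $n=52$ |
| `k_candidates` | 10 | candidate-list length, hence nine swept prefixes |
| `k_folds` | 3 | cross-validation folds; with 13 controls, 3 stratified folds keep 4–5 controls per held-out part |
| `stratified` | True | unstratified 3-fold splits of a 39/13 cohort can starve a fold of controls |
| `seed` | 0 | fold-plan shuffle; everything else is deterministic |

Boosting details: weighted error $\beta_t$ below the floor $10^{-10}$ is
clamped there so $\alpha_t$ stays finite (a perfect round ends training —
no weight update can follow it); $\beta_t \ge 0.5$ stops training, and on
round one raises an error since no weak learner beats chance. With
continuous features and distinct values, a stump's weighted error is at
most the smaller weighted class prior and strictly below 0.5 whenever any
split has positive gain, so the $\beta_t \ge 0.5$ stop is reachable only
on degenerate inputs (e.g. a constant feature with balanced classes) —
random-label cohorts run the full N rounds rather than stopping early.

Tree details: splits maximise the weighted gain ratio (entropy in bits) at
midpoints between consecutive distinct sorted values; candidates that put
zero weight on a side are inadmissible; ties break to the lower feature
index then the lower threshold; a value equal to the threshold routes
left; a weighted-majority tie at a leaf votes +1, as does an ensemble vote
of exactly zero. No pruning is applied: pruning under instance weights is
ill-specified and the boosting reweighting supplies the capacity control.
An information-gain criterion is available behind the `criterion` flag.

Metrics: sensitivity $TP/(TP+FN)$, specificity $TN/(TN+FP)$, accuracy
$(TP+TN)/M$, percentages rounded half-up to one decimal. A metric with an
empty denominator is reported as NA, never as 0.

## The synthetic-data generator

Generated cohorts emulate a two-group lab-panel study: 34 parameters (29
routinely named plus a 5-entry electrolyte placeholder block: Na, K, Cl,
Ca, Mg), class-conditional Gaussians on plausible adult reference scales,
class imbalance 39/13 in discovery and a 29/13 + 31/12 two-site validation
pair, and an informative pattern of five biomarkers (MCH, CHO, PDW, LDL,
TCO2) shifted by 0.75/0.70/0.55/0.52/0.48 sd in cases. Those deltas are
calibrated constants of this package: at $n=39$ vs 13 they put roughly two
of the five below $p=0.05$, the regime where marginal testing
under-selects and the wrapper sweep is supposed to help. An optional
equicorrelation $\rho$ within the lipid and red-cell blocks adds
collinearity; it defaults to 0 (independence is the minimal model
consistent with *t*-ranking).

What the generator does **not** emulate: real lab covariance structure,
skewed or heavy-tailed assay distributions, demographic confounding, site
effects in the validation pair, missing values. Passing tests on this
generator therefore demonstrate algorithmic correctness and calibration
under a clean Gaussian world, not clinical performance.

An important quantitative consequence, established while validating the
package: at the default deltas the five informative biomarkers carry a
Mahalanobis separation of ≈1.36, whose population-optimal accuracy on a
70.6%-prevalence validation pair is ≈79%. A stump ensemble estimated from
52 samples sits below that ceiling (measured mean validation accuracy
≈68–70% over 20 seeds, indistinguishable from scikit-learn's SAMME stump
ensemble on identical folds), and the chosen subset size fluctuates
widely because pooled CV accuracy differences between prefixes are often
a single sample. Reliable recovery of the planted 5-biomarker pattern, or
validation accuracy stably in the low-to-mid 80s, requires materially
larger effect sizes than the p-value-pattern calibration allows — a
tension inherent in the study design this package emulates, not a tuning
failure; the generator's defaults are part of the package's contract and
were not adjusted to soften it.

## Numerical choices

- Gain and gain-ratio comparisons use a $10^{-12}$ tolerance; scores
  within it are ties and resolve by the documented deterministic order,
  which makes fitted trees, ensembles and all CLI outputs byte-stable.
- Weights are validated to sum to 1 within $10^{-9}$ and renormalised
  exactly once per round by $Z_t$.
- Unbiased ($n-1$) variances everywhere, as the pooled-variance formula
  requires; groups of size 1 are rejected rather than given variance 0.
- A biomarker constant in both classes has an undefined *t*; in ranking it
  is placed last with $p=1$ and a warning instead of aborting the sweep.
- Percentage rounding uses decimal half-up (not banker's rounding) to
  match conventional clinical-table formatting.
- CSV values are written at 12 significant digits, which round-trips
  typical lab exports bit-identically.

## Design choices where the design was open

- **Prefix sweep, nine subsets.** Only rank prefixes of the candidate
  list are swept (sizes 2–10), not the $2^{10}$ subsets: prefixes are the
  reading consistent with a *t*-ranked candidate list and make the
  selection cheap and interpretable.
- **One shared fold plan across the sweep**, so subset comparisons are
  paired and fold-assignment noise cancels out of accuracy differences.
- **Stump default.** The weak learner's depth is configurable, but the
  sweep behaviour — not the tree flavour — is what the method is about.
- **Exhaustive deterministic weak-learner search** over all feature ×
  midpoint candidates rather than any heuristic, so identical inputs give
  identical models.
- **Fallback on fold-training failure**: the fold's samples are predicted
  as the training fold's majority class with a warning, so a pathological
  fold degrades the estimate instead of killing the run.

## Problem sizes used in the test suite

Simulation-backed tests use 20 seeded replicates of the 52-sample
discovery design (and 10 for the strong-signal generalisation check),
2 000 simulated null biomarkers for *p*-value calibration, and 50 random
8-sample tables for the stump-enumeration cross-check; these sizes give
stable pass/fail behaviour at the frozen seeds while keeping the default
`pytest` run around one and a half minutes.

## Known limitations

- Binary classification only; no multiclass boosting variants, no
  confidence-rated votes, no shrinkage.
- No missing-value handling by design: cells must be numeric and finite.
- No multiple-testing correction of the reported *p*-values (none is used
  for selection either); no ROC/AUC, only the three clinical metrics.
- The selected pattern's pooled CV accuracy is a selection maximum over
  nine subsets and is therefore optimistically biased; judge a pattern on
  external validation, as the two-site workflow here does.
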