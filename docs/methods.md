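# Methods

This note records the model, the numerical and design choices, and the
limits of what the test suite demonstrates.

## Event-indexed time

All operators run on *event counts*, not calendar days: "a 7-window"
means the last 7 recorded events (sessions and matches), whatever their
calendar spacing. Load monitoring literature habitually conflates
"28-day" windows with 28 sessions; we commit to the event reading
because every formula in the framework indexes events, and irregular
schedules (double sessions, congested fixture weeks) make calendar-day
windows ill-defined without an interpolation model we do not want to
impose. Dates are carried as metadata only. Inputs with double sessions
must arrive pre-ordered; the package does not guess an intra-day order.

## The operators

For a per-event series `x(0..E−1)`:

- `AW(j, τ) = Σ_{z=j−τ+1}^{j} x(z)` — cumulative load over the last τ
  events. Satisfies the recurrence `AW(j,τ) = AW(j,τ−1) + x(j−τ+1)` and
  is non-decreasing in τ for non-negative series.
- `CW28(j) = AW-type sum over the last 28 events / 4` (the mean of four
  weekly blocks including the acute week — *coupled*);
  `CW21(j) = (Σ_{z=j−27}^{j−7} x(z)) / 3` (the three weekly blocks
  preceding the acute week — *uncoupled*).
- `ΔACW(j, τ) = AW(j,τ) − AW(j−1,τ)`, which telescopes exactly to
  `x(j) − x(j−τ)`. The implementation uses the lagged-difference form;
  the equality with the AW-difference form is asserted in tests.
- EWMA ratio: `EWMA_7(x)[j] / EWMA_28(x)[j]`, recursion
  `EWMA[j] = λ·x(j) + (1−λ)·EWMA[j−1]`, λ = 2/(N+1). The smoothing is
  applied to the raw per-event series (the standard EWMA-ACWR
  formulation); initialization is `EWMA[0] = x(0)` by default, with a
  zero-state option.

**Edge policy.** Season starts are governed by `zero_pad` (default):
windows reaching before event 0 treat the missing history as zero load,
consistent with the zero-filled calendar representation. A `strict`
policy raises instead. The variation matrices carry a per-(event, τ)
`history_complete` flag so callers can mask warm-up events; several
identities (e.g. "constant series ⇒ ΔACW = 0") hold only on the
complete-history region, and the tests state them that way.

**Undefined ratios.** Any ACWR with a zero chronic denominator is a
tagged undefined value (NaN), never an exception and never a silent 0 —
zero chronic load is a legitimate pre-season state. Feature tables
replace undefined ratios with 0 so downstream models receive a complete
matrix; the raw operators keep NaN.

**Block layout.** The ΣT/ΔT matrices are stored as dense
`(#V, #E, #T)` arrays; the printed `#V × (#E·#T)` block is exported
τ-major within each event with an explicit `(event, tau)` column
MultiIndex, because the flat shape alone leaves the flattening order
ambiguous.

## Dataset variants and undersampling

Five representations of the same season: raw per-event values on
participated events only (`baseline_raw`); per-variable
(acute, chronic, ratio) triplets for the coupled, uncoupled and EWMA
ratios on the zero-filled calendar; and the footprint variant with the
(AW, ΔACW) pair per variable × τ. Columns are named
`{variable}__{operator}__{tau}` so every table is self-describing.
Participation is inferred from record presence (≥1 record at an event);
played-the-match means ≥1 record at the match event, since playing
minutes are not part of the schema.

Undersampling keeps only MD-1 rows (the last training before a match)
for players who then took part in the match, with match-day injury
labels shifted back onto MD-1 — the pre-match question a practitioner
actually asks. A match injury with no tagged MD-1 predecessor is
dropped with a warning; a training-day injury that happens to fall on
an MD-1 event stays where it is. Two labels can collide when a player
is injured both at MD-1 and in the next match; the binary vector then
holds one positive, which is why label-count conservation is stated
(and tested) for match-day labels only.

## Evaluation pipeline

- **Robust-PCA outlier removal**: rows are scored in a principal
  subspace (up to 10 components, ≥90% of variance, capped at n/4 so the
  covariance fit stays well-posed) by the robust Mahalanobis score
  distance under a minimum-covariance-determinant fit, combined with
  the orthogonal reconstruction residual; each distance is scaled by
  its median and the `ceil(factor·n)` worst rows are removed. The
  method family is fixed; the variant (subspace + MCD + combined
  score/orthogonal distance) is our choice among standard formulations.
- **Temporal split**: first ⌊0.8·n⌋ rows in event order train, the
  season tail tests, no shuffling; the test tail keeps its natural
  prevalence.
- **SMOTE** (in-package): synthetic minority samples are convex
  combinations `x_i + t·(x_nb − x_i)`, `t ~ U(0,1)`, with `x_nb` one of
  the k = 5 minority-class nearest neighbors; originals are preserved
  and classes end exactly balanced. Requires ≥ k+1 minority rows.
- **PCA**: fit on the training set only, without standardization,
  keeping the smallest m with cumulative explained variance ≥ 0.95;
  the test set is projected with the train transform (no leakage, and
  a test asserting train-only fitting enforces it).
- **Cross-validation**: repeated stratified k-fold (default 10×2),
  metrics recorded on both the fitted and held-out fold of every
  split. Eight classifier families (LDA, logistic regression, Gaussian
  naive Bayes, k-NN, RBF-kernel SVM, decision tree, random forest,
  MLP) at library defaults, seeds recorded per split.
- **Metrics**: Type I error = FP/(FP+TN), Type II = FN/(FN+TP),
  G-mean = √((1−TypeI)(1−TypeII)), accuracy at threshold 0.5 on
  probability-like scores; ROC-AUC and PR-AUC threshold-free, with the
  PR baseline equal to positive prevalence. Single-class inputs flag
  the AUCs as undefined rather than failing.
- **Permutation test**: add-one estimator
  `p = (1 + #{null ≥ observed}) / (n_perm + 1)`, which cannot report 0
  and makes the p-value exactly uniform on its grid under the null.
- **Bias–variance**: 0-1-loss decomposition over bootstrap resamples;
  the main prediction is the per-test-point majority vote, bias its
  loss against the truth, variance the mean disagreement of individual
  fits with the main prediction. Single-class resamples are redrawn
  (capped retries).

## Synthetic seasons

The generator emulates the regime the framework targets: weekly
microcycles (MD-4…MD-1, match), lognormal non-negative loads with a
per-microcycle-day shape (hard mid-week and match day, light MD-1),
per-variable mean spread, per-player baseline multipliers, sparse
participation, occasional spikes (×3 with probability 0.1–0.15), and
rare match-day injuries with probability
`logistic(β0 + β1·z)`, where `z` is the standardized lagged difference
of one driver variable at MD-1 — i.e. exactly a ΔACW cell. β0 is
calibrated by bisection to a target mean prevalence. Player
heterogeneity is the deliberate confounder: raw same-day values mix the
player's habitual level with the spike, while the lagged difference
cancels the level — this is what makes the footprint-vs-baseline
contrast meaningful rather than circular in representation (the hazard
is a function of the data, not of any fitted model).

Presets: `paper_scale` (23 players, 45 weeks, 73 variables,
participation 0.8, prevalence 0.025 — ≈4,100 participated player-events
and ≈20 realized injuries per season) matches the sample-size regime of
a full elite-club season; `smoke_test` (6 players, 8 weeks, 5
variables) is the testing scale, with match-day prevalence set to 0.25
once at design time so its ~40-row pre-match table carries enough
positives for stratified 2-fold cross-validation. Training-day hazard
is 0 by default (injuries concentrate in matches), with a config
override.

What the generator does **not** model: biomechanical realism, variable
cross-correlations, fatigue carry-over, recurrence after injury, or
calendar irregularities. Passing tests therefore demonstrate that the
pipeline recovers the class of signal it is designed for under the
stated statistical structure — not that any real squad's injuries are
predictable at these accuracies.

## The comparison study

`variant_comparison` runs at a few dozen samples per season, so the
classifier is a screened linear model: standardize, keep the 3 best
features by univariate F-test *inside each CV fold*, logistic
regression; CV is 3×4-fold so three quarters of the samples are
available to each fit. Both variants pass through the identical
estimator, isolating the feature representation. The permutation test
reuses the same closure with 99 permutations (p-grid 0.01…1.00). At
this scale some season realizations are genuinely uninformative — with
~8 positive labels the planted effect can be washed out by label
sampling noise — so the study reports per-seed results and is judged in
aggregate over ≥10 seeds.

## Numerical choices and degenerate inputs

Rolling sums use cumulative-sum differencing (exact for the test
magnitudes); the EWMA recursion is checked against its closed-form
geometric expansion to 1e-10. Bisection for β0 runs 200 halvings on
[−50, 50] and fails loudly if the target prevalence is unreachable.
Heatmaps use a sequential palette for ΣT (non-negative) and a diverging
palette centered at 0 for ΔT (signed); per-panel scaling is
per-player-event by default with `per_variable`/`global` normalization
options, and rendered values default to raw (no z-scoring). Images are
written with run-independent metadata so identical inputs give
byte-identical files.

## Known limitations

- Calendar-day windows, playing-minutes-based participation, and
  recurrence modelling are out of scope.
- The published full-season column layouts of the engineered datasets
  are not reverse-engineered; the window set T is configuration.
- The held-out tail at smoke scale is tiny (<10 rows); single-run test
  metrics there are illustrative, and all conclusions in the examples
  and tests aggregate over CV splits and seeds.
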