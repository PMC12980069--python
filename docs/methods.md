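# Methods

This note documents the models and procedures implemented in `emocog`, the
assumptions behind them, the tunable parameters and their defaults, what the
synthetic-data generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Task designs

The three touchscreen paradigms have fixed layouts (`emocog.design`):

| task     | practice | main phase                    | go/no-go structure |
|----------|----------|-------------------------------|--------------------|
| eFlanker | 18       | 2 × 90 = 180; 9 target×distractor emotion cells × 20 | every trial requires a response |
| eGoNoGo  | 20       | 2 × 60 = 120; 48 targets (40%), 72 non-targets | 2 of 6 color×emotion combos are targets; 2000 ms deadline |
| eStroop  | 12       | 3 × 36 = 108; 9 color×emotion combos × 12 | one target color → 36 go, 72 no-go; 2000 ms deadline |

Main-phase condition counts are exact, not stochastic; only the order (and
the counterbalanced color assignments) is randomized per participant. The
eStroop target proportion is not fixed by the published task description
beyond the trial total; the balanced layout (every color×emotion combination
12 times, hence 1/3 go trials) is this package's choice.

## Exclusion rules and preprocessing

**Engagement dropout.** A participant's task is excluded when the ordered
main-phase trials contain a run of ≥ 4 consecutive *response-required*
trials with no touch. Any touch (including a commission error on a no-go
trial) resets the run; a correctly withheld no-go trial neither extends nor
breaks it. For the eFlanker, where every trial requires a response, this is
simply "4+ consecutive unanswered trials". Counting raw `responded=False`
runs would misfire on the go/no-go tasks, where long runs of correctly
withheld no-go trials are expected behavior. Runs may span block breaks.
A participant enters the feature matrix only when all three tasks are
present and none is dropout-flagged; the whole task's data are otherwise
discarded (partial sessions are not analysed).

**RT filtering.** RT statistics average correct trials only and discard
reaction times strictly below 200 ms (accidental touches); the 200 ms
boundary value is kept. Filtered trials still count toward accuracy.

**Outlier masking.** Per behavioral index (column), values with
|x − median| > 3·MAD are masked as missing, where MAD is the median of
absolute deviations from the median. The inequality is strict, so a column
with MAD = 0 (e.g. a near-ceiling accuracy index whose median participant
is perfect) masks every value off the median. Masking removes the cell, not
the participant. When such a column becomes constant it carries no
information and the pipeline drops it before the decompositions, recording
the names in `grouping.json`; `winsorized_zscore` raises on constant
columns when called directly.

## The 82-index catalog

The feature catalog (`emocog.indices.default_catalog`) enumerates 82
indices — 46 eFlanker, 18 eGoNoGo, 18 eStroop — each defined by a statistic
(`mean_rt`, `accuracy`, `error_rate` = 1 − accuracy for commission/omission
rates, or `difference` between two condition selectors) over a predicate on
trial conditions. The exact composition of the original battery's index
list is not published in full; this catalog reconstructs it under two hard
constraints — the total of 82 and coverage of every feature named in the
published grouping table (`CANONICAL_FEATURE_LABELS`, checked by a test).
The catalog is plain data (JSON round-trippable), so a different index list
can be swapped in without code changes.

Scoring conventions for the go/no-go style tasks: go accuracy = responses
within the deadline / go trials (a late or absent touch is an omission);
no-go accuracy = withheld / no-go trials (a touch is a commission);
"overall accuracy" = correct decisions over all trials.

## E-score construction

1. **Winsorized z-scoring.** Columns are standardized (mean/SD over
   non-missing entries, SD with ddof = 1), missing cells are imputed at
   z = 0 (the column mean — the least-informative single-value choice;
   imputed cells are recorded), and values are capped at |z| ≤ 2.5 so a few
   extreme children cannot dominate the decompositions. Both
   decompositions below run on this same capped matrix.
2. **Feature embedding.** PCA of the participants × indices z-matrix; each
   index is represented by its loadings on the first two components
   (deterministic sign: the largest-|loading| entry of each component is
   positive). Two components are retained by design (in the study data
   only the first two explained > 10% of variance).
3. **Grouping.** k-means (squared Euclidean) on the 2-D loadings, best of
   50 seeded restarts. k defaults to the study value 3 and can be chosen by
   the inertia elbow: k* maximizes the second difference
   I(k−1) − 2I(k) + I(k+1) over the inertia curve, ties toward smaller k.
   Cluster labels are arbitrary, so groups are canonicalized by their
   composition — sorted by (share of plain-RT indices − share of plain
   accuracy indices), descending — making group 1 RT-dominated and group 3
   accuracy-dominated regardless of k-means label order.
4. **Stability.** Leave-one-out validation: for each index, k-means is
   refit without it, refit clusters are matched to the original groups by
   maximal label overlap (Hungarian assignment), and the held-out index is
   assigned to the nearest refit center (ties to the lowest group number).
   The reported fraction is the share of indices keeping their group.
5. **E-scores.** E-score g = participants' scores on the first principal
   component of group g's columns (centered); loading vectors are unit
   norm, scores have mean 0 by construction. Signs are anchored: overall
   eFlanker RT loads positively on E-score 1, the pooled
   emotional-vs-neutral RT difference on E-score 2, overall eFlanker
   accuracy on E-score 3; if an anchor is missing from its group the
   largest-|loading| index is made positive instead.

## Inference battery

* Condition contrasts: classical paired t tests (two-sided). Identical
  samples return t = 0, p = 1; a constant non-zero difference has no
  estimable variance and raises.
* ANCOVA: OLS of the outcome on a 2-level gender factor plus continuous
  age; F statistics from model-comparison (Type II) sums of squares, with a
  Type III (sum-to-zero contrasts) option since software conventions vary.
  Numerator df 1, denominator df n − 3.
* Partial correlation: Pearson correlation of the least-squares residuals
  of x and y on [1, covariates]; p from t with df = n − #covariates − 2.
  Missing data are handled pairwise-complete and n is reported per test.
* Multiplicity: Benjamini–Hochberg step-up. The declared family for the
  headline analysis is the 3 × 3 E-score × scale partial-correlation
  battery; the optional mutual-control partials (each scale controlling
  for the other two and age) form their own family.
* Sample size for a correlation: Fisher z-transform closed form
  n = ⌈((z₁₋α/₂ + z_pow)/atanh ρ)² + 3⌉, plus an exact method that
  integrates the bivariate-normal sampling density of r (hypergeometric
  form) over the rejection region and searches the smallest n reaching the
  target power. For ρ = 0.342 the Fisher form gives 65 and the exact
  method 64; both are exposed and neither is privileged.

## The synthetic cohort generator

`emocog.simulate` draws, per participant, a set of latent traits and then
simulates every trial:

* **Ages**: truncated normal, parent mean 7.2 y, SD 1.4 y, support [4, 10]
  (the truncated distribution's mean is ≈ 7.16; tests compare against the
  analytic truncated moments).
* **Scales**: CES-DC and STAI-CH are discretized Gaussians sharing a latent
  factor g with loading √0.493 each, so their observed correlation is
  calibrated to ≈ 0.493 (rounding/clipping to the instrument ranges
  attenuates it by < 0.01); K-ARS is an independent discretized Gaussian.
  Defaults: CES-DC ~ (14, 8) on 0–60, STAI-CH ~ (33, 7) on 20–60,
  K-ARS ~ (10, 8) on 0–54.
* **Reaction times**: log-normal; log RT = task baseline + age slope ·
  (age − 7.2) + subject intercept + residual. Defaults: baselines
  e^7.03 ≈ 1130 ms (eFlanker), e^7.10 (eGoNoGo), e^6.68 (eStroop); age
  slope −0.12/y; subject SD 0.15; residual SD 0.35. Emotional interference
  is **additive in milliseconds** on emotional eFlanker targets
  (170 + 130·sensitivity ms) and on negative eStroop trials
  (60·sensitivity ms), and incongruent eFlanker trials are slowed by
  40·sensitivity ms with a zero group-mean congruency effect. An additive
  (rather than log-scale multiplicative) interference term keeps the
  emotional RT contrast independent of overall slowness, matching the
  observed age-invariance of the emotional and congruency effects; a
  multiplicative term would make every contrast index scale with age.
* **Subject intercepts**: the speed intercept loads 0.10 on a
  depression-specific latent (general slowness tracks depression but not
  anxiety), the rest on an independent residual; the accuracy intercept
  (SD 0.4 logits) is shared across tasks, which is what makes accuracy
  indices cluster.
* **Emotional sensitivity** is identified with the shared
  depression/anxiety factor g, so the emotional-interference contrasts
  correlate symmetrically with both scales (the study observed a stronger
  depression than anxiety association; a shared-factor model cannot
  reproduce that asymmetry and targets a compromise ≈ 0.45 for both).
* **Accuracy**: logistic models. eFlanker choice: base 4.1 logits, age
  slope 0.25/y, emotional deficit 0.35 + 0.30·sensitivity +
  0.20·impulsivity, incongruent deficit 0.10·impulsivity. No-go withhold
  models with positive-stimulus shifts (0.8 eGoNoGo, 0.45 eStroop),
  impulsivity slopes (0.18 + 0.08 on positive eGoNoGo; 0.12 eStroop) and a
  positive-commission sensitivity slope (0.15 eGoNoGo, 0.10 eStroop).
  Impulsivity is identified with the K-ARS latent and affects accuracy
  only, never RT.
* **Responses**: go trials lapse with p = 0.01 (no touch) and time out when
  the latent RT exceeds the 2000 ms deadline; 80% of would-be-late
  responses are instead rushed in just under the deadline (children race a
  visible clock), so genuine timeouts are rare but age-linked. Commission
  touches on no-go trials get a uniform RT within the stimulus window and
  never enter RT averages (which use correct trials only).
* **Dropout**: per task, a participant disengages with probability 2/78,
  4/78, 10/78 (eFlanker, eGoNoGo, eStroop) from a random main-phase trial
  onward: no further touches, so go trials become timeouts and no-go trials
  are "correctly" withheld — reproducing the consecutive-miss signature the
  exclusion rule detects.

The planted effect sizes were calibrated once, on large simulated cohorts,
so the subject-level statistics land near the published values (age–speed
r ≈ −0.65, depression–E-score-1 partial r ≈ 0.29, internalizing–E-score-2
≈ 0.45, ADHD–E-score-3 ≈ −0.33, and condition means/accuracies within the
published confidence intervals), then frozen. They are calibration choices,
not measured facts.

**What the generator does not emulate**: practice/learning effects across
blocks, sequential dependencies (post-error slowing), speed–accuracy
trade-offs within a child, asymmetric depression/anxiety loadings of the
interference factor, age trends in the questionnaire scores themselves, and
any cultural or administration-mode effects. Passing tests therefore show
the pipeline recovers structure of this generative form at these effect
sizes — not that real cohorts satisfy the model.

## Study configurations used by the validation suite

Two configurations fix the cohort sizes the statistical checks assume by
disabling the dropout process (dropout behavior is tested separately):
`SimConfig.null(n=64)` zeroes every trait-to-behavior slope (type-I error
check: over 200 cohorts, the 9-test FDR battery flags ≥ 1 partial in ~5% of
runs, bounded at 10%); `SimConfig.recovery(n=200)` keeps the default
planted effects (the three sign patterns are recovered with FDR-significant
partials, and the grouping separates RT-level / emotion-contrast /
accuracy-level indices, in ≥ 90% of 20 cohorts). Problem sizes (200 × 64,
20 × 200, n = 5000 for the scale calibration) were chosen so the whole
suite runs in a few minutes on one core while keeping Monte-Carlo error
well inside the asserted margins.

## Numerical choices and degenerate inputs

* PCA via full SVD (deterministic); k-means ties between equal-inertia
  restarts resolved by scikit-learn's seeded restart order.
* Zero-variance columns: error by default, dropped-with-record in the
  pipeline. Embedding requires rank ≥ 2; E-score groups must be non-empty.
* `detect_dropout` on an empty trial list is an error; `mad_outlier_mask`
  with < 3 values flags nothing and warns; `choose_k` requires a
  non-increasing inertia curve over ≥ 4 candidate k.
* Equidistant ties in leave-one-out reassignment go to the lowest group
  number; all randomness is seeded and every artifact records the seed and
  a configuration hash.

## Known limitations

* The catalog is a reconstruction; if the original 82-index list surfaces,
  it can be loaded as `catalog.json` without code changes.
* Near-ceiling accuracy indices self-destruct under the strict MAD rule
  (masked to constancy, then dropped); this faithfully implements the
  stated rule but means a handful of the 82 columns typically do not reach
  the decompositions.
* With k fixed at 3, cohorts whose emotion-contrast cluster is weak can
  merge it into a neighboring group; the leave-one-out stability fraction
  in `grouping.json` is the diagnostic to inspect before interpreting
  E-score 2.
* The ANCOVA assumes homogeneous covariate slopes across gender (no
  interaction term), matching the reported analysis.
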