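# emocog

Analysis toolkit for a gamified **emotional-cognitive touchscreen battery**
for young children (ages 4–10): an emotional Flanker task (eFlanker), an
emotional Go/No-Go task (eGoNoGo), and an emotional Stroop task (eStroop),
administered alongside standard mental-health questionnaires — the CES-DC
(self-reported depression), STAI-CH (self-reported anxiety) and K-ARS
(parent-reported ADHD symptoms).

The package turns trial-level touchscreen data into interpretable composite
scores and tests their associations with the questionnaires:

1. **Behavioral indices.** Each child's main-phase trials are reduced to 82
   indices: condition-wise mean reaction times (correct trials only, RTs
   < 200 ms discarded as accidental touches), accuracies, commission and
   omission rates, and condition contrasts (emotional vs neutral,
   incongruent vs congruent, positive vs negative). Children who miss 4+
   consecutive response-required trials in a task are excluded (engagement
   dropout); per index, values more than 3 median absolute deviations from
   the median are masked as outliers.
2. **E-scores.** Indices are z-scored with winsorization (|z| ≤ 2.5),
   embedded in 2-D by their loadings on the first two principal components
   of the participants × indices matrix, grouped by k-means (k chosen by the
   inertia elbow; the study value is 3) and checked with leave-one-out
   cluster validation. E-score *g* is the first principal component of group
   *g*'s indices: E-score 1 ≈ general response speed (attention), E-score 2
   ≈ emotion–attention interaction, E-score 3 ≈ accuracy / selective
   inhibition.
3. **Associations.** Each E-score is tested with an ANCOVA (gender as fixed
   factor, age as continuous covariate) and with age-controlled Pearson
   partial correlations against the three scales; the 3 × 3 partial
   correlation family is corrected with Benjamini–Hochberg FDR (two-sided
   α = .05).
4. **Power analysis.** `n_for_correlation` gives the minimum sample size to
   detect a Pearson correlation ρ at power 1 − β via the Fisher z-transform
   closed form n = ⌈((z₁₋α/₂ + z_pow)/atanh ρ)² + 3⌉, or via the exact
   bivariate-normal sampling distribution of r.

Because raw child data cannot be redistributed, the package ships a
**synthetic-cohort generator** (`emocog.simulate`) that reproduces the
statistical structure the analysis assumes — exact task designs, truncated
age distribution, correlated depression/anxiety scales, log-normal RTs with
age-related speeding, emotional interference tied to a shared
internalizing factor, ADHD-linked accuracy deficits, lapses, deadlines and
engagement dropout — so every pipeline stage is testable end to end.

## Worked example

```bash
emocog simulate --out data --seed 11 --n 78
emocog run data/trials.csv data/participants.csv --out results --seed 0
emocog report results
```

prints (abbreviated):

```
emocog run (seed 0, config 7682f3a9509c5f1d)
participants: 78 total, 66 analysed, 12 excluded
exclusions per task: {'eflanker': 5, 'egonogo': 3, 'estroop': 4}
feature groups: k=3 (LOO stability: 1.0)
  group 1: 25 indices (anchor: eflanker_rt_overall)
  group 2: 18 indices (anchor: eflanker_rt_diff_emotional_vs_neutral_target)
  group 3: 21 indices (anchor: eflanker_acc_overall)
E-scores computed: 3 (escore1, escore2, escore3) for 66 participants
age-controlled partial correlations (9 tests, BH-FDR adjusted):
  * escore1 ~ cesdc: r=+0.418 (p_fdr=0.0012, n=66)
  * escore1 ~ staich: r=+0.312 (p_fdr=0.0206, n=66)
    escore1 ~ kars: r=+0.011 (p_fdr=0.9329, n=66)
    escore2 ~ cesdc: r=+0.238 (p_fdr=0.0723, n=66)
  * escore2 ~ staich: r=+0.478 (p_fdr=0.0005, n=66)
    escore2 ~ kars: r=+0.043 (p_fdr=0.8258, n=66)
  * escore3 ~ cesdc: r=-0.287 (p_fdr=0.0307, n=66)
  * escore3 ~ staich: r=-0.446 (p_fdr=0.0008, n=66)
  * escore3 ~ kars: r=-0.439 (p_fdr=0.0008, n=66)
```

Reading: of 78 simulated children, 12 disengaged during one of the three
tasks and were excluded. The feature grouping was fully stable under
leave-one-out refits (every index kept its group). Higher E-score 1
(slower responding) tracks the depression scale, higher E-score 2
(emotional interference) the internalizing scales, and lower E-score 3
(accuracy) the ADHD scale — the planted effect structure. At n = 66 the
individual partial correlations scatter around their population values
(≈ 0.29 for depression–speed, ≈ 0.45 for the E-score 2 pair, ≈ −0.33 for
ADHD–accuracy), so in any one cohort of this size some of them cross the
FDR threshold and others narrowly miss it, exactly as the power analysis
predicts; the parameter-recovery test in `tests/test_acceptance.py` shows
the patterns are recovered reliably at n = 200.

Each stage is also available as a library call (`simulate_cohort`,
`build_feature_matrix`, `derive_escores`, `association_battery`) and as a
separate subcommand (`validate`, `extract`, `escore`, `associate`).

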