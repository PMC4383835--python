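# Methods

## Diary model

A diary day is an ordered sequence of 96 slots; slot *i* covers the half-open
clock interval [15·i, 15·(i+1)) minutes after 00:00. The anchoring is a
convention only: every metric the package computes is invariant to where the
day starts. Each slot holds one activity code resolved against a compendium,
or is missing. A participant contributes one weekday and one weekend day and
enters analysis only when all 192 slots are filled (`filter_complete`); a
single missing slot invalidates the participant, and nothing is imputed.
Day type is taken from the input label, not from calendar dates —
respondents of such surveys choose which days to record.

## Compendium

The compendium maps each activity code to a label, a MET intensity in
[0.9, 18.0], one of four reported behaviour categories — household,
transportation, work, leisure/sports — or the internal fifth category
`uncategorized`, and a free subcategory tag (e.g. `work_standing`,
`commute_walk`). `uncategorized` holds sleep (MET 0.9 by compendium
convention) and personal care/meals: these count toward total MET but never
toward the four category totals, which is why category minutes sum to well
under 1440 per day. The packaged fixture has exactly 91 activities in the
four reported categories, with labels and intensities following standard
compendium conventions. It is a constructed stand-in for any site-specific
menu — no published list exists for the instrument it emulates — and is fully
replaceable through the CSV interface (`code,label,category,subcategory,met`).

## Scoring

Per day: mean MET = (Σ m_i)/96; MET-hours = 0.25·Σ m_i; MVPA = 0.25·Σ m_i
over slots with m_i ≥ 3.0. The threshold is inclusive and the **full** MET
value of a qualifying slot is summed (not MET−1 net); this keeps MVPA in the
same MET-hours units as the totals. Weekly values combine the two days as
(5·weekday + 2·weekend)/7, applied field-by-field (the weighting is linear,
so weighting each metric equals scoring a 5+2 mixture of days). A 10-minute
activity is necessarily recorded as a 15-minute slot; that granularity bias
is inherent to the instrument and deliberately not corrected.

Distribution summaries use the n−1 SD and linear-interpolation percentiles
(numpy's default), stated so results are bit-reproducible. A single-row table
reports SD 0 with `sd_defined=False`.

## Inference layer

- **ANOVA**: classic between/within decomposition (scipy). A summary-statistic
  variant recomputes the identical F from per-group means, SDs and sizes so
  printed tables can be checked without raw data.
- **ANCOVA**: OLS of outcome on group plus covariates (categorical covariates
  reference-coded, reference = first observed level); the group test is the
  partial (type II) F. Adjusted means are model predictions averaged over the
  observed covariate rows with the group forced to each level in turn — the
  least-squares-means convention at observed margins. Rows with missing
  covariates are listwise-dropped and counted (`n_dropped`).
- **Two-way interaction**: outcome ~ A*B + covariates, interaction partial F;
  an empty factor cell is an error.
- **Tukey HSD** uses the studentized range with the Tukey–Kramer unequal-n
  rule (statsmodels), two-sided, family-wise α = .05.
- **Chi-square**: Pearson, no continuity correction, df = (r−1)(c−1).
- **Standardized regression**: OLS on raw scales for R² and SEE (residual SD,
  outcome units, denominator n−p−1); βs are slopes after z-scoring outcome and
  predictors, so with one predictor β equals the Pearson correlation.
  No multiplicity correction is applied across outcome families beyond Tukey
  within a factor.

Simulation checks (seeded, in the test suite) show all three group tests
reject at the nominal 5% rate under a null-configured generator, and the
interaction test detects a one-sex-only area effect with power above 0.8 at
cohort-scale n.

## Synthetic cohort generator

The generator emulates a 2046-person diary survey of Japanese adults aged
30–59 across three residence strata (urban 46.4%, urban-rural 21.1%, rural
32.5%), two diary days per person. Covariates (sex, age band, occupation,
household income, marriage, exercise habit, weight, BMI) are drawn from
stratified categorical distributions taken from the survey's population
table; occupation is sex-conditional so that housewife categories fall to
women, and independence is assumed within strata where joint margins are
unpublished.

Each diary day is built from contiguous blocks, because observed subcategory
times (e.g. ~45 min of transit riding) imply contiguous behaviour rather than
i.i.d. slots:

1. a sleep block wrapping midnight (truncated-normal duration, rounded to
   15-minute multiples, 2–6 slots placed before midnight);
2. morning routine and main meals (personal care);
3. for those who work that day (occupation- and day-type-dependent
   probability): commute legs by a per-person mode (walk / transit+walking
   access / car / cycle), and a work block split into sitting / standing /
   vigorous / walking segments by the person's latent job type (office,
   standing, manual — mixes differ by area and sex, which is what creates the
   urban–rural contrast in standing work);
4. household tasks (cooking, cleaning, laundry, shopping, childcare,
   gardening, car washing) with sex- and day-type-dependent rates; women's
   cleaning/childcare/gardening rates rise with rurality;
5. non-commute errand/outing trips with area-dependent mode shares (walking
   dominant in the urban stratum, car in the rural one);
6. an optional sport session (probability conditioned on the exercise-habit
   covariate); and
7. low-intensity leisure filler tiling the remaining waking slots.

If requested blocks exceed the waking day, discretionary blocks are truncated
proportionally (largest-remainder integer split) before work and commute are
touched. Per-person latent draws (job type, commute mode) persist across both
days. Randomness flows from a single seed through a named substream per
participant (`default_rng([seed, i])`), so regenerating with a larger n
leaves earlier participants byte-identical. Optional incompleteness masks
1–96 random slots in one (or, 30% of the time, both) diaries of a
Bernoulli-selected subset, exercising the completeness filter.

### Calibration

The packaged default configuration (n = 2046, seed 20120712) was fitted by
coarse manual search **only over schedule-level knobs** — job-type mixes,
segment fractions, durations, mode shares, task rates — against the published
population marginals: overall mean MET 1.60, MVPA median 7.92 MET-hours/day,
per-stratum total MET-hours/day (37.9 / 38.8 / 39.1), rural-men MVPA 10.8,
urban walking-commute minutes, and the orderings (total activity rising, and
transportation activity falling, with rurality). `calibration_report`
regenerates the cohort and tabulates observed-vs-target deviations with the
tolerances listed in `CALIBRATION_TARGETS`; all pass for the packaged
configuration, and the orderings were additionally verified across several
independent seeds. Summary statistics are never drawn directly, so the
generator and scorer form a genuine round-trip: the published marginals are
recovered only if scoring, weighting and decomposition are correct.

### What the generator does and does not emulate

It reproduces first-order population marginals and the stratum contrasts
listed above. It does **not** attempt: realistic within-person day-to-day
correlation beyond shared latent job/commute draws, seasonality or weather,
joint covariate structure beyond published margins, recall error, or the
self-selection of an internet panel. Mean-MET spread (SD ≈ 0.20 vs the
reported 0.28) is somewhat narrow — real cohorts contain more extreme
schedules than the block grammar produces. Tests passing on synthetic data
therefore validate the pipeline's arithmetic and inferential machinery, not
any substantive claim about a real population.

## Numerical and design choices

- Durations are truncated normals rounded to whole slots; probability menus
  use exact simplex validation (±1e-9).
- The scored cohort table has a deterministic column order: covariates, the
  three headline metrics, category blocks, then subcategory blocks in sorted
  order; subcategories a participant never logged are zero, not missing.
- p-value rendering follows the journal convention "<.001" below .001, three
  decimals below .01, two otherwise, leading zero stripped; CSVs always carry
  raw floats.
- Problem sizes in the test suite: the calibration round-trip runs at the
  full study scale (n = 2046); type-I calibration uses 500 replicates of
  n = 300, chosen as the smallest scale at which the F statistics' null
  distributions are indistinguishable from nominal in pilot runs.

## Known limitations

- ANCOVA adjusted means use observed-margin g-computation; software using
  different EMMEANS conventions can differ in unbalanced designs.
- The completeness rule is the strictest reading ("both days fully filled");
  surveys that salvage partially filled days will retain more participants.
- MVPA sums full MET per qualifying slot; net-MET (MET−1) MVPA would be
  systematically lower and is not offered.
- The compendium fixture's MET assignments are conventional, not measured;
  substantive analyses must supply their own compendium CSV.
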