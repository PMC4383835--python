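# metdiary

Scoring, simulation and cohort statistics for **15-minute activity diaries
rated in metabolic equivalents (MET)**.

Web-based activity-record systems ask a participant to recall one weekday and
one weekend day in 96 slots of 15 minutes, choosing each slot's behaviour from
a fixed menu of coded activities. Each activity carries a MET intensity (a
multiple of resting metabolic rate), so a completed diary becomes two 96-value
MET series from which daily energy and behaviour profiles follow. `metdiary`
implements that pipeline end to end for epidemiologists working with such
diaries: a validated activity→MET compendium, diary data structures with a
strict completeness rule, the scoring formulas, the inferential layer used in
regional cohort comparisons, and a calibrated synthetic-cohort generator so
the whole pipeline is testable without access to any survey's raw data.

## The quantities computed

For a complete day with slot intensities $m_0,\dots,m_{95}$:

- **24-hour mean MET** $= \frac{1}{96}\sum_i m_i$, and
  **MET-hours/day** $= 0.25\sum_i m_i = 24\times\text{mean MET}$;
- **MVPA** (moderate-to-vigorous physical activity, MET-hours/day)
  $= 0.25\sum_{i:\,m_i \ge 3} m_i$ — the slot sum restricted to intensities of
  at least 3 MET, threshold inclusive;
- behaviour decompositions: minutes and MET-hours per category (household,
  transportation, work, leisure/sports) and per subcategory (standing work,
  walking commute, cooking, …).

Every weekly metric combines the two recorded days as

$$\text{weekly} = \frac{5\times\text{weekday} + 2\times\text{weekend}}{7}.$$

The statistics layer provides one-way ANOVA (raw and from printed
means/SDs/ns), one-way ANCOVA with least-squares adjusted means, the sex×area
two-way ANCOVA interaction, Tukey–Kramer multiple comparisons, Pearson
chi-square for contingency tables, and multiple regression with standardized
coefficients (βs) of MVPA on behaviour subcategories.

## Worked example

```python
from metdiary import (default_compendium, default_config, generate_cohort,
                      score_cohort, distribution_summary, one_way_anova,
                      standardized_regression)
from metdiary.report import REGRESSION_BEHAVIORS

comp = default_compendium()                 # 91 coded activities + sleep/personal care
cohort = generate_cohort(default_config())  # synthetic 2046-person cohort, seeded
table = score_cohort(cohort, comp)          # one row of weekly metrics per person

s = distribution_summary(table, "mean_met")
print(f"n={s.n}  mean MET={s.mean:.2f} (SD {s.sd:.2f})")

r = one_way_anova(table, "met_hours", "area")
print(f"total activity by area: F({r.df_between},{r.df_within})={r.f_stat:.2f}")

res = standardized_regression(
    table, "mvpa_met_hours",
    [f"sub_met_hours_{b}" for b in REGRESSION_BEHAVIORS])
print(f"R2={res.r_squared:.2f}, SEE={res.see:.2f}")
```

prints

```
n=2046  mean MET=1.58 (SD 0.20)
total activity by area: F(2,2043)=7.18
R2=0.92, SEE=2.04
```

i.e. the synthetic cohort averages 1.58 MET over the day, total activity
differs across residence strata (urban lowest), and ten behaviour
subcategories explain 92% of the variance in MVPA — with standing work the
dominant standardized coefficient (β = 0.73).

The same pipeline is available from the shell:

```bash
metdiary all --out out/          # generate → validate → score → analyze → report
metdiary generate --n 500 --seed 7 --out out/   # or stage by stage
```

`out/` then holds the diary and covariate CSVs, per-participant scores, the
characteristics and region-comparison tables with their tests, the regression
table, distribution histograms, and a run manifest with input hashes.

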