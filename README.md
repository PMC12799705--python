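# dentage

Dental age estimation from tooth-development staging, with
population-specific calibration of the reference tables.

## The problem

In forensic odontology, pediatrics and orthodontics, a child's
*chronological age* (CA) is often unknown or disputed, while a panoramic
radiograph of their teeth is available.  The most widely used estimation
method stages the mineralization of the seven left mandibular teeth
(FDI 31–37, central incisor through second molar) on an eight-stage ordinal
scale A–H (A = initial crown calcification, H = apical closure), then:

1. looks up a sex-specific **maturity score** `s_i` for each tooth's stage
   from a reference table,
2. sums them into the maturity score `S = Σ_{i=1..7} s_i`, and
3. converts `S` into a **dental age** (DA) through a sex-specific
   conversion table on a 6.0–16.0 year grid in 0.1-year steps.

Reference tables built on one population bias estimates in another, so the
method must be re-calibrated locally: for every (sex, tooth, stage) cell,
the median CA of the children observed in that stage becomes the cell's
score (making `S` a years-equivalents maturity index), per-age-bin median
summed scores are fitted with a monotone four-parameter logistic

    S(a) = A + (K − A) / (1 + exp(−r (a − m)))

and the fitted curve, discretized to the 0.1-year grid, becomes the new
conversion table.  `dentage` ships the published tables for Kosovar
children and adolescents (ages 6–16, both sexes), implements scoring and
conversion against any such table set, re-derives tables from any staged
cohort, quantifies accuracy (DA−CA bias, deviation bands, correlation,
Cohen's kappa between raters), and simulates staged cohorts for testing.
Staging itself — reading A–H off the radiograph — is upstream human work;
stages are always inputs here.

## Worked example

```python
import dentage as d

ref = d.kosovo_tables()                       # bundled reference tables
chart = d.DentalChart.from_sequence(["H", "H", "H", "G", "G", "H", "F"])
subject = d.Subject(id="case-1", sex="F", chronological_age=12.58, chart=chart)

score = d.total_maturity_score(ref.score_table, subject)
print(score.per_tooth)
# {31: 12.2, 32: 12.7, 33: 14.1, 34: 12.1, 35: 12.6, 36: 12.6, 37: 12.0}
print(round(score.total, 1))                  # 88.3
est = d.score_to_age(ref.grid("F"), score.total)
print(est.dental_age, est.clamped)            # 12.27 False
```

The seven stage lookups sum to a maturity score of 88.3 years-equivalents;
on the girls' conversion grid that falls between the 12.2-year row (88.05)
and the 12.3-year row (88.40), interpolating to a dental age of 12.27 —
0.31 years below this subject's chronological age of 12.58.

Calibrating a new population from a staged cohort follows the
statsmodels convention (model → `fit()` → results):

```python
model = d.DentalMaturityModel.from_dataframe(df, population="mypop")
res = model.fit()
print(res.summary())          # stage cells, anchors, logistic parameters
res.save("mypop.json")        # reloadable reference-table JSON
```

The same operations are exposed on the command line:

```sh
dentage simulate --n-per-bin 50 --seed 42 --output sim.csv
dentage calibrate --input sim.csv --population sim-pop --output tables.json
dentage evaluate --input sim.csv --tables tables.json --seed 17 --output report.json
dentage convert --sex F --score 48.06        # -> 6.00
```

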