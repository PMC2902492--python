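# orcurve

Odds-ratio curves over dichotomization cutoffs for continuous exposures.

## The problem

Epidemiological studies routinely dichotomize a continuous exposure — BMI,
blood pressure, a biomarker — at a single cutoff and report one odds ratio
with its 95% confidence interval, as if no other cutoff had been considered.
But the cutoff → OR relationship is a whole curve, and moving the cutoff
within an entirely defensible range can move the estimate from "strong
association" to "negligible association". A reader cannot tell whether the
published cutoff was fixed a priori or shopped for after the fact; selective
reporting of one cutoff/OR pair from the many computed inside a study is a
form of in-study publication bias.

`orcurve` makes the whole relationship computable and auditable. For a
continuous exposure *x* and binary outcome *y* it computes, at every cutoff
*c* on a dense grid, the 2×2 table induced by the convention
*exposed ⇔ x ≥ c*, and the cross-product odds ratio

    OR(c) = a·d / (b·c),   SE(log OR) = √(1/a + 1/b + 1/c + 1/d),
    95% CI = exp(log OR ± 1.959964 · SE)

where *a, b* are exposed cases/non-cases and *c, d* unexposed cases/non-cases.
This is algebraically identical to the MLE of a logistic regression on the
single binary exposure indicator (the test suite verifies the equivalence
against an independent IRLS fit). On top of the curve it implements every
standard cutoff-selection strategy so their consequences can be compared
side by side:

- **theory-driven** rules: scalar, sex-/stratum-specific, and age-band
  cutoffs, evaluated as given;
- **data-driven, association-independent**: exposure mean / median /
  percentile, the case-median ("equal cases") cutoff, the minimum-SE cutoff,
  and the maximum-AUC cutoff (identical to the Youden-J maximizer, since the
  binary-classifier AUC equals (J+1)/2);
- **association-driven**: the cutoff maximizing, minimizing, or nullifying
  the OR — the abusable practice the curve makes visible. These are provided
  for audit, not endorsement: a CI attached to an association-driven cutoff
  no longer has its nominal frequentist coverage, and the package's
  simulation module quantifies exactly that.

## Worked example

Generate a synthetic sample shaped like a large cross-sectional survey
(right-skewed BMI-like exposure, ~46% outcome prevalence), then compare all
selection strategies inside the 25th–75th-percentile cutoff window:

```bash
orcurve simulate --n 19340 --seed 1 --out sample.csv
orcurve select sample.csv --exposure-col exposure --outcome-col case \
    --cutoffs 25,30 --out strategies.csv
```

which prints:

```
       strategy               display
         theory 25.00: 1.7 (1.6, 1.8)
         theory 30.00: 1.4 (1.3, 1.5)
           mean 27.92: 1.4 (1.3, 1.5)
         median 26.95: 1.4 (1.4, 1.5)
     percentile 30.91: 1.3 (1.2, 1.4)
    equal_cases 27.57: 1.4 (1.3, 1.5)
         min_se 27.00: 1.4 (1.4, 1.5)
        max_auc 24.02: 1.9 (1.8, 2.1)
         max_or 23.87: 2.0 (1.8, 2.1)
         min_or 30.45: 1.3 (1.2, 1.4)
closest_to_null 30.45: 1.3 (1.2, 1.4)
```

Each row is `cutoff: OR (95% CI)`. Every cutoff here is defensible in
isolation, yet the same data support anything from 1.3 to 2.0 depending on
which one is reported — and the max-OR and min-OR rows show exactly how far
cutoff shopping can push the estimate within one interquartile window.
`orcurve scan` writes the full curve (cells, OR, CI, SE per cutoff) as a
tidy CSV; `orcurve report` bundles the curve plot with CI band, the ROC
polyline, the AUC-by-cutoff series, and the strategy table.

The curve's tails are intentionally kept: cutoffs near the exposure extremes
produce tiny cells, unstable ORs, and eventually non-estimable (zero-cell)
tables, which the scan carries as flagged points (or Haldane–Anscombe
corrected ones, with `--correction haldane`) so plots can mask them
explicitly rather than hide them.

## Library use

```python
from orcurve import (nhanes_like_fixture, make_window_grid, scan,
                     select_extreme_or)

sample = nhanes_like_fixture(seed=1)
curve = scan(sample, make_window_grid(sample, 25, 75))
print(select_extreme_or(curve, "max_or").effect.format())
```

## Replicating with real survey data (NHANES recipe)

The analysis that motivated this package relates BMI to high total
cholesterol (case ⇔ ≥ 200 mg/dl) in NHANES 1999–2006. Downloading is the
user's responsibility; with the demographic (age, sex), body-measures (BMI)
and total-cholesterol SAS transport files for the four waves on disk:

1. read each wave's files (`pandas.read_sas(..., format="xport")` is what
   `orcurve.io.load_table` uses for `.xpt` paths) and merge on the
   respondent identifier `SEQN`;
2. keep `RIDAGEYR ≥ 18`, drop records missing `BMXBMI` or `LBXTC`;
3. write the merged table to CSV and run, e.g.

```bash
orcurve report merged.csv --exposure-col BMXBMI --outcome-col LBXTC \
    --outcome-threshold 200 --age-col RIDAGEYR --min-age 18 \
    --window 25 75 --outdir nhanes_report
```

Percentile-based cutoffs (the 75th percentile, the window bounds) depend on
the percentile convention; `--percentile-method` accepts any
`numpy.percentile` method if you need to match another package's definition.

## What this package will not do

No survey-design weighting, no confounder adjustment, no measurement-error
correction, no multiple-comparison adjustment, and no recommendation of any
data-driven cutoff as "correct". The pointwise CIs along a curve are valid
only for a cutoff fixed a priori.
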