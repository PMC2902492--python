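# Methods

## Estimand and estimator

For a continuous exposure *x*, binary outcome *y*, and cutoff *c*, define
exposed ⇔ *x ≥ c* (boundary inclusive; fixed, not configurable). The 2×2
table (a, b, c, d) = (exposed cases, exposed non-cases, unexposed cases,
unexposed non-cases) yields the cross-product odds ratio ad/bc with Woolf
standard error √(1/a + 1/b + 1/c + 1/d) on the log scale and a Wald 95%
interval using z = 1.959964. For a logistic model with the single binary
exposure indicator, the MLE of the exposure coefficient is exactly
log(ad/bc) and its Wald SE is the Woolf SE, so the closed form *is* the
logistic-regression estimate; the suite checks this equivalence against an
independently written IRLS fit to 1e-6 relative tolerance. Stored estimates
are never rounded; one-decimal ORs and two-decimal cutoffs appear only in
display layers.

Zero cells make the cross-product ratio or its SE undefined. The default
policy flags such points non-estimable and keeps them in the curve so tail
instability stays visible; the alternative Haldane–Anscombe policy adds 0.5
to all four cells and marks the point `correction_applied`. The choice is
per-call, because full-range plots need the corrected tails while selectors
should not be allowed to pick a corrected extreme silently (curve-based
selectors only consider estimable points).

## Cutoff grids

Grids are arithmetic sequences stored internally as integer multiples of the
increment (default 0.01 exposure units, matching data recorded to two
decimals); real units appear only at the boundary, so an ~11,700-step grid
accumulates no floating-point drift. The full-range grid runs from
min(x)+increment to max(x)−increment. The windowed grid spans two exposure
percentiles (default 25th–75th), computed by numpy's type-7 linear
interpolation; the convention is a parameter (`percentile_method`, any
`numpy.percentile` method) because statistical packages disagree in the last
digit and percentile-based cutoffs inherit that disagreement.

The scan sorts the exposures once and sweeps cumulative case counts with a
binary search per cutoff, so a full curve over ~20,000 records costs
milliseconds; a per-record brute-force tabulation is kept in the test suite
as the oracle and the two paths must agree exactly (identical integer tables,
identical floating-point formulas).

## Selection strategies

Theory-driven rules (scalar, stratum-specific, age-band) are evaluated as
given, in input order, with no selection. Ages falling outside every band of
an age-band rule are assigned to the nearest band with a logged warning —
age-banded guidelines often start at 19 while analytic samples start at 18,
and dropping such records would silently change the sample. Data-driven
selectors: exposure mean/median/percentile; the case-median cutoff (balances
cases across exposure groups to within one when case exposures are
distinct; an even case count uses the midpoint of the central order
statistics); the minimum-SE cutoff over a curve; the maximum-AUC cutoff,
where the per-cutoff AUC is the two-segment trapezoid (sens + spec)/2 — the
c-statistic of the one-binary-predictor model — making it identical to the
Youden-J maximizer; and the association-driven extremes (max OR, min OR,
closest-to-null, the last judged by |log OR| so protective and harmful
departures are treated symmetrically). All argmax/argmin selectors break
ties toward the smallest cutoff and record a tie note. Search-based
selectors default to the 25th–75th-percentile window but accept any grid.

## Synthetic data

The generators emulate a large cross-sectional survey in structure, not in
microdata. Exposure: shifted lognormal, shift 13, log-mean ln 14, log-SD
0.3716, giving mean ≈ 28, median ≈ 27 kg/m²-like units, a long right tail,
and about two-thirds of records at or above 25. Outcome (standard fixture):
logistic in a saturating transform of exposure, P(case|x) =
expit(−5.487 + 0.22·min(x, 25)), calibrated once on a 4×10⁵-draw sample so
case prevalence ≈ 0.46 and frozen in source. The saturation is the modelled
mechanism for an attenuating association: below the knot, risk rises with
exposure, so low cutoffs separate risk groups sharply (OR ≈ 1.9–2.0 near the
25th-percentile cutoff); above it risk is flat, so high cutoffs split within
a homogeneous-risk region and the OR falls toward ≈ 1.2 at the
75th-percentile cutoff. The windowed OR curve is therefore monotone-ish
decreasing — the qualitative pattern of interest — though its high end
flattens near 1.2 rather than reaching 1.1: with this mechanism and 46%
prevalence, pushing the high-cutoff OR lower would also drag down the
low-cutoff OR.

What the fixture does *not* emulate: survey design (clustering, weights),
covariate structure (age/sex confounding), measurement error, and the
extreme observed exposure maxima of real data (its max is ≈ 75–80 rather
than 130). Tests passing on the fixture therefore demonstrate the
*machinery* — estimation, scanning, selection, diagnostics — under realistic
marginals, not any substantive claim about real BMI–cholesterol data.

Threshold outcomes (step risk p_low → p_high at τ) provide a known
ground-truth OR, (p_high/(1−p_high))/(p_low/(1−p_low)), for recovery and
coverage experiments; null outcomes (constant p) provide the
no-association reference.

## Selection-bias experiment

`pbis_experiment` draws replicate samples, scans the windowed curve in each,
and records the window-maximized and -minimized ORs alongside the OR and CI
at a fixed, pre-registered cutoff (an exposure value or the per-replicate
median). Replicate *r* seeds its generator from `SeedSequence([seed, r])`,
so runs are reproducible and replicates independent regardless of execution
order. Under a null model the fixed-cutoff CI covers OR = 1 at its nominal
95% rate while the selected extremes bracket 1 on average — the
quantitative form of the bias that motivates presenting whole curves. The
default experiment grid uses a 0.05 increment: selection inflation and
coverage are insensitive to grid resolution well below the sampling noise
of the cutoff statistics involved, and the coarser grid keeps 500-replicate
runs in seconds.

## Numerical and interface choices

- Curve CSVs are written with `%.17g` and read with pandas'
  `float_precision="round_trip"`, so export → import is bit-identical.
- Non-estimable points serialize as empty (NaN) numeric fields with
  `estimable=False`; re-ingestion restores the flags.
- SAS transport (XPT) input delegates to `pandas.read_sas`; delimited input
  treats `#`-prefixed lines as comments (the sample writer records its
  generating config there).
- Plots default to SVG; the OR-curve plot masks non-estimable spans and
  returns them in its metadata, and marks corrected points distinctly.
- Problem sizes in the replicated experiments (500 null replicates of
  n = 1,000; 100 threshold replicates of n = 50,000) were chosen so binomial
  noise on the reported rates is small relative to the effects being
  demonstrated.

## Known limitations

No covariate adjustment, survey weighting, exact (conditional) intervals,
risk ratios, simultaneous confidence bands, or curve smoothing. The
pointwise CIs along a curve assume a single a-priori cutoff; no
multiple-comparison adjustment is applied, deliberately — the package's
point is to expose, not launder, the multiplicity.
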