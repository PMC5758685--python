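# Methods

## The LMS growth-reference engine

A reference table is a grid of `(age, L, M, S)` rows: `M(t)` the median,
`S(t)` the coefficient of variation, `L(t)` the Box-Cox power that
removes the age-specific skewness of the measurement distribution.
Conversion of a value `x` at age `t`:

    z = ((x/M)^L − 1) / (L·S)    if |L| ≥ 1e−7
    z = ln(x/M) / S              otherwise (the L → 0 limit)

with `L`, `M`, `S` each interpolated **linearly in age** between grid
rows — the convention of the standard LMS software.  The branch switch at
`|L| < 1e−7` is continuity-tested: the two formulas agree to ~1e−4 in z
at `|L| = 1e−5` and the log branch is the analytic limit.  The inverse is
`x = M(1 + L·S·z)^(1/L)` (or `M·e^{S·z}`); for `L·S·z ≤ −1` the inverse
leaves the measurement domain and the error message reports the
admissible z bound.  Round-trip identity holds to 1e−9 over `z ∈ [−4, 4]`
across the grid (property-tested).

Two deliberate strictnesses:

* **no extrapolation** — an age outside the grid raises an error rather
  than clamping, because clamped SDS near the grid edge silently biases
  exactly the youngest and oldest records an audit cares about;
* **gestation in completed weeks** maps to `week + 0.0` on the
  birthweight grid (no mid-week offset), since cohort gestations are
  recorded as integers.

### Synthetic references

The packaged tables are synthetic stand-ins, not redistributed national
data.  The female height-for-age table (ages 1–21 y) uses hand-anchored
medians that track the shape of a northern-European girls' chart, with
`L = 1` and constant `S = 0.037`; the birthweight-for-gestation table
(24–44 weeks) similarly uses `L = 1`, `S = 0.13`.  With `L = 1` the
reference distribution at each age is exactly `Normal(M, M·S)`, so every
expected value in the test-suite has a closed form — e.g. at age 20,
`M = 163.7` cm and SD `= 6.057` cm, and the MPH→LTR SDS gap is exactly
`−8.5/(163.7·0.037) = −1.4034`.  Real analyses substitute national LMS
tables via `read_lms_table` (CSV, header `age,L,M,S`).

## Parental targets

For a daughter: `MPH = (mother + father − 12.5)/2` cm and
`LTR = MPH − 8.5` cm, where 12.5 cm is the mean adult sex difference in
height and 8.5 cm is taken as two SDs of adult female height.  Both
constants are arguments with these defaults, because the Tanner-derived
target-height system has published variants.  MPH and LTR are converted
to SDS at the adult reference age of 20 years (configurable for
references whose grids end elsewhere).

Parental heights carry provenance (`measured` / `reported` / `missing`).
The target-range *completeness* stratifies analyses: `both_measured`,
`one_measured` (one measured, the other reported), `both_reported`, and
`insufficient` (any height absent — the target range then has no numeric
fields and callers must branch).  A separate audit helper counts how many
parents were actually measured, which is the service-quality question
(e.g. 94/37/41 of 172 → 54.7%/21.5%/23.8% under round-half-even; a
truncating formatter mode is available for comparison with reports that
chopped to 54.6).

Only the combined daughter formula is implemented; no boys' variant is
offered rather than guessed.

## Classification and sensitivity tables

All threshold comparisons are **strict**: `short_population ⇔ Ht SDS <
−2` (a girl at exactly −2.00 belongs to the not-short group) and
`below_family ⇔ Ht SDS < LTR SDS`.  Age bands follow the audit
convention `1–5 / 5.1–10 / 10.1–16` years, implemented as `(1, 5]`,
`(5, 10]`, `(10, 16]`; ages over 16 are `out_of_band` and excluded from
the banded table.  Records measured at or before 1 year raise an
excluded-record signal that the pipeline logs with a reason — never a
silent drop — and the run manifest reconciles
`input = analysed + excluded` exactly.

Percentages are displayed with **round-half-to-even**, integer for
table-style percentages and one decimal where a figure is conventionally
quoted with one (82.6, 26.7, 1.6).  This rule is pinned by tests because
several familiar figures depend on it: 78/92 → 85, 87.5 → 88,
13/800 → 1.6.

Birthweight cut-off sensitivity counts `BW SDS < c` for each cut-off
(default −2, −1.5, −1) over the records with birthweight data, after
excluding implausible outliers (`|BW SDS| > 3` by default, e.g. a
grossly oedematous preterm birthweight); outlier exclusions are logged
separately in the manifest and shrink only the birthweight denominator,
not the height analysis.

The `crude_screening_yield` calculator formalises the national
back-of-envelope: `n_short = births × female_fraction × centile/100`
(by definition of a centile), `n_ts = births × female_fraction ×
prevalence`, PPV = `n_ts/n_short`.  Its compatibility mode rounds
`n_short` to the nearest hundred and `n_ts` to an integer before the
division, the way such figures are quoted (800, 13, 1.6%); exact mode
keeps the raw expectations (807.03, 13.45, 1.67%).  The quantity is a
positive predictive value — the fraction of screen-positives truly
affected — and is labelled PPV throughout, although informal accounts
sometimes call it a specificity.

## The synthetic cohort generator

No patient-level Turner cohort is publicly deposited, so the generator
emulates the statistical structure the analysis assumes.  Per girl:

* **age at first accurate measurement** ~ truncated Normal(7.05, 4.05²)
  on [1.31, 18.5] years;
* **parental heights** ~ Normal(160.0, 6.9²) cm for mothers,
  Normal(175.5, 7.0²) for fathers, independent;
* **latent height SDS**
  `z = 0.4·MPH_SDS + deficit(age) + karyotype_offset + ε`,
  `ε ~ Normal(0, 0.76²)`, where `deficit(age)` is piecewise linear —
  constant −2.11 SDS until age 4, then declining at −0.12 SDS/year —
  the simplest shape consistent with the Turner growth narrative
  (low-normal velocity for the first 3–4 years, falling away
  thereafter); the mosaic karyotypes 45,X/46,XX and 45,X/47,XXX get a
  milder offset of +0.7 SDS.  The recorded height in cm is the inverse
  LMS transform of `z` at the girl's age, so the pipeline's re-derived
  SDS recovers the latent value;
* **karyotype** drawn from the census of a 94-girl clinic stratum
  (45,X 34/94, 45,X/46,XiXq 17/94, …);
* **birthweight SDS** ~ Normal(−0.91, 1.1²) converted to grams at a
  gestation drawn from a discrete 27–44-week distribution centred on
  39–40; birth data present with probability 0.79;
* **parental measurement provenance**: both/one/neither measured with
  probabilities 94/172, 37/172, 41/172; when one parent is unmeasured it
  is the father 97% of the time, and an unmeasured height is *reported*
  (rather than absent) with probability 0.37, perturbed by the
  configured biases — fathers over-report by 2.5 cm, mothers
  under-report by 2.5 cm.

One `numpy` Generator seeded per call drives everything; identical
config + seed gives byte-identical cohorts, and config invariants
(probabilities summing to 1, positive SDs) are validated before any
sampling.

### Calibration

The defaults were solved analytically so the model's expectations equal
the cohort statistics the analysis is designed around: mean Ht SDS
−2.63 (SD 0.94) and mean LTR SDS −1.77 (SD 0.81).  With `L = 1` at age
20 the cm→SDS map is affine, so `MPH_SDS ~ Normal(−0.363, 0.811²)` and
`LTR_SDS = MPH_SDS − 1.403` follow in closed form; the deficit intercept
(−2.11) and residual SD (0.76) then solve the two moment equations given
the truncated-normal age moments (`E[(A−4)⁺] = 3.852`,
`Var[(A−4)⁺] = 10.21`).  `expected_statistics` recomputes these
expectations from any config at run time, including the below-LTR rate:
conditional on age and karyotype, `Ht SDS − LTR SDS` is Gaussian, so
`P(below) = Φ(−gap/σ)` integrated over the age distribution and summed
over the karyotype mix (≈ 0.804 at the defaults).  Parameter-recovery
tests compare 10 000-girl Monte-Carlo cohorts against these oracles
within 3 standard errors.

The parent–child coupling of 0.4 is a modelling choice — the clinical
literature documents that childhood height in Turner syndrome is
influenced by parental height but gives no regression coefficient for
this cohort — and is exposed in the config like every other parameter.

### What the generator does and does not emulate

It reproduces the *cross-sectional* joint structure (age, family,
karyotype, height SDS, birthweight, provenance) but not longitudinal
growth curves, secular trends, assortative mating (parents are drawn
independently, so mid-parent variance is slightly high for given
parental SDs), referral bias, or any comorbidity structure.  Passing
tests therefore demonstrate that the pipeline's arithmetic and the
generator's self-consistency are correct — not that real clinic data
would show these exact sensitivities.  One known directional caveat: in
the generator, an over-reported father height *raises* the apparent LTR
and hence the LTR−Ht gap in the one-measured stratum, whereas clinic
reports have shown a smaller gap in that stratum; published stratum
means confound reporting bias with group composition, and the generator
models only the mechanism (bias on reported heights), not the
composition effects.

## Numbers the documentation quotes

Published accounts of this analysis contain small internal
inconsistencies, which this package surfaces rather than adjudicates:
the overall below-LTR count is quoted both as 78/92 (85%) and as a
76/92 (83%) table row; the 1–5-year band appears both as 71% (27/38)
and 74% (28/38); and a cohort mean age appears as both 6.93 ± 3.9 and
7.05 ± 4.05.  The package always computes percentages from the counts it
is given; the fixed-count acceptance tests assert each published figure
from its own printed contingency.  Likewise the birthweight denominator
135 (136 with data minus one outlier) is the default because it
reproduces the quoted 26.7%; the alternative is a config choice.

## Problem sizes and runtimes

Property suites run at hundreds of Hypothesis examples; Monte-Carlo
checks use 10 000-girl cohorts (≈ 1 s to simulate and analyse) with
3-standard-error bands, and the acceptance-level calibration check uses
5 000 girls with a ±0.05 band on the mean Ht SDS (analytic mean
−2.628, Monte-Carlo SE 0.013).  The whole suite completes in a few
seconds on one CPU.
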