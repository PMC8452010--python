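# Methods

## Model and assumptions

The package implements a deterministic, point-estimate exposure model. Per
source *i* with per-capita consumption *q<sub>i</sub>* g/day and salt
fraction *f<sub>i</sub>*:

- salt intake: `salt_i = q_i · f_i` (household salt has *f* = 1);
- iodine intake: `iodine_i = salt_i · c · r · a_i`, with *c* the salt iodine
  concentration (mg/kg; g salt × mg/kg = µg, so no additional unit factor),
  *r* the retention factor, *a<sub>i</sub>* the iodized fraction of the
  source's salt;
- scenarios: a `potential` mode forces *a<sub>i</sub>* ≡ 1; a `salt_scale`
  factor multiplies every `salt_i` uniformly.

Assumptions inherited from this modelling tradition, and their consequences:

- **Coverage as an iodized fraction.** The share of households using salt
  iodized to at least the legal minimum (e.g. 78 % nationally in Sri Lanka)
  is treated as the fraction of household salt iodized at exactly the
  standard midpoint; non-covered salt contributes zero iodine. This is a
  simplification — real coverage is a distribution over concentrations — but
  it makes the "a" factor uniform across household salt and foods.
- **Uniform reduction.** Salt-reduction scenarios scale all sources by one
  factor; per-source factors could be represented by editing the consumption
  vector, but the default models an evenly applied policy target.
- **Linearity.** Everything downstream of consumption is linear, so a
  reduced result equals the unreduced result times the factor, field by
  field; this identity is property-tested to machine precision.
- **National ≠ weighted provinces.** The national row is computed from the
  national profile's own inputs (its own survey estimates), never as a
  population-weighted average of the provincial rows, since published
  national consumption estimates are generally derived independently.

## Parameters

| parameter | units | default | why |
|---|---|---|---|
| `iodine_mg_per_kg` | mg iodine / kg salt | 22.5 | midpoint of the 15–30 mg/kg legal iodization range; a policy lever, so configurable |
| `retention` | fraction | 0.7 | WHO estimate of 30 % iodine loss from production to consumption |
| `ear_ug`, `rni_ug`, `ul_ug` | µg/day | 95, 150, 600 | iodine reference values for non-pregnant adults |
| `who_salt_max_g` | g/day | 5 | WHO recommended maximum salt intake; display only |
| `salt_scale` | factor | 0.7 in the reduction scenario | WHO 30 % salt-reduction target |
| `days_per_month` | days | 30 | divisor converting monthly household quantities to daily |

## Survey aggregation

Per-capita daily consumption = monthly household quantity / household
members / 30. District central estimates use the arithmetic mean (a median
option exists behind `statistic="median"`; surveys of this kind report both,
and the mean is the figure typically carried forward). Provincial estimates
are population-weighted means of district estimates. Households with missing
or sub-1 size are excluded with a logged count, never imputed. A
directly-supplied national figure takes precedence over the derived
population-weighted one, which is logged for comparison.

## Synthetic data generator

`generate_households` emulates the structure of a national nutrition /
household income-expenditure survey: districts with populations, households
with sizes drawn from a discrete distribution over 1–8 (mode 4, typical of
South Asian households; configurable up to size 10), and monthly quantities
equal to `target × size × 30` times multiplicative gamma noise with mean 1
and configurable CV (gamma keeps quantities non-negative; household surveys
provide no standard household-level distribution, so a two-parameter
non-negative family with an interpretable CV was the natural choice). Ground
truth is returned (and written to `truth.csv`) alongside the records so tests
never re-derive it.

What it does **not** emulate: survey non-response, cluster sampling and
design weights, reporting heaping, seasonal variation, or within-household
allocation. Passing recovery tests therefore show the aggregation arithmetic
is correct under idealized sampling, not that real surveys are unbiased.

## Numerical choices

- **Full precision internally, half-up rounding at presentation** (salt to
  one decimal, iodine and percents to nearest integer). Percent-of-reference
  values are computed from *unrounded* µg totals: 165.6585/95 → 174 %, which
  is not recoverable from the rounded 166. Half-up (not banker's) rounding
  is used because it reproduces every printed cell of the published tables;
  values are routed through their shortest decimal repr so decimal-literal
  half-cases (0.45, 0.15) round the way a reader expects.
- **Totals are rounded sums of unrounded components**, never sums of rounded
  components (Western province: components print 7.1 + 0.5 + 1.6 + 0.1 = 9.3
  but the true total 9.248 prints 9.2). Regression-tested.
- One knock-on effect of the unrounded-percent rule: for the Eastern
  province under the 30 % reduction the EAR percent computes to 107 %
  (101.36/95), where an analyst rounding the µg value first (101/95) would
  print 106 %. The package consistently uses unrounded totals.
- CSV results are stored at full float precision and read back with pandas'
  `round_trip` parser, so write-then-read is exact.
- Validation rejects negative or NaN inputs at construction/load time;
  nothing is clamped silently. Missing region-level food consumption falls
  back to the national value with a logged message.
- Degenerate inputs: empty districts, zero-population provinces, duplicate
  region or food names, and missing scenarios at render time all raise typed
  errors (`AggregationError`, `ConfigurationError`, `RenderingError`).

## Problem sizes

The built-in assessment is nine provinces plus a national aggregate, four
sources, three scenarios — milliseconds to run. Synthetic-recovery tests use
500 households/district at CV 0.2 (estimates checked within 3 standard
errors of truth) and a 50-vs-5000 household convergence check; the full
suite runs in a few seconds.

## Known limitations

- Point estimates only: no uncertainty intervals or Monte-Carlo propagation.
- No adult-male-equivalent adjustment; per-capita values treat all household
  members alike, so comparisons against adult reference values are
  approximate.
- Iodine status (urinary iodine) is outside scope; the model covers intake
  from the enumerated salt sources only, and real diets include other iodine
  sources (other processed foods, food eaten outside the home, drinking
  water in some areas).
- The coverage-as-fraction simplification above means provinces with salt
  iodized below/above the midpoint are mis-weighted in an unknowable
  direction.
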