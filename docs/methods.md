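# Methods

## Model

The Exposure Hazard Index scores each enterprise×chemical pair as
`EHI = TI × EI × PDI` and sums over the enterprise's chemicals. The
additivity assumption means no synergy or antagonism between
co-exposures is modelled; it makes the enterprise score linear in its
exposure list (duplicating a chemical row exactly doubles its
contribution), which the tests exploit.

Two rating schemes coexist:

| index | original (categorical) | corrected (continuous / expert-calibrated) |
|---|---|---|
| TI | 8 OEL-TWA bands, ratings 1…128 | `K₀·2^(−log₁₀ OEL)`, K₀ ≈ 17.88 |
| EI | 0.30 / 0.60 / 1.00 at <2 h, 2–4 h, ≥4 h | `a·ED + b` clamped to [0, 1]; a ≈ 0.00240 /min, b ≈ −0.0085 |
| MI | 0.25·N | lookup {0.18, 0.39, 0.60, 0.81, 1.00} for N = 0…4 |
| PI | {0, 0.20, 0.30, 0.50, 0.80, 1.00} | lookup {0, 0.18, 0.42, 0.61, 0.74, 1.00} |

Band boundaries in the original TI table are lower-exclusive /
upper-inclusive (e.g. 100 ppm ≥ OEL > 10 ppm → 4); exactly 100 ppm rates
4 and exactly 10 ppm rates 8. Durations are stored in minutes; the hour
thresholds convert as 2 h = 120 min, 4 h = 240 min.

### Effective OEL rules

`effective_oel` resolves an agent's rating concentration: the OEL-TWA
when present; 3× the OEL-Ceiling for ceiling-only chemicals (implemented
literally as specified for the model, although hygiene convention would
usually place a ceiling above a TWA); 0.001 ppm for carcinogens and
chemicals without any OEL. Under the corrected scheme the 0.001-ppm
substitution yields TI ≈ K₀·8 ≈ 143 rather than the categorical 128; a
`ti_pin_carcinogen` switch pins such agents to 128 for users who prefer
the categorical ceiling. OELs are accepted in ppm only; mg/m³ inputs are
rejected rather than converted, as conversion needs a molecular weight
the survey schema does not carry.

### PDI

The published model specifies only that PDI decreases as MI and PI
increase and that full protection should cancel the hazard term. The
default here is `PDI = 1 − (MI + PI)/2`: it is affine, spans [0, 1],
is 0 at MI = PI = 1 and 1 at MI = PI = 0, and weighs management and
engineering protection equally. Two alternatives are selectable through
`CalibrationParams.pdi_formula`: `product_complement`, `(1−MI)(1−PI)`,
which lets either kind of full protection alone cancel the score, and
`sum_complement`, `2 − MI − PI`, which double-counts deficiencies and
can exceed 1 (it is left unclamped; its range is the caller's
responsibility). All downstream code treats PDI as opaque.

## Calibration

The corrected constants derive from a 20-rater expert panel's mean
ratings on a pilot survey of seven enterprises and nine chemicals
(OEL-TWAs 0.005–750 ppm, durations 10–250 min).

- **TI.** `log₂ TI = log₂ K₀ − log₁₀ OEL` is linear with known slope, so
  the least-squares estimate of `log₂ K₀` is the mean of
  `log₂(rating) + log₁₀(OEL)` over the rows — a closed form, exact on
  noise-free data. The default calibration fits K₀ to the published
  *corrected* TI column (K₀ ≈ 17.88), which that column reproduces to
  ±0.02 (±0.1 for the two lowest-OEL rows, where the 2-dp rounding of
  the printed ratings compounds through the exponent). A fit to the raw
  expert means instead gives K₀ ≈ 16.58 and does not reproduce the
  published corrected column, so it is not the default.
- **EI.** Ordinary least squares of the seven expert mean ratings on
  duration (slope 0.00240 /min, intercept −0.0085); a through-origin
  variant is available and both round to the same predictions at the
  10- and 48-min check points. The line extrapolates below 0 near 0 min
  and above 1 past ~420 min, hence the [0, 1] clamp.
- **MI / PI.** The corrected ratings are lookups of the published
  corrected columns. The expert panel rates N = 0 as 0.00 while the
  corrected table keeps a 0.18 floor (some baseline hygiene awareness is
  assumed even with no formal measures), so the linear MI regression
  stored as a fallback for user-supplied tables is fit over N = 1…4 only
  (slope ≈ 0.209, intercept ≈ 0.175, capped at 1.0).
- **Validation.** `validate_against_expert` regresses expert enterprise
  scores on corrected enterprise scores (slope, intercept, R²; R² is
  defined as 0 for a zero-variance response). The published coefficients
  themselves require the per-enterprise expert scores, which were never
  published; the utility is therefore tested by exact-fit recovery on a
  synthetic line and by noisy parameter recovery.

All internal math is full precision; values are rounded (half-to-even,
2 dp) only for presentation.

## Aggregation and prioritization

The industry statistic is the 95th percentile of the industry's
enterprise scores (a `mean` option exists). Percentiles use linear
interpolation between order statistics with rank `h = (n−1)p + 1` (the
"inclusive" method): this is the convention that reproduces all three
published national cutoffs (32.43, 20.61, 10.41) from the 25 published
industry values exactly to 2 dp, where nearest-rank does not. Banding
uses inclusive lower bounds — a statistic exactly at a cutoff takes the
higher-priority band — which yields the published 3/5/5/12 split.
Priorities warn below 4 industries, where percentile cutoffs are
fragile. Per-band index profiles pool all chemical-level TI/EI/MI/PI
values in a band and report mean ± SE (SE = 0 when n < 2) and a
1.96·SE interval.

## Synthetic databank generator

The national databank behind the published industry table was never
deposited, so `ehi.synthetic` generates structurally faithful stand-ins:
the 25 industries with their published enterprise counts (702 total), a
chemical palette of the nine pilot-survey chemicals plus two synthetic
edge-case agents (a ceiling-only chemical and a no-OEL carcinogen, so
both effective-OEL rules are exercised end to end), durations drawn from
{10, 30, 40, 48, 75, 225, 250, 480} min — the pilot survey's observed
10–250 min range extended to a full 8-h shift so both EI clamps are
hit — and categorical draws for N, engineering controls and PPE. Default
mixture weights are mild, survey-plausible choices (most enterprises
handle 1–2 chemicals, implement 1–3 measures, and have at least partial
controls); they are synthetic, not estimates of the real Taiwanese
industry joint distribution.

Each enterprise draws from `default_rng([seed, enterprise_index])`, so
output is bit-reproducible for a seed and appending industries does not
perturb earlier draws. `generate_tiered` mixes the base distributions
toward an extreme profile (longest durations, N = 0, no controls,
1/OEL-weighted chemical choice) for configured high-risk industries with
a strength in [0, 1]; strength 0 reduces exactly to the plain generator.
At the default test strength (0.8) a 100-seed sweep recovered ≥4 of 5
high-risk industries in bands 1–2 in 100/100 runs, which grounds the
seeded recovery test.

What passing tests on synthetic data do **not** show: the generator has
no industry-specific chemical usage, no correlation between toxicity and
duration within an enterprise, and no enterprise-size effects, so
pipeline results on it validate the computation, not the national risk
ranking itself. The national-level numbers are instead reproduced
directly from the published 25-industry statistics.

## Problem sizes and numerics

The test suite and acceptance script run on desk-scale inputs: the
embedded calibration tables (≤ 9 rows each), the 25 published industry
statistics, and synthetic databanks of ≤ 702 enterprises; everything
completes in seconds. Ties at percentile cutoffs are resolved upward by
the inclusive band rule; equal industry statistics all land in band 1.
Degenerate inputs (empty surveys, empty value lists, n < 2 for a sample
SD, single-x regressions) raise typed validation errors rather than
propagating NaNs.

## Known limitations

Inhalation only — OEL-TWAs target airborne exposure, so dermal and
ingestion routes are out of scope, as are STEL-based ratings, acute vs
chronic separation, and mixture synergy. Carcinogens are handled only
through the 0.001-ppm floor. The corrected EI regression is calibrated
on durations up to 250 min; between 250 min and the ~420-min clamp point
it is extrapolation.
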