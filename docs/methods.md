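# Methods

## Estimation formulas

All estimators operate on a patient's sex, height (cm), actual body weight
(ABW, kg) and hematocrit (fraction; default 0.40).

Anthropometric derivations:

- `BMI = weight / (height/100)²`, carried unrounded;
- Devine ideal body weight `IBW = intercept + 0.91·(height − 152.4)` with
  intercept 50 kg (men) / 45.5 kg (women); heights below 152.4 cm
  extrapolate linearly;
- adjusted IBW `AIBW = IBW + 0.25·(ABW − IBW)`, an exact convex
  combination, so `IBW ≤ AIBW ≤ ABW` whenever the patient is above ideal
  weight;
- obesity classes: non-obese (BMI < 30), non-severe (30.0–34.9), severe
  (≥ 35.0). Morbid obesity (≥ 40) is merged into the severe class because
  morbidly obese subjects are sparse in typical apheresis cohorts; the
  merge is the package default and the only mode the pipeline reports.

TBV estimators (registry ids in parentheses):

- Nadler (`nadler_male`/`nadler_female`): `604.1 + 0.0003668·h³ + 32·w`
  (men), `183.3 + 0.000356·h³ + 33·w` (women); evaluated on AIBW in the
  default matrix, as is common apheresis practice for obese patients.
- Lemmens–Bernstein (`lemmens_bernstein`): `70·ABW / √(BMI/22)`. The BMI is
  recomputed internally from raw height and weight so the weight and BMI
  are always self-consistent and unrounded; the formula is restricted to
  the ABW basis for the same reason. At BMI 22 it reduces to 70 mL/kg; above
  22 it predicts strictly less than 70 mL/kg, scaling as √weight at fixed
  height.
- Gilcher's rule (`gilcher_60`/`gilcher_55`): `w · k`. The constants are
  registry configuration (defaults 60/55 mL/kg, the obese-population
  averages; normal-weight averages differ), usable on ABW or AIBW.

The default per-patient matrix is Nadler/AIBW, Lemmens–Bernstein/ABW,
Gilcher/ABW and Gilcher/AIBW, with sex-matched variants; any other matrix
can be configured.

### The standardized-patient convention

The single-patient worked exercise (`hypothetical_patient_tables`) treats
the standardized patient (173 cm, 120 kg) as sexless: a single AIBW is
computed from the **male** Devine intercept (81.5595 kg) and fed to every
formula row, including the female Nadler and Gilcher-55 rows, so the rows
differ only in formula constants. The general cohort pipeline instead uses
the sex-matched Devine IBW per patient. Both behaviors are deliberate; the
convention applies only to the standardized exercise.

## Procedure planning

- Compartments: `RCV = TBV·Hct`, `TPV = TBV·(1 − Hct)`; the two sum back to
  TBV to machine precision.
- Red cell exchange: the default dose model is isovolemic exponential
  depletion — during a continuous exchange the native red cells decay
  exponentially, so reaching a fraction of cells remaining FCR requires
  replacing `RCV·ln(1/FCR)` of red cells. A linear bulk-removal model
  (`RCV·(1 − FCR)`) is selectable for institutions that dose that way; the
  two differ materially (at FCR 30% the exponential model needs ~1.72× the
  linear volume). FCR = 1 plans zero units; FCR = 0 is a domain error
  (infinite exchange). Units assume 200 mL of erythrocytes per RBC unit
  (unit content, not bag volume).
- Plasma exchange: an N-volume procedure replaces `N·TPV`, in 300 mL plasma
  units by default.
- Collections: `multiplier·TBV` (default 5×) processed at a constant flow
  (default 80 mL/min); duration = volume / flow.

### Rounding

Internal quantities are full-precision floats; rounding happens once, at
report time: volumes to integer mL, unit counts to integers, durations to
0.1 h — all **round half up** (12.5 → 13, 12.44 → 12), implemented with
decimal arithmetic on the float's shortest repr to avoid binary-tie
surprises. Unit counts can instead use a conservative ceiling
(`unit_rounding: ceiling`), off by default. Carrying full precision matters
at the margins: 5 × the full-precision Lemmens–Bernstein estimate for the
standardized patient rounds to 31 111 mL, whereas 5 × the display-rounded
6222 would give 31 110.

## Cohort comparison

The pipeline filters to the obese cohort (BMI ≥ 30.0 by default; an
operator flag switches to strict > 30.0 since the boundary convention
varies between sources), splits by sex, and computes:

- **Difference curves**: per-patient `TBV_a − TBV_b` for every formula
  pair, sorted by (BMI, patient id). A difference is *functionally
  significant* when `|Δ| ≥ 500 mL` (inclusive): at hematocrit 40% that is
  ~300 mL of plasma — one plasma unit in a 1.0-volume TPE — and 2–3 L of
  processed volume in a 5–6× collection. The curve is exactly antisymmetric
  under operand swap.
- **Expected-range coverage**: counts of estimates under / within / over an
  empirical plausibility band, inclusive at both bounds (4000–7000 mL for
  obese men, 3500–6500 mL for obese women; bands are configurable). The
  formula with the highest fraction within the band is flagged best
  performing for that sex.
- **Summaries**: per-formula (min, median, max); even-sized cohorts use the
  midpoint of the two central order statistics.
- **Severity-group comparison**: a two-tailed two-sample t test of mean TBV
  between non-severe and severe obesity, per formula and sex. Welch's
  unequal-variance form is the default; the pooled-variance option
  (`equal_var: true`) is the exact equivalent of a Gaussian GLM with a
  single binary class predictor, which is how such comparisons are often
  framed. No covariates are adjusted for. The mean difference is
  severe − non-severe and is flagged against the same 500 mL threshold.
  A class with fewer than two members raises a statistics error (variance
  undefined); the pipeline logs and skips such strata.

## Synthetic cohorts

`tbvtools.synthetic.generate` emulates the cohort structure the pipeline
assumes, not any particular institution's data:

- counts: 58 women, 97 men by default;
- heights: truncated normal per sex (women 163 ± 6.5 cm, men 177 ± 7 cm,
  bounds 145–200 cm) — unremarkable adult anthropometrics;
- BMI: `30 + Gamma(shape 2, scale 2.5)`, truncated at BMI 60 by rejection.
  This gives a right-skewed obese spectrum reaching past 40 with few morbid
  subjects, and an expected non-severe fraction
  `P(BMI < 35) = γ(2, 2)/γ(2, 12) ≈ 0.594`, matching the ~59% non-severe
  mix the analysis targets. Configurations whose implied fraction misses
  the target by more than a tolerance (0.05) are rejected as infeasible
  rather than silently re-tuned;
- weight is derived as `BMI·(height/100)²`, so height, weight and BMI are
  self-consistent to machine precision;
- hematocrit: fixed 0.40 by default, or truncated Normal(0.40, 0.03) on
  [0.25, 0.55];
- fully deterministic under the config seed (one `numpy` Generator drives
  all draws in a fixed order).

What the generator does *not* emulate: real covariance between height and
adiposity, repeat-donor structure, indication mix, age effects, or any
institution's true BMI distribution. Tests passing on synthetic cohorts
therefore validate the pipeline's mechanics and statistical calibration,
not the clinical conclusions one would draw from real data.

`inject_class_shift` gives the severity comparison a recoverable ground
truth: every severe-class subject's weight is shifted by exactly the amount
that moves a stated weight-linear formula's TBV by a chosen Δ (e.g. +600 mL
under Gilcher-60/ABW = +10 kg; on the AIBW basis the ABW shift is 4× since
dAIBW/dABW = 0.25). The Lemmens–Bernstein formula is nonlinear in weight,
so no uniform weight shift exists for it and the request is rejected.

## Problem sizes and calibration checks

The test suite verifies type-I calibration of the severity test (null
cohorts, rejection rate 0.05 ± 0.02 at α = 0.05 over 1000 replicates of
30 + 30), power/recovery for a 600 mL shift with sd 400 at n = 30/30
(power > 0.9, mean recovered difference within ±100 mL over 200
replicates), and exact recovery of an injected 600 mL class shift across
200 generated 155-subject cohorts. These sizes were chosen to pin the
Monte-Carlo error well below the asserted tolerances while keeping the
suite fast.

## Known limitations

- The estimators themselves are decades-old regressions of contested
  accuracy in obesity; this package compares them, it does not validate
  them against measured TBV.
- The exponential RCE dose model is the standard continuous-exchange
  idealization; device-specific kinetics, extracorporeal volume limits and
  anticoagulant handling are out of scope.
- Expected ranges and the 500 mL threshold are empirical conventions
  exposed as configuration, not physiological constants.
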