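# Methods

## Scope and data model

The package analyses 4-day food diaries in which every consumed item carries a
participant id, recording day, clock time on a 15-minute grid, a self-indicated
meal label, a food-group code (27-group codebook), grams, energy (kJ) and
protein (g). Energy is held in kJ throughout; thresholds stated in kcal are
converted at 4.184 kJ/kcal (thermochemical) and the conversion is recorded in
run manifests. Protein E% uses 17 kJ/g; the factor is configurable because
nutrient databases differ slightly.

## Exclusion filters

A participant is excluded when (in precedence order, one primary reason each):
height or weight is missing; no intake was recorded; or mean daily energy over
the *recorded* days falls outside 800–4000 kcal/day (men) or 500–3500 kcal/day
(women). The inequalities are strict, so a woman at exactly 3500 kcal/day is
retained. The mean over recorded days (rather than a day-wise rule) was chosen
so a single feast day cannot eject an otherwise plausible 4-day record.
Exclusion is idempotent.

## Anthropometry

For BMI > 25 kg/m², protein is normalised to the adjusted body weight

    w_adj = w25 + 0.25 (w − w25),   w25 = 25 h²,

which is continuous at BMI 25 and never exceeds measured weight, so using it
never lowers a heavy participant's g/kg value. Daily protein for the ratio is
the mean over recorded days; the adequacy cutoff (1.1 g/kg) is inclusive.

BMR uses the Henry (Oxford) weight-and-height regression equations, shipped as
an editable CSV with three adult bands per sex (18–30, 30–60, 60+), applied to
the adjusted weight. The weight-and-height form was chosen over the
weight-only form because height enters the published requirement calculations;
a weight-only variant is obtained by zeroing the height column of a custom
table. PAL (reported energy/BMR) is computed for description only — no
energy-expenditure modelling or under-reporting correction is attempted.

## Meal patterns

Hour *h* of a day aggregates entries stamped (h−1):30, (h−1):45, h:00 and
h:15; entries at 23:30/23:45 wrap to hour 0 of the *same* day, keeping
recorded days self-contained (days are independent units in a survey of this
design). An hour is an eating/drinking occasion (EDO) when its energy is
strictly above 210 kJ; an EDO is large when it holds ≥ 15 % of that day's
energy (boundary inclusive), otherwise small. Adjacent EDO hours are never
merged. EDO counts are summed per day and averaged over recorded days.

Per-meal protein is the across-day mean of day-level sums by self-indicated
meal (breakfast/lunch/dinner; all other labels pool to "other"; a meal absent
on a recorded day contributes 0 g that day). Bolus attainment tests that mean
against 30 g — participants are counted once per meal, matching the shape of a
per-participant attainment table; per-day flagging would be a different
estimand. The protein CV uses the sample SD (ddof = 1) over the three
main-meal means.

Surplus redistribution is the counterfactual lunch' = lunch + max(0, dinner −
30), dinner' = min(dinner, 30) for dinner above the bolus. It conserves each
participant's lunch+dinner protein exactly, can only raise lunch attainment,
and is idempotent. The lunch-bolus × dinner-bolus association is a Pearson χ²
on the 2×2 attainment table without continuity correction; a zero margin
flags the test as undefined instead of raising.

## Dietary patterns

The pattern matrix holds mean g/day per food group (25 columns; "other" and
"supplements" are excluded as uninterpretable/rare). Because intake
distributions are right-skewed with many structural zeros (most participants
report no legumes or nuts in four days), values are log(x+1)-transformed —
the +1 g offset is the smallest natural unit on the gram scale and maps zero
to zero; the offset is configurable. Columns are then standardised within each
analysis stratum (correlation-matrix PCA): gram scales differ by orders of
magnitude across groups (coffee vs fat/oil), and covariance PCA would be
dominated by beverages. Standardisation is switchable.

Eigenvalues come from the standardised matrix (they sum to the number of
columns); the retention thresholds (> 1.0 graphical, > 1.5 analysis) apply to
pre-rotation eigenvalues, read as extraction criteria. The retained block is
varimax-rotated with Kaiser row normalisation (tolerance 1e-8, ≤ 1000 sweeps);
percent variance per component is reported post-rotation (sum of squared
loadings / number of columns). Each component's largest-|loading| entry is
forced positive so results do not depend on the linear-algebra backend.
Scores are orthogonally rotated unit-variance component scores; adherence
tertiles are computed within sex by stable ranking, earlier tertiles taking
the extra member when n is not divisible by 3 (n=10 → 4/3/3); an all-tied
score column degenerates to tertile 1 with a warning. Zero-variance columns
are dropped with a warning before extraction. Sex strata never share scaling
or loadings.

## Associations

Spearman correlations use average ranks for ties and pairwise-complete
observations; constant variables yield flagged empty cells. The logistic suite
(outcome: meeting 1.1 g/kg) mirrors a three-block design:

* daily block — protein (per 5 g), energy (per MJ), total EDO (per occasion),
  each individually adjusted for age (continuous) + education (two dummies,
  primary reference), then all three mutually adjusted;
* meal block — protein at each meal (per 5 g), four individual models and one
  additive model, every model also adjusted for energy and total EDO;
* dietary-pattern block — each retained score (per score SD), individually and
  jointly, with the same adjustment set.

The adjustment set is printed beside every estimate because the blocks differ
deliberately: the daily individually-adjusted models omit energy/EDO, all
other models include them. CIs are Wald (exp(β̂ ± z·SE)). Perfect separation
is flagged and the model skipped with a diagnostic; non-convergence raises.
No multiple-testing correction is applied, and no causal claims, survey
weights or imputation are in scope.

## Synthetic cohort generator

The generator exists so every stage is testable without survey microdata. Per
participant it draws sex (47 % male), age (mean 68, truncated to 60–80),
height and BMI by sex (BMI 26.5 ± 3.3 men, 25.5 ± 4.1 women; weight = BMI·h²),
education, and a k=3 latent factor vector. Per day it places breakfast, lunch
and dinner at Gaussian clock times (07:30/12:30/18:30, SD ~1 h) snapped to the
15-minute grid, plus Poisson(2.4) snacks between 09:00 and 21:45.

Day-level meal protein is lognormal, moment-matched to the configured mean/SD
(day-level marginal; defaults at the published per-meal scale: e.g. dinner
33.4 ± 15.0 g men, 27.4 ± 11.3 g women; snacks are parameterised per occasion
so daily "other" protein lands at published scale). Occasion energy is
protein × 17 kJ/g ÷ a per-meal protein-E% target (15/18/20/12 %) with
multiplicative lognormal noise — this ties the energy peaks, the 210 kJ EDO
threshold (mean total EDO ≈ 4.7/day with the default snack rate) and the kcal
exclusion bands to the protein process. Items per occasion are drawn from
per-meal categorical mixtures over the codebook (dairy/bread/cereal breakfasts,
meat/fish/vegetable lunches and dinners, coffee/fruit/cake snacks); item grams
scale a participant-level habitual intake exp(μ_g + (Lz)_g + ε) so the planted
loading matrix L (bread/potatoes/cheese; porridge/milk/sugar-jam;
vegetables/fruit) is recoverable by the pattern pipeline (congruence > 0.9 at
n = 500 under default noise). Meal protein is apportioned over items by
protein density × grams. A configurable fraction (default 3 %) has missing
height or weight to exercise the filters. A within-person day-to-day
correlation of meal protein is exposed (default 0, as nothing in the source
data pins it down).

What the generator does **not** emulate — and what passing tests therefore do
not establish about real data: because the configured meal-protein SD is the
day-level marginal and days are independent by default, the across-participant
spread of 4-day meal means is roughly half the day-level SD, compressing
bolus-attainment percentages and cohort-level surplus relative to a real
cohort where stable between-person habits dominate (set `day_correlation`
closer to 1 to move variance between persons). It also ignores seasonality,
weekday/weekend structure, item-level food composition, under-reporting, and
any true association between dietary patterns and protein adequacy (pattern
factors and meal protein are planted independently), so the dietary-pattern
ORs on synthetic data hover around 1 by construction.

`generate_logistic_fixture` provides the complementary planted-coefficient
fixture (iid normal covariates, Bernoulli outcomes through the logistic link)
used to verify estimator recovery and CI coverage.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.default_rng(seed)`; a missing seed
is an error, never a silent default. Generated timestamps are always on the
15-minute grid. Varimax tolerance 1e-8; eigen-decomposition via `eigh` on the
(co)variance of the scaled data (ddof = 1). Tertile ties break by stable input
order. Run directories contain no timestamps, so identical configurations
produce byte-identical tables.

Problem sizes in the shipped tests and acceptance script: cohorts of 150–1000
participants (533 in the acceptance run, the pre-exclusion study size), 1000
random toy days for the EDO oracle comparison, 10 000 participants for the
redistribution properties, 50 seeds for the isotropic-noise PCA control, and
200 replicate fixtures for CI coverage — sizes at which the checked
conditions (laws of large numbers, recovery bounds) are informative while the
whole suite runs in well under a minute per file.

## Known limitations

* The Henry coefficient table is an implementation input; analyses needing a
  different BMR model must supply their own CSV.
* Only 20 of the 27 food-group codes are fixed by the analysis; the rest are
  survey-style placeholders and should be mapped to the user's codebook.
* The EDO unit is the clock hour; occasions spanning an hour boundary are
  split, and hours are never merged.
* Eigenvalue-threshold retention is the only factor-number rule implemented;
  no oblique rotations.
* Logistic models assume complete covariates (no imputation) and report
  Wald intervals, which can be optimistic in tiny strata; per-sex strata below
  ~50 participants commonly fail to converge and raise.
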