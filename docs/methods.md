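# Methods

This note documents the models, defaults and numerical choices behind
`povdyn`, in the spirit of a statistical package's methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The indicator model

The analysis assumes a two-visit panel of smallholder households in
which each visit captured a full 12-month recall inventory: crops and
livestock products (quantities produced, consumed and sold, plus
reported sale income), off-farm income, the member roster, land
cultivated, and livestock head counts by species.

**Male adult equivalents (MAE).** Household size is rescaled by
age/sex calorie-demand factors so households of different composition
are comparable. The default factor table (adult male 18–59 = 1.00,
adult female = 0.80, 10–17 = 0.90/0.80 by sex, 4–9 = 0.60, under 4 =
0.30, 60+ = 0.80/0.65) follows standard energy-requirement scales; it
is configuration, not a hard-coded constant, because published
analyses rarely print the exact table they used and any comparable
scale preserves the ordering of households.

**Tropical livestock units (TLU).** One TLU is the metabolic
equivalent of a 250 kg cow; five goats equal one cow, fixing
`w_cattle = 1.0` and `w_goat = w_sheep = 0.2`. Remaining defaults
(pig 0.3, donkey 0.5, poultry 0.01) come from standard reference
tables for tropical herds. Unknown species are an error, never
silently zero.

**Component values and TVA.** Consumed produce is valued at the local
site x round price; sold produce at the *reported* sale income when the
survey captured it, else sold kg x price — recall-based sale income is
the more direct observation of realised value. Local values divide by
a purchasing-power-parity factor keyed by (site, round); sites map
one-to-one to countries in the emulated design and the round encodes
the survey year, so no separate (country, year) key is needed. The
total value of activities (TVA) is the sum of the five components;
this identity is asserted on every generated household.

**Food availability (FA).** FA counts the calories of consumed farm
produce plus all cash (sales + off-farm) converted to calorie
equivalents at the local maize price:

    FA = [ Σ consumed kcal + cash · E_maize / p_maize ] / (MAE · 365)

Consumed maize always contributes exactly `kg × E_maize`
(default 3580 kcal/kg, overridable). Other consumed products use a
per-product kcal/kg table when one is configured; products without an
energy entry are valued at their local price and converted through the
maize route, the same conversion applied to cash. This keeps FA
well-defined on datasets that carry prices but no food-composition
table, at the cost of valuing unpriced-energy foods by their market
calorie-purchasing power rather than their own energy content. FA is
invariant to rescaling the local currency (prices, incomes and the
PPP factor together), which a property test asserts.

**Intensities.** Crop value per hectare, livestock value per TLU,
off-farm income per MAE. A 0/0 intensity is 0 (no activity); value
with a zero denominator is *missing* and excluded from group medians
and tests, with the exclusion logged per household.

## Classification and trajectories

Two thresholds define three strata per round: the calorie line
(default 3000 kcal/MAE/day) and the international poverty line
(default $1.90 PPP/day). The poverty-line test dominates: a household
at or above $1.90/day is High even if its FA falls below the calorie
line — High is defined purely by living above the poverty line — and
such discordant households are counted and flagged. Both thresholds
are evaluated per MAE by default; published work is sometimes
ambiguous between per-MAE and per-capita, so a per-capita switch is
provided. Comparisons are closed on the upper side (`>=`): the
thresholds are lines of attainment, and a deterministic, documented
tie-break matters more than its direction.

Trajectories pair the round-1 and round-2 strata into nine labelled
groups with a rising/steady/falling direction. Flow-matrix marginals
equal the per-round strata counts on the matched subsample — asserted,
since it is the easiest invariant to break silently when households
drop out.

## Statistical harness

* **McNemar** on paired above/below-threshold status:
  χ² = (b−c)²/(b+c) on the discordant counts without continuity
  correction; below 25 discordant pairs the exact two-sided binomial
  variant is used (both are exposed). Degenerate b+c = 0 reports
  p = 1 with a flag.
* **Wilcoxon signed rank** on ordinal stratum codes (Low=1, Medium=2,
  High=3): zero differences dropped, average ranks for ties. The null
  is enumerated exactly (all 2^n sign assignments) for up to 15
  nonzero differences and approximated normally with tie correction
  above. Fifteen is the largest n for which full enumeration stays
  exact at negligible cost; beyond it the normal approximation with
  tie correction is accurate to well past the displayed precision.
* **ANOVA + post-hoc letters.** One-way F; Tukey HSD uses the
  studentized-range distribution with the Tukey–Kramer unequal-n
  adjustment (strata sizes are never equal); Fisher LSD is unadjusted
  pairwise t tests on the pooled within-group mean square. Letters use
  the insert-and-absorb compact-letter-display algorithm; groups share
  a letter iff their pair is not significant at α (0.05 throughout,
  significance at p ≤ α; no multiplicity correction beyond the
  post-hoc method itself). Tests always consume untrimmed data — any
  outlier handling is display-only by construction, because nothing in
  the test path ever filters values.
* **Regressions.** OLS of round-2 farm income on round-1 land, TLU
  and off-farm income, untransformed by default with a log1p option
  (no transform is canonical for these right-skewed incomes; both are
  exposed). Rank-deficient designs raise an error naming the collinear
  columns. Education-by-income uses one-way ANOVA with Fisher LSD
  letters, separately for farm and off-farm income.

## Welfare scoring

HFIAS sums nine 0–3 frequency items (0–27) and maps the item pattern
to four severity categories by the standard most-severe-condition-wins
decision rules, implemented as an explicit predicate table so the
mapping is testable by exhaustive enumeration of all 4^9 patterns.
Any missing item makes the score missing (welfare scores require
complete responses; quantities, by contrast, read blank as zero).
HDDS counts consumed food groups (default 10), scored separately for
flush and lean seasons. The poverty-likelihood scorecard is a generic
engine — per-question option points summed and mapped through a
non-increasing step lookup — because published country scorecards are
data, not code; the shipped scorecard
(`data/ppi_scorecard_synthetic.yaml`) is synthetic, with the same
structure (points sum to 100) as published ones. Strata validation
compares each indicator across strata with ANOVA + Tukey HSD on
round 2 only (the emulated design has no round-1 welfare module) and
reports whether medians run in the better-welfare-in-higher-strata
direction.

## Synthetic panel generator

The generator emulates a four-site, two-round design: 7 villages x 20
households per site in round 1 (560 households), with per-site
resurvey retention of 73.5%, 67.5%, 80% and 80% (round(retention x
140) = 103/94/112/112), attrition as simple random subsampling.
Households have 3–8 members (median 5–6), lognormal land (median
1.5 ha) and livestock (median 2 TLU), and right-skewed values —
matching the medians-much-below-means signature of real survey data.

Generation is latent-first: the round-1 stratum is drawn i.i.d. from
the designed proportions (default 0.30/0.33/0.37) and the round-2
stratum from the designed 3x3 transition matrix, whose default implies
a second-round mix of ~0.27/0.33/0.40 with the largest flows out of
High. A (FA, TVA) target pair is then drawn from truncated lognormals
confined to the stratum's region (FA median 1500 kcal for Low, 3500
for Medium; TVA median 2.5 x $1.90 for High), keeping a 2–5% margin
from both thresholds, and back-solved into product quantities against
the generated price table. Products form two buckets with a common
calorie yield per unit value within each bucket (staples: maize,
beans, sorghum; low-calorie produce: vegetables, milk), so the
two-equation system (consumed value, consumed calories) has an exact
non-negative solution; cash converts at the maize price exactly as the
FA indicator assumes. Classification therefore recovers the latent
stratum essentially exactly, and recovery tests measure only
multinomial sampling noise plus any pipeline defect — which is the
point of the design. Welfare responses (round 2) and education are
drawn with stratum-dependent shifts of roughly one within-stratum
standard deviation between adjacent strata.

Randomness: one pseudo-random stream per site, spawned from the master
seed by site index, so adding a site never perturbs the others; the
price table uses its own per-site streams. Identical seeds give
byte-identical outputs.

**What the generator does not emulate.** Distributional families are
modelling choices (the emulated study reports medians, not families).
There is no informative attrition, no spatial or climate structure, no
within-village correlation, and — deliberately — only a weak link
between a household's assets (land, TLU) and its drawn income targets:
asset medians shift by stratum, but income is not generated *from*
assets. Passing recovery tests on synthetic data therefore shows the
pipeline is correct, not that real data will show any particular
asset–income relationship; the regression-calibration test instead
uses a purpose-built simulation with known coefficients (β_land = 400,
β_TLU = 150, β_off-farm = 0, noise SD 800, n = 500, 1000 replicates).

## Data handling

One CSV dialect: comma-separated UTF-8 with "." decimals, long-format
crop/livestock/roster tables keyed by household id and round, and a
wide welfare block. The consumed + sold ≤ produced check allows a 5%
relative overshoot — all quantities are 12-month recall, and hard
equality would reject real responses; rows beyond the tolerance are
excluded and reported per household, never silently dropped.
Validation is report-only and never modifies inputs. Panel retention
is reported as a whole percentage with half-percent ties rounding
down (147 of 200 → 73%).

## Problem sizes and defaults in the test suite

The unit suite exercises small single-site panels (45–135 households);
recovery checks run at n = 600 (proportions, ±4 points against the
designed 0.30/0.33/0.37) and n = 5000 (transition matrix, ±0.03 per
cell); the regression calibration runs its full 1000 replicates; the
LSD-vs-Tukey conservativeness property samples 200 random datasets.
These sizes give each check comfortable statistical resolution while
keeping the whole suite under a minute on one core.

## Known limitations

* FA's maize-route conversion treats cash and unpriced-energy foods as
  interchangeable with staple calories; with a full food-composition
  table configured, consumed produce uses its own energy densities.
* The $1.90 threshold applies to TVA — production value plus income —
  not to consumption expenditure, so it is a production-based proxy
  for the international poverty line, as in the emulated analysis.
* No survey weights, mixed models or attrition adjustment; the design
  is treated as self-weighting simple random sampling within sites.
* The per-site exact McNemar subsets are small; their p-values are
  exact but low-powered, and no cross-site multiplicity correction is
  applied (matching the emulated analysis, which applied none).
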