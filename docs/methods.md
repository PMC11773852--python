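# Methods

## The classification model

A packaged product is under the warning-label scheme only if its
ingredient list shows an *added* critical ingredient (sugars, saturated
fats or sodium).  These scope flags are inputs: parsing free-text
ingredient lists is out of scope.  For a product in scope, each
nutrient flag is raised when the declared amount per 100 g (solids) or
100 mL (liquids) **strictly exceeds** the regime cutoff; ties are
compliant.  This reading follows the regulation's language of amounts
that "exceed" the limits; the comparison operator is nevertheless a
keyword argument (`strict=False` switches to ≥) so the sensitivity of
results to the convention can be measured.  Amounts are compared exactly
as declared — no re-rounding is applied before comparison, since label
values are already the rounded, legally binding declarations.

Energy has no "added calories" analogue, so the calories flag requires
at least one added-ingredient flag plus energy above the energy cutoff.
This gate is configurable (`energy_requires_scope`).

Basis is taken from the declared label unit (g → solid, mL → liquid).
Products sold to be reconstituted (powders, concentrates) are converted
to as-consumed amounts by multiplying every panel amount by the
package's reconstitution factor, and are always judged against liquid
limits.

Threshold regimes are configuration, not code.  The shipped
configuration contains only publicly documented cells: the complete
final phase and the initial-phase solid limits.  Initial-phase liquid
limits and the entire second phase are *not* defaulted — a run that
needs them must supply them, and using a regime for a basis it does not
cover raises an error naming the missing block.  Guessing regulatory
limits silently would be worse than failing.

### Saturated-fat imputation

Labelling rules only force fat subtypes onto the panel when total fat
reaches 3 g per serving.  A record missing saturated fat whose total
fat per serving (totalfat × serving/100) is below 3 g therefore has its
saturated fat read as 0; a record still missing saturated fat after the
rule is incomplete and excluded.  The pipeline applies the rule *after*
reconstitution (the cascade order is fixed, see below), so for
reconstituted products the rule is evaluated on as-consumed amounts.

## The exclusion cascade

Stage order is fixed and documented: baseline pooling → within-period
deduplication → reconstitution → saturated-fat imputation → incomplete
exclusion → out-of-scope exclusion → market-share filter →
classification.  Each period's ledger row conserves exactly
(photographed = final + every removal); the pipeline asserts this on
every run.

Design choices where the procedure was genuinely open:

* **Pooling identity** is the product identifier when present, else
  (group, brand family, panel hash); identity clashes between the 2015
  and 2016 baseline waves resolve to the 2016 version.
* **Duplicate key** within a period is (group, brand family, nutrition
  panel, scope flags) — identical package contents in different sizes.
  The record with the lexicographically smallest identifier is kept;
  duplicates agree on every analysed field, so the choice cannot affect
  any downstream statistic, but a deterministic rule keeps reruns
  byte-identical.
* **Market shares** are computed on a separate, coarser sales taxonomy
  (`market_group`) than the 16 analysis groups, as sales databases and
  analysis taxonomies rarely coincide; share = id sales × 100 / group
  total for the record's collection year, unknown ids count as zero
  with a warning, and a zero group total is an error rather than a
  silent 0/0.  `min_share=0` (or `full_supply=True`) disables the
  filter — the full-supply sensitivity mode, whose output is always a
  superset of the best-selling sample.

## Inference

### Firth bias-reduced logistic regression

Per-period "high in" counts regularly contain zero cells (a group-level
flag can vanish entirely in a period), where ordinary logistic ML
estimates diverge.  We maximise the Jeffreys-penalised likelihood
ℓ(β) + ½ log det I(β) by Newton iterations on the bias-adjusted score
U*(β) = X′(k − n·p + h(½ − p)), h the hat values of the weighted
design, with step-halving whenever a step would lower the penalised
likelihood; convergence at max|U*| < 1e−8, at most 100 iterations.
The covariance is the inverse information at the optimum.  For the
saturated one-factor design used throughout, the fitted proportion of a
period with k of n flagged is exactly (k+½)/(n+1) — the test suite
verifies this identity against a generic numeric maximiser, and checks
that the penalty washes out (< 1% relative coefficient difference at
n = 10⁴ per period against an unpenalised GLM).

Pairwise period contrasts are formed on the proportion scale
(difference of estimated marginal means, delta-method SE, two-sided
Wald p).  They are post-hoc comparisons and are reported unadjusted by
default; Bonferroni adjustment is a keyword option.  Whether such
contrasts should be Wald-on-response, Wald-on-logit or likelihood-ratio
based is not settled; the response scale is used because the reported
quantity is a percentage-point difference.

### Cochran–Armitage trend

Z = Σ sᵍ(kᵍ − nᵍp̄) / √(p̄(1−p̄)(Σ nᵍsᵍ² − (Σ nᵍsᵍ)²/N)), two-sided
normal p-value, no continuity correction.  Scores default to equally
spaced 0..G−1; the periods are ordinal and unevenly spaced in calendar
time, so scores are configurable.  Z² equals the score test for
logistic regression on the scores (checked to 1e−8), and the normal
p-value agrees with an exact margin-preserving permutation null to
about 0.01 on a 30-observation table — the residual gap is
finite-sample normal-approximation error, not Monte-Carlo noise.

### Quantile regression

With period as the only (saturated) categorical predictor, minimising
the pooled check loss Σ ρ_τ(y − fit) separates by period and each
fitted value is a within-period sample quantile.  When nτ is an integer
the minimiser is the interval [y₍nτ₎, y₍nτ₊₁₎]; we return its **lower
endpoint** (the vertex an LP solver reports), so fitted quartiles are
order statistics and tables are exactly reproducible.  Fits are checked
against brute-force check-loss minimisation and against an independent
quantile-regression implementation.

No variance estimator is canonical for quantile differences on grouped
data, so inference is by seeded within-period bootstrap (default 1000
replicates; at least 200 enforced): the p-value is two-sided normal on
(observed difference)/(bootstrap SE of the difference).  Simulation
checks in the suite show type-I error within [0.02, 0.09] at n = 500
per period and power above 0.8 against a 1-SD location shift.  A
degenerate bootstrap (zero spread) yields p = 1 when the observed
difference is 0 and p = 0 otherwise.

## Reporting conventions

Percents are 100·k/n rounded **half-up** to one decimal.  Half-up is
adopted because it reproduces every published percent checked; the
original rounding rule is not documented.  The headline change is the
difference of the *rounded* first- and last-period percents — this
convention reproduces published percentage-point differences including
rows where the unrounded difference rounds the other way.  Significance
is emitted as machine-readable p-values and significant-pair lists, not
superscripts.  Density curves are Gaussian KDEs (Scott or Silverman
bandwidth) per period on one common grid padded by four bandwidths, so
each curve integrates to 1 within 0.01 by the trapezoid rule.

## The synthetic supply

The real label database is not public, so the generator emulates the
structure the analysis depends on, with every planted quantity written
to a truth record:

* **16 groups** (beverages through soups), solids and liquids, sized
  proportionally to the published group sizes (`size_weight`; a scalar
  `products_per_group` rescales the whole supply).  Group sizes differ
  by an order of magnitude and overall prevalence is a size-weighted
  mixture, so relative sizes are a first-class scenario parameter.
* **Amounts** are log-normal per group and nutrient (optionally a
  two-component mixture for bimodal categories), independent across
  nutrients and of the scope flags.  Scales default to σ = 0.8, with
  near-degenerate high cells (candy sugars, soup sodium) narrower.
  Locations are derived from target exceedance probabilities at the
  final-phase limits rather than set directly, which pins the
  classification behaviour; in cells whose published rate is ~0 the
  implied median is not meant to be nutritionally realistic.
* **Reformulation** is a multiplicative left shift of the medians at
  T1/T2/T3, applied only to regulated products — only labelled products
  face reformulation pressure.
* **Plants**: package-size duplicates (extra copies with a new id and
  identical content), incomplete records (a rotating missing field:
  sodium amount, scope flags, energy amount), out-of-scope products,
  and two baseline waves sharing identities (every product appears in
  2016 and/or 2015) to exercise pooling.  Brand-family sales are
  log-normal within each of 32 market groups, so a realistic tail of
  families falls below the 1% share filter.
* **Sub-seeding**: one master seed spawns a stream per (group, period)
  keyed by a hash of the group name, so reordering or extending the
  group list does not perturb existing groups' draws.

### Calibration of the shipped scenario

`default_scenario()` is calibrated deterministically, at construction
time, against the generator's *analytic* prevalence formula (an
8-combination enumeration over the independent scope flags — no
sampling involved):

1. per-group per-nutrient baseline rates are taken from the published
   group-level prevalence tables, then scaled by a single solved factor
   (≈ the correction for the generator's independence of nutrient
   amounts, which otherwise overstates the "any flag" union) so the
   overall baseline prevalence is 70.8%;
2. one shrink factor per post-law period is solved by bisection so the
   overall trajectory is 63.4% / 54.5% / 52.5%, translated into
   per-nutrient shifts through fixed exponents (sugars and sodium shift
   fully, energy and saturated fats at the square root) reflecting the
   published pattern that sugars and sodium moved most.

Default nuisance rates: 13% planted duplicates, 1.2% incomplete, 9%
out of scope per group — within the published per-period ranges.

### What passing tests do and do not show

The generator reproduces the *marginal* structure the estimators
consume: heavy-tailed amounts, scope gating, planted left shifts,
separation-inducing zero cells, duplicate/incomplete/out-of-scope
contamination and skewed sales.  It does **not** model correlation
between nutrients within a product (real recipes correlate sugar, fat
and energy), brand-level persistence of products across periods,
measurement error in label declarations, or market-share dependence on
nutrient content.  Parameter-recovery results therefore validate the
estimators and the pipeline accounting, not the behavioural claims one
could only test on the real supply.

## Problem sizes and numerical choices

The shipped analyses use 60 products per unit group weight
(≈ 960 products per period before exclusions, ≈ 800 after), 1000
bootstrap replicates for reported tables and 300 in simulation loops,
10⁵ draws for the permutation oracle, and 100 seeds for the coverage
check — sizes at which the Monte-Carlo error is well below the effects
of interest while a full suite run stays in the minutes.  Newton
tolerance 1e−8 with 30 step-halvings; KDE grids of 256 points.

## Known limitations

* The initial-phase liquid and second-phase limits are unpublished and
  must be user-supplied; the shipped regime set cannot classify a
  liquid under the initial phase.
* Pairwise EMM p-values are unadjusted post-hoc comparisons.
* The bootstrap p-value for a quantile difference relies on a normal
  approximation to the bootstrap distribution; for tiny groups
  (n ≲ 30 per period) its calibration degrades with the discreteness
  of order statistics.
* The small-producer three-year exemption is not modelled: records
  carry no producer-size field.
* Exact duplicate identity on real data (barcode vs barcode+flavour)
  is coarser than the panel-hash fallback used for synthetic data.
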