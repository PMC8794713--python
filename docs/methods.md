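# Methods

This note documents the models, conventions, and numerical choices behind
`larkscape`, and what the synthetic-data tests do and do not demonstrate.

## Spatial conventions

All coordinates are planar metric (meters) and all distances Euclidean; at
a study extent of a few kilometers geodesy is irrelevant, and the package
performs no CRS transformations. Home-range discs are polygonized with 256
vertices (area error ~10⁻⁴ relative). Disc membership is closed: a point
exactly on the radius is inside. Point-in-polygon lookups use an STR-tree;
a point on a shared boundary resolves to the lowest patch index, a
deterministic tie-break that affects only a measure-zero set of locations.

## Home-range radius and availability

The global radius is a weighted 95th percentile of nest-to-landing
distances in which each nest's points carry weight 1/nᵢ, so every nest
contributes equally regardless of observation effort. The percentile is
defined as the smallest order statistic whose cumulative normalized weight
reaches the target, with no interpolation — the only definition that is
unambiguous under unequal weights. It is invariant to duplicating any
nest's points (weights renormalize), which the tests assert.

Availability inside a home range is computed on a grid (default 5 m,
refused when coarser than radius/10) whose cell centers are symmetric
about the nest. Under *distance weighting*, each cell at distance d gets
weight f̂(d)/(2πd), where f̂ is a histogram estimate (default 10-m bins) of
the pooled nest-weighted flight-distance density; dividing by the
circumference 2πd converts the distance profile into a per-unit-area
intensity. The *flat* option weights uniformly and equals the plain area
share within 0.5 percentage points at the default grid (tested against
exact polygon areas). Unmapped area inside the disc (coverage gaps) is
excluded from the availability denominator and reported per nest, never
silently renormalized.

## Resource-selection model

Presences are in-range safe landing points; pseudo-absences are uniform
points in the disc (rejection sampling from the bounding square, redrawn
when they fall in coverage gaps or covariate-incomplete patches, with a
100× oversampling cap). The model is a weighted binomial additive model on
the logit scale with cubic B-spline smooths (10 basis functions per term)
for vegetation cover, arthropod biomass, insect Shannon diversity, and
distance to the nest, plus unpenalized per-nest intercepts. We fit it by
penalized IRLS, maximizing Σ wᵢ[yᵢηᵢ − log(1+e^ηᵢ)] − ½βᵀSβ, with per-term
penalty weights chosen by coordinate grid search over log-spaced values
minimizing AIC = deviance + 2·edf. Effective degrees of freedom are
diag[(XᵀWX+S)⁻¹XᵀWX]; coefficient uncertainty uses the Bayesian posterior
covariance (XᵀWX+S)⁻¹, the convention of the standard penalized-regression
GAM literature; term-level Wald χ² tests use the term's coefficient block
with its edf as the reference df. The unpenalized limit of this fitter
agrees with a plain weighted GLM to 10⁻⁶ (tested), and a heavy penalty
drives a term's edf to zero.

The nest term is a set of fixed intercepts rather than a shrunk random
effect, so its reported edf equals (number of nests − 1); this choice does
not alter the smooth-term tests or the permutation importance, which treat
the nest block like any other column group.

**Weights.** Nests are weighted equally: within a nest, presence weights
are 1/nᵢ each and pseudo-absence weights 1/240 each, so both classes sum
to 1 per nest and the global presence and absence totals are equal (to
machine precision; tested). Before fitting, the weights are rescaled to
mean 1. The rescaling changes nothing about the fitted curves (weight
*ratios* are what IRLS sees) but sets the likelihood's effective sample
size to the number of points rather than twice the number of nests; the
latter would cap every test statistic at ~2·n_nests, which is incompatible
with the magnitude of test statistics this design is known to produce at
~12,000 points. The same rescaling applies to the per-nest-day weights of
the seasonal models and the per-nest weights of the foraging trend models.

**Selection curves.** Each smooth is evaluated on a 200-point grid over
the observed predictor range and centered to mean zero over the fitted
data, so the zero line is the model's average selection level. A grid
value is *preferred* when the lower 95% bound exceeds zero and *avoided*
when the upper bound is below zero; the two cannot co-occur (tested).

**Permutation importance.** For each variable (the four covariates and
the nest label) the variable's design block is permuted across all points
— permuting raw values and re-evaluating the spline basis is exactly
permuting basis rows — and the raw score is the mean over 100 replicates
of 1 − Pearson r between original and permuted predictions on the
probability scale, floored at zero. Scores are normalized to percentages.
Permutation is global (not within nest); the replicate count and
permutation scope are configurable because the procedure's source
literature leaves them open.

## Compositional analysis

Frequent habitat categories are those with positive availability in at
least one-third of home ranges (configurable); the rest pool into
`other`. A category available to no nest at all is dropped — it carries no
information and would make every log-ratio undefined. Log-ratio
differences use d_ij = ln(use_ij/use_i,ref) − ln(avail_ij/avail_i,ref),
with zero used proportions replaced by 10⁻⁴ (0.01%, the conventional
replacement, configurable) and no renormalization. The reference defaults
to the category available to the most nests, which minimizes undefined
cells; Wilk's Λ is reference-invariant to 10⁻⁸ (tested across all
references). Cells undefined because a category is unavailable to a nest
are filled by the column mean over defined nests (mean substitution); a
`drop_incomplete` switch removes such nests instead.

Λ = det(R₁)/det(R₀) with R₁ the SSCP about the mean and R₀ about zero;
all-zero differences give Λ = 1 by convention. The randomization null
flips the sign of each nest's difference vector with probability ½
(use/availability exchangeable within nest). Because sign flips leave R₀
unchanged, the matrix determinant lemma gives Λ = 1 − n·m̄ᵀR₀⁻¹m̄ for the
flipped mean m̄, which vectorizes the 1000-iteration null to a single
batched computation; the identity is asserted against the determinant
ratio in the tests, and the randomization p agrees with exhaustive 2⁸
enumeration at n = 8 within ±0.02. p = (1 + #{Λ_rand ≤ Λ_obs})/(1 + N);
the test's type-I error at α = .05 is within [0.03, 0.07] over 500 null
datasets (tested). The ranking matrix holds pairwise mean log-ratio
differences with one-sample t statistics over the nests where both
categories are available; a category's rank counts the categories it
beats (positive mean), with significance marked at the two-sided 5% t
critical value.

## Seasonal-use models

For each frequent habitat, every in-range safe landing point of a nest
whose home range contains that habitat is a Bernoulli trial (landed in the
focal habitat or not), modeled as a logistic mixed model with a Gaussian
random nest intercept: response ~ day of season + weighted surface area
(%) + year indicator. Day 1 is April 25, applied within each observation's
own calendar year. "Equal weighting per observation day" is implemented as
observation weight 1/(points of that nest on that day), rescaled to mean 1
(switchable to unweighted). The marginal likelihood is integrated with
25-node Gauss–Hermite quadrature and maximized with BFGS (Nelder–Mead
polish on non-convergence); this fitter reproduces lme4's adaptive
quadrature estimates to ~10⁻⁴ on a frozen fixture (tested). Prediction
curves are conditional on the average nest (random intercept 0) at the
included nests' mean weighted surface area and the reference year, over
days 1–100; each day is *preferred* / *proportional* / *avoided* by where
the 95% CI sits relative to the availability line (mean WSA / 100).

## Foraging parameters

Feeding frequency per session is landings/minutes × 60, and per chick
divides by brood size (the per-session identity per_h = per_h_chick ×
brood is exact). Sessions that did not end before sunset are excluded, as
are nests with unclear brood size. Flight distances use all safe points
with no home-range truncation. MCP95 retains the points whose distance to
the unweighted centroid is at most the 95th percentile of those distances
(same closed, non-interpolated percentile convention as the radius) and
takes the convex-hull area in hectares; nests with fewer than 20 points
are excluded. The area is monotone in the retained fraction and
translation/rotation-invariant (tested).

Trend models: weighted linear mixed models (random nest intercept, ML,
Woodbury-based marginal likelihood; equal-nest weights 1/nᵢ at mean 1) for
the two frequencies and the distance, with day of season, chick age,
session start time, temperature, wind, radio-tagging, and year as fixed
effects; Wald t tests use n − p residual df (no Satterthwaite correction —
p-values for small nest counts are approximate). The MCP95 model is OLS on
hatch day, percent of observations before noon, mean temperature, mean
wind, radio-tagging, and year, with residual-vs-fitted and
residual-quantile diagnostics emitted. The linear fitter matches lmer
(REML=FALSE) to ~10⁻⁵ on a frozen fixture.

## Synthetic-data generator

The generator is the package's ground truth and encodes the study
conditions rather than a convenience fixture:

* **Landscape** — rows of random height (180–260 m) split into fields with
  expected size 5.1 ha, habitat drawn from the observed crop shares
  (winter wheat ~34%, sugar beet ~20%, corn ~9%, barley, rape, flower
  strips, fallow, grassland, trial plots), with 3-m field-path strips
  between rows; fully space-filling. One mosaic is shared by both study
  years (crop rotation is not emulated).
* **Flights** — landing cells on a 5-m grid within 500 m of the nest with
  probability ∝ exp(−d/λ)·weight(habitat, day). λ defaults to 40 m: in two
  dimensions the implied distance density is ∝ d·e^(−d/λ), giving a mean
  flight distance of ~80 m and a 95th-percentile radius of ~190 m, the
  scale reported for this system. Habitat attractiveness defaults give
  flower strips and field paths twice the cropland baseline (the observed
  use:availability ratio) with gentle seasonal trends (wheat rising, beet
  and flower strips declining). Sessions cap at 10 flights or 90 min;
  feeding rate rises with chick age (base 7.3 visits/h + 1.0 per day of
  age); 2.4% of landings are marked ambiguous; brood sizes average ~3.3.
* **Covariates** — per patch, one vacuum sample (counts per arthropod
  group ~ negative binomial around habitat × half-month means, size
  parameter 2; dry mass lognormal around the habitat's biomass density
  times the sampled area 20·π·0.07² m²) and one vegetation record (three
  observers reading a logistic growth curve with ±10 noise, rounded to 10%
  steps, clipped to [0, 100]). Spiders are counted but excluded from the
  insect Shannon index. Covariates exist only around the 42
  covariate-mapped nests of the default 51.

Everything is deterministic given the seed, with independent streams per
stage. The exponential kernel is a modeling choice recorded in
`truth.json`, not an inference about the birds.

**What the synthetic tests show.** Passing parameter-recovery tests shows
the pipeline correctly inverts its own generative model at realistic
sizes: with λ = 60 m and uniform habitat weights, distance receives the
top importance in ≥95/100 seeds; a habitat with doubled attractiveness
attains the top compositional rank with p < .05 in ≥90/100 seeds (40
nests); a 5-fold seasonal attractiveness decay yields a negative,
significant day coefficient in ≥90/100 seeds. They do not show robustness
to what the generator omits: territoriality, weather-dependent behavior,
observer bias in landing positions, spatial autocorrelation of arthropod
communities, or crop rotation between years. Because the generator's
behavior follows the kernel×weight model exactly, its compositional
departures from random use are stronger than typically observed in the
field, where unmodeled heterogeneity inflates between-nest variance.

**Recovery-test study sizes.** The three recovery loops run 100 seeds each
at deliberately compact designs — 8 nests for the selection model (the
importance ranking stabilizes quickly), 40 nests at a 3-ha mosaic for the
compositional rank (a finer mosaic gives each home range more habitats and
tighter use:availability contrasts), and 60 nests for the seasonal slope
(whose identification, partly between nests, needs the larger roster) —
chosen as the smallest designs at which the respective procedure has
adequate power for the stated effect.

## Known limitations

* Term-level p-values of the penalized model use the edf as the reference
  df of a Wald χ²; like all such approximations they are mildly liberal
  for strongly penalized terms.
* The seasonal prediction CI is conditional on the random intercept being
  zero, not marginal over nests.
* LMM p-values use residual df rather than Satterthwaite; with ~50 nests
  the difference is small but real.
* The MCP95 peeling convention (distance to centroid) is the dominant one
  in home-range software but not the only one; a different 5% removal rule
  changes areas slightly.
* `percentage` rounding follows Python's round-half-to-even; shares are
  reported to one decimal.
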