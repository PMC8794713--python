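# larkscape

Habitat-selection and central-place-foraging statistics for
chick-provisioning Eurasian Skylarks (*Alauda arvensis*) in farmland — a
reusable, tested implementation of the full analysis chain used in
observational foraging studies, driven by a synthetic-data generator with
known ground truth.

## The problem

When Skylarks raise chicks they make short provisioning flights from the
nest into the surrounding crop mosaic. Where they choose to forage depends
on prey abundance and diversity, how penetrable the vegetation is, and —
dominantly — how far a patch lies from the nest. Quantifying this
selection, and how it shifts over the breeding season as crops grow,
requires a chain of spatial and statistical steps that this package
implements as a library plus a thin CLI:

1. **Home ranges** (`larkscape.home_range`) — the global radius is the
   nest-weighted 95th percentile of nest-to-landing distances (each nest's
   points carry weight 1/nᵢ; the percentile is the smallest distance whose
   cumulative weight reaches 0.95). Each home range is the disc of that
   radius around the nest, clipped against the habitat mosaic.
2. **Distance-weighted availability** — habitat availability inside the
   disc is the *weighted surface area*: each location at distance d is
   weighted by f̂(d)/(2πd), the per-unit-area intensity of the pooled
   flight-distance distribution, so near-nest area counts for more. With
   flat weighting it reduces exactly to the plain area share.
3. **Resource selection** (`larkscape.rsf`) — observed landing points are
   contrasted with 240 uniform pseudo-absence points per home range in a
   weighted binomial additive model,
   `P(presence) ~ s(FVC) + s(biomass) + s(Shannon H) + s(distance) + nest`,
   fitted by penalized IRLS on B-spline bases. Selection curves are
   classified *preferred / neutral / avoided* where the pointwise 95% CI
   clears the zero line, and variable importance is computed by the random
   permutation procedure (1 − Pearson r between original and
   permuted-predictor predictions).
4. **Compositional analysis** (`larkscape.compositional`) — per-nest
   log-ratio differences between use and availability, one-sample
   Wilk's Λ = det(R₁)/det(R₀), a sign-flip randomization p-value with
   p = (1 + #{Λ_rand ≤ Λ_obs})/(1 + N), and the pairwise ranking matrix
   with one-sample t statistics.
5. **Seasonal use** (`larkscape.seasonal`) — per habitat, a logistic mixed
   model (random nest intercept, Gauss–Hermite ML) of whether each landing
   point fell in the focal habitat, against day of season (day 1 =
   April 25), weighted surface area, and year.
6. **Foraging parameters** (`larkscape.foraging`) — feeding frequency per
   hour and per hour-and-chick, flight distances, MCP95 areas (convex hull
   of the 95% of points closest to their centroid), and their trend models
   (weighted linear mixed models; OLS for MCP95).

The synthetic generator (`larkscape.synth`) simulates the whole study:
a space-filling crop mosaic (~5 ha fields, field-path strips), nests with
hatch dates spanning late April–July, foraging flights drawn on a 5-m grid
with probability ∝ exp(−d/λ)·weight(habitat, day), negative-binomial
arthropod communities, and logistic vegetation growth scored by three
observers on a 10% grid.

## Worked example

```python
from larkscape import pipeline
from larkscape.synth import SimulationTruth, generate_dataset

ds = generate_dataset(SimulationTruth(rng_seed=1))
hr = pipeline.home_range_stage(ds)
print(round(hr["radius_m"], 1))          # 190.6  (m, global home-range radius)

cov = pipeline.covariate_stage(ds, hr)
rsf = pipeline.rsf_stage(ds, hr, cov, seed=3)
print(round(rsf["fit"].deviance_explained, 3))            # 0.231
print(rsf["importance"].relative_pct.round(1).to_dict())
# {'vegetation_cover': 0.0, 'arthropod_biomass': 0.5,
#  'insect_diversity': 1.0, 'distance': 97.3, 'nest': 1.2}

comp = pipeline.compositional_stage(ds, hr, seed=2)
print(round(comp["lambda"], 3), round(comp["p_value"], 3))  # 0.388 0.001
```

Reading: the 95th-percentile radius of the simulated flights is ~190 m;
the selection model explains ~23% of the deviance and attributes ~97% of
the relative importance to nest distance (the generator's dominant force);
and overall habitat use departs from availability (Λ = 0.39, p ≈ 0.001)
because the generator gives flower strips and field paths twice the
baseline attractiveness.

The same stages are available from the shell:

```
larkscape simulate --out study/ --seed 1
larkscape validate --data study/
larkscape homerange --data study/ --out results/
larkscape rsf --data study/ --out results/ --seed 3
larkscape compositional --data study/ --out results/ --seed 2
larkscape seasonal --data study/ --out results/
larkscape foraging --data study/ --out results/
```

## Data model

A study directory holds `landscape.geojson` (planar-metric habitat
polygons with `patch_id`, `habitat_type`, `year`), `nests.csv`,
`sessions.csv`, `landing_points.csv`, `arthropod_samples.csv` (counts per
arthropod group in `count_<group>` columns, dry mass, sampler geometry),
and `vegetation.csv` (up to three observer estimates on a 10% grid).
Habitat labels outside the five canonical categories (`winter_wheat`,
`sugar_beet`, `corn`, `annual_flower_strip`, `field_path`) are namespaced
as `other:<label>`. `larkscape validate --data DIR` exits nonzero on any
integrity error (dangling references, sessions over 90 min, more than 10
points per session).

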