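# ecodensity

Population densities of birds can be measured against two different
denominators: the total physical area a survey covers (**geographical
density**, individuals/ha) or only the area of habitat actually suitable
for each species (**ecological density**, individuals per hectare of
suitable habitat).  The distinction matters for how habitat
specialization relates to abundance: a specialist may be thin on the
ground country-wide yet dense inside its own habitat.  This package
implements that country-scale analysis as a tested pipeline — from
point-count census tables to phylogenetically corrected regressions —
together with a synthetic-data generator with known ground truth, so
every stage is verifiable without field data.

It is written for ecologists working with point-count monitoring data
(censuses of fixed-radius points along transects, two visits per breeding
season) and species-level trait and phylogeny resources.

## What it computes

- **Densities.** Per-point abundance is the maximum of the two visits.
  Geographical density is Σ abundance / (N_points × 3.14159 ha); the
  point area is π·(100 m)².  Ecological density divides the same total by
  the suitable-habitat area at the points where the species occurred
  (habitat compositions × the species' binary habitat-preference vector);
  it is never smaller than the geographical density.
- **Specialization (SSI).** A species occupying *h* of *H* possible
  classes has SSI = √(H/h − 1), identically the population coefficient of
  variation of its binary occupancy vector (H = 15 habitat or 9 diet
  classes in the shipped taxonomies).
- **Trait axes.** Correlation-matrix PCA reduces five morphological
  traits to a structural-size axis (ssPC) and four reproductive traits to
  a slow–fast life-history axis (sfPC); body mass (log) stays separate.
- **PGLS.** Generalized least squares with residual covariance σ²V, where
  V[i,j] is the shared root-to-MRCA branch length under Brownian motion
  on the phylogeny (50% majority-rule consensus of a tree sample, mean
  branch lengths).  Fitting is by maximum likelihood.
- **Multimodel inference.** All-subsets dredging of the full model
  (2^m fits, factor blocks atomic), ΔAIC < 2 retention, Akaike-weighted
  full-model averaging with unconditional and small-sample-adjusted
  standard errors, and a robustness report of the averaged coefficients
  over the whole tree sample.
- **Generator.** Dirichlet habitat mosaics, niche vectors of varying
  breadth, two Poisson visits with within-habitat intensity
  base·exp(γ·SSI), Yule trees with perturbed variants, Brownian traits.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (150 species, 1000 points, γ = 0.2) and write their tables under
`results/`:

```bash
python analysis/01_simulate.py
python analysis/02_densities.py
python analysis/05_density_trait_models.py   # after 03 and 04
```

Selected output from a full run:

```
geographical density: 0.1658-0.7347 ind/ha
ecological density:   0.7285-1.9251 ind/ha
...
eco_density / ssPC: 32 models dredged, 3 retained (delta AIC < 2)
  averaged SSI-habitat coefficient +0.4471  p = 0
...
SSI habitat on ecological density: consensus +0.4471, across-tree mean
+0.4471 (SD 0.0007); sign agreement with the consensus estimate: 100%
```

Ecological densities exceed geographical ones species by species (the
suitable-area denominator is smaller), and the averaged SSI-habitat
coefficient on **ecological** density is positive — specialists are
denser inside their habitat, which is exactly the effect the generator
builds in — and essentially invariant to which of the 100 perturbed trees
supplies the phylogenetic correlation.

The same stages are available as a CLI (`ecodensity simulate|densities|
ssi|consensus|vcv|run`) and as library functions (`ecodensity.fit_pgls`,
`ecodensity.dredge`, `ecodensity.select_and_average`, ...).

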