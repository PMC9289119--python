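# Methods

## Densities from point counts

A census point has radius 100 m, hence area π·(0.1 km)² = 3.14159 ha.
Each point is visited twice in a breeding season; the per-point abundance
of a species is the **maximum** of the two visit counts.  The two visits
exist to bracket early and late breeders, so the visits sample partially
different populations: summing them would double-count, while the
maximum is the best available proxy of the local breeding population.
A missing visit is treated as a zero count with a logged warning.

Geographical density is total abundance divided by the total surveyed
area (N_points × 3.14159 ha).  Ecological density divides the same total
by the area of suitable habitat.  Two denominator conventions are
implemented because the natural-language definition is ambiguous:

- `presence` (default): suitable area summed over the points where the
  species was recorded;
- `all_points`: suitable area summed over every surveyed point.

Both are bounded by the total surveyed area, so ecological ≥
geographical density holds for every species in either mode.  A species
recorded at a point with zero mapped suitable habitat contributes that
point's **full** area to the denominator and is flagged: presence is
itself evidence of suitability, and dropping the count would break the
ordering invariant.  A species never recorded has no defined ecological
density and is excluded with a warning.

Habitat bookkeeping uses three class systems: the 12 field biotope
categories, the 7 aggregated analysis classes (deciduous, coniferous and
mixed forest, shrub, open, water, urban), and the 15-class habitat /
9-class diet preference taxonomy of the European trait catalogue.  The
aggregation maps are shipped as constants; two source classes have no
stated target and are mapped by this package's own choice — woodland →
mixed forest, marine → water — both overridable by passing a custom map.

## Specialization index

SSI = √(H/h − 1) for a species occupying h of H classes.  H is the size
of the preference taxonomy (15 habitat, 9 diet), *not* the number of
classes observed in a given survey: specialization is a species
property, independent of local habitat availability.  The closed form is
algebraically identical to the population (divisor-H) coefficient of
variation of the binary occupancy vector; the sample-SD variant is not,
and is not used.  The tests verify the identity exhaustively for all
1 ≤ h ≤ H ≤ 50.

## Trait reduction

Morphology (body, wing, tail, bill, tarsus length) and reproduction
(clutch size, broods/year, egg mass, life span) are each reduced to
their first principal component (ssPC, sfPC).  PCA runs on the
correlation matrix — traits are z-scored first — because the blocks mix
mm, g and years and a covariance PCA would be dominated by the
largest-unit trait; a `standardize=False` switch exists.  PC1's sign is
oriented so its loading on the first listed trait is positive (signs are
otherwise arbitrary, so tests assert magnitudes).  Sex-dimorphic traits
are averaged across the sexes on the raw scale before any transform.
Body mass enters models separately as a natural logarithm (configurable
base); it correlates with both PC axes, and the pipeline records those
correlations in the run report.

## Phylogeny

Tree samples are read as one Newick per line with a shared tip set.  The
consensus is 50% majority rule on rooted clades: a clade is kept when it
appears in strictly more than the threshold fraction of trees; its
branch length is the mean of its subtending edges over the trees that
contain it, tip edges are means over all trees, and unresolved regions
remain polytomies (for thresholds below 0.5, clades are added greedily
by frequency, skipping incompatible ones).  The Brownian
variance-covariance matrix V has V[i,j] = root-to-MRCA(i,j) path length;
restricting V to a species subset is mathematically identical to pruning
tips while keeping the root, and is implemented that way.  V is used
unscaled: the GLS profiles out σ², so any constant rescaling of V (a
correlation-vs-covariance choice) cancels.

## PGLS, dredging, averaging

The regression model is y = Xβ + ε, ε ~ N(0, σ²V).  V is
Cholesky-factored once; the whitened system gives

- β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y,
- σ̂²_ML = RSS_V/n,
- logLik = −½[n·ln(2πσ̂²) + ln|V| + n].

Maximum likelihood is the default (a REML variant is provided) because
dredging compares models with different fixed effects, for which REML
likelihoods are not comparable.  AIC = −2·logLik + 2k with k counting
σ² as estimated.  Standard errors for single-model t-tests use the
df-corrected variance σ̂²·n/(n − p) with n − p degrees of freedom, which
reproduces ordinary GLS/OLS output exactly when V = I.

Dredging fits every subset of the full model's m terms (2^m fits; the
nest-type factor block enters or leaves as a unit; the intercept is
always present), re-using the single Cholesky factorization.  AIC ties
break by fewer parameters, then term names, so ordering is
deterministic.  Models with ΔAIC < 2 are retained; Akaike weights are
renormalized over the retained set.  Averaging is *full* (zero
substitution): a term absent from a model contributes β = 0 with SE = 0;
conditional averaging is available behind a flag.  The unconditional
standard error is Σᵢ wᵢ·√(SEᵢ² + (βᵢ − β̄)²); the adjusted variant
replaces each SEᵢ by SEᵢ·t(dfᵢ, 0.975)/z(0.975).  Averaged coefficients
are tested against the standard normal (z), single-model coefficients
against t — matching the respective output conventions of the two model
classes.  The robustness stage repeats dredge + averaging per tree of
the sample and reports the across-tree spread and sign agreement with
the consensus-tree result.

Degenerate inputs: a singular design raises an error naming the
collinear columns (QR with pivoting); a non-positive-definite V raises
before any fit; an exactly collinear response (σ̂² = 0) reports an
infinite log-likelihood rather than failing.

## Synthetic data: what it emulates, and what not

The generator reproduces the *design* of a national point-count scheme:
transects of 20 points, Dirichlet habitat compositions per point over
the 7 aggregated classes (concentration 0.5 by default, so most points
are dominated by one or two biotopes, as real mosaics are), binary niche
vectors with breadth drawn uniformly on 1..7, and two independent
Poisson visits with mean intensity × suitable area.  The
intensity–specialization link is log-linear, intensity =
base·exp(γ·SSI), so γ = 0 is an exact null on the intensity scale;
defaults are 150 species, 1000 points, base 0.5 ind/ha, γ = 0.2.  Trees
are Yule (pure-birth) with unit birth rate — sampled directly from the
exponential waiting-time construction so terminal edges are strictly
positive — plus 100 variants with lognormal branch-length jitter
(σ = 0.1) and optional NNI moves for consensus testing.  Continuous
traits are independent Brownian motions (rate 1, root 0); body mass is a
lognormal transform of its own Brownian trait; nest type is categorical;
breeding range is lognormal i.i.d.

Features of real data deliberately *not* emulated, and the resulting
caveats for interpreting green tests:

- No spatial autocorrelation between points, no observer effects, no
  imperfect detection.
- Traits are mutually independent, so PC1 shares are ~30–40%, far below
  the >90% seen in strongly inter-correlated real trait blocks; the PCA
  tests validate the algebra, not realistic loading structure.
- Synthetic densities carry **no phylogenetic signal**, while the PGLS
  assumes Brownian residuals.  Effect *directions* are recovered
  correctly, but p-values on synthetic density responses are
  anti-conservative; the calibration tests therefore simulate the
  response under the fitted model itself (where coverage and type-I
  error are exact) rather than through the census chain.
- The ecological-density *estimator* is upward-biased for sparse
  specialists (conditioning on presence points, and the per-point
  max-of-two-visits exceeding the per-visit mean).  With γ > 0 this does
  not change the sign of the specialization–density contrast, which is
  the generator's purpose; under γ = 0 it produces a small positive
  slope, so the census chain is not a calibrated null for significance
  tests.  Geographical density under this generator *decreases* with
  specialization (the suitable-area factor h/H outweighs exp(γ·SSI) at
  the default γ), so the mirrored headline contrast is "strongly
  positive in ecological space, non-positive in geographical space".

## Problem sizes

Default analysis scale is 150 species × 1000 points × 101 trees; the
full driver chain runs in well under a minute on one CPU, the test suite
(including 100 stochastic replicates of the full chain) in a few
minutes.  These sizes were chosen so the Monte-Carlo checks have tight
sampling error while the whole analysis remains interactive.
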