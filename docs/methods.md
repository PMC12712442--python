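# Methods

This note documents the statistical machinery in `frostdrought`, the
assumptions behind it, and the design choices made where published practice
leaves the details open.

## The scientific question

Woody plants face two physiologically linked hazards: drought-induced xylem
embolism, summarized by P50 (the xylem pressure, in MPa, at which half of
hydraulic conductance is lost), and frost damage, summarized by LT50 (the
temperature, in °C, at which half of cell lysis occurs) or LT0 (the coldest
temperature with no visible damage). Both hazards act on the same vascular
tissue, so a trade-off between the two resistances is plausible; but both
traits are also strongly heritable along the phylogeny, so a cross-species
correlation can arise purely from shared evolutionary history. The package
implements the full comparative workflow needed to ask the question
properly: curate heterogeneous trait databases to one value per species,
quantify phylogenetic signal, and regress one resistance on the other at
several quantiles with and without a phylogenetic covariance structure.

## Database curation

**Frost.** Raw measurements carry organ (branch/bud/leaf), method (EL =
electrolyte leakage, yielding LT50; VS = visual scoring, yielding LT0),
date, latitude, and the freezing/thawing rate. Curation applies, in order:

1. *Midwinter filter* — only measurements from the hemisphere-appropriate
   midwinter months (Dec–Feb north, Jun–Aug south) are kept, so values
   represent maximum hardiness. Hemisphere comes from the study latitude,
   falling back to an explicit `hemisphere` column; rows with no usable
   date are dropped and counted.
2. *Rate screen* — rates below 0.2 °C h⁻¹ or above 9 °C h⁻¹ are removed
   (slow rates induce artificial hardening, fast rates intracellular ice);
   the bounds themselves are kept, and missing rates are retained with a
   flag, keeping as much data as possible.
3. *Per-cell averaging and priority selection* — within a species, values
   are averaged per (organ, method) cell, then one cell is selected in the
   order EL-branch, EL-bud, VS-branch, VS-bud, EL-leaf, VS-leaf. The
   selected priority level is reported as `lt50_category`, and category
   counts always partition the species total.

LT50 can also be estimated from raw electrolyte-leakage curves: REL(T) is
fit with a 4-parameter logistic `b + (p − b)/(1 + exp(s (T − lt50)))` by
robustified least squares with five starts seeded from temperature
quantiles; the inflection is the LT50. Curves whose REL span is below 30
percentage points carry no damage transition and are rejected ("flat
curve") rather than extrapolated.

**Drought.** Vulnerability curves that are r-shaped (the open-vessel
artifact) are removed; per species, P50 is then taken as the mean over the
best available technique tier: (1) stem centrifuge/optical/micro-CT,
(2) stem bench dehydration, (3) leaf values, (4) stem air injection.
Species whose selected P50 is less negative than their turgor-loss point
Ψ_TLP are removed as artifacts. Techniques labelled `other` on stems fall
in no tier and never drive a species value.

Species tables are joined on the canonicalized binomial (single spaces,
genus capitalized, epithet lower-cased); no synonym resolution is
attempted, and duplicate species within one source are an error, not a
silent merge.

## Phylogenetic signal

Trees are rooted with branch lengths; the Brownian covariance matrix C has
entries equal to shared root-to-MRCA path lengths. Species missing from the
tree are grafted into their genus at a uniformly chosen edge (by count) and
a uniform point along it, with the new terminal branch extended to the
clade's mean tip depth; grafting is deterministic given a seed. Pruning
retains the stem path from the original root, so the covariance of retained
tips is exactly the submatrix of the full covariance.

**Blomberg's K** is the ratio of the observed MSE₀/MSE (ordinary vs
phylogenetically corrected mean squared deviation from the GLS mean) to its
Brownian expectation `(tr C − n/(1'C⁻¹1))/(n − 1)`; K = 1 in expectation
under Brownian motion, and K is invariant to affine trait transforms.
Significance against "no signal" uses uniform tip permutations with the
`(1 + b)/(1 + B)` convention, B = 1000 by default.

**Pagel's λ** multiplies the off-diagonal of C; the profile log-likelihood
(root state and rate profiled analytically) is maximized on [0, 1] by
bounded scalar search (tolerance 1e-6). Published tooling allows λ slightly
above 1 on some trees; we clamp to [0, 1]. Likelihood-ratio tests against
λ = 0 and λ = 1 use the plain χ²₁ reference, including at the λ = 1
boundary, matching common practice; p-values near that boundary are
therefore conservative in the usual direction.

**Ancestral states** under Brownian motion are the GLS root estimates of
the tree re-rooted at each internal node; the estimate at the original root
equals the phylogenetically weighted mean by construction.

## Bayesian phylogenetic quantile regression

For species i in functional group g(i):

    y_i = α_g(i) + β_g(i) x_i + u_i + ε_i,
    ε_i ~ AL(0, σ, τ),            u ~ MVN(0, σ_p² C_std)   (phylo variant)

The asymmetric Laplace (AL) likelihood makes the fitted line the
conditional τ-quantile; τ ∈ {0.1, 0.5, 0.9} covers the edges and the
center of the trait distribution. C_std is C scaled to unit maximum
diagonal so σ_p is in response units (°C here).

*Priors* (weakly informative, scale-aware): α_g, β_g ~ Normal(0, 10·SD(y))
(slopes additionally divided by SD(x)); σ ~ half-Student-t(3, 0,
2.5·SD(y)); σ_p ~ half-Normal(0, SD(y)). x is left unstandardized so
slopes are in y-per-x units, and the ROPE applies to raw slopes.

*Sampling.* The AL admits the normal–exponential mixture
ε = σ(θw + ψ√w z) with w ~ Exp(1), θ = (1−2τ)/(τ(1−τ)),
ψ² = 2/(τ(1−τ)). Conditional on w the model is Gaussian, giving a Gibbs
sampler: conjugate multivariate-normal updates for the coefficients and for
u (one Cholesky of an n×n precision per sweep), GIG(½) updates for w drawn
through the reciprocal inverse-Gaussian identity, and adaptive random-walk
Metropolis on log σ and log σ_p. The σ move targets the marginal AL
likelihood (w integrated out) and w is redrawn immediately afterwards; the
σ_p move likewise integrates u out of the Gaussian layer — both are
partially collapsed Gibbs steps, which keeps the chain correct and mixes
far better than naive conditional updates. Step sizes adapt toward 0.44
acceptance during warmup only. Defaults are 4 chains × 10,000 iterations
with 2,000 warmup; split-Rhat and bulk ESS are attached per parameter and
the fit warns when Rhat > 1.01 or ESS < 400. Phylogenetic fits need longer
chains than non-phylogenetic ones because β, u and σ_p are strongly
coupled when the predictor itself is phylogenetically structured.

*Decision rule.* The 95% highest-density interval (narrowest window
holding ⌈0.95·N⌉ sorted draws) is compared with the region of practical
equivalence ±0.1·SD(y): a slope is practically nonzero when the HDI lies
entirely outside the ROPE, practically null when inside, undecided when
overlapping. SD uses the n−1 denominator.

Trait-by-trait panels (wood density, conduit diameter, Ks, height, SLA,
leaf area against either resistance) use per-group ordinary least squares
with the usual t-test on the slope; groups with fewer than three points are
skipped.

## Climate ranges and maximum height

Occurrences are spatially thinned: a greedy pass over seed-shuffled points
keeps a point iff it lies ≥ 10 km (great circle, Earth radius 6371 km) from
every kept point, then the kept set is subsampled to at most 15,000; both
steps are deterministic given the seed, and spacing is enforced before the
cap. Grid layers (plain-text, 6-line header) are read with nearest-cell
extraction — bilinear smoothing is deliberately avoided. Range summaries
are the mean of MAP/MAT and the 5th percentile (linear interpolation
between order statistics) of the aridity index and of daily minimum
temperature, describing the dry and cold edges of the climatic envelope.
Maximum height prefers a model-based asymptotic estimate when available;
otherwise outlier-flagged records are dropped and the 10th tallest record
is used, provided at least 100 records remain — extreme-value order
statistics are unstable below that.

## The synthetic-data generator

The generator provides every input with known truth: pure-birth
(Yule) trees made ultrametric by a final waiting interval (which also keeps
terminal branches strictly positive), genus labels assigned to maximal
clades of ≤ 6 tips, λ-transformed Brownian traits, bivariate Brownian
traits with a chosen increment correlation, functional-group labels from a
latent Brownian liability cut at its terciles (groups are therefore
phylogenetically clustered, as gymnosperms and angiosperms are), responses
with exact AL(τ) noise via inverse-CDF sampling (so the generating line is
exactly the estimand), logistic electrolyte-leakage curves, raw measurement
tables whose curated output is computable a priori (including decoy rows
that every filter must remove), and Gaussian occurrence clouds over linear
climate gradients with closed-form values at every cell.

Default study conditions: 200 species; LT50-like responses around −12 to
−30 °C with group slopes (1.5, 2.5, 1.0) °C MPa⁻¹ on P50-like predictors
(root −4 MPa, Brownian variance 6 on the unit-height tree); AL scale 3 °C
and phylogenetic SD 3 °C, i.e. residual and phylogenetic variation of the
same order, as in the real data.

For the confounding experiment (no causal slope, covariance only through
shared history) the generator uses a deep two-clade phylogeny
(`sim_two_clade_tree`, basal stems six times the clade height): on shallow
Yule trees two independent Brownian traits rarely develop strong spurious
correlation, whereas deep shared stems — the situation of the real
seed-plant phylogeny with its ancient gymnosperm/angiosperm split —
reliably do. The non-phylogenetic model is then misled while the
phylogenetic random effect absorbs the shared-history covariance.

What the generator does **not** emulate: real taxon sampling and its biome
bias, measurement-error heterogeneity across laboratories, taxonomic
synonymy, non-Brownian (e.g. Ornstein–Uhlenbeck) trait evolution, and
spatial autocorrelation in occurrence error. Passing tests demonstrate
correctness of the machinery under the stated model, not robustness to
those real-data complications.

## Numerical choices

- Covariance solves use Cholesky with a one-shot diagonal jitter of
  1e-10·mean(diag) on failure; singular matrices raise with advice.
- The λ profile likelihood flags flat profiles (star trees) instead of
  pretending precision.
- The logistic EL fit bounds lt50 to [min T − 20, max T + 20] and
  normalizes orientation so baseline < plateau.
- HDI requires ≥ 100 draws; with ties the first minimal window (sorted
  order) is reported.
- AL draws use the exact inverse CDF; the Gibbs sampler's GIG(½) draws go
  through `Generator.wald` with χ floored at 1e-12.

## Problem sizes used in the shipped checks

Recovery studies run at sizes chosen to give stable Monte-Carlo estimates
on a single CPU: λ/K recovery on 100 trees of 200 tips (tests) and 30
trees of 100 tips (acceptance script); quantile-regression recovery with 60
replicates of n = 300 per τ (tests) and 20 replicates (script);
attenuation with 50 replicates of n = 80 (tests) and 20 (script);
permutation-test calibration with 200 replicates of 199 permutations.

## Known limitations

- λ is estimated on [0, 1] only; λ > 1 (sometimes meaningful on
  non-ultrametric trees) is not explored.
- The phylogenetic random effect enters the response only; predictor
  measurement error and evolutionary error-in-x models are out of scope.
- No model comparison (LOO/WAIC) across quantiles or against Gaussian
  likelihoods is provided.
- The Gibbs sampler stores thinned summaries of the per-species effects
  (posterior mean) rather than full u draws, to bound memory.
- Grafting preserves mean clade tip depth; on strongly non-ultrametric
  genus clades the new tip's depth is a compromise.
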