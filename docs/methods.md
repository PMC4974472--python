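# Methods

`pa-effect` analyses site-level biodiversity sampled inside and outside
terrestrial protected areas (PAs). This note documents the models, the
synthetic data that the test suite runs them on, the numerical choices, and
the places where the design was genuinely open.

## Site-level biodiversity measures

From a long-format community table (one row per taxon per site) the package
computes, per site:

- **Within-sample species richness** `S`: the number of taxa recorded with a
  measurement > 0.
- **Total abundance** `N`: the plain sum of abundances. Undefined for
  occurrence-coded studies; density-valued abundances are summed as given.
- **Rarefied richness** `E[S_n]`: the analytic (hypergeometric) expectation
  of the number of species in a uniform random subsample of `n` individuals,
  `E[S_n] = Σ_i [1 − C(N−N_i, n)/C(N, n)]` over taxa with count `N_i > 0`.
  Binomial coefficients are evaluated with log-gamma functions, so totals of
  10⁵ individuals pose no overflow problem. `n` is the minimum site total
  within the study ("rarefy to the fewest individuals at any site"); if any
  site of a study is empty (`n = 0`), rarefied richness is undefined for the
  whole study. Rarefaction is restricted to integer counts — density data
  are never rounded into fictional individuals.
- **Endemicity**: the reciprocal of the community-weighted mean (CWM) log10
  geographic range size, `CWM = Σ a_i log10(R_i) / Σ a_i` over recorded
  taxa (`a_i = 1` for occurrence studies). Taxa without a range entry are
  dropped from both sums with a logged warning. Range sizes are in km²; a
  CWM ≤ 0 (possible only with sub-km² ranges) is rejected rather than
  silently inverted.

"Inverse" of the CWM is read as the reciprocal for reported *values*; the
models fit the CWM itself (a well-behaved Gaussian response) and negate the
contrast for reporting, which yields identical inference up to sign. Both
conventions are exposed.

## Protection assignment and matching

A site is protected when its coordinates fall inside any PA polygon.
Containment is topological (raw lon/lat plane, no projection) and
boundary-inclusive: a site exactly on the edge counts as inside —
deterministic, and conservative given that register boundaries are coarser
than site coordinates. Polygons crossing the antimeridian are rejected
rather than silently mishandled.

IUCN categories collapse to a four-level management factor: `unprotected`,
`III-VI` (least restrictive), `unknown` (unreported category, an
intermediate mixture on average), `I-II` (most restrictive). A site inside
several overlapping PAs is attributed to the most restrictive one (order
I-II > III-VI > unknown, ties broken by PA id) — the register does not say
which PA "owns" a point, and this ordering mirrors the management factor.
PA size/age classes cut at age < 20 years (young) and area < 400 km²
(small), computed against a reference year defaulting to 2014 (the PA
database snapshot year). Ages above 85 years or areas above 12,000 km² are
accepted with a warning: the printed ranges describe the sampled PAs, not a
rule. PAs lacking year or area get a missing size/age class and drop out of
the size/age model only.

The **matched-sites dataset** keeps, within each study, the sites whose
land-use class occurs on both sides of the PA boundary; studies with no
shared land use drop out. Matching on land use × use intensity is available
as a switch (the stricter reading; off by default). Matching is idempotent
and every retained study keeps at least one site on each side.

## Mixed-effects models

Every model carries random intercepts for study and for spatial block
nested within study, absorbing between-study differences in sampling
methodology and local spatial structure. Response families:

| measure            | family / scale                           |
|--------------------|------------------------------------------|
| richness           | Poisson, log link                        |
| abundance          | Gaussian on ln(N+1)                      |
| rarefied richness  | Gaussian on ln(E[S_n]+1)                 |
| endemicity         | Gaussian on CWM log10 range (sign flipped at reporting) |

Only the Poisson family for richness is dictated by the study design; the
Gaussian transforms follow standard practice for this kind of collation and
are overridable per model. When the Pearson dispersion of a Poisson fit
exceeds 1.5, an observation-level random intercept (OLRE) is added to
absorb overdispersion.

The Gaussian family is fitted by maximum likelihood (never REML — fixed
effects are compared by likelihood-ratio tests, which REML invalidates)
through statsmodels' linear mixed model, with a short optimizer cascade
(L-BFGS, Powell, CG) because boundary optima (variance components at zero)
defeat individual optimizers; the best converged likelihood wins. In the
single-study limit the study intercept is confounded with the fixed
intercept, so confounded random terms are dropped and the fit collapses to
ordinary least squares, as it should.

The Poisson family is fitted by an in-package Laplace-approximated ML
engine. The marginal likelihood is approximated around the conditional mode
of the random effects (penalized Newton/IRLS inner loop, sparse Cholesky-
free factorizations), with the correction `−½ log det(D·H)` at the mode.
The outer problem runs in two stages: a fast profile stage that optimizes
the joint (β, u) mode over the variance parameters only, then a joint
quasi-Newton polish of the exact Laplace objective over (β, log σ). Wald
covariance for β is the Schur complement of the joint Hessian at the
optimum. Convergence tolerance: relative change in log-likelihood below
1e−9 in the polish stage; log standard deviations are bounded in [−7, 3]
and a fit at the lower bound is flagged singular. The test suite holds this
engine to within 1e−3 of an independent adaptive Gauss–Hermite oracle
(21 nodes) on small datasets, and it reproduces lme4's `glmer` point
estimates to ~1e−4 on spot checks.

Confounders (elevation, slope, agricultural suitability) enter every model
as z-scored covariates; standardization is this package's choice — it only
rescales coefficients. The latitudinal zone splits tropical/temperate at
|latitude| ≤ 23.43665°.

**Backward elimination** repeatedly LRT-tests every droppable fixed term,
drops the one with the highest P when that P ≥ 0.05, and stops when all
droppable terms are significant. Marginality is structural: a term covered
by a retained higher-order interaction is never tested. Terms of scientific
interest (the protection factor in the headline models) are excluded from
elimination; their reported χ² comes from a single with/without-term LRT on
the final model. A negative LRT statistic beyond 0.05 (optimizer noise on
near-singular Gaussian fits) triggers a robust refit of both models before
the test is accepted.

Reported contrasts are back-transformed percentages,
`100·(exp(β) − 1)`, with Wald 95% intervals `100·(exp(β ± 1.96·SE) − 1)`.
Protection effects within a land use combine the protection main effect and
the interaction coefficient with the full covariance.

## Global effectiveness algebra

With inside/outside per-land-use ratios ρ_l aggregated by global land-area
weights w_l (weighted arithmetic mean by default; the ratio-of-weighted-
means variant is behind a flag and needs relative outside levels), the
global state identity `1 − r = a·i + (1 − a)·o` with `i = ρ·o` gives

    o = (1 − r) / (1 + a(ρ − 1)),   i = ρ·o,
    e = 1 − (1 − i)/(1 − o).

`a` is the protected fraction of terrestrial land (default 0.154) and `r`
the global average proportional loss of site-level biodiversity relative to
pristine (default 0.136); both are external inputs, not estimated here. All
internal computation is on proportions; percentages appear only at I/O.
`e` is 0 when protected sites are no better than unprotected ones, 1 when
they match pristine sites, and unbounded on both sides.

The restrictive-management scenario re-solves the identity at the scenario
ratio ρ* (taken from the I-II management contrast), holding the global
state `1 − r` fixed. The required-area inversion instead holds the outside
level fixed: the scenario's global level is `G* = a·ρ*·o + (1 − a)·o` and
the area that matches it with the current per-site levels is
`a′ = (G* − o)/(i − o)`. Holding the state fixed for the inversion would
return `a` identically (the outcome is pinned by construction), which is
why the two operations use different conventions; both are exposed and the
choice is flagged in the output.

Uncertainty on e, e* and a′ is propagated by parametric Monte Carlo:
per-land-use log ratios are drawn from normal sampling distributions on the
link scale (10,000 draws by default, seed-controlled) and pushed through
the full algebra; equal-tailed quantiles are reported.

## The synthetic-data generator

The generator emulates the structure of a large collated site-comparison database: many
independent studies, each with its own taxon pool, sampling method
(counts or occurrences), spatial blocks, one rectangular PA with sites on
both sides of its boundary, eight land-use classes, three use intensities,
and elevation/slope/agricultural-suitability covariates whose means can be
shifted inside PAs to mimic non-random PA placement.

Counts are generated by a hurdle scheme chosen so the configured protection
effects are *exact* multiplicative effects on expectations: taxon t is
present at site s with probability `π_t·exp(η_s)`, where η_s collects the
log richness factor for protection, the log land-use factor, confounder
terms and study/block Gaussian intercepts — so expected richness is exactly
log-linear and the Poisson log-link model is correctly specified for the
mean. Conditional on presence the count is `1 + Poisson(μ)` with mean
`A_t·(f_N/f_S)` at protected sites, making the pooled abundance ratio
exactly the configured abundance factor. Presence probabilities are capped
at 0.95 (capped cells are counted and reported; at the defaults they are
~0.3% of cells, an attenuation far below sampling noise). Negative-binomial
overdispersion enters as gamma mixing of the conditional Poisson mean.
Occurrence-only studies report the presence indicator.

Consequences worth knowing:

- Site richness is Poisson-binomial, slightly *under*dispersed relative to
  Poisson; Wald intervals from the Poisson GLMM are mildly conservative.
- Protection effects on rarefied richness and endemicity are emergent from
  the mechanism, not independently controllable; the configuration rejects
  non-unit factors for those two measures rather than pretending to honour
  them.
- Default conditions: 40 studies of 10–30 sites (~30% of sites
  protected), protection factors 1.106
  (richness) and 1.145 (abundance), land-use factors from 1.0 (primary
  vegetation) down to 0.5 (urban), log10 range sizes ~ N(5, 1) km²,
  study/block intercept SDs 0.30/0.15, 25% occurrence-only studies.
  Heavier calibration runs in the tests use 200 studies × 30 sites (the
  law-of-large-numbers and coverage checks) and 60 studies for the
  end-to-end run — sizes chosen to keep Monte-Carlo error well below the
  effects being verified.

What the generator does **not** emulate: species–area and distance-decay
spatial structure, phylogenetic correlation, temporal dynamics,
non-rectangular PA geometry, and any dependence of sampling effort on land
use. Passing tests therefore demonstrate correctness of the estimation
machinery under the stated generating mechanism, not robustness to every
feature of real collations.

## Numerical and degenerate-input conventions

- Rarefaction: `E[S_0] = 0`, `E[S_N] = S` exactly; `n > N` and non-integer
  counts are errors; empty studies are undefined, not zero.
- Taxa with measurement 0 contribute to neither richness nor the CWM.
- LRT statistics are clipped to zero within a 0.05 tolerance (Gaussian
  optimizer noise); beyond it the refit signal fires.
- Land-use, intensity, and management vocabularies are closed; validation
  reports offending values by name.
- Every stage is a pure function of (inputs, config, seed); the pipeline
  fans one run seed out to fixed per-stage offsets, and identical runs are
  byte-identical.

## Known limitations

- Gaussian variance components sit at boundary optima in small worlds;
  fits are flagged singular rather than re-parameterized.
- The Laplace approximation degrades for very small counts with large
  random-effect variances; the test fixtures keep expected counts moderate,
  as do the defaults.
- The land-use weights used in the effectiveness aggregation default to the
  analysed sites' land-use frequencies when no global weights table is
  supplied; real applications should supply global terrestrial-area weights.
- Covariate-based statistical matching (propensity scores etc.) is out of
  scope; matching is by land-use class only.
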