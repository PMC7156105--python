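# Methods

`ggam` implements a structured quantitative-genetic analysis of an emergent
binomial reproductive trait — brood-level extra-pair paternity (EPP) — in a
small open population receiving occasional immigrants. This note documents
the model, the synthetic-data generator, the numerical choices, and the
limitations a user should know before trusting output on real data.

## The model

### Genetic groups and total additive genetic values

In a pedigreed population with immigration, the base population is split
into two genetic groups: phantom parents of *founders* (individuals with
unknown parents already present) and phantom parents of *recent immigrants*
(parentless, flagged, optionally filtered by an arrival-cohort cutoff).
Each individual's expected genome fraction from the immigrant group,
`q_i ∈ [0, 1]`, follows the halving recursion `q_child = (q_dam + q_sire)/2`
with phantom slots contributing 1 (immigrant group) or 0 (founder group).

The total additive genetic value of individual *i* for a trait is

    u_i = a_i + g · q_i

where `a_i` is the breeding value (a deviation from the individual's
group mean) and `g` is the fixed difference in mean breeding value between
the immigrant and founder groups, estimated inside the animal model as the
regression of the latent phenotype on `q_i`. With `Var(q)` treated as a
plug-in constant computed across phenotyped individuals (both sexes pooled,
sample variance with ddof = 1; a per-sex option exists):

    Var(u_f)      = Var(a_f) + g_f² Var(q)
    Var(u_m)      = Var(a_m) + g_m² Var(q)
    cov(u_f, u_m) = cov(a_f, a_m) + g_f g_m Var(q)
    Var(a_T)      = Var(a_f) + 2 cov(a_f, a_m) + Var(a_m)
    Var(u_T)      = Var(u_f) + 2 cov(u_f, u_m) + Var(u_m)

from which `Var(u_T) − Var(a_T) = (g_f + g_m)² Var(q) ≥ 0` identically.
All derived quantities are computed **draw-wise** over the posterior and
only then summarised; a posterior-mean correlation is the mean of draw-wise
ratios, which differs from the ratio of posterior means.

### The observation model

Each brood *b* contributes `y_b ~ Binomial(n_b, logit⁻¹(η_b))` with

    η_b = β₀ + β_year (year − baseline) + β_age age_m
        + g_f q_fem + g_m q_mal
        + a_f[fem] + a_m[mal] + pe_f[fem] + pe_m[mal]
        + pair + year + e_b .

Every pedigree individual carries a *pair* of breeding values `(a_f, a_m)`
— female liability for extra-pair reproduction and male liability for
paternity loss — with joint prior `N(0, G ⊗ A)`; `G` is the unstructured
2×2 cross-sex genetic covariance matrix and `A` the additive relationship
matrix. The brood-level residual `e_b` provides latent-scale
overdispersion. The residual is applied **per brood**, shared by the
brood's offspring (the offspring of a brood are exchangeable given their
brood's latent liability); this is the parameterisation under which a
"residual variance" exists for a binomial trait at all.

### Fitting

Gibbs sampling with Pólya-Gamma augmentation: given
`ω_b ~ PG(n_b, η_b)` the binomial-logit layer becomes Gaussian with
pseudo-data `κ_b/ω_b` (`κ_b = y_b − n_b/2`) and precision `ω_b`, so every
update is conjugate:

* fixed effects + both breeding-value blocks + permanent-environment
  blocks: one joint multivariate-normal draw (dense Cholesky of the
  blocked precision, with `G⁻¹ ⊗ A⁻¹` as the animal prior precision);
* pair, year, and brood-residual effects: independent scalar normals;
* `G`: inverse-Wishart; scalar variances: inverse-gamma.

PG(1, z) variates are drawn exactly by the Devroye alternating-series
rejection sampler (numba-jitted); PG(n, z) is a sum of n PG(1, z) draws.

Variance components of weakly-informative binomial data mix slowly under
plain Gibbs (the magnitude of an effect vector and its variance random-walk
together). Each iteration therefore adds a multiplicative scale-group move
per random block (a generalized-Gibbs / "sandwich" step with the Haar
measure correction, sampled by 1-D slice sampling): the block and its
variance are rescaled jointly from the exact conditional. Even so,
substantial thinning is required; `fit_mcmc` checks the retained chain
(lag-1 autocorrelation < 0.05, ≥ 2000 retained draws by default) and
**warns, never silently accepts**, when diagnostics fail. `adaptive_thin`
post-thins to the autocorrelation target where the draw budget allows.

A Gaussian-response mode (identity link, optional known residual variance)
exists purely to validate the sampler against closed-form conjugate
posteriors and an independent reference sampler; it shares every code path
except the augmentation.

### Priors (defaults; all configurable)

* fixed effects: `N(0, 1e8)`;
* scalar variances: inverse-gamma with shape ν/2, scale νV/2 at ν = 1,
  V = 1;
* `G`: inverse-Wishart, 2 degrees of belief, identity scale.

These are conventional "relatively uninformative" choices; sensitivity to
them should be checked for any serious application (they matter most for
the weakly-identified permanent-environment and pair variances).

### Posterior summaries

Mean; mode by Gaussian-kernel density (Silverman bandwidth) argmax on a
512-point grid; 95% highest-posterior-density interval as the shortest
empirical interval; percentage of negative draws. Heritabilities divide
the focal additive variance by the sum of all *estimated* variance
components; a flag adds the logit link variance π²/3 for users wanting
that convention.

### Back-transformation

Expected observed-scale EPP rates for a covariate scenario
`(q, year, male age)` integrate the inverse logit over the latent
*residual only*, by Gauss-Hermite quadrature (≥ 20 nodes; default 30;
verified against brute-force Monte-Carlo integration to 1e-3). A scenario
comparison (e.g. observed mean q vs q = 0) is summarised on the rate
difference draw-wise. Integrating over all random effects instead is a
documented alternative the caller can implement by adding the other
variance components to the integration variance; residual-only is the
minimal convention and is what the package reports.

## The synthetic-data generator

`simulate_dataset` runs a forward demographic simulation designed to have
*exactly* the statistical structure the model assumes, so that inference
can be tested against known truth:

* founder pairs plus Poisson(~1)/year parentless, flagged immigrants;
* overlapping generations: adults survive between years (default 0.6),
  re-pair at random (no assortment by breeding value), are capped at a
  population ceiling (default 90 adults);
* each social pair rears ≥ 1 broods per year (truncated Poisson, default
  mean 0.9 before truncation ≈ 1.5 broods/pair/year) of 1–4 offspring
  (uniform);
* breeding values are inherited as parental midpoint plus
  Mendelian-sampling noise with covariance `½G(1 − (F_dam + F_sire)/2)`
  (infinitesimal model with inbreeding); immigrants draw from the same
  `N(0, G)` — their group-mean shift is carried entirely by `g·q`,
  matching the genetic-groups identifiability convention;
* brood EPP counts are binomial in the latent liability above; extra-pair
  offspring receive a random contemporary extra-pair sire, so the recorded
  pedigree is the *genetic* pedigree, as produced by molecular parentage
  assignment.

Default latent-scale parameters are the estimated study conditions of the
motivating island system (intercept −0.67, g_f −1.17, g_m −1.55, β_year
0.05, β_age −0.19, Var(a_f) 1.26, Var(a_m) 0.47, cov −0.37, residual
3.58); the permanent-individual, pair, and year variances are set to 0.1
(reported only as "small"). Demographic knobs were chosen once so that a
24-year run yields ~1,100–1,200 broods from ~35–45 pairs with ~700–800
pruned pedigree individuals — the scale of the motivating data.

Because phenotypes and pedigree are generated jointly (EPP outcomes decide
genetic sires), the engine is the canonical generator. Two decoupled
helpers support replication studies: `simulate_breeding_values` gene-drops
fresh breeding values down a *fixed* pedigree, and `simulate_phenotypes`
redraws environmental effects and binomial counts on a fixed brood
skeleton given a truth table. Replicates produced this way share one
pedigree; that is deliberate (it isolates inferential noise from pedigree
noise) but means pedigree-level variability is not propagated.

What the generator does **not** emulate: parentage-assignment error,
territoriality or other spatial structure, survival/fecundity covariates,
assortative pairing, sex-biased dispersal, and any non-exchangeable brood
structure. Passing recovery tests therefore show the estimator is correct
*under its own assumptions*, not that those assumptions hold in any field
system.

## Numerical choices and degenerate inputs

* Pedigrees are validated on construction (acyclicity via Kahn's
  algorithm naming the offending individuals, dam/sire sex consistency,
  immigrants parentless, referenced parents present) and stored in
  topological order; input row order is never trusted.
* Inbreeding coefficients come from the exact tabular kinship recursion;
  `A⁻¹` is assembled by the Henderson rules with inbreeding-aware
  Mendelian-sampling variances (unknown parent ⇒ F = −1 convention).
  Verified against dense brute-force `A` to 1e-8 on random pedigrees.
* Broods with zero offspring are rejected at read time; individuals
  phenotyped in both sexes are rejected at design construction.
* A non-finite linear predictor aborts the chain with an error naming the
  iteration (never silent NaN); inverse-Wishart draws are positive
  definite by construction and symmetrised against round-off.
* Zero-variance draws in ratio computations (correlations) are skipped and
  counted, never propagated as NaN silently.
* With a fixed seed every output — simulation, chain, pipeline run
  directory — is bit-reproducible; manifests deliberately contain no
  timestamps.

## Problem sizes used by the shipped checks

The test suite and the acceptance script run at desk scale, chosen as
package defaults: the replicate-recovery experiment uses one 12-year
pedigree (~360 broods, ~230 pruned individuals) with six phenotype
redraws and 2,600-iteration chains; the acceptance script simulates 14
years (~400–600 broods) and runs an 11,000-iteration chain retaining
2,000 thinned draws. The same experiment scales to the full
study-condition size (24 years, ~1,200 broods) through the identical API;
expect roughly 10–15 minutes per fit there, and materially longer chains
if the strict lag-1 < 0.05 retention target must be met rather than
warned about.

## Known limitations

* Cross-sex (co)variances are assumed equal in the founder and immigrant
  groups; the model estimates one shared `G`.
* Only two genetic groups are modelled (founder/immigrant); `q` machinery
  generalises to k groups but the model surface does not expose it.
* Mixing of variance components is the binding computational constraint;
  for reporting-grade posteriors on full-size data, budget long chains and
  rely on the autocorrelation diagnostics rather than defaults.
* The back-transformed rate depends on the marginalisation convention
  (residual-only here); comparisons across studies should check which
  convention was used.
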