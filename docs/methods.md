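# Methods

`owlfam` simulates a two-habitat population of burrowing owls (*Athene
cunicularia*) in which some first-year birds delay natal dispersal and
form family units, and re-implements the statistical machinery used to
study that system: spatial conspecific indices, GLM/GLMM fitting with
AICc multimodel inference, a Cormack–Jolly–Seber (CJS) survival engine,
permutation and resampling procedures, and microsatellite kinship.

## The simulated system

The generator (`synthetic_data`) is the reference description of what
every downstream analysis assumes.

**Landscape.** Nests are placed by a parent–child (Thomas) point
process inside a square of side `extent_km` (default 20 km). Urban
nests cluster around many parents with a small dispersion (0.35 km);
rural nests use fewer parents with a wide dispersion (2.5 km). Only the
*ordering* of spatial aggregation between habitats is a modelling
target; the absolute scales were chosen so that the aggregation index
clearly separates habitats at the default nest counts.

**Breeding seasons.** Each nest breeds every year. Family-unit
occurrence is Bernoulli with a logistic linear predictor in the
standardised aggregation index and conspecific-productivity residual
(slopes `density_effect` = 0.30 and `productivity_effect` = 0.22 per
SD, the magnitudes of the published model-averaged estimates). The
habitat intercept is calibrated numerically (Brent root-finding on the
realised covariates) so that the *marginal* family-unit frequency
equals `p_family_urban` = 0.07 and `p_family_rural` = 0.03 — without
this calibration the nonlinear averaging of the logistic over the
covariate distribution would inflate the realised frequency above the
nominal value. Productivity is zero-inflated Poisson (structural-zero
probability 0.2) with habitat means 2.5 (urban) and 2.0 (rural)
fledglings and a log-scale family-unit effect of 0.27. Family units
carry one extra adult in 97% of cases, two otherwise.

**Chicks.** Wing length is Normal(160 mm, 10 mm), truncated at 50 mm.
Mass follows log10(mass) = 1.45 + 0.37·log10(wing) + family shift
(`condition_family_effect`, default 0.02) + Normal(0, 0.05) noise. The
wing and mass distributions are assumptions — only the allometric line
and the size of the family-unit shift are constrained — so tests about
body condition speak to the *residual* structure, not to real
morphometric distributions.

**Attendance.** Monthly natal-nest presence (January = 1 … July = 7)
follows logit p = intercept + slope·month + urban + interaction·month·urban
with slope −0.73, urban effect 1.37 and interaction 0.16 (the published
estimates used as generating truths); the rural baseline intercept
(2.0) is not printed anywhere and was chosen to give realistic early-
season attendance. Presence is coupled within a bird through a single
uniform draw, so the month-wise marginals are exact *and* a bird never
returns after leaving. The binomial GLM fitted to such data therefore
recovers the generating coefficients consistently even though
observations within a bird are dependent; its nominal standard errors
ignore that dependence, which is one reason the analyses report
recovery against generating values rather than coverage rates.

**Encounter histories.** A standard two-age-class CJS process: marking
occasion uniform over all but the last occasion, first-interval
survival `phi_juv_urban` = 0.29 / `phi_juv_rural` = 0.21, adult
survival 0.71 thereafter, detection 0.6 (high-effort occasions) or 0.3
(low effort). An optional `phi_condition_slope` adds a logit-scale
body-condition effect for covariate-recovery experiments; it defaults
to 0.

**Genotypes.** 17 microsatellite loci, 5 alleles each, frequencies
Dirichlet(2)-drawn. Founders are Hardy–Weinberg; offspring inherit one
allele per parent; every reported gene copy is independently replaced
by a frequency-weighted random allele with probability
`genotyping_error` = 0.01.

**Dispersal distances.** Delayers: Uniform(0, 413 m) — matching the
published range for delayers. Dispersers: lognormal with median 1.5 km
and log-SD 1. Only the ordering of the two groups and the delayers'
range are constrained; the shapes are stand-ins.

What the generator does *not* emulate: floaters, movement trajectories,
density dependence, nest turnover, mark loss, heterogeneous detection
within an effort level, and linkage or null alleles in the genotypes.
Passing recovery tests on these data shows the estimators are correct
for the generative model, not that real owl data satisfy it.

## Spatial indices (`metrics`)

The aggregation index of nest *i* is S_i = Σ_{j≠i} exp(−d_ij) with
d_ij the planar distance **in kilometres**. The unit matters: the
exponential kernel in metres underflows for any realistic nest spacing,
so kilometres is the only scale on which the index varies; the unit is
still a flag. Coincident nests are legal (a zero distance contributes
1). The productivity-weighted variant multiplies each neighbour's
kernel weight by its productivity, and the conspecific-productivity
residual is the OLS residual of the weighted index on the plain one
(computed per year over the nests active that year). Body condition is
log10(mass) − (1.45 + 0.37·log10(wing)); base 10 because the printed
coefficients imply ~180 g owls in base 10 and an implausible ~28 g in
base e. Both the coefficients and the base are arguments.

## GLM/GLMM fitting and multimodel inference (`model_selection`)

Fixed-effect fits delegate to statsmodels: `GLM` for binomial, Poisson
and Gaussian; `NegativeBinomial` (NB2, dispersion α estimated by ML and
counted in k); `ZeroInflatedPoisson` / `ZeroInflatedNegativeBinomialP`
with an intercept-only inflation component. All-zero responses under
zero inflation short-circuit to the boundary solution (π = 1,
log-likelihood 0).

Random intercepts use an in-package Laplace-approximated marginal ML:
the joint mode over all random effects is found by Newton iteration
with step halving (family objects supply the first two derivatives of
the conditional log-likelihood in the linear predictor), and the
marginal likelihood is the standard Laplace correction at that mode.
One grouping factor or a crossed pair is supported; the Gaussian case
is exact. Outer optimisation is Nelder–Mead followed by BFGS on
(fixed effects, log-SDs, dispersion); log-SDs are bounded below at
1e-4, so a variance hitting the boundary reproduces the plain GLM fit.
Coefficient covariances come from a central-difference Hessian of the
negative marginal log-likelihood. k counts fixed effects, one variance
component per factor, and any dispersion or zero-inflation parameter;
n is the number of observations (not groups) — a documented convention.

AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1). Akaike weights are
exp(−Δ_i/2)/Σexp(−Δ_j/2); ties in AICc are broken by model name so the
ordering is reproducible. Averaging is full-model (zero-substitution)
over the entire candidate set by default: a term absent from a model
contributes an estimate of 0 with zero variance at that model's weight,
and the unconditional variance is Σ w_m (var_m + (β_m − β̄)²); a
Δ-threshold option restricts the set. Full-set averaging was chosen
because the published tables report averaged CIs for weakly supported
terms, which conditional or Δ≤2 averaging cannot produce.

## The CJS engine (`cmr`)

The likelihood is individual-based (not m-array) so that individual
covariates are supported; the m-array is kept as a summary. For a bird
first caught at f and last seen at l, the history probability is the
product of survival (φ) terms over intervals f..l−1, detection terms
over occasions f+1..l, and the never-seen-again probability
χ_t = (1−φ_t) + φ_t(1−p_{t+1})χ_{t+1}, computed backwards.

Structure: the first interval after marking uses the juvenile parameter
of the bird's natal habitat (JuvU/JuvR), every later interval the adult
parameter. Time enters φ as additive logit-scale deviations shared
across classes; the family-unit flag and the body-condition covariate
enter φ either with one shared slope or with separate slopes per age
class (or per group of classes, e.g. one slope shared by both juvenile
classes). Recapture can carry effort (two levels), habitat and time.
Fitting is bounded L-BFGS-B on the logit scale (|logit| ≤ 15); CIs are
delta-method on the logit, back-transformed. Estimates on the logit
bound are flagged as boundary. AICc uses the number of marked
individuals as the effective sample size. Under fully time-varying φ
and p the terminal product is confounded; the fit is flagged and mean
survival summaries drop the last interval.

Goodness of fit: a chi-square upper-tail utility for externally
computed statistics, and a parametric bootstrap (simulate from the
fitted model, refit, compare −2ℓ at the respective MLEs) reporting p
and the dispersion ratio ĉ.

## Resampling procedures (`resampling`)

The dispersal permutation test draws, in each of n_iter (default 1000)
iterations, a group of the delayers' size from the dispersers' pool
without replacement and records its median; p is the count of null
medians ≤ the observed delayer median divided by exactly n_iter (a
+1-correction variant is available, and a per-individual statistic
behind a flag). Two properties matter for interpretation: (i) the
discreteness of a Monte-Carlo p with denominator n gives a rejection
probability of (k+1)/(n+1) at threshold k/n under a uniform p, slightly
above nominal; (ii) with a finite pool the subsampled medians are
under-dispersed relative to an independent group median, which pushes
the one-sided rejection rate at the study's sizes (14 vs 208) to about
0.055–0.06 rather than 0.05. Both effects vanish as the pool and
n_iter grow; the calibration tests check the near-asymptotic regime and
a wider sanity band at the study sizes.

The survival comparison re-pairs the delayers' encounter histories with
equally many disperser histories drawn in the delayers' cohort
proportions (without replacement within a dataset), fits a constant-φ
constant-p CJS model per group per dataset (200 datasets by default),
and compares the across-dataset means with a one-tailed Z-test,
z = (m₁−m₂)/√(se₁²+se₂²), using the across-dataset spread as the
standard errors. One-tailed because only one tail is consistent with
the published pair (z = 0.76, p = 0.22).

## Kinship (`kinship`)

Pairwise relationships use the IBD-coefficient mixture over U
(k = 1,0,0), HS (0.5,0.5,0), FS (0.25,0.5,0.25) and PO (0,1,0):
per locus L = k₀P(g₁)P(g₂) + k₁S₁ + k₂S₂ with Hardy–Weinberg genotype
probabilities, S₁ the joint probability under exactly one shared IBD
allele and S₂ the identical-genotype mass. Loci multiply (linkage
equilibrium). Genotyping error is a per-allele substitution by a
frequency-weighted allele with probability e; likelihoods marginalise
over true genotypes through precomputed per-locus observation matrices,
so a single mistyping does not hard-exclude a parent at e > 0. This is
simpler than Cervus's class-based error model, so LOD values are
internally consistent but not numerically comparable to Cervus output.
The reported r is k₁/2 + k₂ of the best class; no continuous
relatedness estimator is provided. Inbreeding (published rate 0.06%)
is ignored in the likelihoods — negligible at that magnitude.

Parentage LOD is log L(candidate parent)/L(unrelated); with a known
parent the numerator is the trio likelihood (Mendelian transmission
tensor folded by the error model) and the denominator keeps the known
parent as a parent while the candidate is unrelated. Hard exclusions
at e = 0 return a large negative guard value (−1e9) rather than −inf.
Confidence thresholds follow the Cervus simulation logic: simulate
offspring whose father is in the candidate pool with probability
`prop_candidates_sampled`, score all candidates, and find the smallest
LOD-gap (Δ between best and second-best) at which the assignments above
it are correct at the target rate (80% relaxed, 95% strict). The
published "0.7% sampled parents" is treated as a misprint for the
proportion 0.7 (a 0.007 sampling rate would make assignment impossible
at 23/60 assignments); the literal value remains available. The
default simulation size is 10,000 offspring — the published 100,000
scaled down to keep the calibration under a minute at no practical loss
of threshold precision.

## Pipeline analyses (`pipeline`)

Candidate sets are hard-coded to mirror the published tables rather
than generated by all-subsets search, so reports are comparable line by
line. The family-unit occurrence set contains the 11 distinct models
of the published table (habitat, density, productivity, the pairwise
interactions, singles, null), all with a year random intercept and no
nest term (mirroring the published convergence constraint; the option
exists). Productivity uses zero-inflated Poisson with a year intercept
(all nests) or year + nest (nests ever holding a family unit); body
condition uses Gaussian GLMMs with nest and year intercepts; lifetime
reproductive success uses zero-inflated negative-binomial null vs
strategy. The survival analyses fit the published family-structure and
body-condition CJS sets, model-average real-scale survival by age class
and group, and report the body-condition slope from the best-supported
model that contains it.

Covariates in the occurrence model are centred and scaled to unit SD
(the generator's slopes are per-SD, so recovery is on the same scale);
plain centring is what the field analyses used, and scaling changes
only the units of the reported slopes.

## Numerical choices and degenerate inputs

- Logit bounds ±15 in CJS fits; probability clipping at 1e-12 inside
  likelihoods; variance floors 1e-4 on random-effect SDs.
- All-zero responses: zero-inflated fits short-circuit (π = 1, ℓ = 0);
  LRS falls back from negative binomial to Poisson when every count is
  zero (the NB dispersion is unidentifiable there).
- A constant response in the occurrence analysis (no family units, or
  nothing but family units) aborts with a clear error rather than
  fitting a separated model.
- Model-set ties break by name; permutation draws use key-partitioning
  so results are identical for a given seed regardless of pool order in
  memory.
- Single-level grouping factors are rejected; singleton-nest data shrink
  the nest variance to its floor and otherwise fit normally.

## Problem sizes used in tests

Recovery tests run at the sizes the analyses were designed around:
2,000 encounter histories × 10 occasions for survival recovery (the
estimator's sampling SD for urban juvenile survival is then ≈ 0.017),
~1,000–2,000 nest-years for the occurrence model, ~1,500–4,000 chicks
for condition analyses, 500-replicate calibration loops for the
permutation test, and 17-locus panels with 50–200 simulated pairs or
trios for kinship. These sizes make each check informative while the
whole suite stays fast.

## Known limitations

- The Laplace approximation can bias variance components for binary
  data with few observations per group; the pipeline's grouping factors
  (years, nests) are large enough that this is second-order here.
- The GLMM covariance matrix comes from a finite-difference Hessian;
  for near-boundary variances the corresponding rows are unreliable
  (fixed-effect rows are well-behaved).
- CJS model averaging combines real-scale estimates; averaging on the
  logit scale would give slightly different CIs near 0 or 1.
- The kinship confidence thresholds depend on the simulated candidate
  pool size; they are calibrated quantities, not universal constants.
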