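# Methods

This note documents the models implemented in `plantmating`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Scientific setting

The package targets mating-system analysis of a partially selfing plant
sampled from two soil ecotypes (metallicolous, MET, on metal-contaminated
soil; non-metallicolous, NONMET, on normal soil) with co-dominant
microsatellite markers.  The analyses it supports are: per-population
selfing-rate estimation, a formal between-ecotype comparison of selfing-rate
distributions, progeny-array estimation of the mating system of a single
reproductive event, classical F-statistics and isolation-by-distance
screening, and drift-based effective population size from two consecutive
seasonal samples.

## Selfing rate from multilocus heterozygosity (`selfing`)

**Model.**  An individual whose ancestry contains `n` consecutive selfing
generations has its outbred heterozygosity halved `n` times at every locus
simultaneously.  With constant selfing rate `s`, `n` is geometric, and the
probability of an observed 0/1 heterozygosity vector `x` over `L` loci is

    P(x) = sum_{n>=0} (1-s) s^n  prod_l (h_l 2^-n)^{x_l} (1 - h_l 2^-n)^{1-x_l}

where `h_l` is the outbred heterozygosity of locus `l`, a nuisance
parameter.  Only the presence/absence of heterozygotes enters, which is what
makes the estimate robust to null alleles and allelic dropout: those
artefacts rescale individual `h_l` values without touching the across-locus
correlation of heterozygosity (identity disequilibrium) that identifies `s`.

**Numerics.**
- The geometric sum is truncated at the smallest `n` with `s^(n+1) < 1e-14`
  (capped at 200) and the truncated weights are renormalised, so the
  mixture is an exact probability distribution at any truncation; the
  single-locus closed form `h(1-s)/(1-s/2)` is then reproduced to < 1e-12.
- The profile likelihood is computed on a grid of `s` (default spacing
  0.001, configurable); at each grid point the `h_l` are maximised out by an
  EM algorithm over the latent variables (`n`, ancestral-heterozygosity
  indicators), warm-started from the previous grid point.  The M-step for
  `h_l` is a posterior mean, so each iteration increases the likelihood.
- The MLE is refined between grid points by bounded scalar optimisation to
  1e-4; the 95 % CI is the 1.92 log-likelihood drop interval (chi-square, 1
  df), with one-sided intervals at the boundary `s = 0`.
- Profiles are interpolated with a cubic spline in `z = logit(s)`, where
  they are near-quadratic; piecewise-linear interpolation was measured to
  leave ~1e-4 errors in downstream quadrature and was replaced.
- `h_l` is handled by joint profile maximum likelihood (not a moment
  plug-in); the single-locus marginal closed form and an exhaustive
  2^L-pattern normalisation test pin the implementation down.

Individuals missing at every locus are dropped (logged); a data set with no
heterozygote at any locus is returned as an unidentifiable boundary result
rather than an error.

## Hierarchical ecotype comparison (`hier`)

**Model.**  Population selfing rates are random effects:
`logit(s_i) ~ N(mu_e(i), sigma_e(i)^2)` with ecotype a fixed two-level
factor.  The marginal likelihood treats each population's profile
log-likelihood `l_i(s)` as the exact likelihood of `s` and integrates it
against the random-effect density:

    ln L = sum_i ln  int exp(l_i(invlogit z)) phi(z; mu_e, sigma_e) dz

Constrained variants (shared `mu`, shared `sigma`, `sigma = 0`, fixed
values) are compared with standard chi-square LRTs.  The model ladder
mirrors a mixed-model ANOVA: free SDs, shared SD, SD = 0 group means,
single mean; a seasonal variant compares one `s` per season against a
pooled `s`.

**Numerics.**
- Integration is adaptive Gauss-Hermite (64 nodes, validated by
  node-doubling): the quadrature is centred and scaled on the mode of the
  integrand (profile x prior), found from a parabola through the three grid
  points around the argmax.  Plain Gauss-Hermite centred on the prior
  under-resolves sharp profiles (profile curvature >> random-effect scale)
  and was measured to lose ~1e-4; the adaptive version agrees with the
  conjugate normal-normal closed form on quadratic profiles to machine
  precision.
- `sigma = 0` collapses exactly to the profile values at `invlogit(mu)`.
- Estimated SDs are floored at 0.002 (the precision floor of this kind of
  iterative routine); an estimate at the floor is flagged as "effectively
  zero" rather than reported as a real spread.
- Optimisation is multi-start Nelder-Mead (3 starts: moment estimates,
  pooled, offset); boundary LRTs on `sigma = 0` use the standard chi-square
  reference (the conservative 50:50 mixture reference is a known
  alternative but is not the default).
- Back-transformed group means are the logit-normal median; under the
  `sigma = 0` reporting model used for the headline numbers the median and
  mean coincide.

Treating the profile as an exact likelihood ignores the sampling
uncertainty of the nuisance `h_l`; this is the same approximation the
profile-combination approach always makes and is noted as a limitation.

## Correlated mixed mating from progeny arrays (`progeny`)

**Model.**  For each maternal family: a progeny is selfed with probability
`s = 1 - t_m`, otherwise outcrossed with a paternal gamete from the pollen
pool; with probability `r_t` the whole sibship shares one selfing draw
(correlation of selfing); independently, with probability `r_p` the whole
outcrossed sibship shares a single father whose genotype follows
pollen-pool frequencies with inbreeding `F_p` (correlation of paternity).
Pollen and ovule frequencies are the sample frequencies (the parsimonious
equal-frequencies model).  Loci are in linkage equilibrium.

**Estimation.**  The full-family likelihood of this model is intractable
exactly: in the class "independent selfing draws + shared father",
marginalising one multilocus father over all partially selfed sibships is a
permanent-type sum (2^k selfed subsets for k progeny).  Estimation is
therefore two-stage, over two tractable composite objectives:

1. *(t_m, r_t)* maximise a whole-sibship family likelihood over the
   tractable latent classes — shared selfing draw (all selfed, or all
   outcrossed with one shared father [per-locus father marginalisation is
   exact for a fully outcrossed sibship] or independent fathers) versus
   independent progeny; the one intractable class is approximated by
   independent fathers.  This term carries the all-or-none sibship
   signature, which identifies the correlation of selfing far more sharply
   than progeny pairs do (simulation at the study design roughly halves
   both the sampling SD of the r_t estimate and its boundary mass relative
   to a pairwise fit).
2. *(r_p, F_p)* maximise the exact progeny-PAIR joint likelihood summed
   over within-family pairs with (t_m, r_t) held fixed.  The pair marginals
   of the generative model are matched exactly: the joint selfing pmf of
   two sibs has correlation `r_t`, and outcrossed sibs share a father with
   probability `r_p` (per-locus father marginalisation is exact because,
   conditional on a pair's statuses, loci factorise).  For two-progeny
   families the pair likelihood *is* the family likelihood, which is what
   the exhaustive-enumeration oracle tests check.

**Confidence intervals.**  The default CIs invert adjusted
composite-likelihood-ratio tests: the CLR for parameter k is referred to
`lambda_k * chi2_1`, with `lambda_k = (H^-1 J H^-1)_kk / (H^-1)_kk`
estimated from the empirical per-family score variance J and the CL
Hessian H (finite differences at a 0.01 step; `lambda ~ 1` for the family
objective, ~10-45 for the pairwise objective, reflecting within-family
pair dependence).  Likelihood-ratio inversion keeps a usable upper bound
when a correlation estimate sits on its 0 boundary.  The classical
whole-family percentile bootstrap (default 1000 replicates) is retained
for derived quantities (mean t_s, biparental inbreeding) and as an
optional CI method for the model parameters — measured at the study
design it covers interior parameters at roughly nominal rate but collapses
for boundary-pinned correlation estimates (coverage for r_t near 50 %),
which is why it is not the default.  Even the adjusted CLR intervals for
r_t measure slightly below nominal at 20 families (~88-90 % for a 95 %
interval): the profile is strongly non-quadratic at this sample size, and
this residual anticonservatism is documented rather than patched.

- Unknown mothers are inferred per locus from the family (prior: ovule
  genotype frequencies with inbreeding at the selfing equilibrium of the
  current `t_m`, iterated once; default ML assignment, posterior-weighted
  marginalisation as an option).
- Single-locus rates `t_s` are fitted per locus with the correlation
  parameters held at their multilocus estimates; `t_m - mean(t_s)`
  estimates biparental inbreeding.  `1/r_p` is reported as the effective
  number of fathers per sibship.
- `F_p` enters the father-genotype prior linearly, so pair tables are
  precomputed once and every likelihood evaluation is a few vector
  operations; bootstrap resampling reweights families instead of rebuilding
  tables.
- Optimisation: L-BFGS-B on `[0,1]`-bounded parameters with 5 starts;
  impossible progeny (an allele absent from both the maternal genotype and
  the pollen pool) raise an error naming family, locus and individual.

Whether the inbreeding coefficient applies to the maternal or paternal side
is ambiguous in this estimator family; the package fits `F_p` (paternal)
and exposes the maternal prior inbreeding separately.

## F-statistics and spatial structure (`popstruct`)

- Weir-Cockerham (1984) variance components throughout; multilocus values
  are ratios of summed components (the GENETIX/FSTAT convention).  `H_exp`
  is the unbiased `2n/(2n-1)` gene diversity.
- The three-level decomposition (ecotype / population-within-ecotype /
  individual-within-population) is estimated by Henderson method I on
  allele indicators with the coefficient matrix built from the observed
  (possibly unbalanced) nesting; components are additive over loci, so the
  1000-replicate locus bootstrap resamples per-locus components.  Levels
  made degenerate by the design (e.g. a single group) are dropped from the
  linear system rather than producing singular solves.
- Ecotype comparisons permute populations between ecotypes (5000
  permutations, two-sided, `(k+1)/(n+1)` p-values).
- The linkage screen flags a locus pair only when its association is
  permutation-significant AND the composite allele-count correlation
  exceeds 0.5 in more than two populations — the retention rule used with
  these marker panels.
- Mantel tests are one-sided (positive association), exhaustive over all
  `n!` permutations for `n <= 6`; the isolation-by-distance regression is
  OLS of `F_ST/(1-F_ST)` on `ln(distance km)` (haversine, R = 6371 km) with
  a Mantel-style permutation p for the slope, because pairs are not
  independent.  A simple Mantel is the primary test (no third matrix is
  involved anywhere in the workflow).
- PCA is centred and non-scaled on individual allele counts (0/1/2), with
  missing calls mean-imputed per column.
- Closed forms: `F = s/(2-s)` and its inverse `s = 2F/(1+F)`; relative Ne
  reduction `1 - (1+F(s1))/(1+F(s2))`; survival inbreeding depression
  `delta = (s_primary - s_adult) / (s_primary (1 - s_adult))` from
  `s_adult = s(1-delta)/(1 - s delta)`, forward-checked on evaluation.

## Temporal effective size (`netemporal`)

Per allele (collapsed focal-vs-rest), the likelihood places a uniform prior
on the initial frequency (interior grid, default 64 points, validated by
grid-doubling), propagates it through the `g`-step Wright-Fisher
binomial transition, and applies binomial sampling layers for both samples;
per-allele log-likelihoods are summed over loci into a pseudo-likelihood
maximised over a log-spaced Ne grid with local refinement.  The CI is the
1.92-drop profile interval; the search cap (default 50 000) and saturation
flags mark data without drift signal.  Exact lattice transitions are used
up to Ne = 500; beyond that a beta distribution matched to the WF mean and
variance is used (the two modes agree to a few percent total variation at
the switch point, checked on coarse bins).  The two seasonal samples are
treated as one generation apart, exposed as a parameter because partial
biennial flowering blurs generation length; sampling is plan-II style
(binomial layers independent of the breeding population).  A Nei-Tajima
moment (temporal-F) estimator is provided purely as a cross-check.

The pseudo-likelihood treats alleles as independent, which overstates
curvature somewhat; CIs are therefore likelihood-drop intervals on the
pseudo-likelihood, validated by simulation recovery (median estimates near
truth at Ne = 25 and 100 under the study's sampling design) rather than by
asymptotics.

## Synthetic data (`synthdata`)

The generators define the study conditions used throughout the tests:

| parameter | default | rationale |
|---|---|---|
| populations | 10 (5 MET + 5 NONMET) | the sampled design |
| plants per population | 45 | field sample sizes 40-50 |
| loci x alleles | 14 x ~6, Dirichlet(1.5) base frequencies | marker panel |
| ecotype mean selfing | 0.25 (MET), 0.40 (NONMET), sigma = 0 | observed contrast |
| divergence theta_pop | 0.25 (Balding-Nichols), no ecotype-level divergence | observed pairwise F_ST 0.07-0.42, no ecotype structure |
| progeny design | 20 mothers x 15 seeds; t_m 0.75, r_t 0.1, r_p 0.3, F_p 0.1 | array design and estimate ranges |
| temporal design | Ne 100, g 1, samples of 45 | seasonal resampling |

Individuals are built as an outbred Hardy-Weinberg draw followed by a
geometric number of Mendelian selfing generations (heterozygosity survives
with probability `2^-n`), which reproduces the equilibrium `F = s/(2-s)`.
Allelic dropout is applied after genotype generation (each call at an
affected locus loses one random allele with the given rate), so a clean
twin sharing the seed has identical underlying genotypes — that is what the
paired robustness tests rely on.  Progeny arrays are simulated from the full
whole-sibship shared-draw model, so estimator recovery tests cross model
boundaries (full generative model vs pairwise composite fit).  Not
emulated: spatial continuum structure, selection, linked loci, genotyping
error beyond dropout, and family-size variation within an array; passing
tests therefore demonstrate statistical correctness under the declared
design, not robustness to every field artefact.

## Problem sizes used in the test suite

Replicated checks run at the study design (50 plants x 14 loci; 20 x 15
progeny arrays; temporal samples of 100 at 20 loci) with replicate counts
chosen to keep the full suite inside a practical single-CPU budget: 80
data sets per selfing-recovery setting, 40 paired dropout simulations, 500
null LRT calibrations on closed-form profiles, 30 genotype-level power
replicates, 40 progeny-CI-coverage replicates, and 40-50 temporal-Ne
replicates.  Bulk selfing fits in replicated tests use a 0.01-0.02 profile
grid with 1e-4 refinement, which was verified to match the 0.001 grid to
~1e-4 in the estimate.

## Known limitations

- The selfing profile treats `h_l` as free per locus; with very few loci
  the profile can be flat and the CI wide — flagged, not hidden.
- The hierarchical model inherits whatever bias the per-population profiles
  carry; it does not propagate `h_l` uncertainty.
- The progeny estimator is a composite likelihood: its point estimates are
  consistent and its bootstrap CIs valid, but likelihood ratios between
  nested mating models are not chi-square calibrated and are not offered.
- The temporal likelihood assumes a closed population (no immigration); an
  open population biases Ne downward-to-upward depending on the migrant
  pool and is out of scope.
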