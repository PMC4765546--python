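# plantmating

Mating-system and population-structure analysis for diploid co-dominant
(microsatellite) genotype data, built for studies of partially selfing
plants sampled from contrasting habitats — here, a pseudometallophyte
growing on metal-contaminated (metallicolous) and normal (non-metallicolous)
soils.

The field data such studies rest on are often not depositable, so the
package ships seeded generators that reproduce the study design (10
populations in 2 ecotypes, 40–50 plants, ~14 loci, 20-mother progeny
arrays, two seasonal samples) and every estimator is validated by parameter
recovery against that ground truth.

## What it computes

- **Selfing rate from multilocus heterozygosity** (`plantmating.selfing`):
  the probability of a 0/1 heterozygosity vector under partial selfing is
  `P(x) = Σ_n (1−s) s^n Π_l (h_l 2^−n)^{x_l} (1 − h_l 2^−n)^{1−x_l}` —
  selfing for `n` generations halves heterozygosity at every locus at once,
  and that across-locus correlation (identity disequilibrium) identifies
  `s` robustly against null alleles and dropout.  Profile likelihood on a
  grid of `s` with per-locus `h_l` maximised out by EM; 95 % CIs from the
  1.92 log-likelihood drop.
- **Hierarchical ecotype comparison** (`plantmating.hier`):
  `logit(s_i) ~ N(μ_e, σ_e²)` per ecotype, fitted by combining the
  population profiles with adaptive Gauss–Hermite quadrature; nested
  constraints (shared μ and/or σ, σ = 0) compared by likelihood-ratio
  tests, reproducing the mixed-model ANOVA logic of the ecotype contrast.
- **Correlated mixed mating from progeny arrays** (`plantmating.progeny`):
  multilocus and single-locus outcrossing rates `t_m`, `t_s`, correlation
  of selfing `r_t`, correlation of paternity `r_p` (effective fathers
  `1/r_p`), paternal inbreeding `F_p`; a whole-sibship family likelihood
  for the selfing side plus exact progeny-pair likelihoods for the
  paternity side, with adjusted likelihood-ratio CIs and optional
  whole-family bootstrap.
- **F-statistics and space** (`plantmating.popstruct`): Weir–Cockerham
  F_IS/F_ST with locus bootstraps, a three-level
  ecotype/population/individual decomposition, FSTAT-style permutation
  comparisons, a linkage screen, Mantel tests and the
  `F_ST/(1−F_ST)` vs `ln(distance)` isolation-by-distance regression,
  centred non-scaled PCA, and the closed forms `F = s/(2−s)`,
  `s = 2F/(1+F)`, the Ne reduction `1 − (1+F(s₁))/(1+F(s₂))` and the
  survival inbreeding depression `δ = (s_p − s_a)/(s_p(1 − s_a))`.
- **Temporal effective size** (`plantmating.netemporal`): maximum
  pseudo-likelihood Ne from allele-frequency change between two seasons
  (uniform prior × Wright–Fisher transition × binomial sampling layers),
  with profile CIs, cap/saturation flags and a temporal-F moment
  cross-check.
- **I/O** (`plantmating.geno_io`): Genepop (2- and 3-digit) and tidy-CSV
  genotype tables, progeny-array CSVs, population metadata, pooling with a
  genotyping-platform guard.

## Worked example

```python
import numpy as np
from plantmating import synthdata, selfing, hier

cfg = synthdata.SimConfig(seed=7)          # the two-ecotype study design
pops, truth = synthdata.sim_metapopulation(cfg)

profiles, assign = [], {}
for i, (name, g) in enumerate(pops.items()):
    prof = selfing.fit_selfing(g, grid_step=0.01)
    profiles.append(prof)
    assign[i] = g.meta.ecotype
    print(f"{name}: s = {prof.s_hat:.3f} "
          f"(95% CI {prof.ci95[0]:.3f}-{prof.ci95[1]:.3f})")

ladder = hier.ecotype_pipeline(profiles, assign)
print(ladder[["model", "loglik", "deviance_diff", "df", "pvalue"]])
```

prints (abridged):

```
MET0: s = 0.285 (95% CI 0.160-0.423)
MET1: s = 0.198 (95% CI 0.085-0.341)
...
NONMET3: s = 0.465 (95% CI 0.330-0.595)
NONMET4: s = 0.368 (95% CI 0.220-0.515)
                           model       loglik  deviance_diff   df    pvalue
0  per-group mu, per-group sigma -3827.612479            NaN  NaN       NaN
1     per-group mu, shared sigma -3827.612479       0.000000  1.0  1.000000
2          per-group mu, sigma=0 -3827.612464            NaN  NaN       NaN
3             shared mu, sigma=0 -3833.027270      10.829611  1.0  0.000999
```

Reading: the among-population spread collapses to the σ floor (the two
ecotypes do not differ in spread, deviance ≈ 0), while forcing a single
mean selfing rate across ecotypes costs 10.8 deviance units on 1 df
(p ≈ 0.001) — the ecotypes genuinely differ, as they should: the generator
used mean selfing 0.25 (MET) vs 0.40 (NONMET).

The full narrative analysis lives in `analysis/` (`01_simulate.py` …
`06_effective_size.py`), each step writing its tables under `results/`.

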