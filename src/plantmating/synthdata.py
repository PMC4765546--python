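"""Seeded generators for microsatellite data with known mating-system structure.

These generators emulate the study design every estimator in the package is
aimed at: ten populations in two ecotypes (five metallicolous, five
non-metallicolous soil types), 40-50 plants each, ~14 loci with 5-6 alleles,
population selfing rates drawn logit-normally per ecotype around 0.25 / 0.40,
Balding-Nichols population divergence, optional allelic dropout, 20-mother
progeny arrays of 13-20 seeds, and two consecutive yearly samples linked by
Wright-Fisher drift.

Every generator is a pure function of (config, seed) and returns ground-truth
records sufficient to score the corresponding estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geno_io import (Family, GenotypeMatrix, PopMeta, ProgenyArraySet,
                      TemporalPair)
from .selfing import SelfingProfile, equilibrium_fis


def _logit(p):
    return np.log(p / (1 - p))


def _invlogit(z):
    return 1 / (1 + np.exp(-z))


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generators.

    Defaults mirror the field design the estimators target: 10 populations
    (2 ecotypes x 5), 45 plants each, 14 loci x 6 alleles, ecotype mean
    selfing 0.25 (MET) vs 0.40 (NONMET) with zero among-population spread on
    the logit scale, Balding-Nichols divergence theta_pop = 0.25, no ecotype-
    level divergence, progeny arrays of 20 mothers x 15 seeds with
    t_m = 0.75, r_t = 0.1, r_p = 0.3, F_p = 0.1, and temporal samples one
    generation apart at Ne = 100.
    """

    seed: int = 0
    n_populations: int = 10
    ecotypes: tuple = ("MET", "NONMET")
    pops_per_ecotype: int = 5
    mu_logit_s: dict = field(default_factory=lambda: {
        "MET": _logit(0.25), "NONMET": _logit(0.40)})
    sigma_logit_s: dict = field(default_factory=lambda: {
        "MET": 0.0, "NONMET": 0.0})
    theta_pop: float = 0.25
    theta_ecotype: float = 0.0
    n_loci: int = 14
    n_alleles: int = 6
    dirichlet_alpha: float = 1.5
    n_individuals: int = 45
    dropout: float = 0.0
    dropout_loci: int = 0
    n_families: int = 20
    progeny_per_family: int = 15
    t_m: float = 0.75
    r_t: float = 0.1
    r_p: float = 0.3
    F_p: float = 0.1
    Ne: Optional[int] = 100
    generations: int = 1
    sample_size_temporal: int = 45


def base_frequencies(rng, n_loci: int, n_alleles: int, alpha: float = 1.5):
    """Ancestral per-locus allele frequencies, Dirichlet(alpha) per locus."""
    return [rng.dirichlet(np.full(n_alleles, alpha)) for _ in range(n_loci)]


def bn_population_freqs(rng, base_freqs, theta: float):
    """Balding-Nichols draw of population frequencies around the base pool."""
    if theta <= 0:
        return [f.copy() for f in base_freqs]
    c = (1 - theta) / theta
    return [rng.dirichlet(np.maximum(f * c, 1e-8)) for f in base_freqs]


def _selfing_collapse(rng, geno, n_self):
    """Apply n_self generations of selfing to an outbred draw.

    From a heterozygous ancestor, heterozygosity survives with prob 2^-n;
    otherwise the genotype fixes on either allele with equal probability.
    """
    a, b = geno
    if a == b or n_self == 0:
        return geno
    if rng.random() < 2.0 ** -n_self:
        return geno
    return (a, a) if rng.random() < 0.5 else (b, b)


def sim_population(rng, freqs: Sequence[np.ndarray], s: float, n: int,
                   dropout: float = 0.0, dropout_loci=(),
                   meta: Optional[PopMeta] = None,
                   allele_offset: int = 1) -> GenotypeMatrix:
    """Simulate n individuals at inbreeding equilibrium under selfing rate s.

    Each individual carries a geometric number of consecutive selfing
    generations in its ancestry (n_self ~ Geom(1-s)); the outbred ancestor is
    a Hardy-Weinberg draw from the population frequencies.  ``dropout`` is a
    per-call probability (at the loci listed in ``dropout_loci``) that one
    random allele of the call fails to amplify, turning a heterozygote into
    an apparent homozygote.
    """
    L = len(freqs)
    calls = np.zeros((n, L, 2), dtype=np.int64)
    for i in range(n):
        n_self = rng.geometric(1 - s) - 1 if s > 0 else 0
        for l in range(L):
            k = len(freqs[l])
            a, b = rng.choice(k, size=2, p=freqs[l])
            a, b = _selfing_collapse(rng, (int(a), int(b)), n_self)
            calls[i, l] = (a + allele_offset, b + allele_offset)
    names = [f"ind{i}" for i in range(n)]
    loci = [f"loc{l}" for l in range(L)]
    g = GenotypeMatrix(names, loci, calls, meta or PopMeta())
    if dropout > 0 and len(dropout_loci):
        apply_dropout(g, dropout, dropout_loci, rng)
    return g


def apply_dropout(g: GenotypeMatrix, rate: float, loci, rng) -> GenotypeMatrix:
    """In-place allelic dropout: at each affected locus, each call loses one
    random allele with probability ``rate``; a heterozygote then reads as a
    homozygote for the surviving allele.  Applied after genotype generation,
    so a clean twin of the same seed shares the underlying genotypes.
    """
    for l in loci:
        hit = rng.random(g.n_individuals) < rate
        which = rng.integers(0, 2, g.n_individuals)
        for i in np.where(hit)[0]:
            keep = g.calls[i, l, which[i]]
            if keep != 0:
                g.calls[i, l] = (keep, keep)
    return g


def sim_metapopulation(cfg: SimConfig):
    """Simulate the two-ecotype multi-population design.

    Returns (pops, truth): a dict of GenotypeMatrix keyed by population name
    and a truth record with per-population selfing rates, frequencies and the
    generating divergence/ecotype parameters.
    """
    rng = np.random.default_rng(cfg.seed)
    base = base_frequencies(rng, cfg.n_loci, cfg.n_alleles, cfg.dirichlet_alpha)
    pops, truth_pops = {}, {}
    for e in cfg.ecotypes:
        eco_base = (bn_population_freqs(rng, base, cfg.theta_ecotype)
                    if cfg.theta_ecotype > 0 else base)
        for j in range(cfg.pops_per_ecotype):
            name = f"{e}{j}"
            pf = bn_population_freqs(rng, eco_base, cfg.theta_pop)
            z = rng.normal(cfg.mu_logit_s[e], cfg.sigma_logit_s[e])
            s = float(_invlogit(z))
            n_drop = cfg.dropout_loci
            drop_idx = rng.choice(cfg.n_loci, size=n_drop, replace=False) if n_drop else []
            gm = sim_population(rng, pf, s, cfg.n_individuals,
                                dropout=cfg.dropout, dropout_loci=drop_idx,
                                meta=PopMeta(population=name, ecotype=e))
            pops[name] = gm
            truth_pops[name] = {"s": s, "ecotype": e,
                                "dropout_loci": [int(i) for i in drop_idx],
                                "freqs": [f.tolist() for f in pf]}
    truth = {"populations": truth_pops, "theta_pop": cfg.theta_pop,
             "theta_ecotype": cfg.theta_ecotype,
             "mu_logit_s": dict(cfg.mu_logit_s),
             "sigma_logit_s": dict(cfg.sigma_logit_s)}
    return pops, truth


def _hwe_genotype(rng, p, F=0.0):
    """One genotype from allele frequencies p with inbreeding coefficient F."""
    if F > 0 and rng.random() < F:
        a = rng.choice(len(p), p=p)
        return int(a), int(a)
    a, b = rng.choice(len(p), size=2, p=p)
    return int(a), int(b)


def sim_progeny_arrays(cfg: SimConfig, freqs=None, meta=None):
    """Simulate maternal families under the correlated mixed-mating model.

    Family-level draws: with probability r_t the whole sibship shares one
    selfing draw (selfed with prob s = 1 - t_m), else progeny self
    independently; independently, with probability r_p the whole outcrossed
    sibship shares a single father (genotype from the pollen pool with
    inbreeding F_p), else each outcrossed progeny gets its own father.

    Returns (ProgenyArraySet, truth) with per-progeny selfed flags and father
    identifiers.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    if freqs is None:
        freqs = base_frequencies(rng, cfg.n_loci, cfg.n_alleles, cfg.dirichlet_alpha)
    L = len(freqs)
    s = 1 - cfg.t_m
    F_m = equilibrium_fis(s)
    families = []
    truth_fams = []
    loci = [f"loc{l}" for l in range(L)]
    for fi in range(cfg.n_families):
        mother = np.array([_hwe_genotype(rng, freqs[l], F_m) for l in range(L)],
                          dtype=np.int64) + 1
        k = cfg.progeny_per_family
        shared_self = rng.random() < cfg.r_t
        if shared_self:
            selfed = np.full(k, rng.random() < s)
        else:
            selfed = rng.random(k) < s
        shared_father = rng.random() < cfg.r_p
        common_father = np.array([_hwe_genotype(rng, freqs[l], cfg.F_p)
                                  for l in range(L)], dtype=np.int64) + 1
        calls = np.zeros((k, L, 2), dtype=np.int64)
        father_ids = []
        for i in range(k):
            if selfed[i]:
                father_ids.append(-1)  # self
                for l in range(L):
                    calls[i, l, 0] = mother[l, rng.integers(2)]
                    calls[i, l, 1] = mother[l, rng.integers(2)]
            else:
                if shared_father:
                    father = common_father
                    father_ids.append(0)
                else:
                    father = np.array([_hwe_genotype(rng, freqs[l], cfg.F_p)
                                       for l in range(L)], dtype=np.int64) + 1
                    father_ids.append(1000 + i)
                for l in range(L):
                    calls[i, l, 0] = mother[l, rng.integers(2)]
                    calls[i, l, 1] = father[l, rng.integers(2)]
        gm = GenotypeMatrix([f"fam{fi}_p{i}" for i in range(k)], loci, calls,
                            PopMeta(population=(meta.population if meta else "sim")))
        families.append(Family(progeny=gm, mother=mother.copy()))
        truth_fams.append({"selfed": selfed.tolist(),
                           "father_ids": father_ids,
                           "shared_self_draw": bool(shared_self),
                           "shared_father_draw": bool(shared_father)})
    truth = {"t_m": cfg.t_m, "r_t": cfg.r_t, "r_p": cfg.r_p, "F_p": cfg.F_p,
             "families": truth_fams,
             "freqs": [f.tolist() for f in freqs]}
    return ProgenyArraySet(families, meta or PopMeta(population="sim")), truth


def sim_temporal(cfg: SimConfig, freqs=None):
    """Two samples of one population linked by Wright-Fisher drift.

    ``cfg.Ne is None`` means no drift (infinite effective size).  Samples of
    ``sample_size_temporal`` individuals are Hardy-Weinberg draws from the
    generation-0 and generation-g frequencies.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    if freqs is None:
        freqs = base_frequencies(rng, cfg.n_loci, cfg.n_alleles, cfg.dirichlet_alpha)
    f0 = [f.copy() for f in freqs]
    f1 = [f.copy() for f in f0]
    if cfg.Ne is not None:
        for _ in range(cfg.generations):
            f1 = [rng.multinomial(2 * cfg.Ne, f) / (2 * cfg.Ne) for f in f1]

    def draw(fs, tag):
        n = cfg.sample_size_temporal
        L = len(fs)
        calls = np.zeros((n, L, 2), dtype=np.int64)
        for i in range(n):
            for l in range(L):
                a, b = rng.choice(len(fs[l]), size=2, p=fs[l])
                calls[i, l] = (a + 1, b + 1)
        return GenotypeMatrix([f"{tag}_i{i}" for i in range(n)],
                              [f"loc{l}" for l in range(L)], calls,
                              PopMeta(population="temporal", year=tag))

    pair = TemporalPair(draw(f0, "t0"), draw(f1, "t1"),
                        generations_elapsed=cfg.generations)
    truth = {"Ne": cfg.Ne, "g": cfg.generations,
             "f0": [f.tolist() for f in f0], "f1": [f.tolist() for f in f1]}
    return pair, truth


def sim_profiles(m: Sequence[float], v: float, grid=None):
    """Closed-form quadratic selfing profiles on the logit scale.

    Profile i is l_i(s) = -(logit(s) - m_i)^2 / (2 v): a normal log-density
    kernel in z = logit(s) with mode m_i and curvature 1/v.  Used to exercise
    the hierarchical model against conjugate normal-normal algebra.
    """
    if grid is None:
        grid = np.arange(0.001, 0.9995, 0.001)
    grid = np.asarray(grid)
    z = _logit(grid)
    profiles = []
    for mi in m:
        ll = -((z - mi) ** 2) / (2 * v)
        k = int(np.argmax(ll))
        profiles.append(SelfingProfile(grid, ll, s_hat=float(grid[k]),
                                       ci95=(float(grid[0]), float(grid[-1])),
                                       n_individuals=0, n_loci=0))
    return profiles
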