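"""Correlated mixed-mating progeny-array model."""

import itertools

import numpy as np
import pytest

from plantmating.geno_io import Family, GenotypeMatrix, PopMeta, ProgenyArraySet
from plantmating.progeny import (IncompatibleProgenyError, _father_genotypes,
                                 _out_given_father, biparental_inbreeding,
                                 effective_fathers, family_loglik, fit_mating,
                                 pair_loglik, t_out_prob, t_self_prob)
from plantmating.synthdata import SimConfig, sim_progeny_arrays


def generative_pair_oracle(o1, o2, m, p, t_m, r_t, r_p, F_p):
    """Brute-force enumeration over all latent combinations of the
    generative model: selfing-sharing class x per-progeny selfing draws x
    father-sharing class x shared-father genotypes."""
    s = 1 - t_m
    tot = 0.0
    for t_shared, pt in ((True, r_t), (False, 1 - r_t)):
        if t_shared:
            status_sets = [((True, True), s), ((False, False), 1 - s)]
        else:
            status_sets = [((s1, s2), (s if s1 else 1 - s) * (s if s2 else 1 - s))
                           for s1 in (True, False) for s2 in (True, False)]
        for (s1, s2), ps in status_sets:
            for f_shared, pf in ((True, r_p), (False, 1 - r_p)):
                if f_shared:
                    val = 0.0
                    for g, hw, hom in _father_genotypes(p):
                        pg = (1 - F_p) * hw + F_p * hom
                        v1 = t_self_prob(o1, m) if s1 else _out_given_father(o1, m, g)
                        v2 = t_self_prob(o2, m) if s2 else _out_given_father(o2, m, g)
                        val += pg * v1 * v2
                else:
                    v1 = t_self_prob(o1, m) if s1 else t_out_prob(o1, m, p)
                    v2 = t_self_prob(o2, m) if s2 else t_out_prob(o2, m, p)
                    val = v1 * v2
                tot += pt * ps * pf * val
    return np.log(tot)


P3 = {1: 0.5, 2: 0.3, 3: 0.2}
GENOS = list(itertools.combinations_with_replacement([1, 2, 3], 2))


class TestPairLikelihood:
    def test_matches_generative_enumeration(self):
        params = (0.73, 0.17, 0.29, 0.12)
        for m in [(1, 2), (3, 3)]:
            for o1 in GENOS:
                for o2 in GENOS:
                    try:
                        got = pair_loglik([o1], [o2], [m], [P3], *params)
                    except IncompatibleProgenyError:
                        continue
                    want = generative_pair_oracle(o1, o2, m, P3, *params)
                    assert got == pytest.approx(want, abs=1e-10)

    def test_normalisation_over_genotype_pairs(self):
        params = (0.6, 0.3, 0.4, 0.2)
        total = 0.0
        for o1 in GENOS:
            for o2 in GENOS:
                try:
                    total += np.exp(pair_loglik([o1], [o2], [(1, 2)], [P3],
                                                *params))
                except IncompatibleProgenyError:
                    pass
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_independence_limit_factorises(self):
        """r_t = r_p = 0: the pair splits into per-progeny mixtures."""
        t_m = 0.7
        s = 1 - t_m
        for o1, o2 in [((1, 1), (2, 3)), ((1, 2), (1, 2))]:
            joint = pair_loglik([o1], [o2], [(1, 2)], [P3], t_m, 0.0, 0.0, 0.0)
            parts = sum(
                np.log(s * t_self_prob(o, (1, 2)) +
                       (1 - s) * t_out_prob(o, (1, 2), P3))
                for o in (o1, o2))
            assert joint == pytest.approx(parts, abs=1e-12)

    def test_single_locus_conditional_progeny_probs_sum_to_one(self):
        """Per-progeny genotype probabilities normalise for random params."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            t = rng.random()
            for m in [(1, 2), (2, 2)]:
                tot = sum((1 - t) * t_self_prob(o, m) + t * t_out_prob(o, m, P3)
                          for o in GENOS)
                assert tot == pytest.approx(1.0, abs=1e-12)


def _make_arrays(families_calls, mothers, loci=("L1",)):
    fams = []
    for calls, mother in zip(families_calls, mothers):
        gm = GenotypeMatrix([f"p{i}" for i in range(len(calls))],
                            list(loci), np.asarray(calls))
        fams.append(Family(progeny=gm,
                           mother=None if mother is None else np.asarray(mother)))
    return ProgenyArraySet(fams, PopMeta(population="t"))


class TestFitMating:
    def test_certain_outcrossing_hits_boundary(self):
        """Every progeny carries an allele its homozygous mother lacks."""
        fams = [[[[1, 2]], [[1, 3]], [[1, 2]]] for _ in range(4)]
        mothers = [[[1, 1]]] * 4
        arrays = _make_arrays(fams, mothers)
        with pytest.warns(UserWarning, match="fewer than 5 families"):
            fit = fit_mating(arrays, n_bootstrap=0, fit_ts=False)
        assert fit.params.t_m == pytest.approx(1.0, abs=1e-4)
        assert fit.boundary["t_m"]

    def test_single_locus_biparental_is_zero_by_definition(self):
        cfg = SimConfig(seed=9, n_families=10, progeny_per_family=8, n_loci=1,
                        n_alleles=4)
        arrays, _ = sim_progeny_arrays(cfg)
        fit = fit_mating(arrays, n_bootstrap=0)
        est, _ = biparental_inbreeding(fit)
        assert est == pytest.approx(0.0, abs=1e-3)

    def test_recovery_and_order_invariance(self):
        cfg = SimConfig(seed=21, n_families=20, progeny_per_family=15,
                        n_loci=10, n_alleles=5, t_m=0.75, r_t=0.1, r_p=0.3)
        arrays, _ = sim_progeny_arrays(cfg)
        fit = fit_mating(arrays, n_bootstrap=0, fit_ts=False)
        assert fit.params.t_m == pytest.approx(0.75, abs=0.15)
        # progeny order within family and family order do not change loglik
        perm_fams = [Family(progeny=f.progeny.subset_individuals(
            np.random.default_rng(1).permutation(f.progeny.n_individuals)),
            mother=f.mother) for f in arrays.families][::-1]
        fit2 = fit_mating(ProgenyArraySet(perm_fams, arrays.meta),
                          n_bootstrap=0, fit_ts=False)
        # optimiser termination noise only; the objective itself is invariant
        assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-3)
        assert fit2.params.t_m == pytest.approx(fit.params.t_m, abs=1e-3)

    def test_mother_known_vs_inferred_agree(self):
        cfg = SimConfig(seed=33, n_families=20, progeny_per_family=15,
                        n_loci=10, n_alleles=5, t_m=0.75, r_t=0.1, r_p=0.3)
        arrays, _ = sim_progeny_arrays(cfg)
        fit_known = fit_mating(arrays, n_bootstrap=0, fit_ts=False)
        blind = ProgenyArraySet(
            [Family(progeny=f.progeny, mother=None) for f in arrays.families],
            arrays.meta)
        fit_blind = fit_mating(blind, n_bootstrap=0, fit_ts=False)
        assert fit_blind.params.t_m == pytest.approx(fit_known.params.t_m,
                                                     abs=0.08)

    def test_bootstrap_ci_contains_point_estimate(self):
        cfg = SimConfig(seed=2, n_families=12, progeny_per_family=8,
                        n_loci=6, n_alleles=4)
        arrays, _ = sim_progeny_arrays(cfg)
        fit = fit_mating(arrays, n_bootstrap=60, seed=5, fit_ts=False)
        lo, hi = fit.ci95["t_m"]
        assert 0 <= lo <= hi <= 1


class TestEffectiveFathers:
    @pytest.mark.parametrize("rp,expected", [(0.032, 31), (0.35, 3), (1.0, 1)])
    def test_reported_values(self, rp, expected):
        rounded, raw = effective_fathers(rp)
        assert rounded == expected
        assert raw == pytest.approx(1 / rp)

    def test_zero_correlation_is_unbounded(self):
        rounded, raw = effective_fathers(0.0)
        assert rounded is None and np.isinf(raw)
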