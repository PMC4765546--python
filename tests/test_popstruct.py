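"""F-statistics, permutation tests, geography and closed-form arithmetic."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from plantmating import synthdata as sd
from plantmating.geno_io import GenotypeMatrix, PopMeta
from plantmating.popstruct import (diversity_table, geo_distances,
                                   hierarchical_f, ibd_regression, ld_screen,
                                   mantel, ne_reduction_from_selfing,
                                   pairwise_fst, pca_freqs,
                                   permutation_compare,
                                   required_inbreeding_depression, wc_fis,
                                   wc_fst)


def naive_wc_theta(counts_per_pop):
    """Independent naive Weir-Cockerham theta for one locus from genotype
    count dicts {(a,b): n} per population (variance components written out
    directly from the 1984 definitions)."""
    r = len(counts_per_pop)
    n = np.array([sum(c.values()) for c in counts_per_pop], dtype=float)
    nbar = n.mean()
    nc = (n.sum() - (n ** 2).sum() / n.sum()) / (r - 1)
    alleles = sorted({a for c in counts_per_pop for g in c for a in g})
    a_sum = bc_sum = 0.0
    for al in alleles:
        p = np.array([sum(cnt * ((g[0] == al) + (g[1] == al)) / (2 * ni)
                          for g, cnt in c.items())
                      for c, ni in zip(counts_per_pop, n)])
        h = np.array([sum(cnt * (g[0] != g[1]) * ((al in g))
                          for g, cnt in c.items()) / ni
                      for c, ni in zip(counts_per_pop, n)])
        pbar = (n * p).sum() / n.sum()
        hbar = (n * h).sum() / n.sum()
        s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        a_sum += a
        bc_sum += a + b + c
    return a_sum / bc_sum


def _pop_from_counts(counts, name):
    calls = []
    for g, cnt in counts.items():
        calls.extend([list(g)] * cnt)
    arr = np.array(calls)[:, None, :]
    return GenotypeMatrix([f"{name}{i}" for i in range(len(calls))], ["L"],
                          arr, PopMeta(population=name))


class TestWeirCockerham:
    def test_f_is_one_without_heterozygotes(self):
        g = _pop_from_counts({(1, 1): 5, (2, 2): 5}, "p")
        assert wc_fis(g) == pytest.approx(1.0, abs=1e-12)

    def test_theta_one_for_fixed_difference(self):
        a = _pop_from_counts({(1, 1): 10}, "a")
        b = _pop_from_counts({(2, 2): 10}, "b")
        assert wc_fst([a, b]) == pytest.approx(1.0, abs=1e-12)

    def test_three_population_naive_oracle(self):
        counts = [{(1, 1): 4, (1, 2): 3, (2, 2): 3},
                  {(1, 1): 1, (1, 2): 5, (2, 2): 6},
                  {(1, 2): 2, (2, 2): 5, (1, 1): 5}]
        pops = [_pop_from_counts(c, f"p{i}") for i, c in enumerate(counts)]
        assert wc_fst(pops) == pytest.approx(naive_wc_theta(counts), abs=1e-10)

    def test_null_fis_recovery(self, rng):
        vals = []
        for _ in range(40):
            freqs = sd.base_frequencies(rng, 12, 5)
            vals.append(wc_fis(sd.sim_population(rng, freqs, 0.0, 50)))
        assert np.mean(vals) == pytest.approx(0.0, abs=0.02)

    def test_panmictic_split_theta_near_zero(self, rng):
        vals = []
        for _ in range(40):
            freqs = sd.base_frequencies(rng, 12, 5)
            a = sd.sim_population(rng, freqs, 0.0, 50)
            b = sd.sim_population(rng, freqs, 0.0, 50)
            vals.append(wc_fst([a, b]))
        assert np.mean(vals) == pytest.approx(0.0, abs=0.02)

    def test_diversity_table_shape_and_flags(self, rng):
        freqs = sd.base_frequencies(rng, 8, 5)
        pops = {"hi_s": sd.sim_population(rng, freqs, 0.6, 60),
                "pan": sd.sim_population(rng, freqs, 0.0, 60)}
        dt = diversity_table(pops, n_bootstrap=200, seed=1)
        assert set(dt.population) == {"hi_s", "pan"}
        assert ((0 <= dt.H_obs) & (dt.H_obs <= 1)).all()
        assert ((0 <= dt.H_exp) & (dt.H_exp <= 1)).all()
        row = dt.set_index("population").loc["hi_s"]
        assert row.F_IS_nonzero and row.F_IS > 0.2


class TestHierarchicalF:
    def test_identical_pools_near_zero(self, rng):
        freqs = sd.base_frequencies(rng, 10, 5)
        pops = {f"p{i}": sd.sim_population(rng, freqs, 0.0, 40)
                for i in range(4)}
        assign = {"p0": "A", "p1": "A", "p2": "B", "p3": "B"}
        hf = hierarchical_f(pops, assign, n_bootstrap=50, seed=2)
        assert abs(hf.F.iloc[0]) < 0.05
        assert abs(hf.F.iloc[1]) < 0.05

    def test_collapsing_ecotypes_leaves_pop_level_stable(self):
        cfg = sd.SimConfig(seed=13, n_populations=6, pops_per_ecotype=3,
                           n_individuals=30, n_loci=10, theta_pop=0.2)
        pops, _ = sd.sim_metapopulation(cfg)
        assign2 = {n: g.meta.ecotype for n, g in pops.items()}
        assign1 = {n: "one" for n in pops}
        hf2 = hierarchical_f(pops, assign2, n_bootstrap=0)
        hf1 = hierarchical_f(pops, assign1, n_bootstrap=0)
        assert hf1.F.iloc[1] == pytest.approx(hf2.F.iloc[1], abs=0.05)


class TestPermutationCompare:
    def test_identical_groups_p_near_one(self, rng):
        freqs = sd.base_frequencies(rng, 8, 4)
        base = {f"p{i}": sd.sim_population(rng, freqs, 0.2, 30)
                for i in range(2)}
        pops = {}
        assign = {}
        for grp in ("A", "B"):
            for name, g in base.items():
                key = f"{grp}_{name}"
                pops[key] = GenotypeMatrix(g.individuals, g.loci, g.calls.copy(),
                                           PopMeta(population=key))
                assign[key] = grp
        _, p = permutation_compare("H_exp", pops, assign, n_perm=300, seed=3)
        assert p > 0.9

    def test_minimal_p_bounded_by_permutation_count(self, rng):
        """5+5 fully separated groups: p can never beat 1/(n_perm+1)."""
        pops = {}
        assign = {}
        for i in range(5):
            freqs = sd.base_frequencies(rng, 6, 4)
            pops[f"a{i}"] = sd.sim_population(rng, freqs, 0.0, 30)
            assign[f"a{i}"] = "A"
            pops[f"b{i}"] = sd.sim_population(rng, freqs, 0.8, 30)
            assign[f"b{i}"] = "B"
        _, p = permutation_compare("F_IS", pops, assign, n_perm=999, seed=4)
        assert p >= 1 / 1000
        assert p < 0.05

    def test_degenerate_grouping_raises(self, rng):
        freqs = sd.base_frequencies(rng, 4, 3)
        pops = {"a": sd.sim_population(rng, freqs, 0.0, 10),
                "b": sd.sim_population(rng, freqs, 0.0, 10)}
        with pytest.raises(ValueError):
            permutation_compare("H_obs", pops, {"a": "A", "b": "B"}, 100)


class TestLdScreen:
    def test_duplicated_locus_flagged_everywhere(self, rng):
        pops = {}
        for i in range(3):
            freqs = sd.base_frequencies(rng, 3, 4)
            g = sd.sim_population(rng, freqs, 0.0, 40)
            calls = np.concatenate([g.calls, g.calls[:, [0], :]], axis=1)
            pops[f"p{i}"] = GenotypeMatrix(g.individuals,
                                           g.loci + ["dup0"], calls,
                                           PopMeta(population=f"p{i}"))
        res = ld_screen(pops, n_perm=99, seed=5)
        row = res[(res.locus1 == "loc0") & (res.locus2 == "dup0")].iloc[0]
        assert row.n_populations_flagged == 3
        assert row.remove

    def test_rule_boundary_two_populations_not_removed(self, rng):
        """Perfect duplication in exactly two populations stays below the
        'more than two' removal rule."""
        pops = {}
        for i in range(3):
            freqs = sd.base_frequencies(rng, 3, 4)
            g = sd.sim_population(rng, freqs, 0.0, 40)
            if i < 2:
                extra = g.calls[:, [0], :]
            else:
                g2 = sd.sim_population(rng, freqs, 0.0, 40)
                extra = g2.calls[:, [0], :]
            calls = np.concatenate([g.calls, extra], axis=1)
            pops[f"p{i}"] = GenotypeMatrix(g.individuals, g.loci + ["dup0"],
                                           calls, PopMeta(population=f"p{i}"))
        res = ld_screen(pops, n_perm=99, seed=6)
        row = res[(res.locus1 == "loc0") & (res.locus2 == "dup0")].iloc[0]
        assert not row.remove


class TestGeography:
    def test_distance_closed_forms(self):
        d = geo_distances({"a": (0.0, 0.0), "b": (0.0, 0.0)})
        assert d.loc["a", "b"] == 0.0
        d = geo_distances({"a": (0.0, 0.0), "b": (0.0, 180.0)})
        assert d.loc["a", "b"] == pytest.approx(math.pi * 6371, rel=1e-6)
        d = geo_distances({"a": (0.0, 0.0), "b": (0.0, 1.0)})
        assert d.loc["a", "b"] == pytest.approx(111.19, abs=0.01)

    def test_missing_coordinates_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            d = geo_distances({"a": (0.0, 0.0), "b": None, "c": (1.0, 1.0)})
        assert list(d.index) == ["a", "c"]


class TestMantel:
    @staticmethod
    def _rand_dist(rng, n):
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        return m

    def test_self_correlation(self, rng):
        a = self._rand_dist(rng, 5)
        r, p = mantel(a, a.copy(), n_perm=200, seed=1)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p < 0.05

    def test_exhaustive_enumeration_oracle(self, rng):
        """n=4: p equals the exact fraction over all 4! permutations."""
        a = self._rand_dist(rng, 4)
        b = self._rand_dist(rng, 4)
        r, p = mantel(a, b)
        iu = np.triu_indices(4, 1)
        r_obs = np.corrcoef(a[iu], b[iu])[0, 1]
        count = sum(
            np.corrcoef(a[iu], b[np.ix_(perm, perm)][iu])[0, 1] >= r_obs - 1e-12
            for perm in itertools.permutations(range(4)))
        assert p == pytest.approx(count / 24, abs=1e-12)

    def test_agrees_with_skbio(self, rng):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import mantel as skbio_mantel
        a = self._rand_dist(rng, 8)
        b = self._rand_dist(rng, 8)
        r, _ = mantel(a, b, n_perm=99, seed=0)
        r_ref, _, _ = skbio_mantel(DistanceMatrix(a), DistanceMatrix(b),
                                   permutations=0)
        assert r == pytest.approx(r_ref, abs=1e-10)

    def test_constant_matrix_raises(self):
        m = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError, match="undefined|constant"):
            mantel(m, m * 2)


class TestIbdRegression:
    def test_exact_line_recovered(self, rng):
        n = 6
        d = np.zeros((n, n))
        f = np.zeros((n, n))
        slope_true, intercept_true = 0.02, 0.05
        for i, j in itertools.combinations(range(n), 2):
            dist = 1 + 5 * rng.random()
            y = intercept_true + slope_true * np.log(dist)
            d[i, j] = d[j, i] = dist
            f[i, j] = f[j, i] = y / (1 + y)
        res = ibd_regression(f, d, n_perm=50, seed=0)
        assert res["slope"] == pytest.approx(slope_true, abs=1e-10)
        assert res["intercept"] == pytest.approx(intercept_true, abs=1e-10)


class TestPca:
    def test_inertia_properties_and_duplication_invariance(self, rng):
        cfg = sd.SimConfig(seed=17, n_populations=2, pops_per_ecotype=1,
                           n_individuals=25, n_loci=8, theta_pop=0.3)
        pops, _ = sd.sim_metapopulation(cfg)
        coords, inertia = pca_freqs(pops)
        assert inertia.sum() == pytest.approx(1.0, abs=1e-10)
        assert (np.diff(inertia) <= 1e-12).all()
        # duplicating every individual leaves the leading direction unchanged
        doubled = {n: GenotypeMatrix(g.individuals + g.individuals, g.loci,
                                     np.concatenate([g.calls, g.calls]),
                                     g.meta) for n, g in pops.items()}
        c2, _ = pca_freqs(doubled)
        v1 = coords["PC1"].values
        first_copy = np.r_[0:25, 50:75]  # first copy of each population
        v2 = c2["PC1"].values[first_copy]
        corr = abs(np.corrcoef(v1, v2)[0, 1])
        assert corr == pytest.approx(1.0, abs=1e-8)

    def test_diverged_populations_separate_on_pc1(self, rng):
        cfg = sd.SimConfig(seed=19, n_populations=2, pops_per_ecotype=1,
                           n_individuals=30, n_loci=12, theta_pop=0.45)
        pops, _ = sd.sim_metapopulation(cfg)
        coords, _ = pca_freqs(pops)
        grp = coords.groupby("population")["PC1"].agg(["mean", "std"])
        sep = abs(grp["mean"].iloc[0] - grp["mean"].iloc[1])
        assert sep > 2 * grp["std"].max()


class TestClosedForms:
    def test_ne_reduction_examples(self):
        assert ne_reduction_from_selfing(0.3, 0.3) == 0.0
        assert ne_reduction_from_selfing(0.25, 0.40) == pytest.approx(
            0.0857, abs=1e-3)
        assert ne_reduction_from_selfing(0.0, 1.0) == pytest.approx(0.5)

    def test_inbreeding_depression_examples(self):
        assert required_inbreeding_depression(0.4, 0.25) == pytest.approx(0.5)
        assert required_inbreeding_depression(0.3, 0.3) == 0.0
        assert required_inbreeding_depression(0.5, 1 / 3) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            required_inbreeding_depression(0.25, 0.4)
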