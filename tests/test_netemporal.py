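"""Drift transition, temporal likelihood and effective-size estimation."""

import numpy as np
import pytest
from scipy.stats import binom

from plantmating import synthdata as sd
from plantmating.geno_io import TemporalPair
from plantmating.netemporal import (drift_transition, fit_ne, fk_moment_ne,
                                    temporal_loglik, wf_moments)


def exhaustive_temporal_oracle(counts0, counts1, ne, g, n_grid=64):
    """Triple-loop sum over the prior grid and the full Wright-Fisher
    lattice of intermediate states, written independently of the
    vectorised implementation."""
    total = 0.0
    n2 = 2 * ne
    for c0, c1 in zip(counts0, counts1):
        m0, m1 = sum(c0.values()), sum(c1.values())
        for a in set(c0) | set(c1):
            k0, k1 = c0.get(a, 0), c1.get(a, 0)
            if k0 == 0 and k1 == 0:
                continue
            acc = 0.0
            for i in range(n_grid):
                x0 = (i + 0.5) / n_grid
                dist = {}
                for j in range(n2 + 1):
                    dist[j] = binom.pmf(j, n2, x0)
                for _ in range(g - 1):
                    nxt = dict.fromkeys(range(n2 + 1), 0.0)
                    for j, pj in dist.items():
                        if pj == 0:
                            continue
                        for j2 in range(n2 + 1):
                            nxt[j2] += pj * binom.pmf(j2, n2, j / n2)
                    dist = nxt
                inner = sum(pj * binom.pmf(k1, m1, j / n2)
                            for j, pj in dist.items())
                acc += binom.pmf(k0, m0, x0) * inner
            total += np.log(acc / n_grid)
    return total


class TestDriftTransition:
    def test_single_generation_tiny_ne(self):
        xs, ps = drift_transition(0.5, 1, 1)
        np.testing.assert_allclose(xs, [0, 0.5, 1])
        np.testing.assert_allclose(ps, [0.25, 0.5, 0.25])

    def test_rows_sum_to_one_and_absorbing_states(self):
        for x0 in (0.0, 0.3, 1.0):
            xs, ps = drift_transition(x0, 20, 3)
            assert ps.sum() == pytest.approx(1.0, abs=1e-12)
        xs, ps = drift_transition(0.0, 20, 5)
        assert ps[0] == pytest.approx(1.0, abs=1e-12)
        xs, ps = drift_transition(1.0, 20, 5)
        assert ps[-1] == pytest.approx(1.0, abs=1e-12)

    def test_martingale_mean_and_variance_closed_form(self):
        for ne, g, x0 in [(10, 1, 0.3), (50, 4, 0.7), (200, 2, 0.5)]:
            xs, ps = drift_transition(x0, ne, g)
            m = float((xs * ps).sum())
            v = float(((xs - m) ** 2 * ps).sum())
            em, ev = wf_moments(x0, ne, g)
            assert m == pytest.approx(em, abs=1e-8)
            assert v == pytest.approx(ev, abs=1e-8)

    def test_exact_and_approximate_modes_agree(self):
        """Coarse-binned total variation between the WF lattice and the
        moment-matched beta stays small at the mode boundary."""
        xs_e, ps_e = drift_transition(0.3, 300, 3, mode="exact")
        xs_a, ps_a = drift_transition(0.3, 300, 3, mode="approx",
                                      grid_size=256)
        nb = 20
        he, ha = np.zeros(nb), np.zeros(nb)
        np.add.at(he, np.clip((xs_e * nb).astype(int), 0, nb - 1), ps_e)
        np.add.at(ha, np.clip((xs_a * nb).astype(int), 0, nb - 1), ps_a)
        assert 0.5 * np.abs(he - ha).sum() < 0.05


COUNTS0 = [{1: 30, 2: 40, 3: 20}, {1: 50, 2: 40}]
COUNTS1 = [{1: 35, 2: 35, 3: 20}, {1: 45, 2: 45}]


class TestTemporalLoglik:
    @pytest.mark.parametrize("ne,g", [(5, 1), (12, 2), (20, 1)])
    def test_exhaustive_lattice_oracle(self, ne, g):
        got = temporal_loglik(COUNTS0, COUNTS1, ne, g)
        want = exhaustive_temporal_oracle(COUNTS0, COUNTS1, ne, g)
        assert got == pytest.approx(want, abs=1e-10)

    def test_no_change_favours_larger_ne(self):
        counts = [{1: 40, 2: 40}, {1: 30, 2: 50}]
        lls = [temporal_loglik(counts, counts, ne, 1)
               for ne in (10, 50, 250, 450)]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_prior_grid_doubling(self):
        a = temporal_loglik(COUNTS0, COUNTS1, 50, 1, n_prior_grid=64)
        b = temporal_loglik(COUNTS0, COUNTS1, 50, 1, n_prior_grid=128)
        assert abs(a - b) < 1e-4


class TestFitNe:
    def test_identical_samples_hit_cap(self):
        cfg = sd.SimConfig(seed=1, Ne=None, n_loci=15, n_alleles=5,
                           sample_size_temporal=60)
        pair, _ = sd.sim_temporal(cfg)
        same = TemporalPair(pair.sample0, pair.sample0, 1)
        est = fit_ne(same, cap=10_000)
        assert est.at_cap
        assert est.ci95[1] == pytest.approx(10_000, rel=1e-3)

    def test_invariance_to_locus_order_and_allele_relabeling(self):
        cfg = sd.SimConfig(seed=3, Ne=80, n_loci=8, n_alleles=4,
                           sample_size_temporal=50)
        pair, _ = sd.sim_temporal(cfg)
        est = fit_ne(pair)
        order = list(np.array(pair.sample0.loci)[[5, 2, 7, 0, 1, 6, 3, 4]])
        pair2 = TemporalPair(pair.sample0.subset_loci(order),
                             pair.sample1.subset_loci(order), 1)
        pair2.sample0.calls += 7
        pair2.sample1.calls += 7
        est2 = fit_ne(pair2)
        assert est2.ne_hat == pytest.approx(est.ne_hat, rel=1e-6)

    def test_no_polymorphic_loci_raises(self):
        from plantmating.geno_io import GenotypeMatrix
        calls = np.full((10, 3, 2), 4)
        g = GenotypeMatrix([f"i{k}" for k in range(10)], ["a", "b", "c"], calls)
        with pytest.raises(ValueError, match="polymorphic"):
            fit_ne(TemporalPair(g, g, 1))

    def test_estimate_increases_with_true_ne(self):
        medians = []
        for true_ne in (25, 400):
            est = []
            for r in range(6):
                cfg = sd.SimConfig(seed=40 + r, Ne=true_ne, n_loci=15,
                                   n_alleles=5, sample_size_temporal=60)
                pair, _ = sd.sim_temporal(cfg)
                est.append(fit_ne(pair).ne_hat)
            medians.append(np.median(est))
        assert medians[0] < medians[1]


class TestMomentEstimator:
    def test_identical_samples_capped(self):
        cfg = sd.SimConfig(seed=6, Ne=None, n_loci=10, sample_size_temporal=40)
        pair, _ = sd.sim_temporal(cfg)
        ne, capped = fk_moment_ne(TemporalPair(pair.sample0, pair.sample0, 1))
        assert capped

    def test_stronger_drift_raises_temporal_f(self):
        """Halving Ne increases the median standardised frequency change."""
        med = {}
        for true_ne in (30, 120):
            vals = []
            for r in range(8):
                cfg = sd.SimConfig(seed=60 + r, Ne=true_ne, n_loci=15,
                                   n_alleles=5, sample_size_temporal=80)
                pair, _ = sd.sim_temporal(cfg)
                ne, capped = fk_moment_ne(pair)
                vals.append(ne)
            med[true_ne] = np.median(vals)
        assert med[30] < med[120]
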