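"""Hierarchical logit-normal model over selfing profiles and its LRTs."""

import numpy as np
import pytest
from scipy.stats import chi2, norm

from plantmating.hier import (HierModelSpec, fit_hier, group_mean_ci, lrt,
                              marginal_loglik, seasonal_test)
from plantmating.synthdata import sim_profiles


def _logit(p):
    return np.log(p / (1 - p))


def _invlogit(z):
    return 1 / (1 + np.exp(-z))


M5 = [-1.2, -0.4, 0.1, -0.8, -1.5]
V = 0.09


@pytest.fixture(scope="module")
def quad_profiles():
    return sim_profiles(M5, V)


@pytest.fixture(scope="module")
def one_group_spec():
    return HierModelSpec({i: "A" for i in range(5)}, "per_group", "per_group")


class TestMarginalLoglik:
    def test_sigma_zero_collapses_to_profile_sum(self, quad_profiles,
                                                 one_group_spec):
        mu = {"A": -0.7}
        ml = marginal_loglik(quad_profiles, one_group_spec, mu, {"A": 0.0})
        direct = sum(float(p.interp(_invlogit(-0.7))) for p in quad_profiles)
        assert ml == pytest.approx(direct, abs=1e-12)

    def test_conjugate_normal_normal_closed_form(self, quad_profiles,
                                                 one_group_spec):
        """Quadratic profiles: marginal equals sum ln N(m_i; mu, sigma^2+v) + const."""
        mu, sig = -0.7, 0.5
        ml = marginal_loglik(quad_profiles, one_group_spec,
                             {"A": mu}, {"A": sig})
        closed = (sum(norm.logpdf(m, mu, np.sqrt(sig ** 2 + V)) for m in M5)
                  + 5 * 0.5 * np.log(2 * np.pi * V))
        assert ml == pytest.approx(closed, abs=1e-4)

    def test_quadrature_node_doubling(self, quad_profiles, one_group_spec):
        a = marginal_loglik(quad_profiles, one_group_spec, {"A": -0.7},
                            {"A": 0.5}, n_nodes=32)
        b = marginal_loglik(quad_profiles, one_group_spec, {"A": -0.7},
                            {"A": 0.5}, n_nodes=64)
        assert abs(a - b) < 1e-6

    def test_sigma_floor_continuity(self, quad_profiles, one_group_spec):
        """Marginal at the sigma floor is close to the collapsed sigma=0 form."""
        a = marginal_loglik(quad_profiles, one_group_spec, {"A": -0.7},
                            {"A": 0.002})
        b = marginal_loglik(quad_profiles, one_group_spec, {"A": -0.7},
                            {"A": 0.0})
        assert a == pytest.approx(b, abs=1e-3)


class TestFitHier:
    def test_matches_conjugate_mle(self, quad_profiles, one_group_spec):
        fit = fit_hier(quad_profiles, one_group_spec)
        assert fit.mu["A"] == pytest.approx(np.mean(M5), abs=1e-4)
        assert fit.sigma["A"] == pytest.approx(
            np.sqrt(max(np.var(M5) - V, 0)), abs=1e-4)

    def test_sharp_profile_limit_sigma_equals_sd_of_modes(self):
        profs = sim_profiles(M5, 1e-4,
                             grid=np.arange(0.0005, 0.9999, 0.0005))
        spec = HierModelSpec({i: "A" for i in range(5)}, "per_group",
                             "per_group")
        fit = fit_hier(profs, spec)
        assert fit.sigma["A"] == pytest.approx(np.std(M5), rel=0.01)

    def test_single_population_sigma_at_floor(self):
        profs = sim_profiles([-1.0], 0.001,
                             grid=np.arange(0.001, 0.9995, 0.001))
        spec = HierModelSpec({0: "A"}, "per_group", "per_group")
        fit = fit_hier(profs, spec)
        assert fit.mu["A"] == pytest.approx(-1.0, abs=0.01)
        assert fit.sigma_boundary["A"]

    def test_two_group_mean_recovery(self):
        """Groups generated at selfing 0.25 vs 0.40 are recovered within 0.03."""
        rng = np.random.default_rng(4)
        m = np.concatenate([rng.normal(_logit(0.25), 0.15, 5),
                            rng.normal(_logit(0.40), 0.15, 5)])
        profs = sim_profiles(m, 0.0225)
        assign = {i: ("M" if i < 5 else "N") for i in range(10)}
        fit = fit_hier(profs, HierModelSpec(assign, "per_group", "zero"))
        assert fit.mean_selfing["M"] == pytest.approx(0.25, abs=0.03)
        assert fit.mean_selfing["N"] == pytest.approx(0.40, abs=0.03)

    def test_nesting_monotonicity(self, quad_profiles):
        assign = {i: ("M" if i < 3 else "N") for i in range(5)}
        full = fit_hier(quad_profiles, HierModelSpec(assign, "per_group", "shared"))
        mid = fit_hier(quad_profiles, HierModelSpec(assign, "per_group", "zero"))
        con = fit_hier(quad_profiles, HierModelSpec(assign, "shared", "zero"))
        assert full.loglik >= mid.loglik - 1e-6
        assert mid.loglik >= con.loglik - 1e-6


class TestLrt:
    def test_identical_specs_give_zero_deviance(self, quad_profiles):
        assign = {i: "A" for i in range(5)}
        f1 = fit_hier(quad_profiles, HierModelSpec(assign, "per_group", "zero"))
        f2 = fit_hier(quad_profiles, HierModelSpec(assign, "shared", "zero"))
        res = lrt(f1, f2)
        assert res.deviance == pytest.approx(0.0, abs=1e-6)
        assert res.pvalue == pytest.approx(1.0, abs=1e-6)

    def test_reported_deviance_to_pvalue(self):
        """Deviance 4.68 with 1 df corresponds to p ~ 0.03."""
        assert chi2.sf(4.68, 1) == pytest.approx(0.0305, abs=5e-4)

    def test_non_nested_raises(self, quad_profiles):
        a1 = {i: ("M" if i < 3 else "N") for i in range(5)}
        full = fit_hier(quad_profiles, HierModelSpec(a1, "per_group", "zero"))
        other = fit_hier(quad_profiles, HierModelSpec(a1, "shared", "per_group"))
        with pytest.raises(ValueError, match="nested"):
            lrt(full, other)


class TestSeasonalAndCI:
    def test_seasonal_constant_s_not_significant(self):
        """Four seasonal profiles from one constant s: 3-df LRT stays null."""
        rng = np.random.default_rng(11)
        m = rng.normal(_logit(0.3), 0.12, 4)
        profs = sim_profiles(m, 0.0144)
        res = seasonal_test({f"y{k}": [profs[k]] for k in range(4)})
        assert res.df == 3
        assert res.pvalue > 0.05

    def test_group_mean_ci_covers_estimate(self, quad_profiles):
        assign = {i: "A" for i in range(5)}
        spec = HierModelSpec(assign, "per_group", "zero")
        fit = fit_hier(quad_profiles, spec)
        lo, hi = group_mean_ci(quad_profiles, spec, fit, "A")
        assert lo <= fit.mean_selfing["A"] <= hi
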