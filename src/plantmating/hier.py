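"""Hierarchical logit-normal model over population selfing-rate profiles.

Population selfing rates are treated as random effects: within ecotype e,
logit(s_i) ~ Normal(mu_e, sigma_e^2).  The marginal log-likelihood combines
the population-specific profile log-likelihoods l_i(s) (treated as exact
likelihoods of s) by Gauss-Hermite quadrature:

    ln L = sum_i ln  integral  exp(l_i(invlogit(z))) phi(z; mu_e(i), sigma_e(i)) dz

Constrained variants (shared mean and/or SD across ecotypes, SD fixed at 0)
are compared with standard likelihood-ratio tests, mirroring a mixed-model
ANOVA with 'ecotype' fixed and 'population within ecotype' random.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .selfing import SelfingProfile

SIGMA_FLOOR = 0.002  # numerical precision floor for estimated SDs

_GH_NODES = 64


def _invlogit(z):
    return 1 / (1 + np.exp(-z))


def _logit(p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


@dataclass
class HierModelSpec:
    """Structure of the logit-normal random-effects model.

    mean_structure: "per_group" or "shared"
    sd_structure:   "per_group", "shared", or "zero"
    fixed: optional {"mu": value-or-dict, "sigma": value-or-dict} pinning
    parameters instead of estimating them.
    """

    groups: dict  # population index or name -> group label
    mean_structure: str = "per_group"
    sd_structure: str = "per_group"
    fixed: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mean_structure not in ("per_group", "shared"):
            raise ValueError("mean_structure must be per_group|shared")
        if self.sd_structure not in ("per_group", "shared", "zero"):
            raise ValueError("sd_structure must be per_group|shared|zero")

    @property
    def group_labels(self):
        return sorted(set(self.groups.values()))

    def n_free_params(self) -> int:
        n = 0
        g = len(self.group_labels)
        if "mu" not in self.fixed:
            n += g if self.mean_structure == "per_group" else 1
        if self.sd_structure != "zero" and "sigma" not in self.fixed:
            n += g if self.sd_structure == "per_group" else 1
        return n

    def is_nested_in(self, other: "HierModelSpec") -> bool:
        """True if self is a constrained version of other.

        Requires the same population keys, the constrained grouping to be a
        coarsening of the full grouping, and no richer mean/SD structure.
        """
        if set(self.groups) != set(other.groups):
            return False
        # coarsening: each full group maps into exactly one constrained group
        mapping = {}
        for k, g_full in other.groups.items():
            g_con = self.groups[k]
            if mapping.setdefault(g_full, g_con) != g_con:
                return False
        mean_rank = {"shared": 0, "per_group": 1}
        sd_rank = {"zero": 0, "shared": 1, "per_group": 2}
        return (mean_rank[self.mean_structure] <= mean_rank[other.mean_structure]
                and sd_rank[self.sd_structure] <= sd_rank[other.sd_structure]
                and self.n_free_params() <= other.n_free_params())


@dataclass
class HierFit:
    spec: HierModelSpec
    mu: dict            # group -> logit-scale mean
    sigma: dict         # group -> SD (0 allowed)
    loglik: float
    converged: bool = True
    sigma_boundary: dict = field(default_factory=dict)

    @property
    def mean_selfing(self) -> dict:
        """Back-transformed group means (the logit-normal median; equals the
        mean when sigma = 0, the reporting convention used)."""
        return {g: float(_invlogit(m)) for g, m in self.mu.items()}

    @property
    def df(self) -> int:
        return self.spec.n_free_params()


@dataclass
class LRTResult:
    deviance: float
    df: int
    pvalue: float


def _adaptive_gh_lse(g_fun, z_grid, g_on_grid, n_nodes):
    """log integral exp(g(z)) dz by Gauss-Hermite centred on the mode of g.

    The centre and scale come from a parabola through the three grid points
    around the argmax, so narrow profile peaks (curvature much larger than
    the random-effect scale) are resolved.
    """
    j = int(np.argmax(g_on_grid))
    j = int(np.clip(j, 1, len(z_grid) - 2))
    z3 = z_grid[j - 1:j + 2]
    g3 = g_on_grid[j - 1:j + 2]
    c2, c1, _ = np.polyfit(z3 - z3[1], g3, 2)
    if c2 < -1e-12:
        z_star = z3[1] - c1 / (2 * c2)
        scale = 1.0 / np.sqrt(-2 * c2)
    else:
        z_star, scale = z3[1], (z_grid[-1] - z_grid[0]) / 10
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    z = z_star + np.sqrt(2.0) * scale * nodes
    a = g_fun(z) + nodes ** 2 + np.log(weights)
    amax = a.max()
    return float(amax + np.log(np.sum(np.exp(a - amax)))
                 + 0.5 * np.log(2.0) + np.log(scale))


def marginal_loglik(profiles: Sequence[SelfingProfile], spec: HierModelSpec,
                    mu: dict, sigma: dict, n_nodes: int = _GH_NODES) -> float:
    """Marginal log-likelihood of the random-effects model.

    Each population contributes ln of the integral of exp(profile loglik)
    against the logit-normal random-effect density, computed by adaptive
    Gauss-Hermite quadrature (centred on the integrand's mode, so it stays
    accurate when the profile is much sharper than the random effect).
    sigma = 0 collapses exactly to the profile value at s = invlogit(mu).
    """
    total = 0.0
    keys = list(spec.groups.keys())
    for key, prof in zip(keys, profiles):
        g = spec.groups[key]
        m, sd = mu[g], sigma[g]
        if sd <= 0:
            total += float(prof.interp(_invlogit(m), warn=False))
            continue

        def g_fun(z, m=m, sd=sd, prof=prof):
            return (prof.interp(_invlogit(z), warn=False)
                    - 0.5 * ((z - m) / sd) ** 2
                    - np.log(sd) - 0.5 * np.log(2 * np.pi))

        z_grid = _logit(prof.grid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            total += _adaptive_gh_lse(g_fun, z_grid, g_fun(z_grid), n_nodes)
    return total


def _unpack(theta, spec: HierModelSpec):
    labels = spec.group_labels
    mu, sigma = {}, {}
    i = 0
    if "mu" in spec.fixed:
        fx = spec.fixed["mu"]
        mu = dict(fx) if isinstance(fx, dict) else {g: float(fx) for g in labels}
    elif spec.mean_structure == "per_group":
        for g in labels:
            mu[g] = theta[i]; i += 1
    else:
        for g in labels:
            mu[g] = theta[i]
        i += 1
    if spec.sd_structure == "zero":
        sigma = {g: 0.0 for g in labels}
    elif "sigma" in spec.fixed:
        fx = spec.fixed["sigma"]
        sigma = dict(fx) if isinstance(fx, dict) else {g: float(fx) for g in labels}
    elif spec.sd_structure == "per_group":
        for g in labels:
            sigma[g] = max(abs(theta[i]), SIGMA_FLOOR); i += 1
    else:
        for g in labels:
            sigma[g] = max(abs(theta[i]), SIGMA_FLOOR)
        i += 1
    return mu, sigma


def fit_hier(profiles: Sequence[SelfingProfile], spec: HierModelSpec,
             n_starts: int = 3, n_nodes: int = _GH_NODES,
             max_restarts: int = 6) -> HierFit:
    """Maximise the marginal likelihood by multi-start Nelder-Mead.

    SDs are constrained to the numerical floor 0.002; an estimate at the
    floor is reported as a boundary (effectively zero spread).
    """
    labels = spec.group_labels
    keys = list(spec.groups.keys())
    # moment starts from per-profile MLEs
    by_group = {g: [] for g in labels}
    for key, prof in zip(keys, profiles):
        by_group[spec.groups[key]].append(_logit(prof.s_hat))
    g_mean = {g: (np.mean(v) if v else 0.0) for g, v in by_group.items()}
    g_sd = {g: (np.std(v) if len(v) > 1 else 0.1) for g, v in by_group.items()}
    all_mean = float(np.mean([_logit(p.s_hat) for p in profiles]))

    def pack(mu, sigma):
        theta = []
        if "mu" not in spec.fixed:
            if spec.mean_structure == "per_group":
                theta += [mu[g] for g in labels]
            else:
                theta += [np.mean([mu[g] for g in labels])]
        if spec.sd_structure != "zero" and "sigma" not in spec.fixed:
            if spec.sd_structure == "per_group":
                theta += [sigma[g] for g in labels]
            else:
                theta += [np.mean([sigma[g] for g in labels])]
        return np.asarray(theta, dtype=float)

    def neg(theta):
        mu, sigma = _unpack(theta, spec)
        return -marginal_loglik(profiles, spec, mu, sigma, n_nodes)

    starts = [
        pack(g_mean, {g: max(g_sd[g], SIGMA_FLOOR) for g in labels}),
        pack({g: all_mean for g in labels}, {g: 0.3 for g in labels}),
        pack({g: g_mean[g] + 0.5 for g in labels}, {g: 0.05 for g in labels}),
    ][:max(n_starts, 1)]

    if spec.n_free_params() == 0:
        mu, sigma = _unpack(np.empty(0), spec)
        return HierFit(spec, mu, sigma,
                       marginal_loglik(profiles, spec, mu, sigma, n_nodes))

    best = None
    n_done = 0
    for x0 in starts:
        res = minimize(neg, x0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 4000})
        n_done += 1
        if best is None or res.fun < best.fun:
            best = res
    while not best.success and n_done < max_restarts:
        jitter = best.x + np.random.default_rng(n_done).normal(0, 0.1, best.x.shape)
        res = minimize(neg, jitter, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 4000})
        n_done += 1
        if res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise RuntimeError(f"hierarchical fit did not converge: {best}")
    mu, sigma = _unpack(best.x, spec)
    boundary = {g: (spec.sd_structure != "zero" and sigma[g] <= SIGMA_FLOOR + 1e-9)
                for g in labels}
    return HierFit(spec, mu, sigma, -float(best.fun),
                   converged=bool(best.success), sigma_boundary=boundary)


def lrt(full: HierFit, constrained: HierFit) -> LRTResult:
    """Likelihood-ratio test of a nested constraint (chi-square reference)."""
    if not constrained.spec.is_nested_in(full.spec):
        raise ValueError("constrained spec is not nested in the full spec")
    dev = 2 * (full.loglik - constrained.loglik)
    if dev < -1e-6:
        raise ValueError(
            f"nested fit has higher likelihood (deviance {dev:.3g}); "
            "full model under-optimised")
    dev = max(dev, 0.0)
    df = full.df - constrained.df
    if df < 0:
        raise ValueError("full model has fewer free parameters")
    if df == 0:  # identical constraint: nothing to test
        return LRTResult(dev, 0, 1.0)
    return LRTResult(dev, df, float(chi2.sf(dev, df)))


def group_mean_ci(profiles, spec: HierModelSpec, fit: HierFit, group,
                  n_nodes: int = _GH_NODES):
    """95 % likelihood CI for one group's mean selfing rate (profile on mu)."""
    target = fit.loglik - 1.9207

    def ll_at(mu_g):
        mu = dict(fit.mu); mu[group] = mu_g
        sub = HierModelSpec(spec.groups, "per_group", spec.sd_structure, spec.fixed)
        return marginal_loglik(profiles, sub, mu, fit.sigma, n_nodes)

    grid = np.linspace(fit.mu[group] - 6, fit.mu[group] + 6, 481)
    vals = np.array([ll_at(m) for m in grid])
    above = vals >= target
    idx = np.where(above)[0]
    if idx.size == 0:
        return (fit.mean_selfing[group],) * 2
    lo, hi = grid[idx[0]], grid[idx[-1]]
    return float(_invlogit(lo)), float(_invlogit(hi))


def ecotype_pipeline(profiles: Sequence[SelfingProfile], assignment: dict,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Model ladder comparing selfing-rate distributions between groups.

    Steps (the shape of the published model-comparison tables):
      1. per-group mu, per-group sigma   (full)
      2. per-group mu, shared sigma      -> LRT vs 1 (equal SDs?)
      3. per-group mu, sigma = 0         (SDs at the floor collapse to zero)
      4. shared mu,    sigma = 0         -> LRT vs 3 (equal means?)

    Returns a model-comparison table with lnL, deviance difference, df, p.
    """
    if len(set(assignment.values())) < 2:
        raise ValueError("between-group tests need at least 2 groups")
    specs = {
        "per-group mu, per-group sigma": HierModelSpec(assignment, "per_group", "per_group"),
        "per-group mu, shared sigma": HierModelSpec(assignment, "per_group", "shared"),
        "per-group mu, sigma=0": HierModelSpec(assignment, "per_group", "zero"),
        "shared mu, sigma=0": HierModelSpec(assignment, "shared", "zero"),
    }
    fits = {name: fit_hier(profiles, sp) for name, sp in specs.items()}
    rows = []
    comparisons = [
        ("per-group mu, per-group sigma", None),
        ("per-group mu, shared sigma", "per-group mu, per-group sigma"),
        ("per-group mu, sigma=0", None),
        ("shared mu, sigma=0", "per-group mu, sigma=0"),
    ]
    for name, vs in comparisons:
        fit = fits[name]
        row = {"model": name, "loglik": fit.loglik,
               "mean_selfing": {g: round(v, 4) for g, v in fit.mean_selfing.items()},
               "deviance_diff": np.nan, "df": np.nan, "pvalue": np.nan}
        if vs is not None:
            res = lrt(fits[vs], fit)
            row.update(deviance_diff=res.deviance, df=res.df, pvalue=res.pvalue)
        rows.append(row)
    return pd.DataFrame(rows)


def seasonal_test(profiles_by_season: dict) -> LRTResult:
    """Test temporal variation: one s per season vs a single overall s.

    ``profiles_by_season`` maps season label -> list of profiles; all
    profiles share the population set across seasons.  Fitted with sigma = 0
    (selfing treated as a fixed rate per cell).
    """
    seasons = list(profiles_by_season)
    if len(seasons) < 2:
        raise ValueError("need at least two seasons")
    profiles = [p for s in seasons for p in profiles_by_season[s]]
    assign_full = {}
    assign_null = {}
    i = 0
    for s in seasons:
        for _ in profiles_by_season[s]:
            assign_full[i] = s
            assign_null[i] = "all"
            i += 1
    full = fit_hier(profiles, HierModelSpec(assign_full, "per_group", "zero"))
    null = fit_hier(profiles, HierModelSpec(assign_null, "per_group", "zero"))
    return lrt(full, null)
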