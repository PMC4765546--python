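"""Maximum-likelihood selfing-rate estimation from multilocus heterozygosity.

The estimator exploits identity disequilibrium: under partial selfing, an
individual whose ancestry contains n consecutive selfing generations has its
outbred heterozygosity halved n times at *every* locus, which correlates
heterozygosity across loci.  With selfing rate s, n is geometric:

    P(x_1..x_L) = sum_n (1-s) s^n  prod_l (h_l 2^-n)^{x_l} (1 - h_l 2^-n)^{1-x_l}

where x_l is the observed 0/1 heterozygosity at locus l and h_l the outbred
(n = 0) heterozygosity, a nuisance parameter per locus.  Because only the
presence/absence of heterozygotes enters, the estimate is robust to null
alleles and allelic dropout, which merely rescale the locus-specific h_l.

The profile likelihood over a grid of s (h maximised out at each point, via
EM on the latent (n, ancestral-heterozygosity) variables) yields the MLE and
a 95 % likelihood interval from the 1.92 log-likelihood drop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .geno_io import GenotypeMatrix, het_patterns

_TAIL_TOL = 1e-14
_N_MAX_CAP = 200


def _n_max_for(s: float, n_max: Optional[int] = None) -> int:
    """Truncation of the selfing-generation count: geometric tail below tolerance."""
    if n_max is not None:
        return int(n_max)
    if s <= 0:
        return 1
    n = int(np.ceil(np.log(_TAIL_TOL) / np.log(s))) if s < 1 else _N_MAX_CAP
    return int(np.clip(n, 1, _N_MAX_CAP))


def _weights(s: float, n_max: int) -> np.ndarray:
    """Truncated geometric P(n) = (1-s)s^n, renormalised to sum to one."""
    n = np.arange(n_max + 1)
    if s == 0:
        w = np.zeros(n_max + 1)
        w[0] = 1.0
        return w
    w = (1 - s) * s ** n
    return w / w.sum()


@dataclass
class SelfingMixtureParams:
    """Parameters of the heterozygosity mixture: selfing rate and per-locus h."""

    s: float
    h: np.ndarray
    n_max: Optional[int] = None

    def __post_init__(self):
        if not 0 <= self.s < 1:
            raise ValueError("s must be in [0, 1)")
        self.h = np.asarray(self.h, dtype=float)
        if np.any((self.h < 0) | (self.h > 1)):
            raise ValueError("each h_l must be in [0, 1]")


def individual_loglik(x, params: SelfingMixtureParams, mask=None) -> float:
    """Log-probability of one 0/1 heterozygosity vector under the mixture.

    Masked (missing) loci contribute a factor of 1.
    """
    x = np.asarray(x, dtype=float)
    if mask is None:
        mask = np.zeros_like(x, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.all():
        raise ValueError("no information: all loci masked")
    n_max = _n_max_for(params.s, params.n_max)
    w = _weights(params.s, n_max)
    pn = 2.0 ** -np.arange(n_max + 1)  # (N,)
    h = params.h[~mask]
    xv = x[~mask]
    # P(x_l | n) for each kept locus and each n
    p1 = h[None, :] * pn[:, None]                      # (N, L)
    pl = np.where(xv[None, :] == 1, p1, 1.0 - p1)
    with np.errstate(divide="ignore"):
        lp = np.log(pl).sum(axis=1)
    m = lp.max()
    if not np.isfinite(m):
        return -np.inf
    return float(m + np.log(np.sum(w * np.exp(lp - m))))


@dataclass
class SelfingProfile:
    """Likelihood profile of the selfing rate for one population."""

    grid: np.ndarray
    loglik: np.ndarray
    s_hat: float
    ci95: tuple
    n_individuals: int
    n_loci: int
    boundary: bool = False
    h_hat: Optional[np.ndarray] = None
    max_loglik: Optional[float] = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.loglik = np.asarray(self.loglik, dtype=float)
        if self.max_loglik is None:
            self.max_loglik = float(self.loglik.max())

    def interp(self, s, warn: bool = True):
        """Profile log-likelihood at arbitrary s, cubic-spline interpolated.

        The spline is built in z = logit(s), where profiles are near-quadratic,
        so interpolation error is negligible at the 0.001 grid spacing.
        Values outside the grid clamp to the boundary value (with a warning).
        """
        s = np.asarray(s, dtype=float)
        if warn and (np.any(s < self.grid[0]) or np.any(s > self.grid[-1])):
            warnings.warn("s outside profile support; using boundary value")
        if not hasattr(self, "_spline") or self._spline is None:
            from scipy.interpolate import CubicSpline
            with np.errstate(divide="ignore"):
                z = np.log(self.grid / (1 - self.grid))
            ok = np.isfinite(z) & np.isfinite(self.loglik)
            self._spline = CubicSpline(z[ok], self.loglik[ok])
            self._zlim = (z[ok][0], z[ok][-1])
        sc = np.clip(s, self.grid[0], self.grid[-1])
        with np.errstate(divide="ignore"):
            zq = np.log(sc / (1 - sc))
        return self._spline(np.clip(zq, *self._zlim))

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"s": self.grid, "loglik": self.loglik})

    def summary(self) -> dict:
        return {
            "s_hat": self.s_hat,
            "ci95": list(self.ci95),
            "n_individuals": self.n_individuals,
            "n_loci": self.n_loci,
            "boundary": self.boundary,
        }


def _profile_em(X: np.ndarray, M: np.ndarray, s: float, h0: np.ndarray,
                n_max: Optional[int] = None, tol: float = 1e-10,
                max_iter: int = 500):
    """Maximise the likelihood over h at fixed s by EM.

    Latent variables per individual: n (selfing generations) and, per locus,
    the ancestral heterozygosity indicator z ~ Bernoulli(h_l); the observed
    x_l equals z AND retention (prob 2^-n).  The M-step for h_l is the
    posterior mean of z over non-missing calls.

    X : (n, L) 0/1 het matrix, M : (n, L) missing mask (True = missing).
    Returns (loglik, h_hat).
    """
    nm = _n_max_for(s, n_max)
    w = _weights(s, nm)
    pn = 2.0 ** -np.arange(nm + 1)
    h = h0.copy()
    obs = ~M
    denom = obs.sum(axis=0).astype(float)  # non-missing per locus
    X1 = (X == 1) & obs
    X0 = (X == 0) & obs
    ll_old = -np.inf
    h = np.clip(h, 1e-12, 1 - 1e-12)
    for _ in range(max_iter):
        p1 = np.clip(h[None, :] * pn[:, None], 1e-300, 1 - 1e-16)  # (N, L)
        # log P(x_il | n): sum over loci of log p or log(1-p)
        lp1 = np.log(p1)
        lp0 = np.log1p(-p1)
        # per individual: sum over non-missing loci
        A = X1 @ lp1.T + X0 @ lp0.T                    # (n, N)
        m = A.max(axis=1, keepdims=True)
        post = np.exp(A - m) * w[None, :]
        norm = post.sum(axis=1, keepdims=True)
        ll = float(np.sum(m[:, 0] + np.log(norm[:, 0])))
        post /= norm                                   # gamma_i(n)
        # E[z | x=0, n] = h (1 - 2^-n) / (1 - h 2^-n)
        ez0 = h[None, :] * (1 - pn[:, None]) / np.maximum(1 - h[None, :] * pn[:, None], 1e-300)
        num = X1.sum(axis=0).astype(float) + ((post @ ez0) * X0).sum(axis=0)
        h_new = np.where(denom > 0, num / np.maximum(denom, 1), h)
        h_new = np.clip(h_new, 1e-12, 1 - 1e-12)
        if abs(ll - ll_old) < tol and np.max(np.abs(h_new - h)) < 1e-9:
            h = h_new
            ll_old = ll
            break
        h = h_new
        ll_old = ll
    return ll_old, h


def fit_selfing(g: GenotypeMatrix, grid_step: float = 0.001,
                n_max: Optional[int] = None, refine_tol: float = 1e-4,
                s_max: float = 0.999) -> SelfingProfile:
    """Profile-likelihood fit of the selfing rate for one population.

    At each grid point s the per-locus outbred heterozygosities h are
    maximised out by EM (warm-started from the previous grid point); the MLE
    is refined around the best grid point to ``refine_tol`` precision and the
    95 % CI taken where the profile drops 1.92 log-units below the maximum.
    """
    if g.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    Xm = het_patterns(g)
    X = Xm.data.astype(float)
    M = np.asarray(Xm.mask, dtype=bool)
    if M.ndim == 0:  # mask=False scalar
        M = np.zeros_like(X, dtype=bool)

    # drop individuals with no scored locus
    keep = ~M.all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"dropping {dropped} individual(s) with no non-missing loci")
    X, M = X[keep], M[keep]
    obs = ~M
    # loci never scored are uninformative; loci never heterozygous are kept
    # (their h_l simply fits to ~0) but identifiability needs >=2 loci with
    # heterozygosity variation
    het_per_locus = ((X == 1) & obs).sum(axis=0)
    obs_per_locus = obs.sum(axis=0)
    informative = (obs_per_locus > 0)
    if not informative.any() or (het_per_locus > 0).sum() == 0:
        # no heterozygote anywhere: s unidentifiable from the top
        warnings.warn("no heterozygote observed at any locus; unidentifiable h, "
                      "returning boundary estimate")
        grid = np.arange(0, s_max + 1e-12, grid_step)
        ll = np.zeros_like(grid)
        return SelfingProfile(grid, ll, s_hat=float(grid[-1]),
                              ci95=(0.0, float(grid[-1])),
                              n_individuals=X.shape[0], n_loci=int(informative.sum()),
                              boundary=True)
    poly = (het_per_locus > 0) & (het_per_locus < obs_per_locus)
    if informative.sum() >= 2 and poly.sum() < 2 and (het_per_locus > 0).sum() < 2:
        raise ValueError("need >=2 loci with heterozygosity variation for identifiability")
    X, M = X[:, informative], M[:, informative]
    obs = ~M
    L = X.shape[1]

    grid = np.arange(0.0, s_max + 1e-12, grid_step)
    ll = np.empty_like(grid)
    h = np.clip(((X == 1) & obs).sum(axis=0) / np.maximum(obs.sum(axis=0), 1), 1e-6, 1 - 1e-6)
    h_best = None
    for k, s in enumerate(grid):
        it = 500 if k == 0 else 60
        ll[k], h = _profile_em(X, M, float(s), h, n_max=n_max, max_iter=it)
        if k == int(np.argmax(ll[: k + 1])):
            h_best = h.copy()

    k0 = int(np.argmax(ll))
    lo = grid[max(k0 - 1, 0)]
    hi = grid[min(k0 + 1, len(grid) - 1)]
    h_warm = h_best.copy()

    def negprof(s):
        v, _ = _profile_em(X, M, float(s), h_warm, n_max=n_max, max_iter=200)
        return -v

    if hi > lo:
        res = minimize_scalar(negprof, bounds=(lo, hi), method="bounded",
                              options={"xatol": refine_tol})
        s_hat, ll_max = float(res.x), -float(res.fun)
        if ll[k0] > ll_max:  # numerical safety
            s_hat, ll_max = float(grid[k0]), float(ll[k0])
    else:
        s_hat, ll_max = float(grid[k0]), float(ll[k0])

    boundary = s_hat <= grid_step / 2 or s_hat >= s_max - grid_step / 2

    # 95 % likelihood interval: profile drops by chi2_1(0.95)/2 = 1.92
    drop = ll_max - 1.9207
    above = ll >= drop
    idx = np.where(above)[0]
    if idx.size == 0:
        ci = (s_hat, s_hat)
    else:
        lo_i, hi_i = idx[0], idx[-1]

        def cross(i, j):
            # linear interpolation of the crossing between grid i and j
            if ll[j] == ll[i]:
                return grid[j]
            t = (drop - ll[i]) / (ll[j] - ll[i])
            return float(grid[i] + t * (grid[j] - grid[i]))

        ci_lo = 0.0 if lo_i == 0 else cross(lo_i - 1, lo_i)
        ci_hi = float(grid[-1]) if hi_i == len(grid) - 1 else cross(hi_i + 1, hi_i)
        ci = (min(ci_lo, s_hat), max(ci_hi, s_hat))

    _, h_hat = _profile_em(X, M, s_hat, h_warm, n_max=n_max, max_iter=500)
    return SelfingProfile(grid, ll, s_hat=s_hat, ci95=ci,
                          n_individuals=X.shape[0], n_loci=L,
                          boundary=boundary, h_hat=h_hat, max_loglik=ll_max)


# ---------------------------------------------------------------------------
# F_IS <-> s conversions (equilibrium under constant partial selfing)
# ---------------------------------------------------------------------------

def selfing_from_fis(F: float) -> float:
    """Equilibrium selfing rate implied by an inbreeding coefficient: s = 2F/(1+F)."""
    if F <= -1:
        raise ValueError("F must be > -1")
    if F < 0:
        warnings.warn("negative F treated as 0 selfing")
        return 0.0
    return 2 * F / (1 + F)


def equilibrium_fis(s: float) -> float:
    """Stationary inbreeding coefficient under constant selfing: F = s/(2-s)."""
    if not 0 <= s <= 1:
        raise ValueError("s must be in [0, 1]")
    return s / (2 - s)
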