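"""Correlated mixed-mating estimation from progeny arrays.

For each maternal family the model is: a progeny is selfed with probability
s = 1 - t_m or outcrossed with a paternal gamete from the pollen pool; with
probability r_t the whole sibship shares a single selfing draw (correlation
of selfing); with probability r_p the outcrossed sibship shares a single
father whose genotype follows pollen-pool frequencies with inbreeding F_p
(correlation of paternity).  Pollen and ovule allele frequencies are equal
to the sample frequencies by default.

Estimation is two-stage.  (t_m, r_t) are fitted by a whole-sibship family
likelihood over the tractable latent classes (all-selfed / all-outcrossed
with shared or independent fathers / independent progeny), which captures
the all-or-none sibship signature that identifies the correlation of
selfing; the one intractable class (independent selfing draws combined
with a shared father — a permanent-type sum) is approximated by
independent fathers.  (r_p, F_p) are then fitted from an exact
progeny-PAIR joint likelihood summed over all within-family pairs, whose
pair marginals reproduce the generative model exactly: the pairwise
correlation of selfing equals r_t and the pairwise father-sharing
probability among outcrossed sibs equals r_p.  For two-progeny families
the pair likelihood IS the exact family likelihood.  Default CIs invert
adjusted composite-likelihood-ratio tests (sandwich correction for pair
dependence); whole-family percentile bootstrap CIs are available but
undercover correlation parameters whose estimates sit on the 0 boundary.

Single-locus outcrossing rates t_s are fitted locus by locus with the
correlation parameters held at their multilocus estimates; t_m - mean(t_s)
estimates biparental inbreeding (mating among relatives).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .geno_io import MISSING, Family, ProgenyArraySet
from .selfing import equilibrium_fis


@dataclass
class MatingParams:
    t_m: float
    r_t: float
    r_p: float
    F_p: float
    t_s: Optional[np.ndarray] = None  # per-locus single-locus outcrossing rates

    @property
    def s_m(self) -> float:
        """Multilocus selfing rate, 1 - t_m."""
        return 1 - self.t_m

    @property
    def t_s_mean(self) -> float:
        return float(np.mean(self.t_s)) if self.t_s is not None else np.nan

    @property
    def biparental_inbreeding(self) -> float:
        return self.t_m - self.t_s_mean


@dataclass
class MatingFit:
    params: MatingParams
    ci95: dict = field(default_factory=dict)
    converged: bool = True
    loglik: float = np.nan
    family_selfing_posterior: Optional[np.ndarray] = None
    n_families: int = 0
    boundary: dict = field(default_factory=dict)


class IncompatibleProgenyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Per-locus genotype-probability primitives
# ---------------------------------------------------------------------------

def _mother_gamete(m):
    """Gamete distribution of a mother genotype (dict allele -> prob)."""
    a, b = m
    return {a: 1.0} if a == b else {a: 0.5, b: 0.5}


def t_self_prob(o, m) -> float:
    """P(offspring genotype o | Mendelian selfing of mother m), one locus."""
    q = _mother_gamete(m)
    x, y = o
    if x == y:
        return q.get(x, 0.0) ** 2
    return 2 * q.get(x, 0.0) * q.get(y, 0.0)


def t_out_prob(o, m, p: dict) -> float:
    """P(o | outcross: one maternal gamete, one pollen-pool gamete)."""
    q = _mother_gamete(m)
    x, y = o
    if x == y:
        return q.get(x, 0.0) * p.get(x, 0.0)
    return q.get(x, 0.0) * p.get(y, 0.0) + q.get(y, 0.0) * p.get(x, 0.0)


def _out_given_father(o, m, g) -> float:
    """P(o | outcross with father genotype g), one locus."""
    q = _mother_gamete(m)
    r = _mother_gamete(g)  # father's gamete distribution
    x, y = o
    if x == y:
        return q.get(x, 0.0) * r.get(x, 0.0)
    return q.get(x, 0.0) * r.get(y, 0.0) + q.get(y, 0.0) * r.get(x, 0.0)


def _father_genotypes(p: dict):
    """Unordered genotypes with HWE (F=0) and fully-inbred (F=1) probabilities."""
    alleles = sorted(p)
    out = []
    for i, a in enumerate(alleles):
        out.append(((a, a), p[a] ** 2, p[a]))
        for b in alleles[i + 1:]:
            out.append(((a, b), 2 * p[a] * p[b], 0.0))
    return out


def shared_father_terms(o1, o2, m, p: dict):
    """(S0, S1): pair probability under one shared father at F_p = 0 and 1.

    The father-genotype prior is linear in F_p, so the pair term at any F_p
    is S0 + F_p (S1 - S0).
    """
    s0 = s1 = 0.0
    for g, hw, hom in _father_genotypes(p):
        v = _out_given_father(o1, m, g) * _out_given_father(o2, m, g)
        s0 += hw * v
        s1 += hom * v
    return s0, s1


def pair_selfing_pmf(s: float, r_t: float):
    """Joint pmf of two sibs' selfing indicators under correlation r_t."""
    p11 = r_t * s + (1 - r_t) * s * s
    p10 = (1 - r_t) * s * (1 - s)
    p00 = r_t * (1 - s) + (1 - r_t) * (1 - s) * (1 - s)
    return p11, p10, p00


def pair_loglik(o1, o2, mother, freqs, t_m, r_t, r_p, F_p) -> float:
    """Exact joint log-likelihood of a progeny pair (lists over loci).

    o1, o2: allele-pair tuples per locus; mother likewise; freqs: list of
    dicts allele->frequency.  This is the family likelihood for two-progeny
    families under the correlated mating model.
    """
    s = 1 - t_m
    A1 = A2 = O1 = O2 = 1.0
    SH0 = []
    for l, p in enumerate(freqs):
        A1 *= t_self_prob(o1[l], mother[l])
        A2 *= t_self_prob(o2[l], mother[l])
        O1 *= t_out_prob(o1[l], mother[l], p)
        O2 *= t_out_prob(o2[l], mother[l], p)
        SH0.append(shared_father_terms(o1[l], o2[l], mother[l], p))
    SH = 1.0
    for s0, s1 in SH0:
        SH *= s0 + F_p * (s1 - s0)
    p11, p10, p00 = pair_selfing_pmf(s, r_t)
    lik = (p11 * A1 * A2 + p10 * (A1 * O2 + A2 * O1)
           + p00 * (r_p * SH + (1 - r_p) * O1 * O2))
    if lik <= 0:
        raise IncompatibleProgenyError("progeny pair impossible under the model")
    return float(np.log(lik))


def family_loglik(family_tables, t_m, r_t, r_p, F_p) -> float:
    """Composite log-likelihood of one family: sum of its pair logliks
    (singleton mixture term for one-progeny families).

    ``family_tables`` is the precomputed structure from :func:`_precompute`.
    """
    lt_self, lt_out, S0, dS, pi, pj = family_tables[:6]
    s = 1 - t_m
    A = np.exp(lt_self.sum(axis=1))
    O = np.exp(lt_out.sum(axis=1))
    if len(pi) == 0:
        return float(np.log(s * A[0] + (1 - s) * O[0]))
    SH = np.prod(S0 + F_p * dS, axis=1)
    p11, p10, p00 = pair_selfing_pmf(s, r_t)
    lik = (p11 * A[pi] * A[pj] + p10 * (A[pi] * O[pj] + A[pj] * O[pi])
           + p00 * (r_p * SH + (1 - r_p) * O[pi] * O[pj]))
    if np.any(lik <= 0):
        raise IncompatibleProgenyError("impossible progeny pair in family")
    return float(np.log(lik).sum())


# ---------------------------------------------------------------------------
# Preparation: frequencies, maternal inference, per-family tables
# ---------------------------------------------------------------------------

def sample_frequencies(arrays: ProgenyArraySet):
    """Per-locus allele frequencies pooled over progeny and known mothers."""
    L = len(arrays.loci)
    freqs = []
    for l in range(L):
        counts = {}
        for fam in arrays.families:
            col = fam.progeny.calls[:, l, :].ravel()
            for a in col[col != MISSING]:
                counts[int(a)] = counts.get(int(a), 0) + 1
            if fam.mother is not None and fam.mother[l, 0] != MISSING:
                for a in fam.mother[l]:
                    counts[int(a)] = counts.get(int(a), 0) + 1
        tot = sum(counts.values())
        freqs.append({a: c / tot for a, c in counts.items()})
    return freqs


def infer_mother_locus(progeny_calls, p: dict, s0: float, F_m: float,
                       mode: str = "ml"):
    """Maternal genotype posterior at one locus from the family's progeny.

    Prior: genotype frequencies with inbreeding F_m; likelihood: per-progeny
    selfing mixture at rate s0.  Returns list of (genotype, weight); a single
    entry in "ml" mode.
    """
    cands = []
    for g, hw, hom in _father_genotypes(p):
        prior = (1 - F_m) * hw + F_m * hom
        if prior <= 0:
            continue
        ll = np.log(prior)
        ok = True
        for o in progeny_calls:
            if o[0] == MISSING:
                continue
            v = s0 * t_self_prob(o, g) + (1 - s0) * t_out_prob(o, g, p)
            if v <= 0:
                ok = False
                break
            ll += np.log(v)
        if ok:
            cands.append((g, ll))
    if not cands:
        raise IncompatibleProgenyError("no maternal genotype compatible with family")
    lls = np.array([c[1] for c in cands])
    w = np.exp(lls - lls.max())
    w /= w.sum()
    if mode == "ml":
        best = cands[int(np.argmax(lls))][0]
        return [(best, 1.0)]
    return [(c[0], float(wi)) for c, wi in zip(cands, w) if wi > 1e-12]


def _precompute(arrays: ProgenyArraySet, freqs, mothers):
    """Per-family probability tables for fast likelihood evaluation.

    mothers: per family, per locus, list of (genotype, weight) — maternal
    genotype known (single entry) or posterior-weighted.
    Returns a list of family tables (lt_self, lt_out, S0, dS, pi, pj).
    """
    tables = []
    L = len(freqs)
    for fi, fam in enumerate(arrays.families):
        calls = fam.progeny.calls
        k = calls.shape[0]
        lt_self = np.zeros((k, L))
        lt_out = np.zeros((k, L))
        for i in range(k):
            for l in range(L):
                o = tuple(calls[i, l])
                if o[0] == MISSING:
                    continue  # missing contributes factor 1
                ts = sum(w * t_self_prob(o, m) for m, w in mothers[fi][l])
                to = sum(w * t_out_prob(o, m, freqs[l]) for m, w in mothers[fi][l])
                if ts <= 0 and to <= 0:
                    raise IncompatibleProgenyError(
                        f"family {fi}, locus {arrays.loci[l]}, progeny "
                        f"{fam.progeny.individuals[i]}: genotype {o} impossible "
                        "under both selfing and outcrossing")
                with np.errstate(divide="ignore"):
                    lt_self[i, l] = np.log(ts) if ts > 0 else -np.inf
                    lt_out[i, l] = np.log(to) if to > 0 else -np.inf
        pi, pj = np.triu_indices(k, 1)
        S0 = np.ones((len(pi), L))
        dS = np.zeros((len(pi), L))
        for idx, (i, j) in enumerate(zip(pi, pj)):
            for l in range(L):
                o1, o2 = tuple(calls[i, l]), tuple(calls[j, l])
                if o1[0] == MISSING and o2[0] == MISSING:
                    continue
                if o1[0] == MISSING or o2[0] == MISSING:
                    # only one scored: shared-father term reduces to its
                    # single-progeny outcross probability
                    o = o1 if o1[0] != MISSING else o2
                    v = sum(w * t_out_prob(o, m, freqs[l]) for m, w in mothers[fi][l])
                    S0[idx, l] = v
                    continue
                s0 = s1 = 0.0
                for m, w in mothers[fi][l]:
                    a, b = shared_father_terms(o1, o2, m, freqs[l])
                    s0 += w * a
                    s1 += w * b
                S0[idx, l] = s0
                dS[idx, l] = s1 - s0
        # whole-sibship shared-father terms per locus (F = 0 / F = 1 parts):
        # sum_g P(g) prod_i P(o_i | mother, father g), missing progeny skipped
        SF0 = np.ones(L)
        SF1 = np.ones(L)
        for l in range(L):
            s0 = s1 = 0.0
            for m, wm in mothers[fi][l]:
                for g, hw, hom in _father_genotypes(freqs[l]):
                    v = 1.0
                    for i in range(k):
                        o = tuple(calls[i, l])
                        if o[0] == MISSING:
                            continue
                        v *= _out_given_father(o, m, g)
                    s0 += wm * hw * v
                    s1 += wm * hom * v
            SF0[l], SF1[l] = s0, s1
        tables.append((lt_self, lt_out, S0, dS, pi, pj, SF0, SF1))
    return tables


class _Assembled:
    """All families' pair/singleton probability tables in flat arrays.

    Pre-exponentiated per-pair ingredients make one likelihood evaluation a
    handful of vector operations; a family-weight vector turns whole-family
    bootstrap resampling into a reweighting, so bootstrap refits never
    rebuild the tables.
    """

    def __init__(self, tables):
        Ai, Aj, Oi, Oj, fam_pair = [], [], [], [], []
        Ai_l, Aj_l, Oi_l, Oj_l, S0_l, dS_l = [], [], [], [], [], []
        sA, sO, fam_single = [], [], []
        self.fam_terms = []  # per family: (A_il, O_il matrices, SF0, SF1)
        for fi, (lt_self, lt_out, S0, dS, pi, pj, SF0, SF1) in enumerate(tables):
            a_l = np.exp(lt_self)
            o_l = np.exp(lt_out)
            a = np.exp(lt_self.sum(axis=1))
            o = np.exp(lt_out.sum(axis=1))
            self.fam_terms.append((a_l, o_l, SF0, SF1))
            if len(pi) == 0:
                sA.append(a[0])
                sO.append(o[0])
                fam_single.append(fi)
                continue
            Ai.append(a[pi]); Aj.append(a[pj])
            Oi.append(o[pi]); Oj.append(o[pj])
            Ai_l.append(a_l[pi]); Aj_l.append(a_l[pj])
            Oi_l.append(o_l[pi]); Oj_l.append(o_l[pj])
            S0_l.append(S0); dS_l.append(dS)
            fam_pair.extend([fi] * len(pi))
        cat = (lambda x: np.concatenate(x) if x else np.empty(0))
        self.Ai, self.Aj = cat(Ai), cat(Aj)
        self.Oi, self.Oj = cat(Oi), cat(Oj)
        cat2 = (lambda x: np.concatenate(x, axis=0) if x
                else np.empty((0, tables[0][0].shape[1])))
        self.Ai_l, self.Aj_l = cat2(Ai_l), cat2(Aj_l)
        self.Oi_l, self.Oj_l = cat2(Oi_l), cat2(Oj_l)
        self.S0_l, self.dS_l = cat2(S0_l), cat2(dS_l)
        self.fam_pair = np.asarray(fam_pair, dtype=int)
        self.sA, self.sO = np.asarray(sA), np.asarray(sO)
        self.fam_single = np.asarray(fam_single, dtype=int)
        self.n_families = len(tables)

    def neg_loglik(self, theta, w=None, locus=None):
        t_m, r_t, r_p, F_p = theta
        s = 1 - t_m
        if locus is None:
            Ai, Aj, Oi, Oj = self.Ai, self.Aj, self.Oi, self.Oj
            SH = np.prod(self.S0_l + F_p * self.dS_l, axis=1)
            sA, sO = self.sA, self.sO
        else:
            Ai, Aj = self.Ai_l[:, locus], self.Aj_l[:, locus]
            Oi, Oj = self.Oi_l[:, locus], self.Oj_l[:, locus]
            SH = self.S0_l[:, locus] + F_p * self.dS_l[:, locus]
            sA, sO = self.sA, self.sO  # singleton loci folded multilocus
        p11, p10, p00 = pair_selfing_pmf(s, r_t)
        lik = (p11 * Ai * Aj + p10 * (Ai * Oj + Aj * Oi)
               + p00 * (r_p * SH + (1 - r_p) * Oi * Oj))
        if np.any(lik <= 0):
            return 1e12
        ll = np.log(lik)
        if w is None:
            total = ll.sum()
        else:
            total = float(w[self.fam_pair] @ ll)
        if len(self.sA):
            sl = np.log(s * sA + (1 - s) * sO)
            total += (sl.sum() if w is None
                      else float(w[self.fam_single] @ sl))
        return -total

    def family_loglik_per(self, theta, locus=None):
        """Per-family log-likelihood under the whole-sibship class model.

        Classes: with prob r_t the sibship shares one selfing draw (all
        selfed, or all outcrossed — then one shared father with prob r_p,
        independent fathers otherwise); with prob 1 - r_t progeny self
        independently with independent fathers.  The remaining generative
        class (independent selfing draws combined with a shared father) is
        approximated by independent fathers — the exact term is a
        permanent-type sum.  This captures the all-or-none sibship
        signature that identifies the correlation of selfing far more
        sharply than progeny pairs do.
        """
        t_m, r_t, r_p, F_p = theta
        s = 1 - t_m
        out = np.empty(self.n_families)
        for fi, (A_il, O_il, SF0, SF1) in enumerate(self.fam_terms):
            if locus is None:
                A = A_il.prod(axis=1)
                O = O_il.prod(axis=1)
                shfam = float(np.prod(SF0 + F_p * (SF1 - SF0)))
            else:
                A = A_il[:, locus]
                O = O_il[:, locus]
                shfam = float(SF0[locus] + F_p * (SF1[locus] - SF0[locus]))
            indep = float(np.prod(s * A + (1 - s) * O))
            shared = (s * float(np.prod(A))
                      + (1 - s) * (r_p * shfam + (1 - r_p) * float(np.prod(O))))
            out[fi] = np.log(max(r_t * shared + (1 - r_t) * indep, 1e-300))
        return out

    def neg_family_loglik(self, theta, w=None, locus=None):
        ll = self.family_loglik_per(theta, locus=locus)
        return -(ll.sum() if w is None else float(w @ ll))


def _pair_loglik_per_family(asm: _Assembled, th):
    """Per-family totals of the pairwise composite log-likelihood."""
    out = np.zeros(asm.n_families)
    t_m, r_t, r_p, F_p = th
    s = 1 - t_m
    SH = np.prod(asm.S0_l + F_p * asm.dS_l, axis=1)
    p11, p10, p00 = pair_selfing_pmf(s, r_t)
    lik = (p11 * asm.Ai * asm.Aj + p10 * (asm.Ai * asm.Oj + asm.Aj * asm.Oi)
           + p00 * (r_p * SH + (1 - r_p) * asm.Oi * asm.Oj))
    np.add.at(out, asm.fam_pair, np.log(np.maximum(lik, 1e-300)))
    if len(asm.sA):
        sl = np.log(np.maximum(s * asm.sA + (1 - s) * asm.sO, 1e-300))
        np.add.at(out, asm.fam_single, sl)
    return out


def _sandwich_adjustments(asm: _Assembled, theta, objective: str = "pair"):
    """Per-parameter variance adjustments for composite-likelihood ratios.

    Within-family progeny pairs are dependent, so the pairwise composite
    likelihood is overconfident; the CLR statistic for parameter k is
    asymptotically lambda_k * chi2_1 with
    lambda_k = (H^-1 J H^-1)_kk / (H^-1)_kk, where H is the negative CL
    Hessian and J the empirical variance of per-family scores (Varin-style
    adjustment).  For the family-level objective lambda is typically ~1.
    """
    theta = np.asarray(theta, dtype=float)
    p = len(theta)
    if objective == "family":
        famwise = asm.family_loglik_per
    else:
        famwise = lambda th: _pair_loglik_per_family(asm, th)

    # Fixed-step central differences.  The CL total is O(1e4-1e5), so tiny
    # steps cancel catastrophically; a 0.01 step keeps round-off negligible.
    # The algebraic CL formula remains valid slightly outside [0,1], so
    # boundary estimates still get central differences.
    h = np.full(p, 1e-2)
    scores = np.zeros((asm.n_families, p))
    H = np.zeros((p, p))
    for k in range(p):
        tp, tm_ = theta.copy(), theta.copy()
        tp[k] += h[k]
        tm_[k] -= h[k]
        scores[:, k] = (famwise(tp) - famwise(tm_)) / (2 * h[k])
        for j in range(k, p):
            tpp, tpm = tp.copy(), tp.copy()
            tmp_, tmm = tm_.copy(), tm_.copy()
            tpp[j] += h[j]; tpm[j] -= h[j]
            tmp_[j] += h[j]; tmm[j] -= h[j]
            H[k, j] = H[j, k] = (
                (famwise(tpp).sum() - famwise(tpm).sum())
                - (famwise(tmp_).sum() - famwise(tmm).sum())) / (4 * h[k] * h[j])
    scores -= scores.mean(axis=0)
    J = scores.T @ scores
    # lambda < 1 cannot arise from positively dependent pairs; values below 1
    # indicate numerical noise and are floored (conservative: widens CIs)
    lam = np.ones(p)
    try:
        Hinv = np.linalg.pinv(-H)
        G = Hinv @ J @ Hinv
        for k in range(p):
            if Hinv[k, k] > 1e-12:
                lam[k] = max(G[k, k] / Hinv[k, k], 1.0)
    except np.linalg.LinAlgError:
        pass
    return lam


def _profile_ci(asm: _Assembled, x_hat, cl_max, k, lam_k,
                objective: str = "pair", fixed=(), n_grid=41):
    """Adjusted composite-likelihood-ratio CI for parameter k.

    CI = {psi : 2 (CL_max - CL_profile(psi)) <= lambda_k * 3.84}, found on a
    grid over the parameter's range; the parameters not in ``fixed`` are
    re-optimised (warm-started) at each grid point.
    """
    from scipy.stats import chi2
    thresh = lam_k * chi2.ppf(0.95, 1) / 2
    bounds = [(1e-6, 1.0), (0.0, 1.0), (0.0, 1.0), (0.0, 0.999)]
    lo_b, hi_b = bounds[k]
    lo_b = 0.0 if k != 0 else lo_b
    grid = np.linspace(lo_b, hi_b, n_grid)
    free = [i for i in range(4) if i != k and i not in fixed]
    x_hat = np.asarray(x_hat, dtype=float)
    neg_fn = (asm.neg_family_loglik if objective == "family"
              else asm.neg_loglik)

    def prof(psi):
        th = x_hat.copy()
        th[k] = psi
        if not free:
            return -neg_fn(th)

        def neg(sub):
            th[free] = sub
            return neg_fn(th)

        res = minimize(neg, x_hat[free], method="L-BFGS-B",
                       bounds=[bounds[i] for i in free])
        return -res.fun

    vals = np.array([prof(psi) for psi in grid])
    ok = cl_max - vals <= thresh
    idx = np.where(ok)[0]
    est = float(x_hat[k])
    if idx.size == 0:
        return (est, est)

    def cross(i, j):
        target = cl_max - thresh
        if vals[j] == vals[i]:
            return grid[j]
        t = (target - vals[i]) / (vals[j] - vals[i])
        return float(np.clip(grid[i] + t * (grid[j] - grid[i]), lo_b, hi_b))

    lo = lo_b if idx[0] == 0 else cross(idx[0] - 1, idx[0])
    hi = hi_b if idx[-1] == n_grid - 1 else cross(idx[-1] + 1, idx[-1])
    return (min(lo, est), max(hi, est))


def _fit_family(asm: _Assembled, w=None, x0=None, n_starts: int = 5, rng=None):
    """Multi-start L-BFGS-B on the whole-sibship family likelihood."""
    bounds = [(1e-6, 1.0), (0.0, 1.0), (0.0, 1.0), (0.0, 0.999)]
    rng = rng or np.random.default_rng(0)
    starts = []
    if x0 is not None:
        starts.append(np.asarray(x0, dtype=float))
    starts.append(np.array([0.7, 0.2, 0.2, 0.1]))
    while len(starts) < n_starts:
        starts.append(np.array([rng.uniform(0.2, 0.98), rng.uniform(0, 0.6),
                                rng.uniform(0, 0.6), rng.uniform(0, 0.4)]))
    best = None
    for s0 in starts:
        res = minimize(lambda th: asm.neg_family_loglik(th, w=w), s0,
                       method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-12, "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    # coordinate polish: finite-difference gradients leave ~1e-3 parameter
    # slack, which breaks exact identities (e.g. t_s == t_m on 1-locus data)
    x = np.asarray(best.x, dtype=float)
    for _ in range(2):
        for k in range(4):
            def neg_k(v, k=k):
                th = x.copy()
                th[k] = v
                return asm.neg_family_loglik(th, w=w)

            r = minimize_scalar(neg_k, bounds=bounds[k], method="bounded",
                                options={"xatol": 1e-7})
            if r.fun <= best.fun:
                x[k] = r.x
                best.fun = r.fun
    best.x = x
    return best


def _two_stage_fit(asm: _Assembled, w=None, x0=None, n_starts: int = 5,
                   rng=None):
    """Point estimation: (t_m, r_t) from the family likelihood, then
    (r_p, F_p) from the pairwise composite with (t_m, r_t) held fixed.

    Returns (theta, fam_cl_max, pair_cl_max, success).
    """
    bf = _fit_family(asm, w=w, x0=x0, n_starts=n_starts, rng=rng)
    theta = np.asarray(bf.x, dtype=float)

    def neg_pf(sub):
        th = theta.copy()
        th[2], th[3] = sub
        return asm.neg_loglik(th, w=w)

    starts = [theta[2:].copy(), np.array([0.2, 0.1])]
    best = None
    for s0 in starts:
        res = minimize(neg_pf, s0, method="L-BFGS-B",
                       bounds=[(0.0, 1.0), (0.0, 0.999)])
        if best is None or res.fun < best.fun:
            best = res
    theta[2], theta[3] = best.x
    return theta, -float(bf.fun), -float(best.fun), bool(bf.success and best.success)


def fit_mating(arrays: ProgenyArraySet, infer_mother: str = "ml",
               n_bootstrap: int = 1000, seed: int = 0,
               n_starts: int = 5, fit_ts: bool = True,
               ci_method: str = "profile") -> MatingFit:
    """Fit the correlated mixed-mating model to a set of progeny arrays.

    Parameters
    ----------
    infer_mother : "ml" or "marginal"
        How to handle families without a maternal genotype: per-locus ML
        assignment (default) or posterior-weighted marginalisation.  The
        maternal prior uses ovule frequencies with inbreeding at the
        selfing equilibrium of the current t_m; inference is iterated once.
    n_bootstrap : whole-family bootstrap replicates (percentile CIs and the
        CIs of derived quantities: mean t_s, biparental inbreeding).
    ci_method : "profile" (default) or "bootstrap"
        CI type for (t_m, r_t, r_p, F_p).  "profile" uses adjusted
        composite-likelihood-ratio intervals (sandwich correction for
        within-family pair dependence), which stay calibrated when a
        correlation estimate sits on the 0 boundary; "bootstrap" uses the
        classical whole-family percentile bootstrap, which measurably
        undercovers boundary parameters (see docs) but is retained as the
        field's conventional method.
    """
    if arrays.n_families < 5:
        warnings.warn("fewer than 5 families: estimates will be imprecise")
    freqs = sample_frequencies(arrays)
    L = len(freqs)

    def build_mothers(s0):
        mothers = []
        F_m = equilibrium_fis(s0)
        for fam in arrays.families:
            per_locus = []
            for l in range(L):
                if fam.mother is not None and fam.mother[l, 0] != MISSING:
                    per_locus.append([(tuple(sorted(fam.mother[l])), 1.0)])
                else:
                    calls = [tuple(c) for c in fam.progeny.calls[:, l, :]]
                    per_locus.append(infer_mother_locus(
                        calls, freqs[l], s0, F_m, mode=infer_mother))
            mothers.append(per_locus)
        return mothers

    mothers = build_mothers(0.3)
    tables = _precompute(arrays, freqs, mothers)
    asm = _Assembled(tables)
    rng = np.random.default_rng(seed)
    theta, fam_cl, pair_cl, success = _two_stage_fit(asm, n_starts=n_starts,
                                                     rng=rng)
    # one round of maternal re-inference at the fitted selfing rate
    if any(f.mother is None for f in arrays.families):
        mothers = build_mothers(1 - theta[0])
        tables = _precompute(arrays, freqs, mothers)
        asm = _Assembled(tables)
        theta, fam_cl, pair_cl, success = _two_stage_fit(
            asm, x0=theta, n_starts=n_starts, rng=rng)
    if not success:
        raise RuntimeError("mating-model fit did not converge")
    t_m, r_t, r_p, F_p = theta

    def fit_ts_all(theta, w=None):
        # single-locus outcrossing rates: the family likelihood restricted
        # to one locus, correlations held at the multilocus estimates
        ts = np.empty(L)
        for l in range(L):
            def neg(t, l=l):
                return asm.neg_family_loglik((t, theta[1], theta[2], theta[3]),
                                             w=w, locus=l)

            res = minimize_scalar(neg, bounds=(1e-6, 1.0), method="bounded",
                                  options={"xatol": 1e-5})
            ts[l] = res.x
        return ts

    ts = fit_ts_all(theta) if fit_ts else None
    params = MatingParams(t_m=float(t_m), r_t=float(r_t), r_p=float(r_p),
                          F_p=float(F_p), t_s=ts)

    # per-progeny posterior probability of being selfed, averaged per family
    post = []
    s = 1 - t_m
    for lt_self, lt_out, *_ in tables:
        A = np.exp(lt_self.sum(axis=1))
        O = np.exp(lt_out.sum(axis=1))
        post.append(float(np.mean(s * A / (s * A + (1 - s) * O))))

    ci = {}
    if ci_method == "profile":
        # (t_m, r_t): family-likelihood profiles (lambda ~ 1); (r_p, F_p):
        # pairwise-CL profiles with sandwich adjustment, (t_m, r_t) fixed
        lam_f = _sandwich_adjustments(asm, theta, objective="family")
        ci["t_m"] = _profile_ci(asm, theta, fam_cl, 0, lam_f[0], "family")
        ci["r_t"] = _profile_ci(asm, theta, fam_cl, 1, lam_f[1], "family")
        lam_p = _sandwich_adjustments(asm, theta, objective="pair")
        ci["r_p"] = _profile_ci(asm, theta, pair_cl, 2, lam_p[2], "pair",
                                fixed=(0, 1))
        ci["F_p"] = _profile_ci(asm, theta, pair_cl, 3, lam_p[3], "pair",
                                fixed=(0, 1))
        ci["s_m"] = (1 - ci["t_m"][1], 1 - ci["t_m"][0])
    if n_bootstrap > 0:
        nf = len(tables)
        keys = ["t_m", "s_m", "r_t", "r_p", "F_p", "t_s_mean", "biparental"]
        stats = {k: [] for k in keys}
        for _ in range(n_bootstrap):
            w = np.bincount(rng.integers(0, nf, nf), minlength=nf).astype(float)
            bt, *_ = _two_stage_fit(asm, w=w, x0=theta, n_starts=1)
            stats["t_m"].append(bt[0])
            stats["s_m"].append(1 - bt[0])
            stats["r_t"].append(bt[1])
            stats["r_p"].append(bt[2])
            stats["F_p"].append(bt[3])
            if fit_ts:
                tsb = fit_ts_all(bt, w=w)
                stats["t_s_mean"].append(float(np.mean(tsb)))
                stats["biparental"].append(bt[0] - float(np.mean(tsb)))
        for k, v in stats.items():
            if not v:
                continue
            lo = (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
            if ci_method == "bootstrap" or k in ("t_s_mean", "biparental"):
                ci[k] = lo
            else:
                ci[f"{k}_bootstrap"] = lo
    boundary = {"t_m": t_m >= 1 - 1e-5 or t_m <= 1e-5,
                "r_t": r_t <= 1e-9 or r_t >= 1 - 1e-9,
                "r_p": r_p <= 1e-9 or r_p >= 1 - 1e-9,
                "F_p": F_p <= 1e-9}
    return MatingFit(params=params, ci95=ci, converged=success,
                     loglik=fam_cl + pair_cl,
                     family_selfing_posterior=np.array(post),
                     n_families=arrays.n_families, boundary=boundary)


def biparental_inbreeding(fit: MatingFit):
    """t_m - mean(t_s) with its bootstrap CI (positive under mating among relatives)."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    return fit.params.biparental_inbreeding, fit.ci95.get("biparental")


def effective_fathers(r_p: float):
    """Effective number of fathers per sibship, 1/r_p (rounded and raw).

    Returns (rounded, raw); r_p = 0 means unbounded (None, inf).
    """
    if r_p < 0 or r_p > 1:
        raise ValueError("r_p must be in [0, 1]")
    if r_p == 0:
        return None, np.inf
    raw = 1.0 / r_p
    return int(round(raw)), raw
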