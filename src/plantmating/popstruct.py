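"""Classical population-structure statistics for co-dominant multilocus data.

Weir & Cockerham (1984) variance-components estimators of F_IS and F_ST
(multilocus values as ratios of summed components, the GENETIX/FSTAT
convention), a three-level hierarchical decomposition
(ecotype / population-within-ecotype / individual-within-population),
FSTAT-style permutation comparisons of per-population statistics between
groups, a linkage screen, great-circle distances, Mantel tests, the
isolation-by-distance regression of F_ST/(1-F_ST) on log distance, and a
centred (non-scaled) PCA of individual allele counts.

Also houses two closed-form mating-system quantities: the relative loss of
effective size caused by a higher equilibrium inbreeding coefficient, and
the inbreeding depression required to reconcile a primary selfing rate with
the rate observed among surviving adults.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geno_io import MISSING, GenotypeMatrix
from .selfing import equilibrium_fis

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components
# ---------------------------------------------------------------------------

def _locus_allele_tables(pops, locus_index):
    """Per-population sample sizes, allele freqs and het freqs at one locus.

    Returns (alleles, n_i, p_ia, h_ia): n_i individuals scored per pop,
    p_ia allele frequency, h_ia observed frequency of heterozygotes carrying
    allele a.
    """
    alleles = sorted({int(a) for g in pops
                      for a in g.calls[:, locus_index, :].ravel() if a != MISSING})
    r = len(pops)
    k = len(alleles)
    a_index = {a: i for i, a in enumerate(alleles)}
    n = np.zeros(r)
    p = np.zeros((r, k))
    h = np.zeros((r, k))
    for i, g in enumerate(pops):
        calls = g.calls[:, locus_index, :]
        scored = calls[:, 0] != MISSING
        ni = scored.sum()
        n[i] = ni
        if ni == 0:
            continue
        cc = calls[scored]
        for a, cnt in zip(*np.unique(cc, return_counts=True)):
            p[i, a_index[int(a)]] = cnt / (2 * ni)
        het = cc[:, 0] != cc[:, 1]
        for a in alleles:
            h[i, a_index[a]] = np.mean(het & ((cc[:, 0] == a) | (cc[:, 1] == a)))
    return alleles, n, p, h


def wc_components(pops, loci=None):
    """Weir-Cockerham (1984) per-locus-allele variance components.

    Returns a DataFrame with columns locus, allele, a, b, c where a, b, c
    are the among-population, among-individual-within-population, and
    within-individual components.
    """
    L = pops[0].n_loci
    loci = range(L) if loci is None else loci
    rows = []
    for l in loci:
        alleles, n, p, h = _locus_allele_tables(pops, l)
        keep = n >= 1
        n, p, h = n[keep], p[keep], h[keep]
        r = len(n)
        if r == 0 or n.sum() == 0:
            continue
        nbar = n.mean()
        if r > 1:
            nc = (n.sum() - (n ** 2).sum() / n.sum()) / (r - 1)
        else:
            nc = n[0]
        for ai in range(len(alleles)):
            pbar = (n * p[:, ai]).sum() / n.sum()
            hbar = (n * h[:, ai]).sum() / n.sum()
            if r > 1:
                s2 = (n * (p[:, ai] - pbar) ** 2).sum() / ((r - 1) * nbar)
            else:
                s2 = 0.0
            if r > 1:
                a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                         - hbar / 4) / (nbar - 1))
            else:
                a = 0.0
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar)
                                       - (r - 1) / r * s2
                                       - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            rows.append({"locus": pops[0].loci[l], "allele": alleles[ai],
                         "a": a, "b": b, "c": c})
    return pd.DataFrame(rows)


def wc_fis(g: GenotypeMatrix, loci=None):
    """Single-population multilocus Weir-Cockerham f (F_IS), ratio of sums."""
    comp = wc_components([g], loci=loci)
    if comp.empty:
        return np.nan
    denom = (comp.b + comp.c).sum()
    if denom <= 0:
        return np.nan
    return float(1 - comp.c.sum() / denom)


def wc_fst(pops, loci=None):
    """Multilocus Weir-Cockerham theta across populations, ratio of sums."""
    comp = wc_components(pops, loci=loci)
    if comp.empty:
        return np.nan
    denom = (comp.a + comp.b + comp.c).sum()
    if denom <= 0:
        return np.nan
    return float(comp.a.sum() / denom)


def diversity_table(pops: dict, n_bootstrap: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per-population diversity summary: n, A, H_obs, H_exp, F_IS with CI.

    H_exp is the unbiased (2n/(2n-1)) gene diversity averaged over loci;
    F_IS is the multilocus Weir-Cockerham f with a locus-bootstrap 95 % CI
    and a flag set when the CI excludes zero.
    """
    rows = []
    for name, g in pops.items():
        if g.n_individuals < 2:
            raise ValueError(f"population {name}: need >=2 individuals")
        A, hobs, hexp = [], [], []
        for l in range(g.n_loci):
            calls = g.calls[:, l, :]
            scored = calls[:, 0] != MISSING
            ni = scored.sum()
            if ni == 0:
                continue
            cc = calls[scored]
            alleles, counts = np.unique(cc, return_counts=True)
            p = counts / (2 * ni)
            A.append(len(alleles))
            hobs.append(np.mean(cc[:, 0] != cc[:, 1]))
            hexp.append((2 * ni / (2 * ni - 1)) * (1 - np.sum(p ** 2)))
        comp = wc_components([g])
        if comp.empty or (comp.b + comp.c).sum() <= 0:
            fis, ci, flag = np.nan, (np.nan, np.nan), False
        else:
            by_locus = comp.groupby("locus", sort=False)[["b", "c"]].sum().values
            fis = float(1 - by_locus[:, 1].sum() / by_locus.sum())
            rng = np.random.default_rng(seed)
            nl = len(by_locus)
            vals = []
            for _ in range(n_bootstrap):
                bs = by_locus[rng.integers(0, nl, nl)].sum(axis=0)
                if bs.sum() > 0:
                    vals.append(1 - bs[1] / bs.sum())
            ci = ((float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))
                  if vals else (np.nan, np.nan))
            flag = bool(ci[0] > 0 or ci[1] < 0)
        rows.append({"population": name, "ecotype": g.meta.ecotype,
                     "n": g.n_individuals, "A": float(np.mean(A)),
                     "H_obs": float(np.mean(hobs)), "H_exp": float(np.mean(hexp)),
                     "F_IS": fis, "F_IS_ci_low": ci[0], "F_IS_ci_high": ci[1],
                     "F_IS_nonzero": flag})
    return pd.DataFrame(rows)


def pairwise_fst(pops: dict) -> pd.DataFrame:
    """Symmetric matrix of pairwise multilocus Weir-Cockerham theta."""
    names = list(pops)
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for i, j in itertools.combinations(range(len(names)), 2):
        v = wc_fst([pops[names[i]], pops[names[j]]])
        mat.iloc[i, j] = mat.iloc[j, i] = v
    return mat


# ---------------------------------------------------------------------------
# Hierarchical (three-level) F-statistics
# ---------------------------------------------------------------------------

def _henderson_components(pops: dict, assignment: dict, loci):
    """Per-locus variance components (ecotype, population, individual, gene)
    by Henderson method I on allele indicators, summed over alleles.

    Returns an array (len(loci), 4); components are additive over loci, so
    locus bootstraps can resample rows.
    """
    names = list(pops)
    out = np.zeros((len(loci), 4))  # sigma2_e, sigma2_p, sigma2_i, sigma2_w
    for li, l in enumerate(loci):
        # per-gene-copy codes: ecotype, population, individual
        ind_ids, pop_ids, eco_ids, ys = [], [], [], []
        gid = 0
        for pn, n in enumerate(names):
            g = pops[n]
            calls = g.calls[:, l, :]
            eco_code = sorted(set(assignment.values())).index(assignment[n])
            for r in range(g.n_individuals):
                if calls[r, 0] == MISSING:
                    continue
                for copy in range(2):
                    ind_ids.append(gid + r)
                    pop_ids.append(pn)
                    eco_ids.append(eco_code)
                    ys.append(int(calls[r, copy]))
            gid += g.n_individuals
        if not ys:
            continue
        ind_arr = np.array(ind_ids)
        pop_arr = np.array(pop_ids)
        eco_arr = np.array(eco_ids)
        ys = np.array(ys)
        N = len(ys)
        alleles = np.unique(ys)
        if len(alleles) < 2:
            continue

        def codes(arr):
            _, c = np.unique(arr, return_inverse=True)
            return c

        groupings = [np.zeros(N, dtype=int), codes(eco_arr), codes(pop_arr),
                     codes(ind_arr), np.arange(N)]
        comps = [codes(eco_arr), codes(pop_arr), codes(ind_arr)]
        # degenerate levels (e.g. a single ecotype) make the system singular:
        # a level identical to the one above contributes no component
        active = [True] * 4
        for ci in range(3):
            if groupings[ci + 1].max() == groupings[ci].max():
                active[ci] = False

        # coefficients of E[S_X] in the variance components (data-independent)
        C = []
        for gx in groupings:
            Kx = gx.max() + 1
            Nx = np.bincount(gx, minlength=Kx).astype(float)
            row = np.zeros(4)
            for ci, gc in enumerate(comps):
                Kc = gc.max() + 1
                pair = gx.astype(np.int64) * Kc + gc
                cnt = np.bincount(pair, minlength=Kx * Kc).astype(float)
                cnt2 = cnt.reshape(Kx, Kc) ** 2
                row[ci] = float((cnt2.sum(axis=1) / Nx).sum())
            row[3] = float(Kx)  # sigma2_w: one per group
            C.append(row)
        A = np.array([C[i + 1] - C[i] for i in range(4)])
        keep_rows = [i for i in range(4) if active[i] or i == 3
                     or not np.allclose(A[i], 0)]
        keep_cols = [i for i in range(4) if active[i]]
        keep_rows = keep_rows[-len(keep_cols):]
        Ared = A[np.ix_(keep_rows, keep_cols)]

        comp_l = np.zeros(4)
        for al in alleles:
            y = (ys == al).astype(float)
            S_vals = []
            for gx in groupings:
                Kx = gx.max() + 1
                Nx = np.bincount(gx, minlength=Kx).astype(float)
                T = np.bincount(gx, weights=y, minlength=Kx)
                S_vals.append(float((T * T / Nx).sum()))
            bvec = np.array([S_vals[i + 1] - S_vals[i] for i in range(4)])
            try:
                sol = np.linalg.solve(Ared, bvec[keep_rows])
            except np.linalg.LinAlgError:
                continue
            full = np.zeros(4)
            full[keep_cols] = sol
            comp_l += full
        out[li] = comp_l
    return out


def hierarchical_f(pops: dict, assignment: dict, n_bootstrap: int = 1000,
                   seed: int = 0) -> pd.DataFrame:
    """Three-level fixation indexes with locus-bootstrap CIs.

    Rows: among ecotypes (F_E/T), among populations within ecotypes (F_P/E),
    among individuals within populations (F_I/P), estimated from nested
    variance components of allele indicators.
    """
    groups = set(assignment.values())
    single_pop_groups = [g for g in groups
                         if sum(1 for v in assignment.values() if v == g) < 2]
    if single_pop_groups:
        warnings.warn(f"groups with a single population: {single_pop_groups}; "
                      "their level CI is degenerate")
    L = pops[next(iter(pops))].n_loci
    per_locus = _henderson_components(pops, assignment, list(range(L)))

    def indexes(rows):
        e, p, i, w = per_locus[rows].sum(axis=0)
        tot = e + p + i + w
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.array([e / tot if tot > 0 else np.nan,
                             p / (p + i + w) if (p + i + w) > 0 else np.nan,
                             i / (i + w) if (i + w) > 0 else np.nan])

    est = indexes(np.arange(L))
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        boots.append(indexes(rng.integers(0, L, L)))
    if boots:
        boots = np.array(boots)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lo = np.nanpercentile(boots, 2.5, axis=0)
            hi = np.nanpercentile(boots, 97.5, axis=0)
    else:
        lo = hi = np.full(3, np.nan)
    return pd.DataFrame({
        "level": ["among_ecotypes", "among_populations_within_ecotypes",
                  "among_individuals_within_populations"],
        "F": est, "ci_low": lo, "ci_high": hi,
    })


# ---------------------------------------------------------------------------
# Permutation comparison of per-population statistics between groups
# ---------------------------------------------------------------------------

def _pop_stat(stat: str, g: GenotypeMatrix):
    if stat == "F_IS":
        return wc_fis(g)
    hobs, hexp = [], []
    for l in range(g.n_loci):
        calls = g.calls[:, l, :]
        scored = calls[:, 0] != MISSING
        ni = scored.sum()
        if ni == 0:
            continue
        cc = calls[scored]
        _, counts = np.unique(cc, return_counts=True)
        p = counts / (2 * ni)
        hobs.append(np.mean(cc[:, 0] != cc[:, 1]))
        hexp.append((2 * ni / (2 * ni - 1)) * (1 - np.sum(p ** 2)))
    return float(np.mean(hobs)) if stat == "H_obs" else float(np.mean(hexp))


def permutation_compare(stat: str, pops: dict, assignment: dict,
                        n_perm: int = 5000, seed: int = 0):
    """Two-sided permutation test of a statistic between two groups.

    The permutation unit is the population (labels shuffled between groups,
    the FSTAT scheme).  For H_obs, H_exp and F_IS the group statistic is the
    mean of per-population values; for F_ST it is the multilocus theta among
    the group's populations.  Returns (observed difference, p-value).
    """
    if stat not in ("H_obs", "H_exp", "F_IS", "F_ST"):
        raise ValueError(f"unsupported statistic {stat!r}")
    names = list(pops)
    labels = [assignment[n] for n in names]
    groups = sorted(set(labels))
    if len(groups) != 2 or min(labels.count(g) for g in groups) < 2:
        raise ValueError("need two groups with >=2 populations each")

    if stat == "F_ST":
        per_pop = None

        def group_stat(sel_names):
            return wc_fst([pops[n] for n in sel_names])
    else:
        per_pop = {n: _pop_stat(stat, pops[n]) for n in names}

        def group_stat(sel_names):
            return float(np.mean([per_pop[n] for n in sel_names]))

    def diff(lbls):
        g0 = [n for n, l in zip(names, lbls) if l == groups[0]]
        g1 = [n for n, l in zip(names, lbls) if l == groups[1]]
        return group_stat(g0) - group_stat(g1)

    obs = diff(labels)
    rng = np.random.default_rng(seed)
    count = 0
    lab_arr = np.array(labels)
    for _ in range(n_perm):
        perm = rng.permutation(lab_arr)
        if abs(diff(perm)) >= abs(obs) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return obs, p


# ---------------------------------------------------------------------------
# Linkage screen
# ---------------------------------------------------------------------------

def _pair_association(g: GenotypeMatrix, l1: int, l2: int, n_perm: int, rng):
    """(max allele-count correlation, permutation G-test p) for a locus pair."""
    c1 = g.calls[:, l1, :]
    c2 = g.calls[:, l2, :]
    scored = (c1[:, 0] != MISSING) & (c2[:, 0] != MISSING)
    c1, c2 = c1[scored], c2[scored]
    if len(c1) < 4:
        return 0.0, 1.0
    al1 = np.unique(c1)
    al2 = np.unique(c2)
    # composite correlation: max |corr| between allele-count vectors
    rmax = 0.0
    for a in al1:
        x = (c1 == a).sum(axis=1).astype(float)
        if x.std() == 0:
            continue
        for b in al2:
            y = (c2 == b).sum(axis=1).astype(float)
            if y.std() == 0:
                continue
            rmax = max(rmax, abs(np.corrcoef(x, y)[0, 1]))

    def gstat(cc2):
        g1 = np.array([f"{min(a)}/{max(a)}" for a in c1])
        g2 = np.array([f"{min(a)}/{max(a)}" for a in cc2])
        tab = pd.crosstab(pd.Series(g1), pd.Series(g2)).values.astype(float)
        tot = tab.sum()
        exp = np.outer(tab.sum(1), tab.sum(0)) / tot
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(tab > 0, tab * np.log(tab / exp), 0.0)
        return 2 * terms.sum()

    obs = gstat(c2)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(c2))
        if gstat(c2[perm]) >= obs - 1e-12:
            count += 1
    return rmax, (count + 1) / (n_perm + 1)


def ld_screen(pops: dict, r_threshold: float = 0.5,
              pop_count_threshold: int = 2, n_perm: int = 200,
              alpha: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Screen locus pairs for linkage disequilibrium across populations.

    A pair is flagged for removal only when its association is significant
    AND the composite correlation exceeds ``r_threshold`` in more than
    ``pop_count_threshold`` populations.
    """
    rng = np.random.default_rng(seed)
    any_pop = pops[next(iter(pops))]
    L = any_pop.n_loci
    if L < 2:
        raise ValueError("need >= 2 loci")
    rows = []
    for l1, l2 in itertools.combinations(range(L), 2):
        n_hits = 0
        for g in pops.values():
            r, p = _pair_association(g, l1, l2, n_perm, rng)
            if p < alpha and r > r_threshold:
                n_hits += 1
        rows.append({"locus1": any_pop.loci[l1], "locus2": any_pop.loci[l2],
                     "n_populations_flagged": n_hits,
                     "remove": n_hits > pop_count_threshold})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Geography: distances, Mantel, isolation by distance, PCA
# ---------------------------------------------------------------------------

def geo_distances(coords: dict) -> pd.DataFrame:
    """Great-circle (haversine) distance matrix in km from lat/lon degrees."""
    names = [n for n, c in coords.items()
             if c is not None and not any(v is None or (isinstance(v, float) and math.isnan(v)) for v in c)]
    dropped = set(coords) - set(names)
    if dropped:
        warnings.warn(f"populations without coordinates excluded: {sorted(dropped)}")
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for i, j in itertools.combinations(range(len(names)), 2):
        la1, lo1 = map(math.radians, coords[names[i]])
        la2, lo2 = map(math.radians, coords[names[j]])
        dlat, dlon = la2 - la1, lo2 - lo1
        h = math.sin(dlat / 2) ** 2 + math.cos(la1) * math.cos(la2) * math.sin(dlon / 2) ** 2
        d = 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))
        mat.iloc[i, j] = mat.iloc[j, i] = d
    return mat


def _offdiag(m):
    m = np.asarray(m, dtype=float)
    iu = np.triu_indices_from(m, 1)
    return m[iu]


def mantel(dist_a, dist_b, n_perm: int = 5000, seed: int = 0,
           exhaustive_max: int = 6):
    """Mantel correlation between two distance matrices.

    One-sided (positive association) p by permuting rows/columns of the
    second matrix; exhaustive enumeration of all n! permutations when
    n <= ``exhaustive_max``.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and same shape")
    va, vb = _offdiag(a), _offdiag(b)
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    n = a.shape[0]
    if n <= exhaustive_max:
        perms = list(itertools.permutations(range(n)))
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(n_perm)]
    count = 0
    total = 0
    for p in perms:
        p = list(p)
        vb_p = _offdiag(b[np.ix_(p, p)])
        total += 1
        if np.corrcoef(va, vb_p)[0, 1] >= r_obs - 1e-12:
            count += 1
    if n <= exhaustive_max:
        p_val = count / total  # identity included in the enumeration
    else:
        p_val = (count + 1) / (total + 1)
    return r_obs, float(p_val)


def ibd_regression(fst_matrix, dist_matrix, n_perm: int = 5000, seed: int = 0):
    """Isolation-by-distance regression: F_ST/(1-F_ST) on ln(distance km).

    Ordinary least squares for slope/intercept; the p-value for the slope is
    a Mantel-style permutation p (pairs are not independent, so the
    parametric regression p is not used).
    Returns dict(slope, intercept, pvalue, n_pairs).
    """
    f = np.asarray(fst_matrix, dtype=float).copy()
    d = np.asarray(dist_matrix, dtype=float)
    vf, vd = _offdiag(f), _offdiag(d)
    keep = vd > 0
    if np.any(vf >= 1):
        warnings.warn("pairs with F_ST = 1 dropped")
        keep &= vf < 1
    vf, vd = vf[keep], vd[keep]
    y = vf / (1 - vf)
    x = np.log(vd)
    slope, intercept = np.polyfit(x, y, 1)

    n = f.shape[0]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        fp = f[np.ix_(p, p)]
        vfp = _offdiag(fp)[keep]
        yp = vfp / (1 - np.minimum(vfp, 1 - 1e-12))
        sl = np.polyfit(x, yp, 1)[0]
        if abs(sl) >= abs(slope) - 1e-15:
            count += 1
    return {"slope": float(slope), "intercept": float(intercept),
            "pvalue": (count + 1) / (n_perm + 1), "n_pairs": int(keep.sum())}


def pca_freqs(pops):
    """Centred, non-scaled PCA of individual allele counts.

    Rows are individuals, columns are allele indicators (0/1/2 copies);
    missing calls are imputed with the column mean before centring.
    Returns (coordinates DataFrame, inertia fractions).
    """
    if isinstance(pops, dict):
        mats = list(pops.values())
    elif isinstance(pops, GenotypeMatrix):
        mats = [pops]
    else:
        mats = list(pops)
    loci = mats[0].loci
    alleles_per_locus = []
    for l in range(len(loci)):
        al = sorted({int(a) for g in mats
                     for a in g.calls[:, l, :].ravel() if a != MISSING})
        alleles_per_locus.append(al)
    cols = [(l, a) for l, als in enumerate(alleles_per_locus) for a in als]
    rows, labels, pop_labels = [], [], []
    for g in mats:
        for r in range(g.n_individuals):
            vec = []
            for l, a in cols:
                call = g.calls[r, l, :]
                vec.append(np.nan if call[0] == MISSING
                           else float((call == a).sum()))
            rows.append(vec)
            labels.append(g.individuals[r])
            pop_labels.append(g.meta.population)
    X = np.array(rows)
    col_mean = np.nanmean(X, axis=0)
    keep = ~np.isnan(col_mean)
    X = X[:, keep]
    col_mean = col_mean[keep]
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    Xc = X - X.mean(axis=0)
    u, sv, _ = np.linalg.svd(Xc, full_matrices=False)
    inertia = sv ** 2 / (sv ** 2).sum()
    coords = u * sv
    ncomp = min(10, coords.shape[1])
    df = pd.DataFrame(coords[:, :ncomp],
                      columns=[f"PC{i+1}" for i in range(ncomp)])
    df.insert(0, "individual", labels)
    df.insert(1, "population", pop_labels)
    return df, inertia


# ---------------------------------------------------------------------------
# Closed-form mating-system arithmetic
# ---------------------------------------------------------------------------

def ne_reduction_from_selfing(s1: float, s2: float) -> float:
    """Relative reduction of effective size moving from selfing s1 to s2.

    Under partial selfing Ne is scaled by 1/(1+F) with F = s/(2-s), so the
    relative reduction is 1 - (1+F(s1)) / (1+F(s2)); positive when s2 > s1.
    """
    if not (0 <= s1 <= 1 and 0 <= s2 <= 1):
        raise ValueError("selfing rates must be in [0, 1]")
    return 1 - (1 + equilibrium_fis(s1)) / (1 + equilibrium_fis(s2))


def required_inbreeding_depression(s_primary: float, s_adult: float) -> float:
    """Survival inbreeding depression delta reconciling primary and adult selfing.

    Viability selection against selfed offspring deflates the selfing rate
    observed among surviving adults: s_adult = s(1-delta) / (1 - s*delta).
    Solving for delta gives (s_primary - s_adult) / (s_primary (1 - s_adult)).
    """
    if not 0 < s_adult <= s_primary <= 1:
        raise ValueError("need 0 < s_adult <= s_primary <= 1")
    delta = (s_primary - s_adult) / (s_primary * (1 - s_adult))
    # forward check
    back = s_primary * (1 - delta) / (1 - s_primary * delta)
    assert abs(back - s_adult) < 1e-12
    return delta
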