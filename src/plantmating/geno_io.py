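"""Data model and I/O for diploid co-dominant multilocus genotype data.

The central container is :class:`GenotypeMatrix`: individuals x loci unordered
allele pairs (positive-integer allele labels) with a missing mask and
population-level metadata (population ID, ecotype, season, GPS coordinates,
genotyping platform).  Family-structured progeny data and two-season temporal
samples are thin wrappers around it.

Supported formats: Genepop (2- and 3-digit allele encodings) and a CSV dialect
with one ``a/b`` column per locus.  A half-missing call (one allele coded 0)
is treated as fully missing — Genepop cannot represent half-calls.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MISSING = 0  # sentinel allele label inside `calls`


class GenepopParseError(ValueError):
    pass


@dataclass
class PopMeta:
    """Population-level metadata attached to a GenotypeMatrix."""

    population: str = ""
    ecotype: Optional[str] = None
    year: Optional[str] = None
    lat: Optional[float] = None
    lon: Optional[float] = None
    platform: Optional[str] = None


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid allele pairs with missing mask.

    Parameters
    ----------
    individuals : list of str
        Individual identifiers, one per row.
    loci : list of str
        Locus names, one per column.
    calls : ndarray of int, shape (n, L, 2)
        Allele labels (positive integers); ``0`` marks a missing allele.
        A call with either allele 0 is normalised to fully missing.
    meta : PopMeta
    """

    individuals: list
    loci: list
    calls: np.ndarray
    meta: PopMeta = field(default_factory=PopMeta)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        if np.any(self.calls < 0):
            raise ValueError("allele labels must be non-negative integers")
        # half-missing -> fully missing
        half = np.any(self.calls == MISSING, axis=2)
        self.calls[half] = MISSING

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L); True where the call is missing."""
        return np.all(self.calls == MISSING, axis=2)

    def subset_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            [self.individuals[i] for i in idx], list(self.loci),
            self.calls[idx].copy(), replace(self.meta),
        )

    def subset_loci(self, names: Sequence[str]) -> "GenotypeMatrix":
        pos = [self.loci.index(n) for n in names]
        return GenotypeMatrix(
            list(self.individuals), list(names),
            self.calls[:, pos].copy(), replace(self.meta),
        )


def pool(samples: Sequence[GenotypeMatrix], force: bool = False) -> GenotypeMatrix:
    """Concatenate samples of one population (e.g. two seasons) row-wise.

    Refuses to pool across different genotyping platforms unless ``force``:
    allele bins from different analyzers are not comparable, so
    frequency-based analyses must not mix them.
    """
    if not samples:
        raise ValueError("nothing to pool")
    loci = samples[0].loci
    for s in samples[1:]:
        if s.loci != loci:
            raise ValueError("cannot pool samples with different locus lists")
    platforms = {s.meta.platform for s in samples}
    if len(platforms) > 1 and not force:
        raise ValueError(
            f"refusing to pool across genotyping platforms {sorted(map(str, platforms))}; "
            "pass force=True to override"
        )
    calls = np.concatenate([s.calls for s in samples], axis=0)
    individuals = [i for s in samples for i in s.individuals]
    return GenotypeMatrix(individuals, list(loci), calls, replace(samples[0].meta))


@dataclass
class Family:
    """One maternal family: optional maternal genotype plus its progeny."""

    progeny: GenotypeMatrix
    mother: Optional[np.ndarray] = None  # (L, 2) allele pairs, 0 = missing

    def __post_init__(self):
        if self.progeny.n_individuals < 1:
            raise ValueError("family needs at least one progeny")
        if self.mother is not None:
            self.mother = np.asarray(self.mother, dtype=np.int64)
            if self.mother.shape != (self.progeny.n_loci, 2):
                raise ValueError("maternal genotype must cover the family's loci")


@dataclass
class ProgenyArraySet:
    """Families of progeny genotypes sharing one locus list."""

    families: list
    meta: PopMeta = field(default_factory=PopMeta)

    def __post_init__(self):
        if not self.families:
            raise ValueError("empty progeny array set")
        loci = self.families[0].progeny.loci
        for f in self.families[1:]:
            if f.progeny.loci != loci:
                raise ValueError("all families must share the same locus list")

    @property
    def loci(self):
        return self.families[0].progeny.loci

    @property
    def n_families(self):
        return len(self.families)


@dataclass
class TemporalPair:
    """Two samples of one population taken g generations apart."""

    sample0: GenotypeMatrix
    sample1: GenotypeMatrix
    generations_elapsed: int = 1

    def __post_init__(self):
        if self.sample0.loci != self.sample1.loci:
            raise ValueError("temporal samples must share the locus list")
        if self.generations_elapsed < 1:
            raise ValueError("generations_elapsed must be >= 1")


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

def _detect_width(tokens):
    widths = {len(t) for t in tokens}
    if widths <= {4}:
        return 2
    if widths <= {6}:
        return 3
    raise GenepopParseError(
        f"mixed or unsupported allele-code widths {sorted(widths)} in one file"
    )


def read_genepop(text: str) -> dict:
    """Parse Genepop-format content into per-population GenotypeMatrix objects.

    Returns a dict keyed by population name (the identifier of each
    population's last individual, the Genepop convention).  ``00``/``000``
    codes a missing allele; a call with either allele missing is treated as
    fully missing.
    """
    lines = [ln.rstrip("\r\n") for ln in io.StringIO(text)]
    lines = [ln for ln in lines if ln.strip() != ""]
    if len(lines) < 3:
        raise GenepopParseError("file too short to be Genepop")
    # title line, then locus names (one per line or comma-separated)
    body = lines[1:]
    loci: list = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        loci.extend([t.strip() for t in body[i].split(",") if t.strip()])
        i += 1
    if i == len(body):
        raise GenepopParseError("no 'Pop' line found")

    pops = {}
    current: list = []
    all_tokens: list = []
    pop_rows = []  # list of (name_list, row_tokens_list)

    def flush():
        if current:
            pop_rows.append(list(current))
            current.clear()

    for lineno, ln in enumerate(body[i:], start=i + 2):
        if ln.strip().lower() == "pop":
            flush()
            continue
        if "," not in ln:
            raise GenepopParseError(f"line {lineno}: expected 'name , genotypes'")
        name, geno = ln.split(",", 1)
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise GenepopParseError(
                f"line {lineno}: {len(tokens)} genotype fields for {len(loci)} loci"
            )
        if not all(re.fullmatch(r"\d+", t) for t in tokens):
            raise GenepopParseError(f"line {lineno}: non-numeric genotype field")
        current.append((name.strip(), tokens))
        all_tokens.extend(tokens)
    flush()

    width = _detect_width(all_tokens)
    for rows in pop_rows:
        n = len(rows)
        calls = np.zeros((n, len(loci), 2), dtype=np.int64)
        names = []
        for r, (name, tokens) in enumerate(rows):
            names.append(name)
            for c, t in enumerate(tokens):
                calls[r, c, 0] = int(t[:width])
                calls[r, c, 1] = int(t[width:])
        pop_name = names[-1]
        if pop_name in pops:
            pop_name = f"{pop_name}_{len(pops)}"
        pops[pop_name] = GenotypeMatrix(
            names, list(loci), calls, PopMeta(population=pop_name)
        )
    return pops


def write_genepop(pops, title: str = "plantmating export", width: int = 3) -> str:
    """Serialise populations (dict or list of GenotypeMatrix) to Genepop text."""
    if isinstance(pops, dict):
        pops = list(pops.values())
    loci = pops[0].loci
    for p in pops[1:]:
        if p.loci != loci:
            raise ValueError("all populations must share the locus list")
    fmt = f"%0{width}d%0{width}d"
    out = [title]
    out.extend(loci)
    for p in pops:
        out.append("Pop")
        for r, name in enumerate(p.individuals):
            fields = [fmt % (p.calls[r, c, 0], p.calls[r, c, 1])
                      for c in range(len(loci))]
            out.append(f"{name} , " + " ".join(fields))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

_META_COLS = ["individual", "population", "ecotype", "year"]


def _format_call(pair) -> str:
    if pair[0] == MISSING:
        return "."
    return f"{pair[0]}/{pair[1]}"


def _parse_call(s: str):
    s = str(s).strip()
    if s in (".", "", "nan", "./."):
        return (MISSING, MISSING)
    a, b = s.split("/")
    return (int(a), int(b))


def to_csv(pops, path_or_buf=None):
    """Write populations as a tidy CSV: metadata columns then one a/b column per locus."""
    if isinstance(pops, dict):
        pops = list(pops.values())
    loci = pops[0].loci
    rows = []
    for p in pops:
        for r, name in enumerate(p.individuals):
            row = {
                "individual": name,
                "population": p.meta.population,
                "ecotype": p.meta.ecotype,
                "year": p.meta.year,
            }
            for c, loc in enumerate(loci):
                row[loc] = _format_call(p.calls[r, c])
            rows.append(row)
    df = pd.DataFrame(rows)
    if path_or_buf is None:
        return df.to_csv(index=False)
    df.to_csv(path_or_buf, index=False)


def from_csv(path_or_buf) -> dict:
    """Read the tidy CSV genotype dialect back into per-population matrices."""
    df = pd.read_csv(path_or_buf, dtype=str)
    loci = [c for c in df.columns if c not in _META_COLS]
    pops = {}
    for pop_name, sub in df.groupby("population", sort=False):
        n = len(sub)
        calls = np.zeros((n, len(loci), 2), dtype=np.int64)
        for r, (_, row) in enumerate(sub.iterrows()):
            for c, loc in enumerate(loci):
                calls[r, c] = _parse_call(row[loc])
        eco = sub["ecotype"].iloc[0] if "ecotype" in sub else None
        year = sub["year"].iloc[0] if "year" in sub else None
        pops[pop_name] = GenotypeMatrix(
            list(sub["individual"]), loci, calls,
            PopMeta(population=str(pop_name),
                    ecotype=None if pd.isna(eco) else eco,
                    year=None if pd.isna(year) else year),
        )
    return pops


def progeny_to_csv(arrays: ProgenyArraySet, path_or_buf=None):
    """Write a ProgenyArraySet as CSV with family and role columns."""
    loci = arrays.loci
    rows = []
    for fi, fam in enumerate(arrays.families):
        fam_id = f"fam{fi}"
        if fam.mother is not None:
            row = {"individual": f"{fam_id}_mother", "population": arrays.meta.population,
                   "family": fam_id, "role": "mother"}
            for c, loc in enumerate(loci):
                row[loc] = _format_call(fam.mother[c])
            rows.append(row)
        for r, name in enumerate(fam.progeny.individuals):
            row = {"individual": name, "population": arrays.meta.population,
                   "family": fam_id, "role": "progeny"}
            for c, loc in enumerate(loci):
                row[loc] = _format_call(fam.progeny.calls[r, c])
            rows.append(row)
    df = pd.DataFrame(rows)
    if path_or_buf is None:
        return df.to_csv(index=False)
    df.to_csv(path_or_buf, index=False)


def progeny_from_csv(path_or_buf) -> ProgenyArraySet:
    df = pd.read_csv(path_or_buf, dtype=str)
    loci = [c for c in df.columns
            if c not in _META_COLS + ["family", "role"]]
    families = []
    pop = df["population"].iloc[0] if "population" in df else ""
    for _, sub in df.groupby("family", sort=False):
        mother = None
        mrows = sub[sub["role"] == "mother"]
        if len(mrows):
            mother = np.array([_parse_call(mrows.iloc[0][loc]) for loc in loci])
        prows = sub[sub["role"] == "progeny"]
        calls = np.zeros((len(prows), len(loci), 2), dtype=np.int64)
        for r, (_, row) in enumerate(prows.iterrows()):
            for c, loc in enumerate(loci):
                calls[r, c] = _parse_call(row[loc])
        gm = GenotypeMatrix(list(prows["individual"]), loci, calls,
                            PopMeta(population=str(pop)))
        families.append(Family(progeny=gm, mother=mother))
    return ProgenyArraySet(families, PopMeta(population=str(pop)))


# ---------------------------------------------------------------------------
# Summaries consumed by the estimators
# ---------------------------------------------------------------------------

def allele_freqs(g: GenotypeMatrix):
    """Per-locus allele frequencies and gene-copy counts, missing excluded.

    Returns
    -------
    freqs : dict locus -> {allele: frequency}
    counts : dict locus -> int (non-missing gene copies)

    All-missing loci are excluded with a warning.
    """
    freqs, counts = {}, {}
    for c, loc in enumerate(g.loci):
        col = g.calls[:, c, :].ravel()
        col = col[col != MISSING]
        if col.size == 0:
            warnings.warn(f"locus {loc} has no non-missing calls; excluded")
            continue
        alleles, n = np.unique(col, return_counts=True)
        freqs[loc] = dict(zip(alleles.tolist(), (n / col.size).tolist()))
        counts[loc] = int(col.size)
    return freqs, counts


def het_patterns(g: GenotypeMatrix) -> np.ma.MaskedArray:
    """Per-individual 0/1 heterozygosity with missing propagated as masked."""
    het = (g.calls[:, :, 0] != g.calls[:, :, 1]).astype(np.int8)
    return np.ma.MaskedArray(het, mask=g.missing_mask)
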