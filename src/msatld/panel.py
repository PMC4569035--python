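"""Genotype panels, linkage maps, cohorts and pedigrees.

The central container is :class:`GenotypeMatrix`: an individuals x loci array
of unphased diploid multi-allelic genotypes with missing data, plus optional
per-individual yearly cross-section membership and population tags.  Genotypes
are unordered allele pairs; a missing genotype means both alleles are missing
(GenePop cannot encode half-calls).

File formats are the ones long-term microsatellite studies actually use:
GenePop 4.x for genotypes, small TSVs for the linkage map (marker, chromosome,
position in cM), cohorts (individual, year) and pedigree (individual, sire,
dam, with NA for unknown parents).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "Locus",
    "LinkageMap",
    "GenotypeMatrix",
    "LocusStats",
    "Pedigree",
    "GenePopFormatError",
    "read_genepop",
    "write_genepop",
    "read_map",
    "read_cohorts",
    "read_pedigree",
    "filter_panel",
    "allele_frequencies",
]


class GenePopFormatError(ValueError):
    """Raised for malformed GenePop input, with a line number."""


@dataclass(frozen=True)
class Locus:
    """A mapped autosomal marker: id, chromosome label, position in cM."""

    id: str
    chromosome: int
    position: float

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"locus {self.id}: negative map position {self.position}")


class LinkageMap:
    """Ordered collection of mapped loci with cM distances.

    Distance is defined only within a chromosome (|pos_a - pos_b|); pairs on
    different chromosomes are nonsyntenic and have no distance.
    """

    def __init__(self, loci: Iterable[Locus]):
        self.loci: list[Locus] = list(loci)
        self._by_id: dict[str, Locus] = {}
        for loc in self.loci:
            if loc.id in self._by_id:
                raise ValueError(f"duplicate marker id in map: {loc.id}")
            self._by_id[loc.id] = loc

    def __len__(self) -> int:
        return len(self.loci)

    def __contains__(self, marker: str) -> bool:
        return marker in self._by_id

    def __getitem__(self, marker: str) -> Locus:
        return self._by_id[marker]

    def chromosomes(self) -> list[int]:
        return sorted({loc.chromosome for loc in self.loci})

    def distance(self, a: str, b: str) -> float | None:
        """Intermarker distance in cM, or None if nonsyntenic."""
        la, lb = self._by_id[a], self._by_id[b]
        if la.chromosome != lb.chromosome:
            return None
        return abs(la.position - lb.position)

    def synteny_class(self, a: str, b: str, threshold: float = 50.0) -> str:
        """'syntenic_lt50', 'syntenic_ge50' or 'nonsyntenic'."""
        d = self.distance(a, b)
        if d is None:
            return "nonsyntenic"
        return "syntenic_lt50" if d < threshold else "syntenic_ge50"


@dataclass
class LocusStats:
    """Allele frequencies and expected heterozygosity at one locus."""

    locus: str
    freqs: dict[int, float]
    n_typed: int
    missing_fraction: float

    @property
    def heterozygosity(self) -> float:
        """Expected heterozygosity Hz = 1 - sum(p_i^2)."""
        return 1.0 - sum(p * p for p in self.freqs.values())


class GenotypeMatrix:
    """Unphased diploid genotypes for individuals x loci.

    Internally an (n_ind, n_loc, 2) int array; ``MISSING`` (=-1) in both
    slots marks an untyped genotype.  Allele order within a genotype carries
    no meaning.
    """

    def __init__(
        self,
        individuals: Sequence[str],
        loci: Sequence[str],
        genotypes: np.ndarray,
        populations: Sequence[str] | None = None,
        years: Mapping[str, set[int]] | None = None,
    ):
        self.individuals = list(individuals)
        self.loci = list(loci)
        genotypes = np.asarray(genotypes, dtype=np.int32)
        if genotypes.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError(
                f"genotype array shape {genotypes.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        self.genotypes = genotypes
        self.populations = (
            list(populations) if populations is not None else ["pop1"] * len(self.individuals)
        )
        self.years: dict[str, set[int]] = {k: set(v) for k, v in (years or {}).items()}
        self._ind_index = {ind: i for i, ind in enumerate(self.individuals)}
        self._loc_index = {loc: j for j, loc in enumerate(self.loci)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def genotype(self, ind: str, locus: str) -> tuple[int, int] | None:
        g = self.genotypes[self._ind_index[ind], self._loc_index[locus]]
        if g[0] == MISSING:
            return None
        return int(g[0]), int(g[1])

    def locus_index(self, locus: str) -> int:
        return self._loc_index[locus]

    def year_of(self, ind: str) -> set[int]:
        return self.years.get(ind, set())

    def individuals_in_year(self, year: int) -> list[str]:
        return [ind for ind in self.individuals if year in self.years.get(ind, ())]

    def missing_by_locus(self) -> np.ndarray:
        """Fraction of individuals untyped at each locus."""
        return (self.genotypes[:, :, 0] == MISSING).mean(axis=0)

    def missing_by_individual(self) -> np.ndarray:
        """Fraction of loci untyped for each individual."""
        return (self.genotypes[:, :, 0] == MISSING).mean(axis=1)

    # -- subsetting ------------------------------------------------------
    def subset(
        self,
        individuals: Sequence[str] | None = None,
        loci: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        inds = self.individuals if individuals is None else list(individuals)
        locs = self.loci if loci is None else list(loci)
        ii = [self._ind_index[i] for i in inds]
        jj = [self._loc_index[l] for l in locs]
        return GenotypeMatrix(
            inds,
            locs,
            self.genotypes[np.ix_(ii, jj)],
            [self.populations[i] for i in ii],
            {i: self.years[i] for i in inds if i in self.years},
        )

    def subset_indices(self, ind_idx: np.ndarray) -> "GenotypeMatrix":
        """Row subset by integer positions (fast path for resampling)."""
        inds = [self.individuals[i] for i in ind_idx]
        return GenotypeMatrix(
            inds,
            self.loci,
            self.genotypes[ind_idx],
            [self.populations[i] for i in ind_idx],
            {i: self.years[i] for i in inds if i in self.years},
        )


@dataclass
class Pedigree:
    """Pedigree records (individual, sire, dam); None for unknown parents."""

    records: list[tuple[str, str | None, str | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.parents: dict[str, tuple[str | None, str | None]] = {
            ind: (sire, dam) for ind, sire, dam in self.records
        }

    def individuals(self) -> list[str]:
        return [r[0] for r in self.records]

    def topological_order(self) -> list[str]:
        """Parents-before-offspring order; raises on a cycle, naming it."""
        known = self.parents
        order: list[str] = []
        state: dict[str, int] = {}  # 0 in-progress, 1 done

        for root in known:
            if state.get(root) == 1:
                continue
            stack = [(root, iter([p for p in known[root] if p in known]))]
            state[root] = 0
            while stack:
                node, it = stack[-1]
                advanced = False
                for parent in it:
                    if state.get(parent) == 0:
                        cycle = [n for n, _ in stack] + [parent]
                        raise ValueError(f"pedigree cycle detected: {' -> '.join(cycle)}")
                    if state.get(parent) != 1:
                        state[parent] = 0
                        stack.append((parent, iter([p for p in known[parent] if p in known])))
                        advanced = True
                        break
                if not advanced:
                    stack.pop()
                    state[node] = 1
                    order.append(node)
        return order


# ---------------------------------------------------------------------------
# GenePop I/O
# ---------------------------------------------------------------------------

def _parse_genotype(tok: str, lineno: int) -> tuple[int, int, int]:
    """Return (allele1, allele2, digits) from a 4- or 6-char GenePop token."""
    if len(tok) == 4:
        w = 2
    elif len(tok) == 6:
        w = 3
    else:
        raise GenePopFormatError(
            f"line {lineno}: genotype token '{tok}' is neither 4 nor 6 digits"
        )
    if not tok.isdigit():
        raise GenePopFormatError(f"line {lineno}: non-numeric genotype token '{tok}'")
    a, b = int(tok[:w]), int(tok[w:])
    if a == 0 or b == 0:
        # GenePop convention: all-zero code is missing; partial zero is
        # treated as missing too since half-calls are not representable.
        return MISSING, MISSING, w
    return a, b, w


def read_genepop(path: str | Path) -> GenotypeMatrix:
    """Read a GenePop 4.x file (2- or 3-digit allele codes).

    POP blocks become population tags ``pop1``, ``pop2``, ...; "0000" /
    "000000" genotypes become missing cells.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenePopFormatError("empty GenePop file")

    # header = title line; then locus names until first POP
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        line = lines[i].strip()
        if not line:
            raise GenePopFormatError(f"line {i + 1}: blank line in locus-name section")
        # locus names may be comma-separated on one line
        loci.extend(tok.strip() for tok in line.split(",") if tok.strip())
        i += 1
    if i == len(lines):
        raise GenePopFormatError("no POP keyword found")
    if not loci:
        raise GenePopFormatError("no locus names before first POP")

    individuals: list[str] = []
    genotypes: list[list[tuple[int, int]]] = []
    pops: list[str] = []
    pop_n = 0
    width: int | None = None

    for lineno0 in range(i, len(lines)):
        raw = lines[lineno0]
        line = raw.strip()
        lineno = lineno0 + 1
        if not line:
            continue
        if line.upper() == "POP":
            pop_n += 1
            continue
        if "," not in line:
            raise GenePopFormatError(f"line {lineno}: expected 'id , genotypes' line")
        ind_id, _, geno_part = line.partition(",")
        ind_id = ind_id.strip()
        toks = geno_part.split()
        if len(toks) != len(loci):
            raise GenePopFormatError(
                f"line {lineno}: {len(toks)} genotypes for {len(loci)} loci"
            )
        row: list[tuple[int, int]] = []
        for tok in toks:
            a, b, w = _parse_genotype(tok, lineno)
            if width is None:
                width = w
            elif w != width:
                raise GenePopFormatError(
                    f"line {lineno}: inconsistent allele-code width "
                    f"({w} vs {width} digits)"
                )
            row.append((a, b))
        individuals.append(ind_id)
        genotypes.append(row)
        pops.append(f"pop{pop_n}")

    if not individuals:
        raise GenePopFormatError("no individuals found")
    arr = np.array(genotypes, dtype=np.int32)
    return GenotypeMatrix(individuals, loci, arr, populations=pops)


def write_genepop(gm: GenotypeMatrix, path: str | Path, title: str = "msatld export") -> None:
    """Write a GenotypeMatrix in GenePop format (allele-code width inferred)."""
    max_allele = int(gm.genotypes.max(initial=0))
    w = 3 if max_allele > 99 else 2
    zero = "0" * w

    def fmt(a: int) -> str:
        return zero if a == MISSING else f"{a:0{w}d}"

    out: list[str] = [title]
    out.extend(gm.loci)
    current_pop = None
    for i, ind in enumerate(gm.individuals):
        pop = gm.populations[i]
        if pop != current_pop:
            out.append("POP")
            current_pop = pop
        toks = [
            fmt(int(gm.genotypes[i, j, 0])) + fmt(int(gm.genotypes[i, j, 1]))
            for j in range(gm.n_loci)
        ]
        out.append(f"{ind} , " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# TSV readers
# ---------------------------------------------------------------------------

def read_map(path: str | Path) -> LinkageMap:
    """Read a linkage map TSV with columns marker, chromosome, position_cM."""
    df = pd.read_csv(path, sep="\t")
    required = {"marker", "chromosome", "position_cM"}
    if not required.issubset(df.columns):
        raise ValueError(f"map file missing columns: {required - set(df.columns)}")
    if df["marker"].duplicated().any():
        dups = df.loc[df["marker"].duplicated(), "marker"].tolist()
        raise ValueError(f"duplicate marker ids in map: {dups}")
    if (df["position_cM"] < 0).any():
        bad = df.loc[df["position_cM"] < 0, "marker"].tolist()
        raise ValueError(f"negative map positions for: {bad}")
    return LinkageMap(
        Locus(str(r.marker), int(r.chromosome), float(r.position_cM))
        for r in df.itertuples()
    )


def write_map(lmap: LinkageMap, path: str | Path) -> None:
    pd.DataFrame(
        {
            "marker": [l.id for l in lmap.loci],
            "chromosome": [l.chromosome for l in lmap.loci],
            "position_cM": [l.position for l in lmap.loci],
        }
    ).to_csv(path, sep="\t", index=False)


def read_cohorts(path: str | Path) -> dict[str, set[int]]:
    """Read a cohort TSV (individual, year) into individual -> {years}."""
    df = pd.read_csv(path, sep="\t")
    if not {"individual", "year"}.issubset(df.columns):
        raise ValueError("cohort file needs columns: individual, year")
    years: dict[str, set[int]] = {}
    for r in df.itertuples():
        years.setdefault(str(r.individual), set()).add(int(r.year))
    return years


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a pedigree TSV (individual, sire, dam); 'NA' = unknown parent."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"individual", "sire", "dam"}.issubset(df.columns):
        raise ValueError("pedigree file needs columns: individual, sire, dam")

    def norm(x: str) -> str | None:
        return None if x in ("", "NA", "na", "0") else x

    return Pedigree(
        [(r.individual, norm(r.sire), norm(r.dam)) for r in df.itertuples()]
    )


def write_cohorts(years: Mapping[str, set[int]], path: str | Path) -> None:
    rows = [(ind, y) for ind, ys in years.items() for y in sorted(ys)]
    pd.DataFrame(rows, columns=["individual", "year"]).to_csv(path, sep="\t", index=False)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    rows = [
        (ind, sire if sire is not None else "NA", dam if dam is not None else "NA")
        for ind, sire, dam in ped.records
    ]
    pd.DataFrame(rows, columns=["individual", "sire", "dam"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Filters and per-locus statistics
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    dropped_loci: list[str]
    dropped_individuals: list[str]


def filter_panel(
    gm: GenotypeMatrix,
    max_locus_missing: float = 0.15,
    max_individual_missing: float = 0.15,
    return_report: bool = False,
):
    """Drop loci, then individuals, exceeding the missingness thresholds.

    Loci are filtered on the pre-filter individual set; individuals are then
    filtered on the retained loci (one pass each).  The default 15% threshold
    on both axes is the usual inclusion rule for mapped microsatellite panels.
    """
    if not (0 <= max_locus_missing <= 1 and 0 <= max_individual_missing <= 1):
        raise ValueError("missingness thresholds must lie in [0, 1]")

    loc_miss = gm.missing_by_locus()
    keep_loc = [l for l, m in zip(gm.loci, loc_miss) if m <= max_locus_missing]
    dropped_loc = [l for l in gm.loci if l not in set(keep_loc)]
    if not keep_loc:
        raise ValueError("all loci dropped by missingness filter")

    trimmed = gm.subset(loci=keep_loc)
    ind_miss = trimmed.missing_by_individual()
    keep_ind = [i for i, m in zip(trimmed.individuals, ind_miss) if m <= max_individual_missing]
    dropped_ind = [i for i in trimmed.individuals if i not in set(keep_ind)]
    if not keep_ind:
        raise ValueError("all individuals dropped by missingness filter")

    out = trimmed.subset(individuals=keep_ind)
    if return_report:
        return out, FilterReport(dropped_loc, dropped_ind)
    return out


def allele_frequencies(
    gm: GenotypeMatrix,
    locus: str,
    individuals: Sequence[str] | None = None,
) -> LocusStats:
    """Gene-count allele frequencies at one locus over non-missing genotypes."""
    j = gm.locus_index(locus)
    if individuals is None:
        col = gm.genotypes[:, j, :]
        n_total = gm.n_individuals
    else:
        ii = [gm._ind_index[i] for i in individuals]
        col = gm.genotypes[ii, j, :]
        n_total = len(ii)
    typed = col[col[:, 0] != MISSING]
    if typed.size == 0:
        raise ValueError(f"no non-missing genotypes at locus {locus}")
    alleles, counts = np.unique(typed.ravel(), return_counts=True)
    total = counts.sum()
    freqs = {int(a): c / total for a, c in zip(alleles, counts)}
    return LocusStats(
        locus=locus,
        freqs=freqs,
        n_typed=typed.shape[0],
        missing_fraction=1.0 - typed.shape[0] / n_total,
    )
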