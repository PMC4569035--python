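"""Marker- and pedigree-based relatedness, and yearly correlation tests.

The marker-based estimator is the Queller-Goodnight moment estimator,
symmetrized as a ratio of sums: per locus, with focal individual x carrying
alleles (a, b) and partner y carrying (c, d),

    num_x = 0.5 (I_ac + I_ad + I_bc + I_bd) - p_a - p_b
    den_x = 1 + I_ab - p_a - p_b

and the multilocus estimate is (sum num_x + sum num_y) / (sum den_x +
sum den_y) over loci typed in both individuals, with reference allele
frequencies taken from the full panel (never from a subsample).

Pedigree relatedness is the additive relationship A (twice the kinship),
built by the tabular method:  A_xy = 0.5 (A_{x,sire(y)} + A_{x,dam(y)}) and
A_xx = 1 + 0.5 A_{sire(x),dam(x)}, with unknown parents contributing 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .panel import MISSING, GenotypeMatrix, LocusStats, Pedigree

__all__ = [
    "RelatednessEstimate",
    "PedigreeRelatedness",
    "CorrelationTest",
    "qg_relatedness",
    "QGMatrix",
    "qg_matrix",
    "pedigree_relatedness",
    "pearson_test",
]


@dataclass
class RelatednessEstimate:
    x: str
    y: str
    r: float
    n_loci: int


@dataclass
class CorrelationTest:
    r: float
    t: float
    df: int
    p: float


def qg_relatedness(
    gm: GenotypeMatrix,
    freqs: dict[str, LocusStats],
    x: str,
    y: str,
) -> RelatednessEstimate:
    """Queller-Goodnight relatedness for one pair (explicit per-locus loop).

    ``freqs`` must hold full-panel reference frequencies for every locus
    used.  Loci missing in either individual are skipped.  Returns NaN (with
    the locus count) when the summed denominator is zero; raises if the pair
    shares no typed loci.
    """
    num = 0.0
    den = 0.0
    n_loci = 0
    for locus in gm.loci:
        gx = gm.genotype(x, locus)
        gy = gm.genotype(y, locus)
        if gx is None or gy is None:
            continue
        p = freqs[locus].freqs
        a, b = gx
        c, d = gy
        s = 0.5 * ((a == c) + (a == d) + (b == c) + (b == d))
        num += (s - p[a] - p[b]) + (s - p[c] - p[d])
        den += (1 + (a == b) - p[a] - p[b]) + (1 + (c == d) - p[c] - p[d])
        n_loci += 1
    if n_loci == 0:
        raise ValueError(f"no shared typed loci for pair ({x}, {y})")
    r = num / den if den != 0 else float("nan")
    return RelatednessEstimate(x=x, y=y, r=r, n_loci=n_loci)


class QGMatrix:
    """All-pairs Queller-Goodnight relatedness over a panel.

    Computed once from full-panel reference frequencies; subsample means are
    then cheap lookups.  Entries are NaN where undefined (zero denominator
    or no shared typed loci); the diagonal is not meaningful.
    """

    def __init__(self, individuals: list[str], r: np.ndarray, n_loci: np.ndarray):
        self.individuals = individuals
        self.r = r
        self.n_loci = n_loci
        self._index = {ind: i for i, ind in enumerate(individuals)}

    def pair(self, x: str, y: str) -> float:
        return float(self.r[self._index[x], self._index[y]])

    def mean_over(self, individuals: list[str] | np.ndarray) -> float:
        """Mean pairwise r over k(k-1)/2 pairs, NaN pairs excluded."""
        if isinstance(individuals, np.ndarray) and individuals.dtype.kind in "iu":
            idx = individuals
        else:
            idx = np.array([self._index[i] for i in individuals])
        sub = self.r[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        vals = sub[iu]
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if vals.size else float("nan")


def qg_matrix(gm: GenotypeMatrix, freqs: dict[str, LocusStats]) -> QGMatrix:
    """Vectorized all-pairs Queller-Goodnight estimate.

    Uses the identity that the summed cross-locus allele matches between two
    genotypes equal the inner product of their per-allele count vectors, so
    every pairwise sum reduces to a matrix product.  Agrees with
    :func:`qg_relatedness` pair by pair (tested).
    """
    n, n_loc = gm.n_individuals, gm.n_loci
    g = gm.genotypes  # (n, L, 2)
    typed = g[:, :, 0] != MISSING  # M

    # per-individual, per-locus: sum of reference freqs of own alleles, and
    # homozygosity indicator; zeroed where untyped
    pa = np.zeros((n, n_loc))
    hom = (g[:, :, 0] == g[:, :, 1]) & typed
    col_offsets = np.zeros(n_loc + 1, dtype=int)
    allele_maps: list[dict[int, int]] = []
    for j, locus in enumerate(gm.loci):
        p = freqs[locus].freqs
        amap = {a: i for i, a in enumerate(sorted(p))}
        allele_maps.append(amap)
        col_offsets[j + 1] = col_offsets[j] + len(amap)
        pj = np.zeros(n)
        for ii in range(n):
            if typed[ii, j]:
                a, b = int(g[ii, j, 0]), int(g[ii, j, 1])
                pj[ii] = p.get(a, 0.0) + p.get(b, 0.0)
        pa[:, j] = pj

    # allele-count design matrix C: (n, total alleles), entries 0/1/2
    C = np.zeros((n, col_offsets[-1]), dtype=np.float32)
    for j in range(n_loc):
        amap = allele_maps[j]
        off = col_offsets[j]
        for ii in range(n):
            if typed[ii, j]:
                for a in (int(g[ii, j, 0]), int(g[ii, j, 1])):
                    if a in amap:
                        C[ii, off + amap[a]] += 1.0

    M = typed.astype(np.float64)
    paM = pa * M
    homM = hom.astype(np.float64)

    match_sum = (C @ C.T).astype(np.float64)        # sum over shared loci of 2*S
    pa_xy = paM @ M.T                               # sum shared pa_x
    shared = M @ M.T                                # number of shared loci
    hom_xy = homM @ M.T

    num = match_sum - pa_xy - pa_xy.T
    den = 2.0 * shared + hom_xy + hom_xy.T - pa_xy - pa_xy.T
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where((den != 0) & (shared > 0), num / den, np.nan)
    np.fill_diagonal(r, np.nan)
    return QGMatrix(list(gm.individuals), r, shared.astype(int))


@dataclass
class PedigreeRelatedness:
    """Additive relationship matrix with an individual index."""

    individuals: list[str]
    A: np.ndarray

    def pair(self, x: str, y: str) -> float:
        i = self.individuals.index(x)
        j = self.individuals.index(y)
        return float(self.A[i, j])

    def mean_over(self, individuals: list[str]) -> float:
        idx = np.array([self.individuals.index(i) for i in individuals])
        sub = self.A[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        return float(sub[iu].mean())


def pedigree_relatedness(ped: Pedigree) -> PedigreeRelatedness:
    """Additive relationship matrix by the tabular method.

    Founders are assumed unrelated and non-inbred (A = identity block);
    unknown parents contribute 0.  Raises on a pedigree cycle.
    """
    order = ped.topological_order()
    idx = {ind: i for i, ind in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for ind in order:
        i = idx[ind]
        sire, dam = ped.parents.get(ind, (None, None))
        si = idx.get(sire) if sire is not None else None
        di = idx.get(dam) if dam is not None else None
        # off-diagonals against all previously placed individuals
        for other in order[:i]:
            j = idx[other]
            a = 0.0
            if si is not None:
                a += 0.5 * A[j, si]
            if di is not None:
                a += 0.5 * A[j, di]
            A[i, j] = A[j, i] = a
        A[i, i] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
    return PedigreeRelatedness(order, A)


def pearson_test(x: np.ndarray, y: np.ndarray) -> CorrelationTest:
    """Pearson correlation with the t test on n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length series with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    df = x.size - 2
    if abs(r) >= 1.0:
        r = float(np.sign(r))
        t = float(np.sign(r) * np.inf)
        p = 0.0
    else:
        t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
        p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationTest(r=r, t=t, df=df, p=p)
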