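"""Two-locus haplotype frequencies by EM gene counting and multi-allelic LD.

Unphased diploid genotypes leave the gametic phase of double heterozygotes
unknown; the classical gene-counting EM resolves it by splitting each double
heterozygote between its two phase decompositions in proportion to the
current haplotype-frequency estimates.  From the fitted table x_ij with
marginals p_i, q_j two standardized multi-allelic statistics are computed:

* D' — the allele-frequency-weighted sum of |D_ij / D_max(i,j)| over all
  allele pairs, where D_ij = x_ij - p_i q_j.
* chi'2 — sum_ij D_ij^2 / (p_i q_j) divided by min(k, m) - 1, i.e. the
  classical chi-square normalized by 2N(min(k,m)-1).  For biallelic loci it
  reduces to r^2.

Both lie in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .panel import MISSING, GenotypeMatrix, LinkageMap

__all__ = [
    "HaplotypeTable",
    "LDEstimate",
    "PairLD",
    "em_haplotype_frequencies",
    "haplotype_loglik",
    "dprime",
    "chi2prime",
    "ld_estimate",
    "pairwise_ld",
]


@dataclass
class HaplotypeTable:
    """EM haplotype-frequency estimate for one marker pair.

    ``x`` is the k x m frequency table over the alleles actually observed in
    the pairwise-complete subset (labels in ``alleles_a`` / ``alleles_b``);
    ``p`` / ``q`` are its marginals, ``n`` the number of individuals typed at
    both loci.
    """

    x: np.ndarray
    alleles_a: np.ndarray
    alleles_b: np.ndarray
    p: np.ndarray
    q: np.ndarray
    n: int
    loglik: float
    iterations: int
    converged: bool
    ambiguous: bool = False
    loglik_trace: list[float] | None = None

    @property
    def k(self) -> int:
        return self.x.shape[0]

    @property
    def m(self) -> int:
        return self.x.shape[1]


@dataclass
class LDEstimate:
    dprime: float
    chi2prime: float


@dataclass
class PairLD:
    """LD between one marker pair, with map context."""

    locus_a: str
    locus_b: str
    chromosome_a: int
    chromosome_b: int
    d_cM: float | None
    synteny: str  # syntenic_lt50 | syntenic_ge50 | nonsyntenic
    n: int
    k: int
    m: int
    dprime: float | None
    chi2prime: float | None
    mean_hz: float
    em_iterations: int
    converged: bool

    @property
    def defined(self) -> bool:
        return self.dprime is not None


# ---------------------------------------------------------------------------
# genotype-class collapsing
# ---------------------------------------------------------------------------

def _collapse_pair(ga: np.ndarray, gb: np.ndarray):
    """Collapse pairwise-complete genotypes into counted classes.

    Returns (k, m, alleles_a, alleles_b, fixed_counts, dh, dh_counts, classes)
    where ``fixed_counts`` is the k x m matrix of phase-determined haplotype
    counts, ``dh`` an (n_types, 4) array of (i1, j1, i2, j2) double-het index
    quadruples and ``classes`` the unique genotype rows with their counts
    (for the log-likelihood).
    """
    alleles_a, ga_idx = np.unique(ga, return_inverse=True)
    alleles_b, gb_idx = np.unique(gb, return_inverse=True)
    ga_idx = ga_idx.reshape(ga.shape)
    gb_idx = gb_idx.reshape(gb.shape)
    k, m = len(alleles_a), len(alleles_b)

    # normalize within-genotype allele order so (1,2) == (2,1)
    ga_idx = np.sort(ga_idx, axis=1)
    gb_idx = np.sort(gb_idx, axis=1)
    rows = np.column_stack([ga_idx, gb_idx])  # (n, 4): a1 a2 b1 b2
    uniq, counts = np.unique(rows, axis=0, return_counts=True)

    fixed = np.zeros((k, m))
    dh_list: list[tuple[int, int, int, int]] = []
    dh_counts: list[int] = []
    classes: list[tuple[bool, tuple, int]] = []  # (is_dh, indices, count)
    for (a1, a2, b1, b2), c in zip(uniq, counts):
        if a1 != a2 and b1 != b2:
            dh_list.append((a1, b1, a2, b2))
            dh_counts.append(int(c))
            classes.append((True, (a1, b1, a2, b2), int(c)))
        else:
            # phase determined: haplotypes (a1,b1) and (a2,b2)
            fixed[a1, b1] += c
            fixed[a2, b2] += c
            classes.append((False, (a1, b1, a2, b2), int(c)))
    dh = np.array(dh_list, dtype=np.intp).reshape(-1, 4)
    return k, m, alleles_a, alleles_b, fixed, dh, np.array(dh_counts, dtype=float), classes


def _loglik(x: np.ndarray, classes) -> float:
    ll = 0.0
    for is_dh, (a1, b1, a2, b2), c in classes:
        if is_dh:
            p = 2.0 * (x[a1, b1] * x[a2, b2] + x[a1, b2] * x[a2, b1])
        else:
            p = x[a1, b1] * x[a2, b2]
            if (a1, b1) != (a2, b2):
                p *= 2.0
        ll += c * np.log(max(p, 1e-300))
    return float(ll)


def haplotype_loglik(x: np.ndarray, ga: np.ndarray, gb: np.ndarray) -> float:
    """Log-likelihood of a haplotype table given unphased genotype columns.

    Standalone entry point used by brute-force oracles; independent of the
    EM bookkeeping beyond genotype-class collapsing.
    """
    _, _, _, _, _, _, _, classes = _collapse_pair(ga, gb)
    return _loglik(np.asarray(x, dtype=float), classes)


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def em_haplotype_frequencies(
    gm: GenotypeMatrix,
    locus_a: str,
    locus_b: str,
    tol: float = 1e-8,
    max_iter: int = 1000,
    restarts: int = 0,
    seed: int | None = None,
    track_loglik: bool = False,
) -> HaplotypeTable:
    """Estimate two-locus haplotype frequencies by EM gene counting.

    Uses pairwise-complete individuals only; alleles unobserved in that
    subset are dropped.  Initialization is the independence table p_i q_j;
    the E-step splits each double heterozygote (i1/i2, j1/j2) between phases
    (i1 j1, i2 j2) and (i1 j2, i2 j1) in proportion
    x_{i1j1} x_{i2j2} : x_{i1j2} x_{i2j1}; the M-step renormalizes expected
    haplotype counts over 2N.  Iteration stops when max |dx| < tol.

    ``restarts`` adds random-initialization runs (best log-likelihood kept),
    useful for the degenerate all-double-heterozygote case.  A table whose
    pairwise-complete sample contains only double heterozygotes is flagged
    ``ambiguous`` (the likelihood does not separate the two phase classes).
    """
    ja, jb = gm.locus_index(locus_a), gm.locus_index(locus_b)
    ga_all = gm.genotypes[:, ja, :]
    gb_all = gm.genotypes[:, jb, :]
    complete = (ga_all[:, 0] != MISSING) & (gb_all[:, 0] != MISSING)
    n = int(complete.sum())
    if n == 0:
        raise ValueError(f"no individuals typed at both {locus_a} and {locus_b}")
    ga, gb = ga_all[complete], gb_all[complete]

    k, m, al_a, al_b, fixed, dh, dh_n, classes = _collapse_pair(ga, gb)

    # gene-count marginals (exact: each individual contributes 2 alleles)
    p = np.bincount(np.searchsorted(al_a, ga.ravel()), minlength=k) / (2.0 * n)
    q = np.bincount(np.searchsorted(al_b, gb.ravel()), minlength=m) / (2.0 * n)

    all_dh = fixed.sum() == 0 and len(dh) > 0

    def run(x0: np.ndarray):
        x = x0.copy()
        it = 0
        converged = False
        trace: list[float] = []
        i1, j1, i2, j2 = (dh[:, 0], dh[:, 1], dh[:, 2], dh[:, 3]) if len(dh) else (None,) * 4
        for it in range(1, max_iter + 1):
            if track_loglik:
                trace.append(_loglik(x, classes))
            counts = fixed.copy()
            if len(dh):
                w1 = x[i1, j1] * x[i2, j2]
                w2 = x[i1, j2] * x[i2, j1]
                s = w1 + w2
                frac = np.where(s > 0, w1 / np.where(s > 0, s, 1.0), 0.5)
                c1 = dh_n * frac
                c2 = dh_n - c1
                np.add.at(counts, (i1, j1), c1)
                np.add.at(counts, (i2, j2), c1)
                np.add.at(counts, (i1, j2), c2)
                np.add.at(counts, (i2, j1), c2)
            x_new = counts / (2.0 * n)
            if np.abs(x_new - x).max() < tol:
                x = x_new
                converged = True
                break
            x = x_new
        if track_loglik:
            trace.append(_loglik(x, classes))
        return x, it, converged, trace

    x, it, conv, trace = run(np.outer(p, q))
    best = (_loglik(x, classes), x, it, conv, trace)
    if restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(restarts):
            x0 = rng.dirichlet(np.ones(k * m)).reshape(k, m)
            xr, itr, convr, tracer = run(x0)
            llr = _loglik(xr, classes)
            if llr > best[0] + 1e-12:
                best = (llr, xr, itr, convr, tracer)
    ll, x, it, conv, trace = best

    return HaplotypeTable(
        x=x,
        alleles_a=al_a,
        alleles_b=al_b,
        p=x.sum(axis=1),
        q=x.sum(axis=0),
        n=n,
        loglik=ll,
        iterations=it,
        converged=conv,
        ambiguous=all_dh,
        loglik_trace=trace if track_loglik else None,
    )


# ---------------------------------------------------------------------------
# LD statistics
# ---------------------------------------------------------------------------

def _check_polymorphic(h: HaplotypeTable) -> None:
    if h.k < 2 or h.m < 2:
        raise ValueError("LD undefined: at least one locus is monomorphic")


def dprime(h: HaplotypeTable) -> float:
    """Multi-allelic D': sum_ij p_i q_j |D_ij / D_max(i,j)|, in [0, 1]."""
    _check_polymorphic(h)
    p, q = h.p, h.q
    D = h.x - np.outer(p, q)
    P, Q = np.meshgrid(p, q, indexing="ij")
    dmax_neg = np.minimum(P * Q, (1 - P) * (1 - Q))
    dmax_pos = np.minimum(P * (1 - Q), (1 - P) * Q)
    with np.errstate(divide="ignore", invalid="ignore"):
        dn = np.where(D > 0, D / dmax_pos, np.where(D < 0, -D / dmax_neg, 0.0))
    dn = np.nan_to_num(dn, nan=0.0, posinf=0.0)
    return float(np.clip((P * Q * dn).sum(), 0.0, 1.0))


def chi2prime(h: HaplotypeTable) -> float:
    """chi'2: [sum_ij D_ij^2 / (p_i q_j)] / (min(k, m) - 1), in [0, 1]."""
    _check_polymorphic(h)
    p, q = h.p, h.q
    D = h.x - np.outer(p, q)
    pq = np.outer(p, q)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pq > 0, D * D / pq, 0.0)
    val = terms.sum() / (min(h.k, h.m) - 1)
    return float(np.clip(val, 0.0, 1.0))


def ld_estimate(h: HaplotypeTable) -> LDEstimate:
    return LDEstimate(dprime=dprime(h), chi2prime=chi2prime(h))


# ---------------------------------------------------------------------------
# panel-wide pairwise LD
# ---------------------------------------------------------------------------

def pairwise_ld(
    gm: GenotypeMatrix,
    lmap: LinkageMap,
    pairs: Literal["all", "syntenic_lt50", "nonsyntenic"] = "all",
    tol: float = 1e-8,
    max_iter: int = 1000,
    loci: Sequence[str] | None = None,
) -> list[PairLD]:
    """LD for every requested marker pair, in deterministic locus-list order.

    Pairs with no shared typed individuals, or monomorphic at either locus in
    the pairwise-complete subset, are recorded with undefined estimates
    rather than raising.  ``mean_hz`` is the average expected heterozygosity
    of the two loci over the panel passed in.
    """
    use_loci = [l for l in (loci if loci is not None else gm.loci) if l in lmap]

    # per-locus expected heterozygosity over this panel
    hz: dict[str, float] = {}
    for loc in use_loci:
        j = gm.locus_index(loc)
        col = gm.genotypes[:, j, :]
        typed = col[col[:, 0] != MISSING]
        if typed.size == 0:
            hz[loc] = np.nan
            continue
        _, counts = np.unique(typed.ravel(), return_counts=True)
        f = counts / counts.sum()
        hz[loc] = 1.0 - float((f * f).sum())

    out: list[PairLD] = []
    for a_i in range(len(use_loci)):
        for b_i in range(a_i + 1, len(use_loci)):
            la, lb = use_loci[a_i], use_loci[b_i]
            cls = lmap.synteny_class(la, lb)
            if pairs != "all" and cls != pairs:
                continue
            d = lmap.distance(la, lb)
            base = dict(
                locus_a=la,
                locus_b=lb,
                chromosome_a=lmap[la].chromosome,
                chromosome_b=lmap[lb].chromosome,
                d_cM=d,
                synteny=cls,
                mean_hz=(hz[la] + hz[lb]) / 2.0,
            )
            try:
                h = em_haplotype_frequencies(gm, la, lb, tol=tol, max_iter=max_iter)
            except ValueError:
                out.append(
                    PairLD(**base, n=0, k=0, m=0, dprime=None, chi2prime=None,
                           em_iterations=0, converged=False)
                )
                continue
            if h.k < 2 or h.m < 2:
                out.append(
                    PairLD(**base, n=h.n, k=h.k, m=h.m, dprime=None, chi2prime=None,
                           em_iterations=h.iterations, converged=h.converged)
                )
                continue
            out.append(
                PairLD(**base, n=h.n, k=h.k, m=h.m,
                       dprime=dprime(h), chi2prime=chi2prime(h),
                       em_iterations=h.iterations, converged=h.converged)
            )
    return out


def pairs_to_dataframe(pairs: Iterable[PairLD]):
    """Long-format table of pairwise LD (one row per marker pair)."""
    import pandas as pd

    return pd.DataFrame(
        [
            dict(
                locus_a=p.locus_a, locus_b=p.locus_b,
                chromosome_a=p.chromosome_a, chromosome_b=p.chromosome_b,
                d_cM=p.d_cM if p.d_cM is not None else np.nan,
                synteny=p.synteny, n=p.n, k=p.k, m=p.m,
                dprime=p.dprime if p.dprime is not None else np.nan,
                chi2prime=p.chi2prime if p.chi2prime is not None else np.nan,
                mean_hz=p.mean_hz, em_iter=p.em_iterations, converged=p.converged,
            )
            for p in pairs
        ]
    )
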