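"""Fixed-size subsampling designs for sample-size bias and temporal series.

Two designs are implemented, both drawing individuals *without replacement*
and recomputing every statistic (allele frequencies, EM haplotype
frequencies, background LD, decay fit) from scratch on each draw:

* the sample-size curve — subsamples of 10..200 individuals, many
  replicates each, quantifying how small samples inflate background LD and
  depress half-lengths;
* yearly cross-sections — a fixed number of individuals (k = 20) drawn
  repeatedly within each year, making yearly LD summaries comparable across
  years and populations; mean pairwise relatedness is computed on the same
  draws so LD and relatedness replicates are paired.

Each replicate's decay fit uses that replicate's own nonsyntenic mean as
the fixed background level P3.  A single master seed spawns an independent
substream per (size-or-year, replicate), so results do not depend on
execution order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .decay import background_ld, fit_decay
from .ld import pairwise_ld
from .panel import GenotypeMatrix, LinkageMap

__all__ = ["SubsampleCurve", "YearlySeries", "subsample_curve", "yearly_cross_sections"]

DEFAULT_SIZES = (10, 25, 50, 75, 100, 125, 150, 175, 200)


def _substream(seed: int, tag: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, tag, rep]))


def _replicate_stats(
    sub: GenotypeMatrix,
    lmap: LinkageMap,
    metric: str,
    max_em_iter: int,
) -> tuple[float, float]:
    """(background mean, half-length) for one subsample; NaN where undefined."""
    pairs = pairwise_ld(sub, lmap, max_iter=max_em_iter)
    try:
        bg = background_ld(pairs, metric)
    except ValueError:
        return np.nan, np.nan
    try:
        fit = fit_decay(pairs, metric, p3=bg.mean)
        hl = fit.p2 if fit.converged else np.nan
    except ValueError:
        hl = np.nan
    return bg.mean, hl


@dataclass
class SubsampleCurve:
    metric: str
    sizes: list[int]
    reps: int
    seed: int
    background: dict[int, np.ndarray] = field(default_factory=dict)
    half_length: dict[int, np.ndarray] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for s in self.sizes:
            bg, hl = self.background[s], self.half_length[s]
            rows.append(
                {
                    "size": s,
                    "background_mean": np.nanmean(bg),
                    "background_sd": np.nanstd(bg, ddof=1) if len(bg) > 1 else 0.0,
                    "half_length_mean": np.nanmean(hl),
                    "half_length_sd": np.nanstd(hl, ddof=1) if len(hl) > 1 else 0.0,
                    "fit_failure_rate": np.isnan(hl).mean(),
                }
            )
        return pd.DataFrame(rows)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.sizes:
            for r in range(self.reps):
                rows.append(
                    {
                        "size_or_year": s,
                        "replicate": r,
                        "background_ld": self.background[s][r],
                        "half_length": self.half_length[s][r],
                        "converged": not np.isnan(self.half_length[s][r]),
                    }
                )
        return pd.DataFrame(rows)


def subsample_curve(
    gm: GenotypeMatrix,
    lmap: LinkageMap,
    sizes: Sequence[int] = DEFAULT_SIZES,
    reps: int = 1000,
    metric: str = "chi2prime",
    seed: int = 0,
    max_em_iter: int = 200,
) -> SubsampleCurve:
    """Background LD and half-length across subsample sizes.

    Draws are without replacement; a size equal to the panel size yields
    identical replicates by construction (computed once).  Failed decay
    fits within a replicate are recorded as NaN and excluded from summary
    means, with the failure rate reported.
    """
    n = gm.n_individuals
    too_big = [s for s in sizes if s > n]
    if too_big:
        raise ValueError(f"subsample sizes exceed panel size {n}: {too_big}")

    out = SubsampleCurve(metric=metric, sizes=list(sizes), reps=reps, seed=seed)
    for s in sizes:
        bg = np.empty(reps)
        hl = np.empty(reps)
        if s == n:
            b, h = _replicate_stats(gm, lmap, metric, max_em_iter)
            bg[:], hl[:] = b, h
        else:
            for r in range(reps):
                rng = _substream(seed, s, r)
                idx = rng.choice(n, size=s, replace=False)
                b, h = _replicate_stats(gm.subset_indices(idx), lmap, metric, max_em_iter)
                bg[r], hl[r] = b, h
        out.background[s] = bg
        out.half_length[s] = hl
    return out


@dataclass
class YearlySeries:
    metric: str
    k: int
    reps: int
    seed: int
    years: list[int] = field(default_factory=list)
    n_year: dict[int, int] = field(default_factory=dict)
    background: dict[int, np.ndarray] = field(default_factory=dict)
    half_length: dict[int, np.ndarray] = field(default_factory=dict)
    mean_relatedness: dict[int, np.ndarray] = field(default_factory=dict)
    skipped_years: list[int] = field(default_factory=list)

    def yearly_means(self) -> pd.DataFrame:
        rows = []
        for y in self.years:
            row = {
                "year": y,
                "n_year": self.n_year[y],
                "background_mean": np.nanmean(self.background[y]),
                "background_sd": np.nanstd(self.background[y], ddof=1)
                if self.reps > 1 else 0.0,
                "half_length_mean": np.nanmean(self.half_length[y]),
                "fit_failure_rate": np.isnan(self.half_length[y]).mean(),
            }
            if y in self.mean_relatedness:
                row["relatedness_mean"] = np.nanmean(self.mean_relatedness[y])
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for y in self.years:
            for r in range(self.reps):
                row = {
                    "size_or_year": y,
                    "replicate": r,
                    "background_ld": self.background[y][r],
                    "half_length": self.half_length[y][r],
                    "converged": not np.isnan(self.half_length[y][r]),
                }
                if y in self.mean_relatedness:
                    row["mean_relatedness"] = self.mean_relatedness[y][r]
                rows.append(row)
        return pd.DataFrame(rows)


def yearly_cross_sections(
    gm: GenotypeMatrix,
    lmap: LinkageMap,
    years: Sequence[int],
    k: int = 20,
    reps: int = 500,
    metric: str = "chi2prime",
    seed: int = 0,
    relatedness=None,
    max_em_iter: int = 200,
) -> YearlySeries:
    """Per-year replicate distributions of background LD and half-length.

    Years with fewer than k sampled individuals are skipped with a warning.
    A year with exactly k individuals produces identical replicates (the
    same individuals are drawn again and again).  ``relatedness`` may be a
    QGMatrix or PedigreeRelatedness; its ``mean_over`` is evaluated on the
    same subsample draws, pairing the relatedness and LD replicates.
    """
    out = YearlySeries(metric=metric, k=k, reps=reps, seed=seed)
    eligible = False
    for y in years:
        inds = gm.individuals_in_year(y)
        if len(inds) < k:
            warnings.warn(f"year {y}: only {len(inds)} individuals (< k = {k}), skipped")
            out.skipped_years.append(y)
            continue
        eligible = True
        out.years.append(y)
        out.n_year[y] = len(inds)
        bg = np.empty(reps)
        hl = np.empty(reps)
        rel = np.empty(reps) if relatedness is not None else None

        if len(inds) == k:
            b, h = _replicate_stats(gm.subset(individuals=inds), lmap, metric, max_em_iter)
            bg[:], hl[:] = b, h
            if rel is not None:
                rel[:] = relatedness.mean_over(inds)
        else:
            for r in range(reps):
                rng = _substream(seed, y, r)
                chosen = [inds[i] for i in rng.choice(len(inds), size=k, replace=False)]
                b, h = _replicate_stats(gm.subset(individuals=chosen), lmap, metric, max_em_iter)
                bg[r], hl[r] = b, h
                if rel is not None:
                    rel[r] = relatedness.mean_over(chosen)
        out.background[y] = bg
        out.half_length[y] = hl
        if rel is not None:
            out.mean_relatedness[y] = rel
    if not eligible:
        raise ValueError("no year has at least k individuals")
    return out
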