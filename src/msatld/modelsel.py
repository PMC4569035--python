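"""Linear models for what drives LD among syntenic markers, ranked by AICc.

The response is the LD of syntenic pairs under 50 cM; candidate terms are
log intermarker distance, mean expected heterozygosity of the pair, and
chromosome as a factor.  Continuous predictors are standardized on 2 SD
(Gelman's convention, making them comparable with binary indicators, which
are centered only).  All 2^T term subsets are fitted by OLS, ranked by

    AICc = -2 logLik + 2k + 2k(k+1)/(n - k - 1)

where k counts the intercept, slopes and the residual variance, and Akaike
weights exp(-delta/2)/sum exp(-delta/2) are computed over the full model
set.  The reporting view keeps models within 2 AICc of the best.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ld import PairLD

__all__ = [
    "ModelFit",
    "standardize_2sd",
    "build_design",
    "ols_fit",
    "aicc",
    "akaike_weights",
    "all_subsets",
    "table1_analysis",
]

_LOGLIK_VAR_FLOOR = 1e-12


@dataclass
class ModelFit:
    metric: str
    terms: tuple[str, ...]
    coefficients: dict[str, float]
    loglik: float
    k: int
    n: int
    aicc: float
    delta: float | None = None
    weight: float | None = None
    degenerate: bool = False
    extra: dict = field(default_factory=dict)


def standardize_2sd(values: np.ndarray, is_binary: bool = False, ddof: int = 1) -> np.ndarray:
    """Standardize a predictor on 2 SD; binary indicators are centered only."""
    x = np.asarray(values, dtype=float)
    if is_binary:
        return x - x.mean()
    sd = x.std(ddof=ddof)
    if sd == 0:
        raise ValueError("cannot 2-SD standardize a constant predictor")
    return (x - x.mean()) / (2.0 * sd)


def build_design(
    pairs: Iterable[PairLD],
    metric: str,
    log_offset: float = 0.1,
) -> pd.DataFrame:
    """Design frame from syntenic (<50 cM) pairs with defined estimates.

    Columns: the response (named after the metric), ``distance`` (natural
    log of d + offset, 2-SD standardized), ``hz`` (2-SD standardized mean
    heterozygosity) and centered chromosome indicators ``chr_*`` (first
    level dropped).  The offset keeps 0 cM pairs representable; 0.1 cM is
    below typical microsatellite map resolution.
    """
    sel = [
        p for p in pairs
        if p.synteny == "syntenic_lt50" and getattr(p, metric) is not None
    ]
    if not sel:
        raise ValueError("no syntenic (<50 cM) pairs with a defined estimate")
    df = pd.DataFrame(
        {
            metric: [getattr(p, metric) for p in sel],
            "distance": standardize_2sd(
                np.log(np.array([p.d_cM for p in sel]) + log_offset)
            ),
            "hz": standardize_2sd(np.array([p.mean_hz for p in sel])),
            "chromosome": [p.chromosome_a for p in sel],
        }
    )
    levels = sorted(df["chromosome"].unique())
    for lvl in levels[1:]:
        ind = (df["chromosome"] == lvl).astype(float)
        df[f"chr_{lvl}"] = standardize_2sd(ind.to_numpy(), is_binary=True)
    return df.drop(columns="chromosome")


def _term_columns(df: pd.DataFrame, term: str) -> list[str]:
    if term == "chromosome":
        return [c for c in df.columns if c.startswith("chr_")]
    return [term]


def ols_fit(df: pd.DataFrame, response: str, terms: Sequence[str]) -> ModelFit:
    """OLS of the response on the given terms (intercept always included).

    logLik is the Gaussian maximum with sigma^2 = RSS/n; k counts the
    intercept, the slopes, and sigma^2.  Exact fits (RSS ~ 0) are floored
    and flagged degenerate rather than reporting an infinite likelihood.
    """
    cols = [c for t in terms for c in _term_columns(df, t)]
    y = df[response].to_numpy()
    X = sm.add_constant(df[cols].to_numpy()) if cols else np.ones((len(df), 1))
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n = {n} too small for {p} coefficients")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(f"rank-deficient design for terms {terms}: rank {rank} < {p}")

    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    degenerate = rss / n < _LOGLIK_VAR_FLOOR
    sigma2 = max(rss / n, _LOGLIK_VAR_FLOOR)
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    k = p + 1  # + residual variance
    names = ["intercept"] + cols
    return ModelFit(
        metric=response,
        terms=tuple(terms),
        coefficients=dict(zip(names, map(float, res.params))),
        loglik=float(loglik),
        k=k,
        n=n,
        aicc=aicc(float(loglik), k, n),
        degenerate=degenerate,
        extra={"r2": float(res.rsquared) if np.isfinite(res.rsquared) else np.nan},
    )


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n = {n}, k = {k} (n - k - 1 <= 0)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """exp(-delta/2) normalized over the model set."""
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def all_subsets(
    df: pd.DataFrame,
    response: str,
    candidate_terms: Sequence[str] = ("distance", "hz", "chromosome"),
) -> list[ModelFit]:
    """Fit and rank all 2^T term subsets (intercept-only model included).

    Sorted by AICc; AICc ties are broken by term count (fewer first).
    Akaike weights are computed over the full set; use
    ``[m for m in fits if m.delta < 2]`` for the reporting view.
    """
    if not candidate_terms:
        raise ValueError("candidate term set is empty")
    fits: list[ModelFit] = []
    for r in range(len(candidate_terms) + 1):
        for subset in itertools.combinations(candidate_terms, r):
            try:
                fits.append(ols_fit(df, response, subset))
            except ValueError:
                continue  # recorded by absence; weights renormalize over fits
    fits.sort(key=lambda f: (round(f.aicc, 12), len(f.terms)))
    weights = akaike_weights([f.aicc for f in fits])
    best = fits[0].aicc
    for f, w in zip(fits, weights):
        f.delta = f.aicc - best
        f.weight = float(w)
    return fits


def table1_analysis(
    pairs: Iterable[PairLD],
    metric: str,
    log_offset: float = 0.1,
    delta_max: float = 2.0,
) -> pd.DataFrame:
    """All-subsets ranking formatted as a report table.

    One row per retained model (delta < ``delta_max``): intercept, the
    standardized distance and hz coefficients, a '+' marker for chromosome
    presence, df (= k), logLik, AICc, delta and weight.
    """
    df = build_design(pairs, metric, log_offset=log_offset)
    fits = all_subsets(df, metric)
    rows = []
    for f in fits:
        if f.delta is not None and f.delta >= delta_max:
            continue
        rows.append(
            {
                "intercept": f.coefficients.get("intercept", np.nan),
                "chromosome": "+" if "chromosome" in f.terms else "",
                "distance": f.coefficients.get("distance", np.nan),
                "hz": f.coefficients.get("hz", np.nan),
                "df": f.k,
                "logLik": f.loglik,
                "AICc": f.aicc,
                "delta": f.delta,
                "weight": f.weight,
            }
        )
    return pd.DataFrame(rows)
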