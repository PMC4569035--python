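"""Background LD, the half-length decay fit, and the LD-vs-n power fit.

Background LD is the mean LD among nonsyntenic pairs — the level expected
with no linkage, inflated by drift, admixture and finite samples.  The decay
of LD with map distance d (cM) among syntenic pairs closer than 50 cM is
summarized by

    LD(d) = (b - P3) * exp(-d * ln 2 / P2) + P3

where P3 is the background level (fixed from the nonsyntenic mean before
fitting), b the intercept at d = 0 (estimated, not constrained to 1, since
completely linked markers need not be in complete LD), and P2 the
half-length: the distance at which LD above background halves.  Under this
parameterization LD(P2) - P3 = (b - P3)/2 holds exactly.

The sample-size analysis models mean LD against the number of individuals n
with a power function f(x) = c * x^r.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from scipy.optimize import curve_fit

from .ld import PairLD

__all__ = [
    "BackgroundLD",
    "DecayFit",
    "PowerFit",
    "background_ld",
    "fit_decay",
    "fit_power",
    "decay_curve",
]

Metric = Literal["dprime", "chi2prime"]


@dataclass
class BackgroundLD:
    metric: str
    mean: float
    sd: float
    n_pairs: int


@dataclass
class DecayFit:
    metric: str
    b: float
    p2: float  # half-length, cM
    p3: float  # fixed background level
    se_b: float
    se_p2: float
    n_pairs: int
    converged: bool

    @property
    def p1(self) -> float:
        return self.b - self.p3

    def predict(self, d: np.ndarray) -> np.ndarray:
        return decay_curve(np.asarray(d, dtype=float), self.b, self.p2, self.p3)


@dataclass
class PowerFit:
    c: float
    r: float
    r2: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.c * np.asarray(x, dtype=float) ** self.r


def decay_curve(d: np.ndarray, b: float, p2: float, p3: float) -> np.ndarray:
    return (b - p3) * np.exp(-d * np.log(2.0) / p2) + p3


def _metric_values(pairs: Iterable[PairLD], metric: Metric) -> np.ndarray:
    vals = [getattr(p, metric) for p in pairs]
    return np.array([v for v in vals if v is not None], dtype=float)


def background_ld(pairs: Iterable[PairLD], metric: Metric = "chi2prime") -> BackgroundLD:
    """Mean and sample SD of LD over nonsyntenic pairs with defined estimates.

    Syntenic pairs at >= 50 cM belong to neither the background set nor the
    decay fit; they are simply excluded here.
    """
    vals = _metric_values((p for p in pairs if p.synteny == "nonsyntenic"), metric)
    if vals.size == 0:
        raise ValueError("no nonsyntenic pairs with a defined LD estimate")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return BackgroundLD(metric=metric, mean=float(vals.mean()), sd=sd, n_pairs=int(vals.size))


def fit_decay(
    pairs: Iterable[PairLD],
    metric: Metric,
    p3: float,
    max_distance: float = 50.0,
) -> DecayFit:
    """Fit the half-length model to syntenic pairs closer than ``max_distance``.

    Nonlinear least squares (Levenberg-Marquardt via trust-region with
    bounds) for b and P2 with P3 held fixed.  Starting values: b0 = mean LD
    of pairs under 2 cM (falling back to the maximum observed LD), P2_0 = 10
    cM.  Bounds: P2 > 0, b in (p3, 1].  Standard errors come from the
    Jacobian-based asymptotic covariance at the optimum.

    Raises if fewer than 3 pairs with distinct distances remain, or if the
    responses are flat at the background level (P2 unidentifiable).  A
    fitted half-length far beyond the observed distance window (P2 > 2 x
    max distance) means the curve never approaches its asymptote within the
    data; such fits are returned with ``converged=False`` since the
    half-length is not identified by the data range.
    """
    sel = [
        p for p in pairs
        if p.synteny == "syntenic_lt50" and p.d_cM is not None
        and p.d_cM < max_distance and getattr(p, metric) is not None
    ]
    d = np.array([p.d_cM for p in sel], dtype=float)
    y = np.array([getattr(p, metric) for p in sel], dtype=float)
    if len(np.unique(d)) < 3:
        raise ValueError("need >= 3 syntenic pairs with distinct distances")

    if np.allclose(y, p3, atol=1e-10) or y.std() < 1e-12:
        raise ValueError("responses flat at background level: P2 unidentifiable")

    near = y[d < 2.0]
    b0 = float(near.mean()) if near.size else float(y.max())
    b0 = min(max(b0, p3 + 1e-3), 1.0)

    def model(dd, b, p2):
        return decay_curve(dd, b, p2, p3)

    try:
        popt, pcov = curve_fit(
            model, d, y,
            p0=[b0, 10.0],
            bounds=([p3 + 1e-9, 1e-6], [1.0, 1e4]),
            maxfev=20000,
        )
        converged = True
    except RuntimeError:
        return DecayFit(metric=metric, b=np.nan, p2=np.nan, p3=p3,
                        se_b=np.nan, se_p2=np.nan, n_pairs=len(sel), converged=False)

    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(2, np.nan)
    if popt[1] > 2.0 * d.max():
        converged = False  # half-length outside the identifiable range
    return DecayFit(
        metric=metric, b=float(popt[0]), p2=float(popt[1]), p3=p3,
        se_b=float(se[0]), se_p2=float(se[1]), n_pairs=len(sel), converged=converged,
    )


def fit_power(x: np.ndarray, y: np.ndarray) -> PowerFit:
    """Least-squares fit of y = c * x^r with r2 = 1 - SSres/SStot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(x <= 0):
        raise ValueError("power fit requires strictly positive x")

    if np.allclose(y, y[0]):
        return PowerFit(c=float(y.mean()), r=0.0, r2=1.0 if y.std() == 0 else 0.0)

    # log-log start when y > 0, else neutral start
    if np.all(y > 0):
        r0, logc0 = np.polyfit(np.log(x), np.log(y), 1)
        p0 = [float(np.exp(logc0)), float(r0)]
    else:
        p0 = [float(y.mean()), 0.0]

    popt, _ = curve_fit(lambda xx, c, r: c * xx**r, x, y, p0=p0, maxfev=20000)
    resid = y - popt[0] * x ** popt[1]
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return PowerFit(c=float(popt[0]), r=float(popt[1]), r2=r2)
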