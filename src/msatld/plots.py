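"""Diagnostic plots: decay scatter with fitted curve, LD vs sample size,
yearly box plots."""

from __future__ import annotations

from typing import Iterable

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .decay import DecayFit, PowerFit
from .ld import PairLD
from .resample import SubsampleCurve, YearlySeries


def plot_decay(pairs: Iterable[PairLD], fit: DecayFit, path: str) -> None:
    """Syntenic LD against distance with the fitted half-length curve."""
    sel = [p for p in pairs if p.synteny == "syntenic_lt50" and getattr(p, fit.metric) is not None]
    d = np.array([p.d_cM for p in sel])
    y = np.array([getattr(p, fit.metric) for p in sel])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(d, y, s=8, alpha=0.5, color="k")
    xs = np.linspace(0, max(d.max(), 1), 200)
    ax.plot(xs, fit.predict(xs), color="C3")
    ax.axhline(fit.p3, ls="--", color="C0", lw=0.8)
    ax.set_xlabel("intermarker distance (cM)")
    ax.set_ylabel(fit.metric)
    ax.set_title(f"half-length {fit.p2:.2f} cM (b = {fit.b:.2f}, P3 = {fit.p3:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_sample_size(curve: SubsampleCurve, path: str, power: PowerFit | None = None) -> None:
    """Mean background LD (with SD bars) against subsample size."""
    s = curve.summary()
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].errorbar(s["size"], s["background_mean"], yerr=s["background_sd"], fmt="o-")
    if power is not None:
        xs = np.linspace(s["size"].min(), s["size"].max(), 100)
        axes[0].plot(xs, power.predict(xs), color="C3", lw=1)
    axes[0].set_xlabel("subsample size")
    axes[0].set_ylabel(f"background {curve.metric}")
    axes[1].errorbar(s["size"], s["half_length_mean"], yerr=s["half_length_sd"], fmt="o-")
    axes[1].set_xlabel("subsample size")
    axes[1].set_ylabel("half-length (cM)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_yearly(series: YearlySeries, path: str) -> None:
    """Box plots of yearly replicate distributions."""
    panels = [("background", series.background, f"background {series.metric}"),
              ("half_length", series.half_length, "half-length (cM)")]
    if series.mean_relatedness:
        panels.append(("relatedness", series.mean_relatedness, "mean relatedness"))
    fig, axes = plt.subplots(len(panels), 1, figsize=(7, 2.6 * len(panels)), squeeze=False)
    for ax, (_, data, label) in zip(axes[:, 0], panels):
        vals = [data[y][~np.isnan(data[y])] for y in series.years]
        ax.boxplot(vals, tick_labels=[str(y) for y in series.years], showfliers=False)
        ax.set_ylabel(label)
        ax.tick_params(axis="x", rotation=90, labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
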