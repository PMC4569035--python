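"""End-to-end orchestration: panel -> LD -> decay -> resampling -> report.

A :class:`RunConfig` (usually loaded from YAML) names the input files and
parameters; :func:`run_pipeline` executes the stages in order, writes TSV/
JSON artifacts plus plots into the output directory, and finishes with a
manifest recording the seed, package version and a checksum per artifact so
identical (inputs, config, seed) runs are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decay import background_ld, fit_decay, fit_power
from .ld import pairs_to_dataframe, pairwise_ld
from .modelsel import table1_analysis
from .panel import (
    allele_frequencies,
    filter_panel,
    read_cohorts,
    read_genepop,
    read_map,
    read_pedigree,
)
from .relatedness import pearson_test, qg_matrix
from .resample import DEFAULT_SIZES, subsample_curve, yearly_cross_sections

log = logging.getLogger("msatld")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    genepop: str
    map: str
    cohorts: str
    pedigree: str | None = None
    metrics: list[str] = field(default_factory=lambda: ["dprime", "chi2prime"])
    max_missing: float = 0.15
    sizes: list[int] = field(default_factory=lambda: list(DEFAULT_SIZES))
    curve_reps: int = 1000
    k: int = 20
    temporal_reps: int = 500
    log_offset: float = 0.1
    seed: int = 0
    outdir: str = "msatld_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**data)
        for name in ("genepop", "map", "cohorts"):
            p = getattr(cfg, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if cfg.pedigree is not None and not Path(cfg.pedigree).exists():
            raise FileNotFoundError(f"pedigree file not found: {cfg.pedigree}")
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json).

    Any stage failure aborts with the stage name; artifacts written so far
    are listed in a partial manifest next to them.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed, "stages": {}, "artifacts": {}}
    stage = "setup"

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        manifest["artifacts"][name] = _sha256(path)

    def emit_json(name: str, obj) -> None:
        path = out / name
        path.write_text(json.dumps(obj, indent=2, default=float) + "\n")
        manifest["artifacts"][name] = _sha256(path)

    try:
        # ---- stage 1: panel -------------------------------------------
        stage = "panel"
        t0 = time.time()
        gm = read_genepop(cfg.genepop)
        gm.years.update(read_cohorts(cfg.cohorts))
        lmap = read_map(cfg.map)
        gm, report = filter_panel(gm, cfg.max_missing, cfg.max_missing, return_report=True)
        log.info("panel: %d individuals x %d loci (dropped %d loci, %d individuals)",
                 gm.n_individuals, gm.n_loci, len(report.dropped_loci),
                 len(report.dropped_individuals))
        manifest["stages"][stage] = {
            "individuals": gm.n_individuals, "loci": gm.n_loci,
            "dropped_loci": report.dropped_loci,
            "dropped_individuals": report.dropped_individuals,
            "seconds": round(time.time() - t0, 2),
        }

        # ---- stage 2: pairwise LD -------------------------------------
        stage = "pairwise_ld"
        t0 = time.time()
        pairs = pairwise_ld(gm, lmap)
        emit("pairs.tsv", pairs_to_dataframe(pairs))
        manifest["stages"][stage] = {
            "n_pairs": len(pairs),
            "n_undefined": sum(1 for p in pairs if not p.defined),
            "seconds": round(time.time() - t0, 2),
        }

        # ---- stage 3: background + decay ------------------------------
        stage = "decay"
        t0 = time.time()
        decay_report = {}
        fits = {}
        for metric in cfg.metrics:
            bg = background_ld(pairs, metric)
            fit = fit_decay(pairs, metric, p3=bg.mean)
            fits[metric] = fit
            decay_report[metric] = {
                "background_mean": bg.mean, "background_sd": bg.sd,
                "background_n_pairs": bg.n_pairs,
                "b": fit.b, "p1": fit.p1, "p2_half_length_cM": fit.p2,
                "p3": fit.p3, "se_b": fit.se_b, "se_p2": fit.se_p2,
                "n_pairs": fit.n_pairs, "converged": fit.converged,
            }
        emit_json("decay.json", decay_report)
        try:
            from .plots import plot_decay
            for metric, fit in fits.items():
                plot_decay(pairs, fit, str(out / f"decay_{metric}.png"))
        except Exception:  # plotting is best-effort
            log.warning("decay plot failed", exc_info=True)
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

        # ---- stage 4: sample-size curve -------------------------------
        stage = "sample_size_curve"
        t0 = time.time()
        sizes = [s for s in cfg.sizes if s <= gm.n_individuals]
        curve_frames = []
        for metric in cfg.metrics:
            curve = subsample_curve(gm, lmap, sizes=sizes, reps=cfg.curve_reps,
                                    metric=metric, seed=cfg.seed)
            df = curve.to_dataframe()
            df.insert(0, "metric", metric)
            curve_frames.append(df)
        emit("sscurve.tsv", pd.concat(curve_frames, ignore_index=True))
        manifest["stages"][stage] = {"sizes": sizes, "reps": cfg.curve_reps,
                                     "seconds": round(time.time() - t0, 2)}

        # ---- stage 5: relatedness -------------------------------------
        stage = "relatedness"
        t0 = time.time()
        freqs = {loc: allele_frequencies(gm, loc) for loc in gm.loci}
        qg = qg_matrix(gm, freqs)
        manifest["stages"][stage] = {"individuals": gm.n_individuals,
                                     "seconds": round(time.time() - t0, 2)}

        # ---- stage 6: temporal series ---------------------------------
        stage = "temporal"
        t0 = time.time()
        years = sorted({y for ys in gm.years.values() for y in ys})
        series_by_metric = {}
        temporal_frames = []
        for metric in cfg.metrics:
            series = yearly_cross_sections(
                gm, lmap, years, k=cfg.k, reps=cfg.temporal_reps,
                metric=metric, seed=cfg.seed, relatedness=qg,
            )
            series_by_metric[metric] = series
            df = series.to_dataframe()
            df.insert(0, "metric", metric)
            temporal_frames.append(df)
        emit("temporal.tsv", pd.concat(temporal_frames, ignore_index=True))
        try:
            from .plots import plot_yearly
            for metric, series in series_by_metric.items():
                plot_yearly(series, str(out / f"yearly_{metric}.png"))
        except Exception:
            log.warning("yearly plot failed", exc_info=True)
        manifest["stages"][stage] = {"years": [int(y) for y in years],
                                     "seconds": round(time.time() - t0, 2)}

        # ---- stage 7: correlations (yearly relatedness vs LD) ---------
        stage = "correlations"
        t0 = time.time()
        rows = []
        for metric, series in series_by_metric.items():
            ym = series.yearly_means()
            if "relatedness_mean" not in ym or len(ym) < 3:
                continue
            for quantity, col in (("background", "background_mean"),
                                  ("half_length", "half_length_mean")):
                sub = ym.dropna(subset=[col, "relatedness_mean"])
                if len(sub) < 3:
                    continue
                try:
                    ct = pearson_test(sub["relatedness_mean"].to_numpy(),
                                      sub[col].to_numpy())
                except ValueError:
                    continue
                rows.append({"metric": metric, "quantity": quantity,
                             "r": ct.r, "t": ct.t, "df": ct.df, "p": ct.p,
                             "n_years": len(sub)})
            # power fit of yearly background vs yearly full-sample n
            sub = ym.dropna(subset=["background_mean"])
            if len(sub) >= 3 and sub["n_year"].std() > 0:
                try:
                    pf = fit_power(sub["n_year"].to_numpy(),
                                   sub["background_mean"].to_numpy())
                    rows.append({"metric": metric, "quantity": "background_vs_n_power",
                                 "r": pf.r, "t": np.nan, "df": len(sub) - 2,
                                 "p": np.nan, "n_years": len(sub)})
                except (ValueError, RuntimeError):
                    pass
        emit("correlations.tsv", pd.DataFrame(rows))
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

        # ---- stage 8: model selection ---------------------------------
        stage = "model_selection"
        t0 = time.time()
        tables = []
        for metric in cfg.metrics:
            tab = table1_analysis(pairs, metric, log_offset=cfg.log_offset)
            tab.insert(0, "metric", metric)
            tables.append(tab)
        emit("model_selection.tsv", pd.concat(tables, ignore_index=True))
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
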