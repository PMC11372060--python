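"""End-to-end orchestration of the backscatter and co-occurrence analyses.

`run_backscatter_analysis` takes a plate (file or PlateSeries) plus a
RunConfig, runs detrend -> normalize -> smooth -> cosine fit -> first-cycle /
first-peak features -> strain summaries -> mutant-vs-reference comparisons ->
pairwise statistics, and writes every stage's table to the output directory
together with a machine-readable manifest.  Per-well feature failures are
logged and recorded, not fatal: strains with decaying low-amplitude rhythms
legitimately lose wells to the peak detectors.

All defaults equal the printed analysis parameters: polynomial degree 4,
3 h fit exclusion, 40-sample smoothing kernel, peak distance 150 samples,
period-detection height 50, first-peak width 65 and height mean + 20 % of
max, alpha 0.05, FDR 0.01.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cooccurrence import (
    FDR_DEFAULT,
    bh_adjust,
    cooccurrence_network,
    read_presence_matrix,
)
from .errors import ConfigError, FeatureError, FitError
from .group_stats import ALPHA_DEFAULT, compare_strains
from .harmonic import (
    DEFAULT_MAX_PERIOD_H,
    DEFAULT_MIN_PERIOD_H,
    default_bounds,
    fit_cosine,
)
from .plate_io import PlateSeries, read_plate_long, sampling_interval
from .preprocess import DetrendConfig, preprocess_series
from .rhythm_features import (
    FIRST_PEAK_PARAMS,
    PERIOD_PEAK_PARAMS,
    PeakParams,
    compare_to_reference,
    first_cycle_period,
    first_peak_features,
    summarize_strain,
)

logger = logging.getLogger("cyanorhythm")

CSV_FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    """Configuration of one analysis run; defaults match the printed
    parameters of the original analysis."""

    reference_strain: str = "WT"
    detrend: DetrendConfig = field(default_factory=DetrendConfig)
    min_period_h: float = DEFAULT_MIN_PERIOD_H
    max_period_h: float = DEFAULT_MAX_PERIOD_H
    period_bounds_per_strain: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_starts: int = 8
    fit_tolerance: float = 1e-10
    period_peaks: PeakParams = field(default_factory=lambda: PERIOD_PEAK_PARAMS)
    first_peaks: PeakParams = field(default_factory=lambda: FIRST_PEAK_PARAMS)
    fit_averaged: bool = True  # fit the replicate-averaged signal per strain
    fit_signal: str = "normalized"  # "normalized" (default) or "smoothed"
    alpha: float = ALPHA_DEFAULT
    adjust_pairwise_bh: bool = False  # BH over the pairwise strain grid
    fdr_q: float = FDR_DEFAULT
    cooccur_anchor: str | None = None
    cooccur_use_raw: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "detrend" in kwargs and isinstance(kwargs["detrend"], dict):
            d = kwargs["detrend"]
            kwargs["detrend"] = DetrendConfig(
                degree=d.get("degree", 4),
                exclude_before=d.get("exclude_before_h", 3.0),
                kernel_size=d.get("kernel_samples", 40),
            )
        for key in ("period_peaks", "first_peaks"):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = PeakParams(**kwargs[key])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**kwargs)


@dataclass
class BackscatterResult:
    """Tables produced by one backscatter analysis run."""

    processed: pd.DataFrame
    fits: pd.DataFrame
    well_features: pd.DataFrame
    strain_summary: pd.DataFrame
    comparisons: pd.DataFrame
    first_periods: pd.DataFrame
    pairwise_tests: pd.DataFrame
    manifest: dict


def _strain_bounds(config: RunConfig, strain: str) -> tuple[float, float]:
    return config.period_bounds_per_strain.get(
        strain, (config.min_period_h, config.max_period_h)
    )


def run_backscatter_analysis(
    plate, config: RunConfig, out_dir=None
) -> BackscatterResult:
    """Run the full rhythm-analysis pipeline on a plate.

    ``plate`` is a PlateSeries or a path to a long-format CSV.  When
    ``out_dir`` is given, every table plus a JSON manifest is written there.
    """
    series = plate if isinstance(plate, PlateSeries) else read_plate_long(plate)
    strains = series.strains()
    if config.reference_strain not in strains:
        raise ConfigError(
            f"reference strain {config.reference_strain!r} not found; "
            f"plate has {strains}"
        )
    dt = sampling_interval(series)
    times = series.times

    processed = preprocess_series(series, config.detrend)
    by_strain: dict[str, list] = {s: [] for s in strains}
    for tr in processed:
        by_strain[tr.strain].append(tr)

    processed_rows = []
    for tr in processed:
        processed_rows.append(
            pd.DataFrame(
                {
                    "well": tr.well_id,
                    "strain": tr.strain,
                    "time_h": times,
                    "normalized": tr.normalized,
                    "smoothed": tr.smoothed,
                }
            )
        )
    processed_df = pd.concat(processed_rows, ignore_index=True)

    # Harmonic fit: replicate-averaged smoothed signal per strain (default),
    # or per well with strain-level averaging of the fitted periods.
    fit_rows = []
    failures: list[dict] = []
    if config.fit_signal not in ("normalized", "smoothed"):
        raise ConfigError("fit_signal must be 'normalized' or 'smoothed'")
    pick = (lambda tr: tr.normalized) if config.fit_signal == "normalized" else (
        lambda tr: tr.smoothed
    )
    for strain in strains:
        lo, hi = _strain_bounds(config, strain)
        targets = (
            [("strain-average", np.mean([pick(t) for t in by_strain[strain]], axis=0))]
            if config.fit_averaged
            else [(t.well_id, pick(t)) for t in by_strain[strain]]
        )
        for label, sig in targets:
            try:
                fit = fit_cosine(
                    times, sig, default_bounds(sig, lo, hi),
                    n_starts=config.n_starts, tolerance=config.fit_tolerance,
                )
                fit_rows.append(
                    {
                        "strain": strain, "signal": label, "A": fit.A,
                        "omega": fit.omega, "phi": fit.phi, "period_h": fit.period,
                        "rss": fit.rss, "relative_rss": fit.relative_rss,
                        "converged": fit.converged, "degenerate": fit.degenerate,
                    }
                )
            except FitError as exc:
                failures.append({"stage": "fit", "strain": strain, "signal": label,
                                 "error": str(exc)})
                logger.warning("cosine fit failed for %s/%s: %s", strain, label, exc)
    fits_df = pd.DataFrame(fit_rows)

    # Per-well first-cycle periods and first-peak features.
    feature_rows = []
    for tr in processed:
        row: dict = {"well": tr.well_id, "strain": tr.strain}
        try:
            row["first_cycle_period_h"] = first_cycle_period(
                tr.smoothed, times, config.period_peaks
            )
        except FeatureError as exc:
            row["first_cycle_period_h"] = np.nan
            failures.append({"stage": "first_cycle_period", "well": tr.well_id,
                             "error": str(exc)})
            logger.warning("first-cycle period failed for %s: %s", tr.well_id, exc)
        try:
            t_pk, h_pk = first_peak_features(tr.smoothed, times, config.first_peaks)
            row["first_peak_time_h"], row["first_peak_height"] = t_pk, h_pk
        except FeatureError as exc:
            row["first_peak_time_h"] = row["first_peak_height"] = np.nan
            failures.append({"stage": "first_peak", "well": tr.well_id,
                             "error": str(exc)})
            logger.warning("first-peak features failed for %s: %s", tr.well_id, exc)
        feature_rows.append(row)
    well_features = pd.DataFrame(feature_rows)

    # Strain summaries of the first peak.
    summaries = {}
    summary_rows = []
    for strain in strains:
        sub = well_features[
            (well_features["strain"] == strain)
            & well_features["first_peak_time_h"].notna()
        ]
        if len(sub):
            s = summarize_strain(
                strain, sub["first_peak_time_h"], sub["first_peak_height"]
            )
            summaries[strain] = s
            summary_rows.append(dataclasses.asdict(s))
    strain_summary = pd.DataFrame(summary_rows)

    # Mutant vs reference comparisons (formulas for shift/ratio and their
    # error boundaries).
    comparison_rows = []
    ref = summaries.get(config.reference_strain)
    for strain in strains:
        if strain == config.reference_strain or strain not in summaries or ref is None:
            continue
        cmp_res = compare_to_reference(summaries[strain], ref)
        comparison_rows.append({"strain": strain, **dataclasses.asdict(cmp_res)})
    comparisons = pd.DataFrame(comparison_rows)

    # First-period distributions and pairwise strain statistics on them.
    period_rows = []
    per_strain_periods: dict[str, np.ndarray] = {}
    for strain in strains:
        vals = well_features.loc[
            well_features["strain"] == strain, "first_cycle_period_h"
        ].dropna().to_numpy()
        per_strain_periods[strain] = vals
        if vals.size:
            period_rows.append(
                {
                    "strain": strain, "n_wells": int(vals.size),
                    "mean_h": float(vals.mean()), "median_h": float(np.median(vals)),
                    "sd_h": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                }
            )
    first_periods = pd.DataFrame(period_rows)

    test_rows = []
    for i, s1 in enumerate(strains):
        for s2 in strains[i + 1 :]:
            a, b = per_strain_periods[s1], per_strain_periods[s2]
            if a.size < 2 or b.size < 2:
                continue
            res = compare_strains(a, b, alpha=config.alpha)
            test_rows.append(
                {
                    "strain_a": s1, "strain_b": s2,
                    "levene_p": res.levene_p, "test_used": res.test_used,
                    "t": res.t_stat, "p": res.p, "significant": res.significant,
                }
            )
    pairwise_tests = pd.DataFrame(test_rows)
    if config.adjust_pairwise_bh and len(pairwise_tests):
        adjusted, _ = bh_adjust(pairwise_tests["p"].to_numpy(), q=config.alpha)
        pairwise_tests["p_adj"] = adjusted
        pairwise_tests["significant"] = pairwise_tests["p_adj"] < config.alpha

    manifest = {
        "tool": "cyanorhythm", "version": __version__,
        "n_wells": len(series), "n_timepoints": int(times.size),
        "sampling_interval_h": dt,
        "config": _config_to_jsonable(config),
        "failures": failures,
    }

    result = BackscatterResult(
        processed=processed_df, fits=fits_df, well_features=well_features,
        strain_summary=strain_summary, comparisons=comparisons,
        first_periods=first_periods, pairwise_tests=pairwise_tests,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_backscatter(result, Path(out_dir))
    return result


def _config_to_jsonable(config: RunConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return convert(config)


def _write_backscatter(result: BackscatterResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = {
        "processed_traces.csv": result.processed,
        "cosine_fits.csv": result.fits,
        "well_features.csv": result.well_features,
        "strain_summary.csv": result.strain_summary,
        "comparisons.csv": result.comparisons,
        "first_periods.csv": result.first_periods,
        "pairwise_tests.csv": result.pairwise_tests,
    }
    for name, df in tables.items():
        df.to_csv(out_dir / name, index=False, float_format=CSV_FLOAT_FORMAT)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)


def run_cooccurrence(matrix, config: RunConfig, out_dir=None, graphml: bool = False):
    """Anchor-restricted pairwise co-occurrence network from a presence
    matrix (DataFrame or path); writes edge/node tables, a manifest and —
    when ``graphml`` is set — a GraphML file of the retained network."""
    df = matrix if isinstance(matrix, pd.DataFrame) else read_presence_matrix(matrix)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ConfigError("empty presence matrix")
    anchor = config.cooccur_anchor
    if anchor is None:
        raise ConfigError("cooccur_anchor must be set")
    if anchor not in df.columns:
        raise ConfigError(f"anchor protein {anchor!r} not in matrix")
    network = cooccurrence_network(
        df, anchor, q=config.fdr_q, use_raw=config.cooccur_use_raw
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        network.edges.to_csv(out / "edges.csv", index=False, float_format=CSV_FLOAT_FORMAT)
        pd.DataFrame(
            [{"protein": p, "degree": d} for p, d in network.degrees.items()]
        ).to_csv(out / "nodes.csv", index=False)
        manifest = {
            "tool": "cyanorhythm", "version": __version__,
            "n_genomes": int(df.shape[0]), "n_proteins": int(df.shape[1]),
            "anchor": anchor, "universe_size": int(df[anchor].sum()),
            "fdr_q": config.fdr_q, "threshold_on_raw": config.cooccur_use_raw,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        if graphml:
            import networkx as nx

            nx.write_graphml(network.graph(), out / "network.graphml")
    return network
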