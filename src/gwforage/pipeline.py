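"""End-to-end pipeline: generate -> summarize -> diagnose -> fidelity ->
spatial -> acoustics -> drivers, with a reproducibility manifest.

Every stage reads/writes plain CSV/JSON/GeoJSON in the output directory;
a single master seed fans out to per-module substreams, so the same
RunConfig reproduces byte-identical outputs.  Stages can be toggled
independently; disabling one never alters another's outputs.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .acoustics import (
    DetectionModel,
    class_distribution,
    context_correlations,
    detection_radius_series,
    join_visual_acoustic,
)
from .diagnostics import cross_correlation, diagnose_series
from .drivers import build_lagged_features, rank_variable_importance, spearman_screen
from .fidelity import classify_catalogue, fidelity_correlations
from .spatial import monthly_heat_grid, monthly_weighted_means
from .synthetic import SimulationConfig, generate_dataset, write_dataset
from .transects import summarize_seasons

logger = logging.getLogger(__name__)

STAGES = ("simulate", "summarize", "diagnose", "fidelity", "spatial", "acoustics", "drivers")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either a simulation config (synthetic run) or paths to existing
    input CSVs must be supplied — never neither.
    """

    outdir: Path
    simulation: SimulationConfig | None = None
    input_paths: dict[str, Path] = field(default_factory=dict)
    stages: tuple[str, ...] = STAGES
    heat_cell_size_deg: float = 0.01
    max_lag: int = 4
    response: str = "mean_whales_lag0"
    seed: int = 0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.simulation is None and not self.input_paths:
            raise ValueError("need either a simulation config or input CSV paths")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and write a manifest.

    Returns the manifest dict; raises at the first failing stage with
    partial outputs preserved on disk.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "outputs": {},
        "inputs": {},
    }

    stage = "simulate"
    try:
        if "simulate" in config.stages:
            sim = config.simulation or SimulationConfig(seed=config.seed)
            dataset = generate_dataset(sim)
            paths = write_dataset(dataset, out)
            manifest["outputs"].update({k: str(v) for k, v in paths.items()})
        else:
            from .fidelity import frame_to_catalogue
            from .transects import frame_to_transects

            dataset = None
            transects = frame_to_transects(pd.read_csv(config.input_paths["transects"]))
            catalogue = frame_to_catalogue(pd.read_csv(config.input_paths["catalogue"]))
            for key, p in config.input_paths.items():
                manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(Path(p))}

        if dataset is not None:
            transects = dataset.transects
            catalogue = dataset.catalogue

        stage = "summarize"
        summaries = summarize_seasons(transects)
        if "summarize" in config.stages:
            annual = pd.DataFrame([s.as_dict() for s in summaries])
            annual.to_csv(out / "annual_summary.csv", index=False)
            manifest["outputs"]["annual_summary"] = str(out / "annual_summary.csv")

        stage = "diagnose"
        if "diagnose" in config.stages:
            pooled = [
                t.whale_count
                for t in sorted(transects, key=lambda t: t.date)
            ]
            annual_means = [s.mean_whales for s in summaries]
            diag = {
                "all_transects": diagnose_series(pooled),
                "annual_means": diagnose_series(annual_means)
                if len(annual_means) >= 3
                else None,
            }
            xcorr = cross_correlation(
                [s.mean_whales for s in summaries],
                [float(s.max_whales) for s in summaries],
                max_lag=min(10, len(summaries) - 3),
            )
            diag["xcorr_mean_vs_max"] = xcorr.to_dict(orient="list")
            (out / "diagnostics.json").write_text(json.dumps(diag, indent=1))
            pd.DataFrame({"residual": np.diff(pooled)}).to_csv(
                out / "residuals.csv", index=False
            )
            # persistence-residual summary rows: pooled, annual-mean series,
            # and one row per season
            from .diagnostics import persistence_residuals

            rows = [{"series": "All", **persistence_residuals(pooled).summary}]
            if len(annual_means) >= 3:
                rows.append(
                    {"series": "Annual", **persistence_residuals(annual_means).summary}
                )
            by_year: dict[int, list[int]] = {}
            for t in sorted(transects, key=lambda t: t.date):
                by_year.setdefault(t.year, []).append(t.whale_count)
            for year, counts in sorted(by_year.items()):
                if len(counts) >= 3:
                    rows.append(
                        {"series": str(year), **persistence_residuals(counts).summary}
                    )
            pd.DataFrame(rows).to_csv(out / "residual_summary.csv", index=False)
            manifest["outputs"]["diagnostics"] = str(out / "diagnostics.json")
            manifest["outputs"]["residuals"] = str(out / "residuals.csv")
            manifest["outputs"]["residual_summary"] = str(out / "residual_summary.csv")

        stage = "fidelity"
        fid = classify_catalogue(catalogue)
        if "fidelity" in config.stages:
            fid.per_year.to_csv(out / "fidelity_summary.csv", index=False)
            fid.per_whale.to_csv(out / "fidelity_per_whale.csv", index=False)
            try:
                corr = fidelity_correlations(fid, summaries)
                corr.to_csv(out / "fidelity_correlations.csv", index=False)
                manifest["outputs"]["fidelity_correlations"] = str(
                    out / "fidelity_correlations.csv"
                )
            except ValueError as e:
                logger.warning("fidelity correlations skipped: %s", e)
            manifest["outputs"]["fidelity_summary"] = str(out / "fidelity_summary.csv")
            manifest["outputs"]["fidelity_per_whale"] = str(out / "fidelity_per_whale.csv")

        stage = "spatial"
        if "spatial" in config.stages:
            means = monthly_weighted_means(transects)
            means.to_csv(out / "weighted_means.csv", index=False)
            obs = [u for t in transects for u in t.units]
            features = []
            for month in sorted({o.timestamp.month for o in obs}):
                grid = monthly_heat_grid(obs, config.heat_cell_size_deg, month)
                features.extend(grid.to_geojson()["features"])
            (out / "heatgrid.geojson").write_text(
                json.dumps({"type": "FeatureCollection", "features": features})
            )
            manifest["outputs"]["weighted_means"] = str(out / "weighted_means.csv")
            manifest["outputs"]["heatgrid"] = str(out / "heatgrid.geojson")

        stage = "acoustics"
        if "acoustics" in config.stages and dataset is not None and dataset.calls:
            dist = class_distribution(dataset.calls)
            dist.to_csv(out / "call_summary.csv", index=False)
            model = DetectionModel(seed=config.seed)
            radii, radius_summary = detection_radius_series(dataset.noise, model)
            radii.rename_axis("timestamp").reset_index().to_csv(
                out / "detection_radii.csv", index=False
            )
            totals = {t.transect_id: t.whale_count for t in transects}
            joined = join_visual_acoustic(
                dataset.snapshots, dataset.calls, transect_totals=totals
            )
            joined.to_csv(out / "joined_context.csv", index=False)
            ctx = context_correlations(joined)
            ctx.to_csv(out / "context_correlations.csv", index=False)
            # mean per-whale hourly rate by number of whales in the bay
            rate_cols = [c for c in joined.columns if c.startswith("rate_")]
            rate_by_n = (
                joined[joined["whales_bay"] >= 1]
                .groupby("whales_bay")[rate_cols]
                .mean()
                .reset_index()
            )
            rate_by_n.to_csv(out / "rate_by_whale_number.csv", index=False)
            (out / "detection_summary.json").write_text(json.dumps(radius_summary, indent=1))
            manifest["outputs"].update(
                {
                    "call_summary": str(out / "call_summary.csv"),
                    "rate_by_whale_number": str(out / "rate_by_whale_number.csv"),
                    "detection_radii": str(out / "detection_radii.csv"),
                    "joined_context": str(out / "joined_context.csv"),
                    "context_correlations": str(out / "context_correlations.csv"),
                    "detection_summary": str(out / "detection_summary.json"),
                }
            )

        stage = "drivers"
        if "drivers" in config.stages:
            annual = pd.DataFrame([s.as_dict() for s in summaries])
            env = None
            if "env" in config.input_paths:
                env = pd.read_csv(config.input_paths["env"])
            table = build_lagged_features(
                annual[
                    ["year", "mean_whales", "max_whales", "peak_date_days",
                     "skewness", "excess_kurtosis"]
                ],
                fid.per_year[["year", "return_proportion"]]
                if not fid.per_year.empty
                else None,
                env,
                max_lag=config.max_lag,
            )
            rs, pv = spearman_screen(table)
            rs.to_csv(out / "spearman.csv")
            predictors = [
                c for c in table.columns
                if c != config.response and not c.endswith("_lag0")
            ]
            report = rank_variable_importance(table, config.response, predictors)
            (out / "importance.json").write_text(
                json.dumps(
                    {
                        "response": report.response,
                        "scores": report.scores.to_dict(),
                        "ranking": report.ranking,
                        "dropped_collinear": report.dropped_collinear,
                        "n_rows": report.n_rows,
                    },
                    indent=1,
                )
            )
            manifest["outputs"]["spearman"] = str(out / "spearman.csv")
            manifest["outputs"]["importance"] = str(out / "importance.json")
    except Exception:
        logger.error("pipeline failed at stage %r", stage)
        raise

    manifest["output_hashes"] = {
        k: _sha256(Path(p)) for k, p in manifest["outputs"].items()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
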