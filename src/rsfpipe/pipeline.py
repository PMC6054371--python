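"""End-to-end seasonal resource-selection pipeline.

``run_full`` drives QC -> seasonality -> used/available sampling -> AIC
competition over aggregation hypotheses -> winning-model fits -> selection
curves -> landscape prediction maps -> pairwise map similarity, from a
single declarative config with one master seed.  In synthetic mode the
input study (landscape, flowlines, GPS tracks with injected defects and a
dependent animal pair) is generated by :mod:`rsfpipe.synthetic`.
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

from . import synthetic
from .design import (
    DEFAULT_SEASONS,
    AggregationScheme,
    Season,
    UseAvailableTable,
    assign_seasons,
    build_design_tables,
    default_schemes,
)
from .flowlines import FlowlineSet, read_flowlines, write_flowlines
from .qc import QCReport, clean_tracks
from .predict import PredictionRaster, SelectionCurve, project_landscape, selection_curves
from .rasters import LandCoverRaster, read_ascii_grid, write_ascii_grid
from .rsf import FittedRSF, ModelRanking, compete_aggregations, wald_summary
from .similarity import SimilarityMatrix, pairwise_similarity
from .tracks import Track, read_tracks, write_tracks

log = logging.getLogger("rsfpipe")

__all__ = ["PipelineConfig", "SyntheticStudyConfig", "RunArtifacts",
           "validate_config", "run_full", "simulate_study", "default_true_models"]


def default_true_models() -> dict[str, synthetic.TrueModel]:
    """Per-season ground-truth selection models for the synthetic study.

    Chosen once to mirror the qualitative seasonal story of the system:
    wetlands attractive year-round, corn avoided early and selected once
    grown, rice peaking at harvest, flowline proximity attractive with a
    quadratic dip, and moderate between-individual heterogeneity
    (sigma_b = 0.5 on the logit scale).
    """
    base = dict(beta0=-0.2, flow_center=450.0, sigma_b=0.5)
    return {
        "early_growing": synthetic.TrueModel(
            beta_cover={"Corn": -0.8, "Rice": 0.3, "Soybeans": 0.4, "OtherCrop": 0.5,
                        "OtherNoncrop": 0.2, "Wetland": 1.0, "Water": 0.2},
            beta_flow_lin=-0.4, beta_flow_quad=0.2, **base),
        "late_growing": synthetic.TrueModel(
            beta_cover={"Corn": 0.9, "Rice": 0.2, "Soybeans": 0.3, "OtherCrop": 0.4,
                        "OtherNoncrop": 0.2, "Wetland": 1.0, "Water": 0.1},
            beta_flow_lin=-0.6, beta_flow_quad=0.3, **base),
        "harvest": synthetic.TrueModel(
            beta_cover={"Corn": 0.7, "Rice": 0.8, "Soybeans": 0.3, "OtherCrop": 0.0,
                        "OtherNoncrop": 0.1, "Wetland": 0.9, "Water": 0.1},
            beta_flow_lin=-0.7, beta_flow_quad=0.3, **base),
        "fallow": synthetic.TrueModel(
            beta_cover={"Corn": 0.5, "Rice": 0.1, "Soybeans": 0.2, "OtherCrop": 0.4,
                        "OtherNoncrop": 0.3, "Wetland": 1.1, "Water": 0.2},
            beta_flow_lin=-0.3, beta_flow_quad=0.2, **base),
    }


@dataclass
class SyntheticStudyConfig:
    """Scale and defect parameters of the synthetic GPS study."""

    n_rows: int = 300
    n_cols: int = 300
    cell_size: float = 30.0
    class_weights: dict[int, float] | None = None
    patch_scale: float = 4.0
    n_flowlines: int = 6
    n_individuals: int = 13
    home_radius: float = 1500.0
    interval_hours: float = 2.0
    spike_rate: float = 0.02
    offhour_rate: float = 0.02
    dependent_jitter_sd: float = 50.0
    n_late_start: int = 3  # individuals deployed after the first season began
    n_early_end: int = 2  # individuals whose collars die before the last season


@dataclass
class PipelineConfig:
    tracks_path: str | None = None
    raster_path: str | None = None
    flowlines_path: str | None = None
    synthetic: SyntheticStudyConfig | None = field(default_factory=SyntheticStudyConfig)
    seasons: list[Season] = field(default_factory=lambda: list(DEFAULT_SEASONS))
    schemes: list[AggregationScheme] = field(default_factory=default_schemes)
    v_max_kmh: float = 20.0
    trim_hours: float = 24.0
    bin_window_minutes: float = 5.0
    r_threshold: float = 0.5
    min_overlap: int = 30
    span_tolerance_days: float = 0.0
    buffer_radius: float = 100.0
    n_nodes: int = 15
    alpha: float = 0.05
    curve_crops: tuple[str, ...] = ("Corn", "Rice", "Soybeans")
    dist_quantiles: tuple[float, ...] = (0.0, 0.5, 1.0)
    curve_grid_size: int = 101
    master_seed: int = 42

    def to_dict(self) -> dict:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            if isinstance(o, dt.date):
                return o.isoformat()
            return o

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}


def validate_config(config: PipelineConfig) -> list[str]:
    """Human-readable findings; empty when the config is valid. Never raises."""
    findings: list[str] = []
    for name in ("v_max_kmh", "trim_hours", "bin_window_minutes", "r_threshold",
                 "buffer_radius", "n_nodes", "alpha"):
        if not getattr(config, name) > 0:
            findings.append(f"QC/model parameter {name} must be positive")
    if config.bin_window_minutes >= 30:
        findings.append("bin_window_minutes must be below 30")
    if config.min_overlap < 3:
        findings.append("min_overlap must be at least 3")
    ordered = sorted(config.seasons, key=lambda s: s.start_date)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_date <= a.end_date:
            findings.append(f"seasons {a.name} and {b.name} overlap")
    for scheme in config.schemes:
        refs = [c for c in scheme.categories if c == scheme.reference_category]
        if len(refs) != 1:
            findings.append(f"scheme {scheme.name} lacks exactly one reference category")
    if config.synthetic is None and not (
        config.tracks_path and config.raster_path and config.flowlines_path
    ):
        findings.append("either synthetic mode or all three input paths are required")
    return findings


def _spawn_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def simulate_study(
    config: PipelineConfig,
) -> tuple[list[Track], LandCoverRaster, FlowlineSet, dict[str, synthetic.TrueModel]]:
    """Generate the synthetic study: landscape, flowlines, corrupted tracks.

    Individuals move within fixed home discs; a few are deployed late or
    lose their collar early, so seasonal full-span inclusion varies as in
    real deployments.  One extra animal is a jittered duplicate of the
    first (a collared pair travelling together) that the independence
    screen should catch.  Speed spikes and off-hour timestamps are injected
    into every track.
    """
    sc = config.synthetic
    if sc is None:
        raise ValueError("simulate_study requires synthetic mode")
    seeds = _spawn_seeds(config.master_seed, 6 + 3 * sc.n_individuals)
    landscape = synthetic.generate_landscape(
        sc.n_rows, sc.n_cols, sc.cell_size, sc.class_weights, sc.patch_scale, seeds[0]
    )
    flows = synthetic.generate_flowlines(landscape.extent, sc.n_flowlines, seeds[1])
    true_models = default_true_models()
    scheme = next(s for s in config.schemes if s.name == "H1")
    rng = np.random.default_rng(seeds[2])
    xmin, ymin, xmax, ymax = landscape.extent
    r = sc.home_radius
    season_bounds = sorted(config.seasons, key=lambda s: s.start_date)
    # collars go on 48 h before the first season and come off 48 h after the
    # last, so the 24 h deployment/mortality trim never bites into a season
    margin = dt.timedelta(hours=48)
    study_start = dt.datetime.combine(season_bounds[0].start_date, dt.time(0, 0)) - margin
    study_end = dt.datetime.combine(season_bounds[-1].end_date, dt.time(22, 0)) + margin
    late_start = dt.datetime.combine(
        season_bounds[1].start_date if len(season_bounds) > 1 else season_bounds[0].start_date,
        dt.time(0, 0),
    ) - margin
    early_end = dt.datetime.combine(
        season_bounds[-2].end_date if len(season_bounds) > 1 else season_bounds[-1].end_date,
        dt.time(22, 0),
    ) + margin
    tracks: list[Track] = []
    for i in range(sc.n_individuals):
        cx = rng.uniform(xmin + r, xmax - r)
        cy = rng.uniform(ymin + r, ymax - r)
        start = late_start if i < sc.n_late_start else study_start
        end = early_end if i >= sc.n_individuals - sc.n_early_end else study_end
        n_fixes = int((end - start).total_seconds() / 3600 / sc.interval_hours) + 1
        # per-season preference: simulate each season's stretch with its truth
        parts = []
        t_cursor = start
        k = 0
        while t_cursor <= end:
            season = next(
                (s for s in season_bounds if s.start_date <= t_cursor.date() <= s.end_date),
                None,
            )
            if season is not None:
                seas_end = min(dt.datetime.combine(season.end_date, dt.time(22, 0)), end)
            else:
                # gap between/around seasons: flat preference until the next one
                upcoming = [s for s in season_bounds if s.start_date > t_cursor.date()]
                seas_end = (
                    min(dt.datetime.combine(upcoming[0].start_date, dt.time(0, 0))
                        - dt.timedelta(hours=sc.interval_hours), end)
                    if upcoming
                    else end
                )
            n_part = int((seas_end - t_cursor).total_seconds() / 3600 / sc.interval_hours) + 1
            model = true_models.get(season.name) if season else synthetic.TrueModel()
            model = model or synthetic.TrueModel()
            part = synthetic.simulate_individual(
                landscape, flows, model, scheme, (cx, cy), r, n_part,
                sc.interval_hours, t_cursor, seeds[6 + 3 * i] + k, f"pig{i:02d}",
                config.buffer_radius,
            )
            parts.append(part)
            t_cursor = t_cursor + dt.timedelta(hours=sc.interval_hours * n_part)
            k += 1
        t = np.concatenate([p.t for p in parts])
        x = np.concatenate([p.x for p in parts])
        y = np.concatenate([p.y for p in parts])
        tr = Track(f"pig{i:02d}", t, x, y,
                   deploy_time=np.datetime64(start),
                   end_time=np.datetime64(end))
        tracks.append(tr)
    companion = synthetic.make_dependent_pair(tracks[0], sc.dependent_jitter_sd, seeds[3])
    companion.deploy_time = tracks[0].deploy_time
    companion.end_time = tracks[0].end_time
    tracks.append(companion)
    tracks = [
        synthetic.corrupt_track(tr, sc.spike_rate, sc.offhour_rate, seeds[4] + 7 * j,
                                config.v_max_kmh)
        for j, tr in enumerate(tracks)
    ]
    return tracks, landscape, flows, true_models


@dataclass
class RunArtifacts:
    qc_report: QCReport
    tables: dict[str, UseAvailableTable]  # per scheme, all seasons pooled
    rankings: dict[str, ModelRanking]  # per season
    fits: dict[str, FittedRSF]  # winning fit per season
    all_fits: dict[str, dict[str, FittedRSF]]  # season -> scheme -> fit
    curves: dict[str, list[SelectionCurve]]
    maps: dict[str, PredictionRaster]
    similarity: SimilarityMatrix | None
    manifest: dict
    true_models: dict | None = None


def run_full(config: PipelineConfig, outdir: str | Path | None = None) -> RunArtifacts:
    """Execute the whole seasonal analysis; optionally write artifacts."""
    findings = validate_config(config)
    if findings:
        raise ValueError("invalid config: " + "; ".join(findings))
    seeds = _spawn_seeds(config.master_seed + 1, 4)
    true_models = None
    if config.synthetic is not None:
        log.info("simulating synthetic study")
        tracks, landscape, flows, true_models = simulate_study(config)
    else:
        tracks = read_tracks(config.tracks_path)
        landscape = read_ascii_grid(config.raster_path, categorical=True)
        flows = read_flowlines(config.flowlines_path)

    log.info("QC on %d tracks", len(tracks))
    clean, qc_report = clean_tracks(
        tracks, config.v_max_kmh, config.trim_hours, config.bin_window_minutes,
        config.r_threshold, config.min_overlap, seeds[0],
    )
    log.info("retained %d tracks after QC", len(clean))

    used_by_season: dict[str, list[Track]] = {s.name: [] for s in config.seasons}
    for tr in clean:
        parts = assign_seasons(tr, config.seasons, config.span_tolerance_days)
        for name, (sub, included) in parts.items():
            if included and len(sub) >= 3:
                used_by_season[name].append(sub)
    for name, lst in used_by_season.items():
        log.info("season %s: %d individuals", name, len(lst))
    used_by_season = {k: v for k, v in used_by_season.items() if len(v) >= 2}

    tables = build_design_tables(
        used_by_season, landscape, flows, config.schemes, config.buffer_radius, seeds[1]
    )

    rankings: dict[str, ModelRanking] = {}
    fits: dict[str, FittedRSF] = {}
    all_fits: dict[str, dict[str, FittedRSF]] = {}
    curves: dict[str, list[SelectionCurve]] = {}
    maps: dict[str, PredictionRaster] = {}
    scheme_by_name = {s.name: s for s in config.schemes}
    for season in used_by_season:
        ranking, season_fits = compete_aggregations(tables, season, config.n_nodes)
        rankings[season] = ranking
        all_fits[season] = season_fits
        winner = ranking.winner
        fit = season_fits[winner]
        fits[season] = fit
        log.info("season %s: AIC winner %s (decisive=%s)", season, winner, ranking.decisive)
        wet = f"prop_Wetland"
        if wet in fit.beta and all(f"prop_{c}" in fit.beta for c in config.curve_crops):
            curves[season] = selection_curves(
                fit, list(config.curve_crops), tables[winner],
                config.dist_quantiles, config.curve_grid_size,
            )
        maps[season] = project_landscape(
            fit, landscape, flows, scheme_by_name[winner], config.buffer_radius
        )

    sim = pairwise_similarity(maps) if len(maps) >= 2 else None

    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "master_seed": config.master_seed,
        "stage_seeds": seeds,
        "n_tracks_in": len(tracks),
        "n_tracks_retained": len(clean),
    }
    artifacts = RunArtifacts(
        qc_report, tables, rankings, fits, all_fits, curves, maps, sim, manifest,
        true_models,
    )
    if outdir is not None:
        _write_artifacts(artifacts, tracks, landscape, flows, Path(outdir))
    return artifacts


def _write_artifacts(art: RunArtifacts, tracks, landscape, flows, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_tracks(tracks, outdir / "tracks_raw.csv")
    write_ascii_grid(landscape, outdir / "landcover.asc")
    write_flowlines(flows, outdir / "flowlines.wkt")
    (outdir / "qc_report.json").write_text(json.dumps({
        "stage_counts": art.qc_report.stage_counts,
        "pairwise_r": art.qc_report.pairwise_r,
        "removed_individuals": art.qc_report.removed_individuals,
    }, indent=1, default=str))
    for name, table in art.tables.items():
        table.write(outdir / f"design_{name}.csv")
    for season, ranking in art.rankings.items():
        ranking.table.to_csv(outdir / f"ranking_{season}.csv", index=False)
    for season, fit in art.fits.items():
        fit.write(outdir / f"fit_{season}.json")
        wald_summary(fit).to_csv(outdir / f"wald_{season}.csv", index=False)
    for season, cvs in art.curves.items():
        rows = []
        for c in cvs:
            for P, p in zip(c.P, c.p_values):
                rows.append({"season": season, "crop": c.crop,
                             "distance_m": c.distance, "P": P, "p": p})
        pd.DataFrame(rows).to_csv(outdir / f"curves_{season}.csv", index=False)
    for season, m in art.maps.items():
        write_ascii_grid(m, outdir / f"prediction_{season}.asc")
    if art.similarity is not None:
        art.similarity.write(outdir / "similarity_matrix.tsv")
    (outdir / "manifest.json").write_text(json.dumps(art.manifest, indent=1, default=str))
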