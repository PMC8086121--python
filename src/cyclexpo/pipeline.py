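"""End-to-end pipeline: simulate -> segment -> describe -> fit -> hazard.

A :class:`PipelineConfig` fully determines a run; rerunning with the same
config and seed is bit-identical. Every output directory gets a manifest
recording the seed, a hash of the config, per-stage timings and a checksum
of each artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .descriptives import summarize_exposure
from .dose import (
    DoseCriteria,
    crossings_table,
    curves_to_frame,
    field_percentile_locations,
    hazard_curves,
    intake_threshold,
    noise_dose,
)
from .gammar import ModelSpec, build_design, coefficient_table, fit_gammar
from .segmentation import merge_streams, segment_one_minute, segments_to_csv
from .synthetic import (
    DAYS,
    PARTICIPANTS,
    ScenarioParams,
    default_scenario,
    make_road_network,
    network_to_geojson,
    simulate_sensor_records,
    simulate_trip,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Reproducible run configuration (YAML-serialisable, fully defaulted)."""

    seed: int = 1
    n_trips: int = 15
    minutes_per_trip: int = 200
    n_nodes: int = 120
    extent: float = 5000.0
    mean_speed_kmh: float = 17.0
    scenario_yaml: str | None = None  # override the default generating scenario
    spline_time: int = 8
    spline_space: int = 30
    ma_order: int = 3
    likelihood: str = "student"
    student_df: float = 4.0
    criteria: dict = field(default_factory=lambda: asdict(DoseCriteria()))
    hazard_road_types: tuple[str, ...] = ("residential", "tertiary", "primary")
    hazard_duration_min: int = 120
    hazard_clock_min: float = 180.0
    responses: tuple[str, ...] = ("noise_db", "no2_ugm3", "inhaled_ug")
    out_dir: str = "runs/latest"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("hazard_road_types", "responses"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def trip_roster(n_trips: int) -> list[tuple[str, str]]:
    """Assign trips to (participant, day) round-robin over the study roster."""
    return [
        (PARTICIPANTS[i % len(PARTICIPANTS)], DAYS[(i // len(PARTICIPANTS)) % len(DAYS)])
        for i in range(n_trips)
    ]


def simulate_study(
    scenario: ScenarioParams,
    seed: int,
    n_trips: int,
    minutes_per_trip: int,
    n_nodes: int = 120,
    mean_speed_kmh: float = 17.0,
    type_mix=None,
):
    """Simulate a full study: one network, ``n_trips`` rides with sensor
    streams, merged and segmented. Returns (network, tracks, segments).
    """
    if n_trips < 1:
        raise ValueError("need at least 1 trip")
    if minutes_per_trip < 1:
        raise ValueError("minutes_per_trip must be >= 1")
    rng = np.random.default_rng(seed)
    network = make_road_network(
        n_nodes, type_mix=type_mix, seed=int(rng.integers(2**31)), extent=scenario.extent
    )
    tracks, segments = [], []
    # Trip starts rotate through day slots so the 08:00-18:00 window is
    # covered evenly (no oversampling of midday clock times).
    slots = max(600 // max(minutes_per_trip, 1), 1)
    for i, (participant, day) in enumerate(trip_roster(n_trips)):
        start = min((i % slots) * minutes_per_trip, max(600 - minutes_per_trip, 0))
        trip_seed = int(rng.integers(2**31))
        trace = simulate_trip(
            network, minutes_per_trip, mean_speed_kmh, start_clock=start, seed=trip_seed
        )
        records = simulate_sensor_records(
            trace, scenario, participant, day, seed=int(rng.integers(2**31)), network=network
        )
        track = merge_streams(
            trace, records, trip_id=f"trip{i:03d}", participant=participant, day=day
        )
        tracks.append(track)
        segments.extend(segment_one_minute(track, network))
    return network, tracks, segments


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write artifacts plus a manifest.

    Any stage failure is recorded in the manifest (stage name and error)
    before the exception propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
        "files": {},
    }
    if config.n_trips < 1:
        manifest["stages"]["simulate"] = {"error": "n_trips must be >= 1"}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise ValueError("n_trips must be >= 1")

    scenario = (
        ScenarioParams.from_yaml(config.scenario_yaml)
        if config.scenario_yaml
        else default_scenario(extent=config.extent)
    )
    criteria = DoseCriteria(**config.criteria)

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            manifest["stages"][name] = {"error": repr(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
            raise
        dt = time.perf_counter() - t0
        manifest["stages"][name] = {"seconds": round(dt, 3)}
        logger.info("stage %-10s %6.2f s", name, dt)
        return result

    def _simulate():
        network, tracks, segments = simulate_study(
            scenario,
            config.seed,
            config.n_trips,
            config.minutes_per_trip,
            n_nodes=config.n_nodes,
            mean_speed_kmh=config.mean_speed_kmh,
        )
        network_to_geojson(network, out / "network.geojson")
        scenario.to_yaml(out / "scenario.yaml")
        return network, tracks, segments

    network, tracks, segments = run_stage("simulate", _simulate)

    run_stage("segment", lambda: segments_to_csv(segments, out / "segments.csv"))

    def _describe():
        summary = summarize_exposure(segments)
        summary.to_csv(out / "summary.csv")
        return summary

    run_stage("describe", _describe)

    def _fit():
        models = {}
        for resp in config.responses:
            spec = ModelSpec(
                response=resp,
                spline_time=config.spline_time,
                spline_space=config.spline_space,
                ma_order=config.ma_order,
                likelihood=config.likelihood,
                student_df=config.student_df,
            )
            models[resp] = fit_gammar(build_design(segments, spec))
        coefficient_table(models).to_csv(out / "coefficients.csv", index=False)
        return models

    models = run_stage("fit", _fit)

    def _hazard():
        xs = [s.midpoint_xy[0] for s in segments]
        ys = [s.midpoint_xy[1] for s in segments]
        locations = field_percentile_locations(
            scenario.spatial_field["no2_ugm3"],
            scenario.extent,
            qs=(25.0, 50.0, 75.0),
            labels=("low", "moderate", "high"),
            bounds=(min(xs), min(ys), max(xs), max(ys)),
        )
        mean_cov = {
            "humidity": float(np.mean([s.humidity_pct for s in segments])),
            "wind": float(np.mean([s.wind_kmh for s in segments])),
            "speed": float(np.mean([s.speed_kmh for s in segments])),
            "slope": float(np.mean([s.slope_pct for s in segments])),
            "intersections": float(np.mean([s.intersections for s in segments])),
        }
        curves = hazard_curves(
            models["noise_db"],
            models["no2_ugm3"],
            locations,
            config.hazard_road_types,
            config.hazard_duration_min,
            criteria,
            clock_min=config.hazard_clock_min,
            covariates=mean_cov,
        )
        curves_to_frame(curves).to_csv(out / "hazard_curves.csv", index=False)
        crossings_table(curves, criteria).to_csv(out / "crossings.csv", index=False)
        report = {
            "noise_dose_56.3dB_24h_pct": round(noise_dose([(56.3, 24.0)], criteria)),
            "noise_dose_75dB_40min_pct": round(noise_dose([(75.0, 40.0 / 60.0)], criteria)),
            "intake_threshold_pedestrian_ug": intake_threshold(
                criteria.no2_guideline, criteria.ve_pedestrian, criteria.guideline_duration
            ),
            "intake_threshold_cyclist_ug": intake_threshold(
                criteria.no2_guideline, criteria.ve_cyclist, criteria.guideline_duration
            ),
        }
        (out / "worked_examples.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        return curves

    run_stage("hazard", _hazard)

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def make_fixtures(seed: int = 7, out_dir: str | Path | None = None):
    """Small deterministic dataset for fast tests: one 40-node network and
    3 trips of 60 minutes (180 segment-minutes, well under 1,000).

    Returns (network, tracks, segments); writes network/segments files when
    ``out_dir`` is given. Regenerating with the same seed is byte-identical.
    """
    scenario = default_scenario()
    network, tracks, segments = simulate_study(
        scenario, seed=seed, n_trips=3, minutes_per_trip=60, n_nodes=40
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        network_to_geojson(network, out / "network.geojson")
        segments_to_csv(segments, out / "segments.csv")
    return network, tracks, segments
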