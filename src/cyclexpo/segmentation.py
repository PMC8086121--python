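"""Merging GPS and sensor streams and one-minute trip segmentation.

The analysis unit downstream is the one-minute trip segment: it carries the
minute's equivalent continuous sound level (L_Aeq,1min), NO2 concentration,
inhaled NO2 dose, minute ventilation, and the model covariates (road-type
time shares, speed, grade, intersections crossed, weather).

Decibel arithmetic is done on the energy scale throughout (3 dB(A) exchange
rate): levels are averaged as 10*log10(mean(10^(L/10))).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import (
    GpsFix,
    ROAD_TYPES,
    RoadNetwork,
    SensorRecord,
    trace_minute_covariates,
)

logger = logging.getLogger(__name__)

#: NO2 molar-mass conversion at 25 degC, 1013 hPa: 1 ppm = 1880 ug/m3.
UGM3_PER_PPM = 1880.0

#: A partial minute with at least this many seconds of fixes is kept (flagged).
MIN_PARTIAL_SECONDS = 30


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class MergedTrack:
    """A trip's 1 Hz fixes, each joined to the sensor record covering its
    minute. Fixes are time-sorted; every fix maps to exactly one record."""

    trip_id: str
    fixes: list[GpsFix]
    records: dict[int, SensorRecord]
    participant: str | None = None
    day: str | None = None
    n_dropped: int = 0

    def duration_seconds(self) -> int:
        return len(self.fixes)


@dataclass
class TripSegment:
    """One minute of riding: exposures, inhaled dose and model covariates."""

    trip_id: str
    segment_index: int
    laeq_1min: float
    no2_ugm3: float
    inhaled_ug: float
    ve_lmin: float
    minutes_by_road_type: dict[str, float]
    speed_kmh: float
    slope_pct: float
    intersections: int
    humidity_pct: float
    wind_kmh: float
    midpoint_xy: tuple[float, float]
    clock_min: float
    participant: str | None = None
    day: str | None = None
    partial: bool = False

    def __post_init__(self) -> None:
        shares = self.minutes_by_road_type
        if any(v < 0 for v in shares.values()):
            raise ValueError("road-type shares must be >= 0")
        if abs(sum(shares.values()) - 1.0) > 1e-9:
            raise ValueError("road-type shares must sum to 1")
        if abs(self.inhaled_ug - (self.ve_lmin * 0.001) * self.no2_ugm3) > 1e-9:
            raise ValueError("inhaled_ug must equal (VE x 0.001) x NO2")
        if not np.isfinite(self.laeq_1min):
            raise ValueError("laeq_1min must be finite")


# ---------------------------------------------------------------------------
# Decibel arithmetic and the inhaled-dose identity
# ---------------------------------------------------------------------------


def laeq_aggregate(levels: Sequence[float], weights: Sequence[float] | None = None) -> float:
    """Energy-weighted equivalent continuous level.

    ``10*log10(sum(w*10^(L/10)) / sum(w))`` with duration weights ``w``
    (equal when omitted). This is the 3 dB(A)-exchange-rate aggregation: a
    3.0103 dB increase doubles the acoustic energy.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("cannot aggregate an empty level series")
    if weights is None:
        w = np.ones_like(levels)
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != levels.size or np.any(w <= 0):
            raise ValueError("weights must be positive and match levels")
    return float(10.0 * np.log10(np.sum(w * 10.0 ** (levels / 10.0)) / np.sum(w)))


def db_mean_sd(levels: Sequence[float]) -> tuple[float, float]:
    """Energy-scale mean and dispersion of a decibel series.

    The mean is ``laeq_aggregate`` with equal weights. Dispersion is computed
    on the linear energy scale and re-expressed in dB as the level increment
    of one energy-SD above the energy mean, ``10*log10(1 + sd_E/mean_E)``, so
    a constant series has dispersion exactly 0.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("empty level series")
    energy = 10.0 ** (levels / 10.0)
    mean_e = float(np.mean(energy))
    sd_e = float(np.std(energy, ddof=1)) if levels.size > 1 else 0.0
    return 10.0 * np.log10(mean_e), float(10.0 * np.log10(1.0 + sd_e / mean_e))


def inhaled_dose(ve_lmin: float, no2_ugm3: float) -> float:
    """Inhaled NO2 per minute: ``(VE x 0.001) x NO2`` in ug, with minute
    ventilation VE in L/min and concentration in ug/m3."""
    if ve_lmin < 0 or no2_ugm3 < 0:
        raise ValueError("ventilation and concentration must be >= 0")
    return (ve_lmin * 0.001) * no2_ugm3


def ppm_to_ugm3(ppm: float) -> float:
    """Convert an NO2 mixing ratio in ppm to ug/m3 (25 degC, 1013 hPa)."""
    return ppm * UGM3_PER_PPM


def ugm3_to_ppm(ugm3: float) -> float:
    return ugm3 / UGM3_PER_PPM


# ---------------------------------------------------------------------------
# Merge and segmentation
# ---------------------------------------------------------------------------


def merge_streams(
    trace: Sequence[GpsFix],
    records: Sequence[SensorRecord],
    trip_id: str = "trip",
    participant: str | None = None,
    day: str | None = None,
) -> MergedTrack:
    """Join 1 Hz fixes to the sensor record of their containing minute.

    Fixes whose minute has no sensor record are dropped (the count is
    logged). Input order does not matter; the result is time-sorted.
    """
    rec_by_minute = {r.timestamp_minute: r for r in records}
    fixes = sorted(trace, key=lambda f: f.timestamp)
    kept = [f for f in fixes if int(f.timestamp // 60) in rec_by_minute]
    dropped = len(fixes) - len(kept)
    if dropped:
        logger.info("merge_streams: dropped %d fixes outside sensor coverage", dropped)
    if not kept:
        raise ValueError("GPS trace and sensor records do not overlap in time")
    used = {int(f.timestamp // 60) for f in kept}
    return MergedTrack(
        trip_id=trip_id,
        fixes=kept,
        records={m: rec_by_minute[m] for m in sorted(used)},
        participant=participant,
        day=day,
        n_dropped=dropped,
    )


def segment_one_minute(track: MergedTrack, network: RoadNetwork) -> list[TripSegment]:
    """Divide a merged track into one-minute segments with aggregated
    covariates.

    Each complete sensor minute yields one segment; a partial minute with at
    least 30 s of fixes is kept and flagged, shorter ones are discarded. Road
    type shares come from 1 Hz fix counts (time shares), the grade is the
    fix-weighted mean edge grade, and intersections are distinct degree->=3
    network nodes traversed within the minute.
    """
    if track.duration_seconds() < MIN_PARTIAL_SECONDS:
        warnings.warn("track shorter than 30 s: no segments produced")
        return []
    cov = trace_minute_covariates(track.fixes, network)
    segments: list[TripSegment] = []
    idx = 0
    for row in cov.itertuples(index=False):
        minute = int(row.minute)
        if row.n_fixes < MIN_PARTIAL_SECONDS:
            continue
        rec = track.records[minute]
        shares = {t: float(getattr(row, f"share_{t}")) for t in ROAD_TYPES}
        segments.append(
            TripSegment(
                trip_id=track.trip_id,
                segment_index=idx,
                laeq_1min=rec.laeq_1min,
                no2_ugm3=rec.no2_ugm3,
                inhaled_ug=inhaled_dose(rec.ve_lmin, rec.no2_ugm3),
                ve_lmin=rec.ve_lmin,
                minutes_by_road_type=shares,
                speed_kmh=float(row.speed),
                slope_pct=float(row.slope),
                intersections=int(row.intersections),
                humidity_pct=rec.humidity_pct,
                wind_kmh=rec.wind_kmh,
                midpoint_xy=(float(row.mid_x), float(row.mid_y)),
                clock_min=float(row.clock_min),
                participant=track.participant,
                day=track.day,
                partial=row.n_fixes < 60,
            )
        )
        idx += 1
    return segments


# ---------------------------------------------------------------------------
# Tabular / GeoJSON output
# ---------------------------------------------------------------------------


def segments_to_frame(segments: Sequence[TripSegment]) -> pd.DataFrame:
    """Flatten segments into a DataFrame (one share column per road class)."""
    rows = []
    for s in segments:
        row = {
            "trip_id": s.trip_id,
            "segment_index": s.segment_index,
            "laeq_1min": s.laeq_1min,
            "no2_ugm3": s.no2_ugm3,
            "inhaled_ug": s.inhaled_ug,
            "ve_lmin": s.ve_lmin,
            "speed_kmh": s.speed_kmh,
            "slope_pct": s.slope_pct,
            "intersections": s.intersections,
            "humidity_pct": s.humidity_pct,
            "wind_kmh": s.wind_kmh,
            "mid_x": s.midpoint_xy[0],
            "mid_y": s.midpoint_xy[1],
            "clock_min": s.clock_min,
            "participant": s.participant,
            "day": s.day,
            "partial": s.partial,
        }
        row.update({f"share_{t}": s.minutes_by_road_type[t] for t in ROAD_TYPES})
        rows.append(row)
    return pd.DataFrame(rows)


def segments_to_csv(segments: Sequence[TripSegment], path) -> None:
    segments_to_frame(segments).to_csv(path, index=False)


def segments_from_csv(path) -> list[TripSegment]:
    df = pd.read_csv(path)
    out = []
    for r in df.itertuples(index=False):
        out.append(
            TripSegment(
                trip_id=str(r.trip_id),
                segment_index=int(r.segment_index),
                laeq_1min=float(r.laeq_1min),
                no2_ugm3=float(r.no2_ugm3),
                inhaled_ug=float(r.inhaled_ug),
                ve_lmin=float(r.ve_lmin),
                minutes_by_road_type={t: float(getattr(r, f"share_{t}")) for t in ROAD_TYPES},
                speed_kmh=float(r.speed_kmh),
                slope_pct=float(r.slope_pct),
                intersections=int(r.intersections),
                humidity_pct=float(r.humidity_pct),
                wind_kmh=float(r.wind_kmh),
                midpoint_xy=(float(r.mid_x), float(r.mid_y)),
                clock_min=float(r.clock_min),
                participant=None if pd.isna(r.participant) else str(r.participant),
                day=None if pd.isna(r.day) else str(r.day),
                partial=bool(r.partial),
            )
        )
    return out


def segments_to_geojson(track: MergedTrack, segments: Sequence[TripSegment], path) -> None:
    """Write one LineString feature per segment (the minute's 1 Hz polyline)
    with all segment attributes as properties."""
    by_minute: dict[int, list[GpsFix]] = {}
    for f in track.fixes:
        by_minute.setdefault(int(f.timestamp // 60), []).append(f)
    minutes = sorted(m for m, fx in by_minute.items() if len(fx) >= MIN_PARTIAL_SECONDS)
    features = []
    for seg, minute in zip(segments, minutes):
        coords = [[f.x, f.y] for f in by_minute[minute]]
        props = {
            k: v
            for k, v in seg.__dict__.items()
            if k not in ("minutes_by_road_type", "midpoint_xy")
        }
        props.update({f"share_{t}": seg.minutes_by_road_type[t] for t in ROAD_TYPES})
        features.append(
            {"type": "Feature", "geometry": {"type": "LineString", "coordinates": coords}, "properties": props}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
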