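"""Descriptive exposure statistics: percentiles, dB-aware moments, the
within-trip autocorrelation index, and distance-band Moran's I.

These reproduce the descriptive machinery of mobile exposure studies: noise
is summarised on the energy scale, the temporal ACF index never crosses trip
boundaries, and spatial autocorrelation is scanned over distance bands with
binary neighbour weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .segmentation import TripSegment, db_mean_sd, segments_to_frame

PERCENTILES = (1, 5, 10, 25, 50, 75, 90, 95, 99)

_RESPONSE_COLUMNS = {
    "noise_db": "laeq_1min",
    "no2_ugm3": "no2_ugm3",
    "inhaled_ug": "inhaled_ug",
}


@dataclass
class SummaryTable:
    """Per-response descriptive summary (one row per statistic)."""

    table: pd.DataFrame  # index: statistic name; columns: responses
    morans_distance: dict[str, float]

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def percentile(values: Sequence[float], q: float) -> float:
    """Percentile by linear interpolation between order statistics."""
    return float(np.percentile(np.asarray(values, dtype=float), q, method="linear"))


def acf_index(
    values: Sequence[float], k: int, trip_ids: Sequence | None = None
) -> float:
    """Lag-k autocorrelation of an ordered per-trip series.

    Computed within each trip (Pearson correlation of the series with its
    lag-k shift) and pooled across trips as the average weighted by the
    number of lagged pairs, so trip boundaries contribute nothing.

    Raises ``ValueError`` for a constant series (undefined correlation).
    """
    x = np.asarray(values, dtype=float)
    if trip_ids is None:
        groups = [x]
    else:
        tid = np.asarray(trip_ids)
        # preserve encounter order of trips
        _, first = np.unique(tid, return_index=True)
        order = tid[np.sort(first)]
        groups = [x[tid == t] for t in order]
    num, den = 0.0, 0.0
    for g in groups:
        if len(g) <= k:
            continue
        a, b = g[:-k], g[k:]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            raise ValueError("constant series within a trip: ACF undefined")
        r = float(np.corrcoef(a, b)[0, 1])
        w = len(g) - k
        num += w * r
        den += w
    if den == 0:
        raise ValueError(f"no trip longer than lag {k}")
    return num / den


def morans_i(
    segments: Sequence[TripSegment] | np.ndarray,
    values: str | Sequence[float],
    d: float,
    coords: np.ndarray | None = None,
) -> float:
    """Moran's I with binary distance-band weights.

    Neighbours of segment i are all segments j with
    ``0 < dist(midpoint_i, midpoint_j) <= d``. The statistic is
    ``I = (n / W) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2)`` with
    ``W = sum_ij w_ij`` and z the centred values.

    ``segments`` may be a list of :class:`TripSegment` (with ``values`` a
    response column name) or ignored when explicit ``values``/``coords``
    arrays are given.
    """
    if isinstance(values, str):
        df = segments_to_frame(segments)
        x = df[_RESPONSE_COLUMNS.get(values, values)].to_numpy(dtype=float)
        pts = df[["mid_x", "mid_y"]].to_numpy(dtype=float)
    else:
        x = np.asarray(values, dtype=float)
        if coords is not None:
            pts = np.asarray(coords, dtype=float)
        else:
            pts = np.array([s.midpoint_xy for s in segments], dtype=float)
    n = len(x)
    if d <= 0:
        raise ValueError("distance band d must be > 0")
    if n < 3:
        raise ValueError("need at least 3 segments")
    z = x - x.mean()
    ss = float(np.sum(z**2))
    if ss == 0:
        raise ValueError("zero variance: Moran's I undefined")
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=d, output_type="ndarray")
    if len(pairs):
        dist = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
        pairs = pairs[dist > 0]  # coincident points are not neighbours
    if len(pairs) == 0:
        raise ValueError("no neighbour pairs within distance d")
    cross = float(np.sum(z[pairs[:, 0]] * z[pairs[:, 1]]))
    w_total = 2.0 * len(pairs)  # symmetric binary weights
    return (n / w_total) * (2.0 * cross) / ss


def morans_i_scan(
    segments: Sequence[TripSegment],
    values: str | Sequence[float],
    d_min: float = 50.0,
    d_max: float = 500.0,
    step: float = 50.0,
    coords: np.ndarray | None = None,
) -> tuple[float, float]:
    """Evaluate Moran's I over the distance-band grid and return the maximum
    and the band where it occurs (only the highest value is reported)."""
    best_i, best_d = -np.inf, None
    grid = np.arange(d_min, d_max + step / 2, step)
    for d in grid:
        try:
            i = morans_i(segments, values, float(d), coords=coords)
        except ValueError:
            continue
        if i > best_i:
            best_i, best_d = i, float(d)
    if best_d is None:
        raise ValueError("Moran's I undefined on the whole distance grid")
    return best_i, best_d


def summarize_exposure(segments: Sequence[TripSegment]) -> SummaryTable:
    """Descriptive summary of the three responses over all segments.

    Percentiles use linear interpolation. The noise mean/SD are energy-scale
    decibel statistics (:func:`cyclexpo.segmentation.db_mean_sd`); NO2 and
    inhaled dose use arithmetic moments. The ACF index is the within-trip
    lag-1 and lag-2 autocorrelation; Moran's I is the distance-band-scan
    maximum with the band it occurs at.
    """
    if len(segments) < 2:
        raise ValueError("need at least 2 segments to summarise")
    df = segments_to_frame(segments)
    stats: dict[str, dict[str, float]] = {}
    morans_d: dict[str, float] = {}
    for resp, col in _RESPONSE_COLUMNS.items():
        x = df[col].to_numpy(dtype=float)
        row: dict[str, float] = {"n": float(len(x))}
        for q in PERCENTILES:
            row[f"p{q}"] = percentile(x, q)
        if resp == "noise_db":
            row["mean"], row["sd"] = db_mean_sd(x)
        else:
            row["mean"], row["sd"] = float(x.mean()), float(x.std(ddof=1))
        tid = df["trip_id"].to_numpy()
        for k in (1, 2):
            try:
                row[f"acf_k{k}"] = acf_index(x, k, trip_ids=tid)
            except ValueError:
                row[f"acf_k{k}"] = np.nan
        try:
            best_i, best_d = morans_i_scan(segments, resp)
            row["morans_i"] = best_i
            morans_d[resp] = best_d
        except ValueError:
            row["morans_i"] = np.nan
            morans_d[resp] = np.nan
        stats[resp] = row
    table = pd.DataFrame(stats)
    table.index.name = "statistic"
    # percentiles must be nondecreasing; guard against pathological inputs
    for resp in stats:
        p = table.loc[[f"p{q}" for q in PERCENTILES], resp].to_numpy()
        if np.any(np.diff(p) < -1e-12):
            raise AssertionError("percentiles are not nondecreasing")
    return SummaryTable(table=table, morans_distance=morans_d)
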