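"""Noise dose, WHO intake thresholds and minutes-to-hazard curves.

Noise dose expresses cumulative exposure as a percentage of a criterion
exposure (criterion level ``L_c`` held for criterion duration ``T_c``):

    D = (100 / T_c) * sum_i T_i * 10^((L_i - L_c) / q)

with ``q = 10`` for a 3 dB exchange rate (a 3.0103 dB(A) increase doubles
the dose accumulation rate). The default criterion is 59.3 dB(A) over 24 h,
the WHO day-evening-night level associated with a 5% excess risk of
ischaemic heart disease.

NO2 intake thresholds convert the WHO 1-hour guideline (200 ug/m3) into an
inhaled mass via a minute-ventilation rate: 180 ug for a pedestrian
(15 L/min) and 420 ug for an urban cyclist (35 L/min).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gammar import FittedModel, predict_exposure


@dataclass
class DoseCriteria:
    """Criterion parameters for noise dose and NO2 intake thresholds."""

    L_c: float = 59.3  # criterion sound level, dB(A)
    T_c: float = 24.0  # criterion duration, hours
    q: float = 10.0  # exchange-rate parameter (10 <-> 3 dB exchange)
    no2_guideline: float = 200.0  # ug/m3, 1-hour guideline
    guideline_duration: float = 60.0  # minutes
    ve_pedestrian: float = 15.0  # L/min
    ve_cyclist: float = 35.0  # L/min

    def __post_init__(self) -> None:
        vals = (
            self.L_c,
            self.T_c,
            self.q,
            self.no2_guideline,
            self.guideline_duration,
            self.ve_pedestrian,
            self.ve_cyclist,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all dose criteria must be positive")


@dataclass
class DoseCurve:
    """Cumulative noise dose (%) or NO2 intake (ug) versus riding minutes."""

    response: str  # "noise_dose_pct" | "no2_intake_ug"
    times: np.ndarray  # minutes
    values: np.ndarray
    threshold: float
    crossing_min: float | None
    road_type: str
    location_label: str

    def __post_init__(self) -> None:
        if np.any(np.diff(self.values) < -1e-12):
            raise ValueError("dose curve must be nondecreasing in time")


def noise_dose(
    levels: Sequence[tuple[float, float]], criteria: DoseCriteria | None = None
) -> float:
    """Total noise dose (%) over exposure intervals ``(L_i dB(A), T_i hours)``.

    Additive over any partition of the exposure; equals exactly 100% for the
    criterion level held for the criterion duration.
    """
    criteria = criteria or DoseCriteria()
    if not len(levels):
        raise ValueError("empty exposure list")
    dose = 0.0
    for L_i, T_i in levels:
        if T_i <= 0:
            raise ValueError("interval durations must be > 0")
        dose += T_i * 10.0 ** ((L_i - criteria.L_c) / criteria.q)
    return 100.0 / criteria.T_c * dose


def intake_threshold(guideline: float, ve: float, duration: float) -> float:
    """Inhaled-mass threshold (ug): guideline concentration x (VE x 0.001) x
    duration in minutes. Zero guideline gives a zero threshold."""
    if guideline < 0 or ve <= 0 or duration <= 0:
        raise ValueError("ve and duration must be positive, guideline >= 0")
    return guideline * (ve * 0.001) * duration


def cumulative_intake(conc_series: Sequence[float], ve: float) -> np.ndarray:
    """Running inhaled NO2 mass (ug) over per-minute concentrations."""
    conc = np.asarray(conc_series, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    return np.cumsum((ve * 0.001) * conc)


def minutes_to_noise_dose(
    level: float, criteria: DoseCriteria | None = None, target_pct: float = 100.0
) -> float:
    """Minutes of constant exposure at ``level`` dB(A) to reach
    ``target_pct`` dose — the closed-form inversion of :func:`noise_dose`:

        minutes = (target/100) * T_c * 60 * 10^((L_c - level) / q)
    """
    criteria = criteria or DoseCriteria()
    if not np.isfinite(level):
        raise ValueError("level must be finite")
    return (target_pct / 100.0) * criteria.T_c * 60.0 * 10.0 ** (
        (criteria.L_c - level) / criteria.q
    )


def minutes_to_intake(conc: float, ve: float, threshold: float) -> float:
    """Minutes of constant concentration to reach an inhaled-mass threshold."""
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    if conc == 0:
        return float("inf")
    return threshold / ((ve * 0.001) * conc)


def _first_crossing(times: np.ndarray, values: np.ndarray, threshold: float) -> float | None:
    """First time the curve reaches the threshold, linearly interpolated
    between minute ticks and reported to 0.1 min."""
    idx = np.nonzero(values >= threshold)[0]
    if len(idx) == 0:
        return None
    i = idx[0]
    if i == 0:
        prev_t, prev_v = 0.0, 0.0
    else:
        prev_t, prev_v = times[i - 1], values[i - 1]
    if values[i] == prev_v:
        return round(float(times[i]), 1)
    t = prev_t + (threshold - prev_v) / (values[i] - prev_v) * (times[i] - prev_t)
    return round(float(t), 1)


def hazard_curves(
    model_noise: FittedModel,
    model_no2: FittedModel,
    locations: Sequence[tuple[float, float, str]],
    road_types: Sequence[str],
    duration_min: int,
    criteria: DoseCriteria | None = None,
    clock_min: float = 180.0,
    covariates: dict | None = None,
) -> list[DoseCurve]:
    """Cumulative dose/intake curves by location and road type.

    For each (location, road type) the fitted models predict a constant
    per-minute noise level and NO2 concentration (random effects excluded;
    covariates held at supplied or zero values; one full minute on the given
    road type; clock time defaults to 11:00). The noise dose accumulates per
    Eq.-style energy weighting; NO2 intake accumulates at the cyclist
    ventilation rate. Crossings of 100% dose and of the pedestrian and
    cyclist intake thresholds are marked.
    """
    criteria = criteria or DoseCriteria()
    if not (model_noise.converged and model_no2.converged):
        raise ValueError("both models must have converged")
    if duration_min == 0:
        return []
    base = dict(covariates or {})
    thr_cyc = intake_threshold(
        criteria.no2_guideline, criteria.ve_cyclist, criteria.guideline_duration
    )
    times = np.arange(1, duration_min + 1, dtype=float)
    curves: list[DoseCurve] = []
    for x, y, label in locations:
        for rt in road_types:
            cov = dict(base)
            for k in ("trunk_motorway", "primary", "secondary", "tertiary", "unclassified_service"):
                cov[k] = 0.0
            if rt != "residential":
                cov[rt] = 1.0
            level = predict_exposure(model_noise, cov, (x, y), clock_min)
            conc = max(predict_exposure(model_no2, cov, (x, y), clock_min), 0.0)
            per_min_dose = noise_dose([(level, 1.0 / 60.0)], criteria)
            dose_vals = per_min_dose * times
            intake_vals = cumulative_intake(np.full(duration_min, conc), criteria.ve_cyclist)
            curves.append(
                DoseCurve(
                    response="noise_dose_pct",
                    times=times,
                    values=dose_vals,
                    threshold=100.0,
                    crossing_min=_first_crossing(times, dose_vals, 100.0),
                    road_type=rt,
                    location_label=label,
                )
            )
            curves.append(
                DoseCurve(
                    response="no2_intake_ug",
                    times=times,
                    values=intake_vals,
                    threshold=thr_cyc,
                    crossing_min=_first_crossing(times, intake_vals, thr_cyc),
                    road_type=rt,
                    location_label=label,
                )
            )
    return curves


def crossings_table(curves: Sequence[DoseCurve], criteria: DoseCriteria | None = None) -> pd.DataFrame:
    """Summary of threshold crossings, including the pedestrian-rate NO2
    threshold for comparison."""
    criteria = criteria or DoseCriteria()
    thr_ped = intake_threshold(
        criteria.no2_guideline, criteria.ve_pedestrian, criteria.guideline_duration
    )
    rows = []
    for c in curves:
        row = {
            "location": c.location_label,
            "road_type": c.road_type,
            "response": c.response,
            "threshold": c.threshold,
            "crossing_min": c.crossing_min,
            "value_60min": float(np.interp(60.0, c.times, c.values)) if len(c.times) else np.nan,
        }
        if c.response == "no2_intake_ug":
            row["crossing_min_pedestrian_threshold"] = _first_crossing(c.times, c.values, thr_ped)
        rows.append(row)
    return pd.DataFrame(rows)


def curves_to_frame(curves: Sequence[DoseCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for t, v in zip(c.times, c.values):
            rows.append(
                {
                    "location": c.location_label,
                    "road_type": c.road_type,
                    "response": c.response,
                    "minute": t,
                    "value": v,
                }
            )
    return pd.DataFrame(rows)


def plot_dose_curves(curves: Sequence[DoseCurve], path) -> None:
    """Plot cumulative noise-dose and NO2-intake curves by location and road
    type, with their thresholds, to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    responses = ("noise_dose_pct", "no2_intake_ug")
    labels = {"noise_dose_pct": "noise dose (%)", "no2_intake_ug": "NO2 intake (ug)"}
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    for ax, resp in zip(axes, responses):
        for c in curves:
            if c.response != resp:
                continue
            ax.plot(c.times, c.values, label=f"{c.location_label}/{c.road_type}")
        thr = next((c.threshold for c in curves if c.response == resp), None)
        if thr is not None:
            ax.axhline(thr, color="k", ls="--", lw=0.8)
        ax.set_xlabel("minutes of riding")
        ax.set_ylabel(labels[resp])
    handles, leg_labels = axes[0].get_legend_handles_labels()
    if handles:
        fig.legend(handles, leg_labels, loc="lower center", ncol=3, fontsize=7)
    fig.tight_layout(rect=(0, 0.12, 1, 1))
    fig.savefig(path, dpi=120)
    plt.close(fig)


def field_percentile_locations(
    field_fn, extent: float, qs: Sequence[float] = (25.0, 50.0, 75.0), labels: Sequence[str] | None = None,
    n_grid: int = 61, bounds: tuple[float, float, float, float] | None = None,
) -> list[tuple[float, float, str]]:
    """Pick representative (x, y) locations where a spatial field sits at
    given percentiles of its distribution — stand-ins for 'low', 'moderate'
    and 'high' exposure areas. ``bounds`` (x0, y0, x1, y1) restricts the
    search to an observed region so predictions there do not extrapolate."""
    if bounds is None:
        bounds = (0.0, 0.0, extent, extent)
    x0, y0, x1, y1 = bounds
    gx, gy = np.meshgrid(np.linspace(x0, x1, n_grid), np.linspace(y0, y1, n_grid))
    vals = np.asarray(field_fn(gx, gy))
    flat = vals.ravel()
    if labels is None:
        labels = [f"p{int(q)}" for q in qs]
    out = []
    for q, lab in zip(qs, labels):
        target = np.percentile(flat, q)
        idx = int(np.argmin(np.abs(flat - target)))
        out.append((float(gx.ravel()[idx]), float(gy.ravel()[idx]), lab))
    return out
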