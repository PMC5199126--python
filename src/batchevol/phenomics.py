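"""Fitness-component extraction from plate-reader growth curves.

A growth curve (optical density every ~20 min over ~72 h) is reduced to
three fitness components:

* **doubling time** — ``ln 2`` over the maximal slope of log population
  size across a sliding window restricted to readings above a detection
  threshold;
* **lag** — the time at which the tangent at the maximal-slope window
  intersects the log inoculum level.  The inoculum of a microplate well
  (~1e5 cells) sits below the instrument's resolution, so the reference
  level is the detection-floor parameter ``inoculum_od``; lag estimates
  shift by ``tau * log2(n0 / inoculum_od)`` if the true inoculum differs;
* **efficiency** — total gain in population size (final minus initial).

Curves are preprocessed by running-median smoothing, subtraction of the
background level (mean of the first three readings) and an optional
monotone OD-to-population-size calibration (identity by default).
Components are log2-transformed and, for cross-plate comparisons,
expressed relative to founder-control wells with a sign convention under
which positive values always indicate adaptation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

__all__ = [
    "GrowthCurve",
    "FitnessComponents",
    "preprocess_curve",
    "extract_fitness_components",
    "normalize_to_founder",
    "read_plate",
    "analyze_plate",
]


@dataclass
class GrowthCurve:
    """A time-OD series from one well, optionally with a calibration
    mapping OD to population-size units."""

    times: np.ndarray
    od: np.ndarray
    well_id: str = ""
    calibration: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape:
            raise ValueError("times and od must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.od)):
            raise ValueError("od readings must be finite")


@dataclass
class FitnessComponents:
    """Extracted (lag, doubling time, efficiency) with log2 transforms.

    ``lag`` and ``doubling_time`` are in hours, ``efficiency`` in OD
    units.  ``no_growth`` flags wells whose OD gain never exceeded the
    detection threshold; their components are NaN.
    """

    lag: float
    doubling_time: float
    efficiency: float
    no_growth: bool = False

    @property
    def log2_lag(self) -> float:
        return math.log2(self.lag) if self.lag > 0 else math.nan

    @property
    def log2_doubling(self) -> float:
        return math.log2(self.doubling_time) if self.doubling_time > 0 else math.nan

    @property
    def log2_efficiency(self) -> float:
        return math.log2(self.efficiency) if self.efficiency > 0 else math.nan


def preprocess_curve(
    raw: GrowthCurve,
    smoothing_window: int = 3,
    calibration: Callable | None = None,
    baseline_points: int = 3,
    floor: float = 1e-4,
) -> GrowthCurve:
    """Smooth, background-subtract and calibrate a raw curve.

    Running-median smoothing (window ``smoothing_window``) removes isolated
    aberrant readings; the background is the mean of the first
    ``baseline_points`` smoothed readings and the corrected signal is
    floored at a small positive value so log transforms stay defined.
    """
    if len(raw.od) < smoothing_window:
        raise ValueError(
            f"curve has {len(raw.od)} points, fewer than the smoothing window"
        )
    smoothed = median_filter(raw.od, size=smoothing_window, mode="nearest")
    baseline = float(np.mean(smoothed[:baseline_points]))
    corrected = np.maximum(smoothed - baseline, floor)
    cal = calibration if calibration is not None else raw.calibration
    if cal is not None:
        corrected = np.asarray(cal(corrected), dtype=float)
    return GrowthCurve(raw.times, corrected, raw.well_id)


def extract_fitness_components(
    curve: GrowthCurve,
    slope_window: int = 9,
    min_od: float = 0.04,
    inoculum_od: float = 1e-3,
    detection_threshold: float = 0.02,
    saturation_correction: bool = True,
    saturation_frac: float = 0.8,
) -> FitnessComponents:
    """Extract lag, doubling time and efficiency from a preprocessed curve.

    The maximal log-slope is the largest OLS slope of ``ln(size)`` over
    ``slope_window`` consecutive points whose size exceeds ``min_od``
    (below which log readings are noise-dominated).  With
    ``saturation_correction`` (the default) the slope is refined over the
    whole rise up to ``saturation_frac`` of the plateau: logistic growth
    obeys ``d ln n / dt = r - (r/K) n`` exactly, so weighted least squares
    of ``ln n`` on time and the running integral of ``n`` recovers the
    intrinsic rate ``r`` free of the curvature bias a short tangent window
    picks up.  The lag is where the (corrected) tangent meets the log
    inoculum level.  Wells whose gain never exceeds
    ``detection_threshold`` are flagged as no-growth.
    """
    t, y = curve.times, curve.od
    gain = float(y[-1] - y[0])
    if np.max(y) - np.min(y[: max(3, slope_window)]) < detection_threshold:
        return FitnessComponents(math.nan, math.nan, math.nan, no_growth=True)
    usable = y > min_od
    logy = np.where(usable, np.log(np.maximum(y, 1e-300)), np.nan)
    best_slope, best_i = -math.inf, None
    n = slope_window
    for i in range(len(t) - n + 1):
        seg = slice(i, i + n)
        if not usable[seg].all():
            continue
        slope = _ols_slope(t[seg], logy[seg])
        if slope > best_slope:
            best_slope, best_i = slope, i
    if best_i is None or best_slope <= 0:
        return FitnessComponents(math.nan, math.nan, math.nan, no_growth=True)
    seg = slice(best_i, best_i + n)
    t_c, y_c = float(np.mean(t[seg])), float(np.mean(logy[seg]))
    slope = best_slope
    intercept = y_c - slope * t_c
    if saturation_correction:
        refined = _saturation_corrected_fit(t, y, usable, saturation_frac)
        if refined is not None:
            intercept, slope = refined
    doubling_min = math.log(2.0) / slope
    lag_min = (math.log(inoculum_od) - intercept) / slope
    return FitnessComponents(
        lag=max(lag_min, 0.0) / 60.0,
        doubling_time=doubling_min / 60.0,
        efficiency=max(gain, 0.0),
    )


def _saturation_corrected_fit(
    t: np.ndarray, y: np.ndarray, usable: np.ndarray, saturation_frac: float
) -> tuple[float, float] | None:
    """Weighted fit of ``ln y ~ t + cumint(y)`` over the rise; returns the
    intrinsic-tangent (intercept, slope) or ``None`` when degenerate."""
    sel = usable & (y <= saturation_frac * y.max())
    if sel.sum() < 5:
        return None
    cumint = np.concatenate([[0.0], np.cumsum(np.diff(t) * (y[1:] + y[:-1]) / 2.0)])
    design = np.column_stack([np.ones(sel.sum()), t[sel], cumint[sel]])
    weights = y[sel]  # log-noise sd scales as 1/od
    coef, *_ = np.linalg.lstsq(
        design * weights[:, None], np.log(y[sel]) * weights, rcond=None
    )
    a, r, _ = coef
    if not np.isfinite(r) or r <= 0:
        return None
    return float(a), float(r)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    return float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))


def normalize_to_founder(
    log2_value: float, founder_log2_values: Sequence[float], component_kind: str
) -> float:
    """Founder-normalized relative component.

    For time-like components (``"lag"``, ``"doubling_time"``) the relative
    measure is founder mean minus the experimental estimate; for
    ``"efficiency"`` the orientation is reversed.  Positive values always
    indicate adaptation.
    """
    founder_log2_values = np.asarray(list(founder_log2_values), dtype=float)
    if founder_log2_values.size == 0:
        raise ValueError("need at least one founder reference value")
    ref = float(founder_log2_values.mean())
    if component_kind in ("lag", "doubling_time"):
        return ref - log2_value
    if component_kind == "efficiency":
        return log2_value - ref
    raise ValueError(f"unknown component kind: {component_kind!r}")


def read_plate(path_or_buf) -> list[GrowthCurve]:
    """Read a delimited-text plate file into growth curves.

    Two dialects are auto-detected: wide format (first column is time in
    minutes, one column per well) and long format (columns ``well``,
    ``time`` and ``od`` in any order).
    """
    df = pd.read_csv(path_or_buf, sep=None, engine="python")
    cols = {c.lower() for c in df.columns}
    if {"well", "time", "od"} <= cols:
        df.columns = [c.lower() for c in df.columns]
        curves = []
        for well, sub in df.groupby("well", sort=True):
            sub = sub.sort_values("time")
            curves.append(
                GrowthCurve(sub["time"].to_numpy(), sub["od"].to_numpy(), str(well))
            )
        return curves
    time_col = df.columns[0]
    return [
        GrowthCurve(df[time_col].to_numpy(), df[c].to_numpy(), str(c))
        for c in df.columns[1:]
    ]


def analyze_plate(
    curves: Sequence[GrowthCurve],
    founder_wells: Sequence[str] = (),
    smoothing_window: int = 3,
    calibration: Callable | None = None,
    **extract_kwargs,
) -> pd.DataFrame:
    """Extract components for every well and, when founder-control wells
    are given, append founder-normalized relative components.

    Relative components are computed against the mean of the founder
    wells' log2 estimates (no-growth founders excluded).
    """
    rows = []
    for curve in curves:
        prepped = preprocess_curve(curve, smoothing_window, calibration)
        comp = extract_fitness_components(prepped, **extract_kwargs)
        rows.append(
            {
                "well": curve.well_id,
                "lag_h": comp.lag,
                "doubling_h": comp.doubling_time,
                "efficiency_od": comp.efficiency,
                "log2_lag": comp.log2_lag,
                "log2_doubling": comp.log2_doubling,
                "log2_efficiency": comp.log2_efficiency,
                "no_growth": comp.no_growth,
            }
        )
    table = pd.DataFrame(rows)
    if founder_wells:
        founders = table[table["well"].isin(founder_wells) & ~table["no_growth"]]
        if founders.empty:
            raise ValueError("no usable founder-control wells for normalization")
        for comp_kind, col in [
            ("lag", "log2_lag"),
            ("doubling_time", "log2_doubling"),
            ("efficiency", "log2_efficiency"),
        ]:
            ref = founders[col]
            table[f"relative_{col[5:]}"] = [
                normalize_to_founder(v, ref, comp_kind) for v in table[col]
            ]
    return table
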