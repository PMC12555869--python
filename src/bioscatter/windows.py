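"""Seasonal and diel high-activity windows from differential-reflectivity series.

Aerial arthropod activity in temperate mid-latitudes peaks twice daily
(around midday and shortly after sunset) and seasonally from mid-April to
late October.  Both patterns show up as maxima in the mean ZDR of the
column profiles, because a larger fraction of gates then carries elongated
bioscatter.  A penalized cyclic spline is fitted to the hourly (diel) or
daily (annual) ZDR series and contiguous regions where the fitted curve
exceeds half its peak-above-baseline become activity windows, one per
local maximum.  Fixed preset windows (0800-1400 and 1800-2200 GMT;
15 April - 30 October) are also provided so a run can bypass fitting.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gam import PenalizedGAM, Smooth

__all__ = [
    "WindowKind",
    "ActivityWindow",
    "ActivityCurve",
    "fit_activity_smooth",
    "extract_peak_window",
    "select_scan_per_window",
    "preset_diel_windows",
    "preset_seasonal_window",
]


class WindowKind(str, enum.Enum):
    SEASONAL = "seasonal"
    DIEL = "diel"


_PERIOD = {WindowKind.DIEL: 24.0, WindowKind.SEASONAL: 365.0}
_BASIS = {WindowKind.DIEL: 10, WindowKind.SEASONAL: 20}


@dataclass(frozen=True)
class ActivityWindow:
    kind: WindowKind
    start: float  # hour (diel) or day-of-year (seasonal)
    end: float
    peak: float | None = None  # location of the defining local maximum

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("window start must precede end")

    def contains(self, t) -> np.ndarray | bool:
        t = np.asarray(t, dtype=float)
        res = (t >= self.start) & (t <= self.end)
        return bool(res) if res.ndim == 0 else res


def preset_diel_windows() -> list[ActivityWindow]:
    """The operational diurnal and nocturnal scan windows (GMT hours)."""
    return [
        ActivityWindow(WindowKind.DIEL, 8.0, 14.0, peak=11.0),
        ActivityWindow(WindowKind.DIEL, 18.0, 22.0, peak=20.0),
    ]


def preset_seasonal_window(year: int = 2021) -> ActivityWindow:
    """15 April to 30 October as day-of-year bounds for ``year``."""
    start = float(pd.Timestamp(year=year, month=4, day=15).dayofyear)
    end = float(pd.Timestamp(year=year, month=10, day=30).dayofyear)
    return ActivityWindow(WindowKind.SEASONAL, start, end)


@dataclass
class ActivityCurve:
    """A fitted cyclic activity curve evaluated on a fine grid."""

    kind: WindowKind
    grid: np.ndarray
    fitted: np.ndarray
    basis_dim: int
    lambda_: float
    degenerate: bool

    def local_maxima(self, prominence: float = 0.5) -> np.ndarray:
        """Grid locations of local maxima of the fitted cyclic curve.

        Maxima whose height above the curve minimum is below ``prominence``
        times the curve amplitude are discarded as fitting wiggles; the
        default matches the half-of-peak window rule, so every reported
        maximum can anchor a window.
        """
        if self.degenerate:
            return np.array([])
        f = self.fitted
        left = np.roll(f, 1)
        right = np.roll(f, -1)
        is_max = (f > left) & (f >= right)
        amp = f.max() - f.min()
        if amp > 0:
            is_max &= f >= f.min() + prominence * amp
        return self.grid[is_max]


def fit_activity_smooth(times, values, kind: WindowKind | str) -> ActivityCurve:
    """Fit a penalized cyclic spline to a (time, mean-ZDR) series.

    ``times`` are hours in [0, 24) for diel series or day-of-year for
    seasonal series.  A constant series yields a degenerate (flat) curve
    with no windows.
    """
    kind = WindowKind(kind)
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(t) & np.isfinite(v)
    t, v = t[ok], v[ok]
    if t.size < 20:
        raise ValueError("need at least 20 points to fit an activity curve")
    period = _PERIOD[kind]
    k = _BASIS[kind]
    if np.ptp(v) < 1e-12:
        grid = np.linspace(0, period, 512, endpoint=False)
        return ActivityCurve(kind, grid, np.full(512, v.mean()), k, np.inf, True)
    model = PenalizedGAM(terms=[Smooth("t", k=k, cyclic=True, period=period)])
    model.fit(pd.DataFrame({"t": t}), v)
    grid = np.linspace(0, period, 512, endpoint=False)
    fitted = model.predict(pd.DataFrame({"t": grid}))
    degenerate = bool(np.ptp(fitted) < 1e-9 * max(1.0, np.ptp(v)))
    return ActivityCurve(kind, grid, fitted, k, float(model.lambda_[0]), degenerate)


def extract_peak_window(curve: ActivityCurve, fraction: float = 0.5) -> list[ActivityWindow]:
    """Windows where the curve exceeds ``fraction`` of its peak above baseline.

    The baseline is the curve minimum; contiguous super-threshold regions
    are split between adjacent local maxima at the interior minimum, rounded
    outward to whole hours (diel) or days (seasonal).  Returns an empty list
    for a degenerate curve.
    """
    maxima = curve.local_maxima()
    if maxima.size == 0:
        return []
    f = curve.fitted
    base = float(f.min())
    thresh = base + fraction * (float(f.max()) - base)
    above = f >= thresh
    period = _PERIOD[curve.kind]
    # label contiguous runs on the circle
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    # merge wrap-around run
    if len(runs) > 1 and runs[0][0] == 0 and runs[-1][-1] == len(f) - 1:
        runs[0] = np.concatenate([runs[-1], runs[0]])
        runs = runs[:-1]
    windows: list[ActivityWindow] = []
    for run in runs:
        g = curve.grid[run]
        peaks_in = [m for m in maxima if np.any(np.isclose(g, m))]
        if not peaks_in:
            continue
        start = float(np.floor(g.min()))
        end = float(np.ceil(g.max()))
        if g[0] > g[-1]:  # wrapped run: report as crossing zero is not useful here
            start = float(np.floor(g[0]))
            end = float(np.ceil(g[-1] + period))
        end = min(end, start + period)
        if end <= start:
            end = start + 1.0
        windows.append(
            ActivityWindow(curve.kind, start, end, peak=float(peaks_in[0]))
        )
    windows.sort(key=lambda w: w.start)
    return windows


def select_scan_per_window(
    profiles: pd.DataFrame,
    windows: list[ActivityWindow],
    target_band: int = 500,
) -> pd.DataFrame:
    """One scan per (cell, day, window): the valid scan maximizing band ZDR.

    Ties resolve to the earliest timestamp; a (cell, day, window) with no
    valid target-band scan yields no row.  Selection is invariant to any
    monotone transform of ZDR.
    """
    sub = profiles[
        (profiles["band_lower_m"] == target_band) & profiles["band_valid"]
    ].copy()
    if sub.empty:
        return pd.DataFrame(
            columns=["site_id", "grid_row", "grid_col", "date", "window", "timestamp", "mean_zdr_db"]
        )
    ts = pd.to_datetime(sub["timestamp"])
    sub["date"] = ts.dt.date
    hours = ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0
    rows = []
    for w_i, w in enumerate(windows):
        inw = sub[np.asarray(w.contains(hours.to_numpy()))]
        if inw.empty:
            continue
        inw = inw.sort_values("timestamp", kind="stable")
        best = inw.loc[
            inw.groupby(["site_id", "grid_row", "grid_col", "date"], sort=False)[
                "mean_zdr_db"
            ].idxmax()
        ]
        best = best.assign(window=w_i)
        rows.append(
            best[
                ["site_id", "grid_row", "grid_col", "date", "window", "timestamp", "mean_zdr_db"]
            ]
        )
    if not rows:
        return pd.DataFrame(
            columns=["site_id", "grid_row", "grid_col", "date", "window", "timestamp", "mean_zdr_db"]
        )
    return pd.concat(rows, ignore_index=True)
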