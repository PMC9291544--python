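"""Marine heatwave detection by baseline-percentile exceedance.

A marine heatwave (MHW) is a maximal run of consecutive days on which daily
SST strictly exceeds a high percentile (typically the 90th or 99th) of a
designated baseline segment of the series — a pre-industrial control in
model output, or any reference span in observations.  The threshold is a
single fixed value computed from all baseline days (no day-of-year
climatology; an optional day-of-year mode is available for comparison with
seasonal-climatology detectors).  Each event is summarized by its duration
(days of exceedance) and maximum intensity (largest SST anomaly above the
threshold).  Events separated by even a single sub-threshold day are not
joined.

Annual statistics attribute day counts to each constituent day's calendar
year and event-level statistics (duration, max intensity) to the event's
start year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from coralmeta.errors import DomainError

__all__ = [
    "SSTSeries", "MHWEvent", "AnnualMHWStats", "percentile_threshold",
    "detect_events", "annual_stats", "model_envelope",
]


@dataclass
class SSTSeries:
    """A daily SST series with a designated baseline span.

    ``dates`` must be strictly increasing daily timestamps; ``baseline_span``
    is an inclusive (start, end) pair of timestamps marking the reference
    segment for percentile thresholds.  365-day model calendars are handled
    by construction (the generator never emits Feb 29) — the detector only
    relies on consecutive-day ordering and each day's calendar year.
    """

    dates: pd.DatetimeIndex
    sst: np.ndarray
    baseline_span: tuple[pd.Timestamp, pd.Timestamp]
    model_id: str = ""

    def __post_init__(self):
        self.dates = pd.DatetimeIndex(self.dates)
        self.sst = np.asarray(self.sst, dtype=float)
        if len(self.dates) != len(self.sst):
            raise ValueError("dates and sst must have equal length")
        if len(self.dates) > 1 and not self.dates.is_monotonic_increasing:
            raise ValueError("dates must be strictly increasing")
        start, end = self.baseline_span
        self.baseline_span = (pd.Timestamp(start), pd.Timestamp(end))

    def baseline_values(self) -> np.ndarray:
        start, end = self.baseline_span
        mask = (self.dates >= start) & (self.dates <= end)
        return self.sst[mask]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, baseline_span, model_id: str = "",
                   date_col: str = "date", sst_col: str = "sst") -> "SSTSeries":
        return cls(dates=pd.DatetimeIndex(pd.to_datetime(df[date_col])),
                   sst=df[sst_col].to_numpy(float),
                   baseline_span=baseline_span, model_id=model_id)


@dataclass(frozen=True)
class MHWEvent:
    """One exceedance event: inclusive date span, duration and max anomaly."""

    start: pd.Timestamp
    end: pd.Timestamp
    duration_days: int
    max_intensity_C: float


@dataclass(frozen=True)
class AnnualMHWStats:
    year: int
    max_annual_intensity_C: float
    mean_annual_duration_days: float
    n_mhw_days: int


def percentile_threshold(series: SSTSeries, p: float,
                         day_of_year: bool = False,
                         window_halfwidth: int = 5):
    """Empirical percentile of the baseline days (linear interpolation).

    With ``day_of_year=True`` returns a 366-entry array of thresholds, each
    computed from baseline days within ``window_halfwidth`` days of that
    day-of-year (the seasonal-climatology alternative); otherwise a single
    scalar from all baseline days.
    """
    if not 0 < p < 100:
        raise DomainError("percentile must lie strictly between 0 and 100")
    base = series.baseline_values()
    if base.size == 0:
        raise DomainError("baseline span contains no days")
    if not day_of_year:
        return float(np.percentile(base, p, method="linear"))
    start, end = series.baseline_span
    mask = (series.dates >= start) & (series.dates <= end)
    doy = series.dates[mask].dayofyear.to_numpy()
    out = np.empty(366)
    for d in range(1, 367):
        dist = np.minimum(np.abs(doy - d), 366 - np.abs(doy - d))
        vals = base[dist <= window_halfwidth]
        out[d - 1] = np.percentile(vals, p, method="linear") if vals.size else np.nan
    return out


def _threshold_per_day(series: SSTSeries, threshold) -> np.ndarray:
    if np.isscalar(threshold):
        return np.full(len(series.sst), float(threshold))
    thr = np.asarray(threshold, dtype=float)
    return thr[series.dates.dayofyear.to_numpy() - 1]


def detect_events(series: SSTSeries, threshold,
                  min_duration: int = 1) -> list[MHWEvent]:
    """Maximal runs of days with SST strictly above the threshold.

    Runs shorter than ``min_duration`` are discarded; sub-threshold gaps are
    never bridged.  ``threshold`` may be a scalar or a 366-entry day-of-year
    array.
    """
    if min_duration < 1:
        raise DomainError("min_duration must be >= 1")
    thr = _threshold_per_day(series, threshold)
    above = series.sst > thr
    events = []
    n = len(above)
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        duration = j - i + 1
        if duration >= min_duration:
            anomaly = series.sst[i:j + 1] - thr[i:j + 1]
            events.append(MHWEvent(
                start=series.dates[i], end=series.dates[j],
                duration_days=duration,
                max_intensity_C=float(anomaly.max()),
            ))
        i = j + 1
    return events


def annual_stats(events: Sequence[MHWEvent], series: SSTSeries) -> pd.DataFrame:
    """Per-calendar-year MHW statistics over the series' full year range.

    Years without events get ``n_mhw_days = 0`` and missing (NaN) intensity
    and duration.  Day counts split boundary-crossing events across years;
    event-level statistics go to the start year.
    """
    years = np.arange(series.dates[0].year, series.dates[-1].year + 1)
    day_counts = {int(y): 0 for y in years}
    durations: dict[int, list[int]] = {int(y): [] for y in years}
    intensities: dict[int, list[float]] = {int(y): [] for y in years}
    for ev in events:
        for day in pd.date_range(ev.start, ev.end, freq="D"):
            if int(day.year) in day_counts:
                day_counts[int(day.year)] += 1
        y0 = int(ev.start.year)
        if y0 in durations:
            durations[y0].append(ev.duration_days)
            intensities[y0].append(ev.max_intensity_C)
    rows = []
    for y in years:
        y = int(y)
        rows.append({
            "year": y,
            "max_annual_intensity_C":
                max(intensities[y]) if intensities[y] else math.nan,
            "mean_annual_duration_days":
                float(np.mean(durations[y])) if durations[y] else math.nan,
            "n_mhw_days": day_counts[y],
        })
    return pd.DataFrame(rows)


def model_envelope(stats_by_model: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Multi-model mean/min/max per year for each annual statistic.

    Input maps model_id -> the annual_stats frame for that model.  Output has
    one row per year with ``<stat>_mean``, ``<stat>_min``, ``<stat>_max``
    columns (NaN years are ignored statistic-wise, matching how plume plots
    treat missing model years).
    """
    if not stats_by_model:
        raise DomainError("envelope needs at least one model")
    frames = []
    for model_id, df in stats_by_model.items():
        d = df.set_index("year")
        d.columns = pd.MultiIndex.from_product([[model_id], d.columns])
        frames.append(d)
    wide = pd.concat(frames, axis=1)
    stats = sorted({c for _, c in wide.columns})
    out = pd.DataFrame({"year": wide.index})
    for stat in stats:
        block = wide.loc[:, pd.IndexSlice[:, stat]]
        out[f"{stat}_mean"] = block.mean(axis=1, skipna=True).to_numpy()
        out[f"{stat}_min"] = block.min(axis=1, skipna=True).to_numpy()
        out[f"{stat}_max"] = block.max(axis=1, skipna=True).to_numpy()
    return out.reset_index(drop=True)
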