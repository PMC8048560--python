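"""Marine heatwave (MHW) detection from daily SST series.

Implements the standard event definition of Hobday et al.: a marine
heatwave is a run of at least ``min_duration`` consecutive days on which
SST exceeds the day-of-year 90th-percentile climatological threshold,
with runs separated by at most ``max_gap`` below-threshold days merged
into a single event.  Event intensities are temperature anomalies
relative to the day-of-year climatological mean.

The climatology is fit on a baseline period by pooling, for each day of
year, all baseline values within ``window_halfwidth`` days, taking the
mean and the empirical 90th percentile, and smoothing both curves with a
centered moving average that wraps across the year boundary.  Days of
year are indexed 1..366 on a leap-year calendar; the Feb-29 climatology
is interpolated from its neighbours to avoid a 1-in-4 sample-size
artifact.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

N_DOY = 366

__all__ = [
    "SSTSeries",
    "Climatology",
    "MHWEvent",
    "MHWGridSummary",
    "compute_climatology",
    "detect_events",
    "summarize_grid",
    "read_sst_netcdf",
    "read_sst_csv",
    "events_to_frame",
]


def _doy366(dates: pd.DatetimeIndex) -> np.ndarray:
    """Day-of-year on a fixed 366-day (leap) calendar, so that a given
    calendar date maps to the same index in every year."""
    doy = dates.dayofyear.to_numpy().copy()
    # in non-leap years, shift Mar 1 onward by +1 so Dec 31 is always 366
    nonleap = ~dates.is_leap_year
    after_feb = doy >= 60
    doy[nonleap & after_feb] += 1
    return doy


@dataclass
class SSTSeries:
    """A contiguous daily SST series for one grid cell.

    Missing values are represented as NaN.
    """

    dates: pd.DatetimeIndex
    sst: np.ndarray
    cell_id: str | None = None
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.sst = np.asarray(self.sst, dtype=float)
        if len(self.dates) != len(self.sst):
            raise ValueError("dates and sst must have equal length")
        if len(self.dates) > 1:
            steps = np.diff(self.dates.to_numpy()).astype("timedelta64[D]")
            if not np.all(steps == np.timedelta64(1, "D")):
                raise ValueError("dates must be strictly increasing with a 1-day step")

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def doy(self) -> np.ndarray:
        return _doy366(self.dates)

    @property
    def years(self) -> np.ndarray:
        return self.dates.year.to_numpy()


@dataclass
class Climatology:
    """Day-of-year climatological mean and 90th-percentile threshold."""

    doy: np.ndarray
    seas_mean: np.ndarray
    thresh90: np.ndarray
    baseline: tuple[int, int]
    window_halfwidth: int
    smooth_width: int

    def __post_init__(self) -> None:
        for name in ("doy", "seas_mean", "thresh90"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if not (len(self.doy) == len(self.seas_mean) == len(self.thresh90) == N_DOY):
            raise ValueError(f"climatology arrays must have length {N_DOY}")


@dataclass
class MHWEvent:
    """One detected marine-heatwave event."""

    start: pd.Timestamp
    end: pd.Timestamp
    duration: int
    mean_intensity: float
    max_intensity: float
    cumulative_intensity: float
    cell_id: str | None = None


@dataclass
class MHWGridSummary:
    """Heatwave-day totals and mean event intensity for one cell over a period."""

    cell_id: str | None
    total_hw_days: int
    mean_event_intensity: float  # NaN when total_hw_days == 0


def _circular_moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average of odd ``width`` wrapping across the year."""
    if width <= 1:
        return x.copy()
    half = width // 2
    xpad = np.concatenate([x[-half:], x, x[:half]])
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    return np.convolve(xpad, kernel, mode="valid")


def compute_climatology(
    series: SSTSeries,
    baseline: tuple[int, int] | None = None,
    window_halfwidth: int = 5,
    smooth_width: int = 31,
    max_missing_frac: float = 0.25,
) -> Climatology:
    """Fit the day-of-year mean and 90th-percentile threshold.

    Parameters
    ----------
    series
        Daily SST series spanning at least three full years.
    baseline
        ``(start_year, end_year)`` inclusive; defaults to the full span
        of the series.
    window_halfwidth
        Half-width in days of the pooling window around each day of year.
    smooth_width
        Width in days of the centered moving average applied to both
        curves; wraps across the year boundary.
    max_missing_frac
        Reject baselines with a larger missing-data fraction.

    The empirical 90th percentile uses the linear-interpolation (type-7)
    convention, fixed for reproducibility.
    """
    years = series.years
    if baseline is None:
        baseline = (int(years.min()), int(years.max()))
    y0, y1 = baseline
    if y0 < years.min() or y1 > years.max() or y0 > y1:
        raise ValueError(
            f"baseline {baseline} outside data span "
            f"({years.min()}–{years.max()})"
        )
    if window_halfwidth < 0:
        raise ValueError("window_halfwidth must be >= 0")

    in_base = (years >= y0) & (years <= y1)
    sst = series.sst[in_base]
    doy = series.doy[in_base]
    missing_frac = float(np.mean(~np.isfinite(sst)))
    if missing_frac > max_missing_frac:
        raise ValueError(
            f"baseline has {missing_frac:.1%} missing SST "
            f"(limit {max_missing_frac:.0%})"
        )
    ok = np.isfinite(sst)
    sst, doy = sst[ok], doy[ok]

    # bucket values by doy, then pool neighbours circularly
    by_doy: list[np.ndarray] = [np.empty(0)] * (N_DOY + 1)
    order = np.argsort(doy, kind="stable")
    doy_sorted, sst_sorted = doy[order], sst[order]
    uniq, starts = np.unique(doy_sorted, return_index=True)
    bounds = np.append(starts, len(doy_sorted))
    for d, lo, hi in zip(uniq, bounds[:-1], bounds[1:]):
        by_doy[d] = sst_sorted[lo:hi]

    seas = np.full(N_DOY, np.nan)
    thresh = np.full(N_DOY, np.nan)
    for d in range(1, N_DOY + 1):
        if d == 60:  # Feb 29: interpolated below
            continue
        offsets = np.arange(-window_halfwidth, window_halfwidth + 1)
        neigh = (d - 1 + offsets) % N_DOY + 1
        pooled = np.concatenate([by_doy[n] for n in neigh]) if len(neigh) else np.empty(0)
        # Feb 29 values still contribute to neighbouring windows
        if pooled.size == 0:
            continue
        seas[d - 1] = pooled.mean()
        thresh[d - 1] = np.quantile(pooled, 0.9)  # type-7 linear interpolation
    # Feb 29 climatology from neighbours (doy 59 and 61)
    seas[59] = 0.5 * (seas[58] + seas[60])
    thresh[59] = 0.5 * (thresh[58] + thresh[60])

    seas = _circular_moving_average(seas, smooth_width)
    thresh = _circular_moving_average(thresh, smooth_width)

    return Climatology(
        doy=np.arange(1, N_DOY + 1),
        seas_mean=seas,
        thresh90=thresh,
        baseline=(y0, y1),
        window_halfwidth=window_halfwidth,
        smooth_width=smooth_width,
    )


def _runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) inclusive index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def detect_events(
    series: SSTSeries,
    clim: Climatology,
    min_duration: int = 5,
    max_gap: int = 2,
) -> list[MHWEvent]:
    """Detect marine-heatwave events against a fitted climatology.

    Maximal runs of days with SST above the day-of-year threshold, of
    length >= ``min_duration``, become events; qualifying runs separated
    by <= ``max_gap`` below-threshold days are merged into a single
    event whose statistics include the gap days.  Missing SST counts as
    below threshold (a conservative choice, logged as a warning).
    """
    if min_duration < 1:
        raise ValueError("min_duration must be >= 1")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")

    idx = series.doy - 1
    thresh = clim.thresh90[idx]
    seas = clim.seas_mean[idx]
    sst = series.sst
    missing = ~np.isfinite(sst)
    if missing.any():
        logger.warning(
            "%d missing SST days treated as below threshold during detection",
            int(missing.sum()),
        )
    exceed = np.where(missing, False, sst > thresh)

    runs = [r for r in _runs_of_true(exceed) if r[1] - r[0] + 1 >= min_duration]

    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= max_gap:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)

    events: list[MHWEvent] = []
    for s, e in merged:
        anom = sst[s : e + 1] - seas[s : e + 1]
        anom = anom[np.isfinite(anom)]
        duration = e - s + 1
        mean_int = float(anom.mean())
        events.append(
            MHWEvent(
                start=series.dates[s],
                end=series.dates[e],
                duration=duration,
                mean_intensity=mean_int,
                max_intensity=float(anom.max()),
                cumulative_intensity=mean_int * duration,
                cell_id=series.cell_id,
            )
        )
    return events


def summarize_grid(
    events_by_cell: dict[str, list[MHWEvent]],
    period: tuple[pd.Timestamp, pd.Timestamp],
) -> list[MHWGridSummary]:
    """Per cell, total event days intersecting ``period`` and the mean
    daily intensity over those days.

    The mean event intensity is the duration-weighted mean of the
    per-event mean anomalies over the days falling inside the period;
    it is NaN for cells with no heatwave days in the period.
    """
    p0, p1 = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    if p0 > p1:
        raise ValueError("period start after period end")
    out = []
    for cell_id, events in events_by_cell.items():
        total = 0
        weighted = 0.0
        for ev in events:
            lo = max(ev.start, p0)
            hi = min(ev.end, p1)
            ndays = (hi - lo).days + 1
            if ndays > 0:
                total += ndays
                weighted += ndays * ev.mean_intensity
        mean_int = weighted / total if total > 0 else float("nan")
        out.append(MHWGridSummary(cell_id=cell_id, total_hw_days=total, mean_event_intensity=mean_int))
    return out


# ---------------------------------------------------------------------------
# I/O

def read_sst_netcdf(path: str, var: str = "sst") -> list[SSTSeries]:
    """Read CF gridded daily SST (time x lat x lon) into per-cell series."""
    ds = xr.open_dataset(path)
    da = ds[var]
    dates = pd.DatetimeIndex(da["time"].values)
    out = []
    for lat in da["lat"].values:
        for lon in da["lon"].values:
            vals = da.sel(lat=lat, lon=lon).values.astype(float)
            if np.all(~np.isfinite(vals)):
                continue
            out.append(
                SSTSeries(
                    dates=dates,
                    sst=vals,
                    cell_id=f"{float(lat):.3f}_{float(lon):.3f}",
                    lat=float(lat),
                    lon=float(lon),
                )
            )
    ds.close()
    return out


def read_sst_csv(path: str) -> list[SSTSeries]:
    """Read long-form CSV (``date,cell_id,lat,lon,sst``) into per-cell series."""
    df = pd.read_csv(path, parse_dates=["date"], comment="#")
    out = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("date")
        out.append(
            SSTSeries(
                dates=pd.DatetimeIndex(grp["date"]),
                sst=grp["sst"].to_numpy(),
                cell_id=str(cell_id),
                lat=float(grp["lat"].iloc[0]) if "lat" in grp else None,
                lon=float(grp["lon"].iloc[0]) if "lon" in grp else None,
            )
        )
    return out


def events_to_frame(events: list[MHWEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": ev.cell_id,
                "start": ev.start.date().isoformat(),
                "end": ev.end.date().isoformat(),
                "duration": ev.duration,
                "mean_intensity": ev.mean_intensity,
                "max_intensity": ev.max_intensity,
                "cumulative_intensity": ev.cumulative_intensity,
            }
            for ev in events
        ]
    )
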