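"""Hourly GPS tracks to displacement series and daily movement records.

The processing chain is: regularize a track onto a strict one-hour grid,
fill failed fixes by linear interpolation between the temporally nearest
successful fixes, convert positions to hourly net displacements (great-circle
distance between consecutive fixes), and aggregate to diel displacement (DD),
the per-day sum of the 24 hourly displacements.  Days with fewer than 20
successful fixes are retained but marked invalid and excluded from modeling.

A "day" is a block of 24 consecutive hours starting at local midnight; the
local offset is configurable (default UTC+3, East Africa).  The displacement
of hour ``t`` is assigned to the day containing the start of hour ``t``, so
the last displacement of a day reaches into the next day's first fix and each
complete day carries exactly 24 hourly displacements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0
#: minimum successful hourly fixes for a day to enter any model
MIN_SUCCESS_FIXES = 20
HOURS_PER_DAY = 24
DEFAULT_DAY_OFFSET_HOURS = 3


@dataclass
class GpsTrack:
    """One individual's fixes on a strict hourly grid.

    ``lat``/``lon`` are NaN where no position is available (failed fix before
    regularization, or an edge gap that could not be interpolated).
    """

    individual_id: str
    times: pd.DatetimeIndex
    lat: np.ndarray
    lon: np.ndarray
    success: np.ndarray
    interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.success = np.asarray(self.success, dtype=bool)
        if self.interpolated is None:
            self.interpolated = np.zeros(len(self.lat), dtype=bool)
        n = len(self.times)
        if not (len(self.lat) == len(self.lon) == len(self.success) == n):
            raise ValueError("track arrays must share one length")
        if n > 1:
            step = np.diff(self.times.asi8)
            if not np.all(step == 3_600_000_000_000):
                raise ValueError("track timestamps must be strictly hourly")
        bad = self.success & ~(np.isfinite(self.lat) & np.isfinite(self.lon))
        if bad.any():
            raise ValueError("successful fixes must have finite coordinates")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class DisplacementSeries:
    """Hourly net displacements S^N for one individual.

    ``values[t]`` is the distance (km) travelled between fix ``t`` and fix
    ``t+1``; ``day_index`` labels the day containing hour ``t``'s start.
    """

    individual_id: str
    start: pd.Timestamp
    values: np.ndarray
    interpolated_flags: np.ndarray
    day_index: np.ndarray
    day_offset_hours: int = DEFAULT_DAY_OFFSET_HOURS

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=len(self.values), freq="h")


def great_circle_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance on a 6371-km sphere (haversine form).

    Inputs are degrees; broadcasting over array arguments is supported.
    """
    args = [np.asarray(a, dtype=float) for a in (lat1, lon1, lat2, lon2)]
    if any(not np.all(np.isfinite(a)) for a in args):
        raise ValueError("coordinates must be finite")
    la1, lo1, la2, lo2 = (np.radians(a) for a in args)
    if np.any(np.abs(args[0]) > 90.0) or np.any(np.abs(args[2]) > 90.0):
        raise ValueError("latitude out of [-90, 90]")
    dphi = la2 - la1
    dlam = lo2 - lo1
    h = np.sin(dphi / 2.0) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return float(d) if np.isscalar(lat1) or np.ndim(d) == 0 else d


def regularize_and_interpolate(track: GpsTrack) -> GpsTrack:
    """Fill failed fixes by linear interpolation between flanking successes.

    Interpolation is linear in raw latitude and longitude degrees
    (independently), matching short hourly steps; slots before the first or
    after the last successful fix stay NaN.  The returned track spans from
    the first to the last successful fix.
    """
    ok = track.success & np.isfinite(track.lat) & np.isfinite(track.lon)
    if ok.sum() < 2:
        raise ValueError("need at least two successful fixes to interpolate")
    first, last = np.flatnonzero(ok)[[0, -1]]
    times = track.times[first : last + 1]
    success = track.success[first : last + 1].copy()
    lat = track.lat[first : last + 1].copy()
    lon = track.lon[first : last + 1].copy()
    okc = ok[first : last + 1]
    idx = np.arange(len(times), dtype=float)
    lat[~okc] = np.interp(idx[~okc], idx[okc], lat[okc])
    lon[~okc] = np.interp(idx[~okc], idx[okc], lon[okc])
    interpolated = ~okc
    return GpsTrack(track.individual_id, times, lat, lon, success, interpolated)


def _day_index(times: pd.DatetimeIndex, day_offset_hours: int) -> np.ndarray:
    shifted = times + pd.Timedelta(hours=day_offset_hours)
    return (shifted.asi8 // (24 * 3_600_000_000_000)).astype(np.int64)


def day_dates(day_index: np.ndarray) -> pd.DatetimeIndex:
    """Calendar (local) date corresponding to each integer day index."""
    return pd.to_datetime(np.asarray(day_index, dtype="int64"), unit="D")


def hourly_displacements(
    track: GpsTrack, day_offset_hours: int = DEFAULT_DAY_OFFSET_HOURS
) -> DisplacementSeries:
    """Hourly net displacement S^N between consecutive regularized fixes.

    Hours with a missing endpoint (edge gaps) yield NaN; an hour is flagged
    interpolated if either endpoint was interpolated.
    """
    n = len(track)
    if n < 2:
        raise ValueError("track too short for displacements")
    lat, lon = track.lat, track.lon
    both = np.isfinite(lat[:-1]) & np.isfinite(lat[1:]) & np.isfinite(lon[:-1]) & np.isfinite(lon[1:])
    values = np.full(n - 1, np.nan)
    if both.any():
        values[both] = great_circle_km(
            lat[:-1][both], lon[:-1][both], lat[1:][both], lon[1:][both]
        )
    flags = track.interpolated[:-1] | track.interpolated[1:]
    day_idx = _day_index(track.times[:-1], day_offset_hours)
    return DisplacementSeries(
        track.individual_id, track.times[0], values, flags, day_idx, day_offset_hours
    )


def day_fix_counts(
    track: GpsTrack, day_offset_hours: int = DEFAULT_DAY_OFFSET_HOURS
) -> pd.Series:
    """Number of successful fixes (0-24) in each complete calendar day."""
    di = _day_index(track.times, day_offset_hours)
    counts = pd.Series(track.success.astype(int)).groupby(di).sum()
    sizes = pd.Series(1, index=di).groupby(level=0).sum()
    return counts[sizes == HOURS_PER_DAY]


def diel_displacement(
    series: DisplacementSeries, fix_counts: pd.Series
) -> pd.DataFrame:
    """Aggregate hourly displacements to one diel-displacement row per day.

    Only days with a full block of 24 finite hourly displacements are
    emitted.  ``valid`` is True iff the day had >= 20 successful fixes.
    """
    df = pd.DataFrame({"v": series.values, "day": series.day_index})
    out = []
    for day, grp in df.groupby("day", sort=True):
        if len(grp) != HOURS_PER_DAY or not np.isfinite(grp["v"]).all():
            continue
        n_fix = int(fix_counts.get(day, 0))
        out.append(
            {
                "individual_id": series.individual_id,
                "date": day_dates(np.array([day]))[0],
                "dd_km": float(grp["v"].sum()),
                "n_fixes": n_fix,
                "valid": n_fix >= MIN_SUCCESS_FIXES,
            }
        )
    rec = pd.DataFrame(
        out, columns=["individual_id", "date", "dd_km", "n_fixes", "valid"]
    )
    rec["mp"] = np.nan
    return rec


def track_to_diel_records(
    track: GpsTrack, day_offset_hours: int = DEFAULT_DAY_OFFSET_HOURS
) -> pd.DataFrame:
    """Full chain raw track -> regularized -> S^N -> diel records."""
    reg = regularize_and_interpolate(track)
    series = hourly_displacements(reg, day_offset_hours)
    return diel_displacement(series, day_fix_counts(reg, day_offset_hours))


def extract_model_rows(records: pd.DataFrame, response: str = "dd") -> pd.DataFrame:
    """Model rows from triplets of three consecutive valid days.

    One row per day ``i`` whose days ``i``, ``i-1`` and ``i-2`` are all valid
    and consecutive calendar days; lag columns carry the response of days
    ``i-1`` and ``i-2``.
    """
    col = {"dd": "dd_km", "mp": "mp"}[response]
    rows = []
    for ind, grp in records.groupby("individual_id", sort=False):
        grp = grp.sort_values("date").reset_index(drop=True)
        day = (pd.to_datetime(grp["date"]).astype("int64") // (24 * 3_600_000_000_000)).to_numpy()
        y = grp[col].to_numpy(dtype=float)
        ok = grp["valid"].to_numpy(dtype=bool) & np.isfinite(y)
        for i in range(2, len(grp)):
            if not (ok[i] and ok[i - 1] and ok[i - 2]):
                continue
            if day[i] - day[i - 1] != 1 or day[i - 1] - day[i - 2] != 1:
                continue
            row = {
                "individual_id": ind,
                "date": grp["date"].iloc[i],
                "y": y[i],
                "lag1": y[i - 1],
                "lag2": y[i - 2],
            }
            for extra in ("ndvi", "rank", "forage_category"):
                if extra in grp.columns:
                    row[extra] = grp[extra].iloc[i]
            rows.append(row)
    cols = ["individual_id", "date", "y", "lag1", "lag2"] + [
        c for c in ("ndvi", "rank", "forage_category") if c in records.columns
    ]
    return pd.DataFrame(rows, columns=cols)
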