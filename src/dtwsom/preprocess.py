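"""Cleaning chain: raw multi-sensor streams -> complete 1440-point daily observations.

Order is fixed: median-smooth each sensor stream, average duplicate sensors,
truncate long gaps / interpolate short ones, min-max scale pollutants, cut
non-overlapping 20:00-anchored daily windows, and match daily outcomes.
Days containing any remaining missing value are dropped, so every emitted
daily observation has exactly one finite value per minute of the day.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from dtwsom.simulate import season_of_month

__all__ = [
    "median_smooth",
    "merge_duplicate_sensors",
    "fill_gaps",
    "rescale_minmax",
    "window_days",
    "match_outcomes",
    "preprocess_pipeline",
]

RAW_COLUMNS = ["timestamp", "site", "location", "variable", "sensor", "value"]


def median_smooth(series, kernel: int = 3) -> np.ndarray:
    """Running median with nearest-value edge padding; NaN-aware.

    Each non-missing point becomes the median of the non-missing values in
    its centred window; missing points stay missing.  Kernel size 3 is the
    minimum that removes isolated one-minute outliers.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("median_smooth: kernel must be an odd positive integer")
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("median_smooth expects a 1-D series")
    if kernel == 1 or x.size == 0:
        return x.copy()
    half = kernel // 2
    padded = np.pad(x, half, mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(padded, kernel)
    with np.errstate(all="ignore"):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            out = np.nanmedian(windows, axis=1)
    out[np.isnan(x)] = np.nan
    return out


def merge_duplicate_sensors(records: pd.DataFrame) -> pd.Series:
    """Average co-located sensors minute by minute.

    ``records`` must all belong to one (site, location, variable) group; the
    result is one value per minute of the group's covered span — the mean of
    whichever sensors report that minute, missing only when all do.
    """
    for col in ("site", "location", "variable"):
        if records[col].nunique() > 1:
            raise ValueError(
                f"merge_duplicate_sensors: records mix multiple {col} values "
                f"({sorted(records[col].unique())})")
    merged = records.groupby("timestamp")["value"].mean()
    freq = _infer_freq(merged.index)
    full = pd.date_range(merged.index.min(), merged.index.max(), freq=freq)
    return merged.reindex(full)


def _infer_freq(index: pd.Index) -> pd.Timedelta:
    if len(index) < 2:
        return pd.Timedelta(minutes=1)
    diffs = pd.Series(index).diff().dropna()
    return diffs.min()


def fill_gaps(series: pd.Series, max_gap: int = 60
              ) -> tuple[pd.Series, list[tuple[pd.Timestamp, pd.Timestamp]]]:
    """Interpolate short missing runs; report long ones as removed intervals.

    Runs of missing values shorter than ``max_gap`` minutes with observed
    values on both sides are filled by bidirectional linear interpolation.
    Runs of ``max_gap`` or longer, and runs touching either boundary of the
    stream (no flanking value to interpolate from), are left missing and
    returned as removed ``(start, end)`` intervals — the days containing
    them will later fail the completeness check.
    """
    values = series.to_numpy(dtype=np.float64, copy=True)
    n = values.size
    freq = _infer_freq(series.index)
    max_gap_steps = max_gap / (freq / pd.Timedelta(minutes=1))
    removed: list[tuple[pd.Timestamp, pd.Timestamp]] = []

    isna = np.isnan(values)
    i = 0
    while i < n:
        if not isna[i]:
            i += 1
            continue
        j = i
        while j < n and isna[j]:
            j += 1
        run_len = j - i
        at_boundary = i == 0 or j == n
        if run_len < max_gap_steps and not at_boundary:
            left, right = values[i - 1], values[j]
            frac = np.arange(1, run_len + 1) / (run_len + 1)
            values[i:j] = left + frac * (right - left)
        else:
            removed.append((series.index[i], series.index[j - 1]))
        i = j
    return pd.Series(values, index=series.index), removed


def rescale_minmax(frame: pd.DataFrame, per=("location", "variable"),
                   value_col: str = "value"
                   ) -> tuple[pd.DataFrame, dict[tuple, tuple[float, float]]]:
    """Affine-map each group's values onto [0, 1] using its global min/max.

    The min/max are taken over the entire group (all sites and days), so
    between-day amplitude differences survive scaling.  Returns the scaled
    frame and the per-group ``(min, max)`` needed to invert the map.
    """
    per = list(per)
    out = frame.copy()
    params: dict[tuple, tuple[float, float]] = {}
    for key, idx in frame.groupby(per).groups.items():
        key = key if isinstance(key, tuple) else (key,)
        vals = frame.loc[idx, value_col]
        lo, hi = float(vals.min()), float(vals.max())
        if not np.isfinite(lo) or not np.isfinite(hi) or hi == lo:
            raise ValueError(
                f"rescale_minmax: group {key} is constant or empty (min == max)")
        out.loc[idx, value_col] = (vals - lo) / (hi - lo)
        params[key] = (lo, hi)
    return out, params


def window_days(series: pd.Series, window_start: dt.time = dt.time(20, 0),
                points_per_day: int = 1440) -> pd.DataFrame:
    """Cut a stream into complete daily windows.

    Non-overlapping windows of ``points_per_day`` samples anchored at
    ``window_start`` (default 20:00, ending 19:59 the next day).  Windows
    with any missing sample are dropped.  Each row of the result carries the
    window-start date, its meteorological season, and the values.
    """
    if series.empty:
        return pd.DataFrame(columns=["date", "season", "values"])
    freq = _infer_freq(series.index)
    rows = []
    first, last = series.index.min(), series.index.max()
    anchor = first.normalize() + pd.Timedelta(hours=window_start.hour,
                                              minutes=window_start.minute)
    if anchor > first:
        anchor -= pd.Timedelta(days=1)
    day = pd.Timedelta(days=1)
    while anchor <= last:
        window = series.loc[anchor:anchor + day - freq]
        if len(window) == points_per_day and not window.isna().any():
            rows.append({
                "date": anchor.date(),
                "season": season_of_month(anchor.month),
                "values": window.to_numpy(),
            })
        anchor += day
    return pd.DataFrame(rows, columns=["date", "season", "values"])


def match_outcomes(days: pd.DataFrame, outcomes: pd.DataFrame | None
                   ) -> pd.DataFrame:
    """Attach the daily binary outcome by (site, window-start date).

    ``outcomes`` needs columns ``site, date, outcome`` with one row per
    site-date.  Days without a matching outcome keep a missing label — they
    stay in the clustering but drop out of outcome overlays.
    """
    out = days.copy()
    if outcomes is None or outcomes.empty:
        out["outcome"] = pd.array([pd.NA] * len(out), dtype="Int64")
        return out
    key = outcomes[["site", "date"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0]
        raise ValueError(
            f"match_outcomes: duplicate outcome rows for site={dup['site']!r} "
            f"date={dup['date']!r}")
    lookup = outcomes.set_index(["site", "date"])["outcome"]
    idx = pd.MultiIndex.from_frame(
        pd.DataFrame({"site": out["site"], "date": _as_date(out["date"])}))
    lookup.index = pd.MultiIndex.from_arrays(
        [lookup.index.get_level_values(0), _as_date(lookup.index.get_level_values(1))])
    out["outcome"] = pd.array(lookup.reindex(idx).to_numpy(), dtype="Int64")
    return out


def _as_date(values) -> pd.Index:
    converted = pd.to_datetime(pd.Index(values))
    return pd.Index(converted.date)


def preprocess_pipeline(raw: pd.DataFrame, outcomes: pd.DataFrame | None = None,
                        kernel: int = 3, max_gap: int = 60,
                        window_start: dt.time = dt.time(20, 0),
                        points_per_day: int = 1440,
                        scale_temperature: bool = False) -> dict:
    """Run the full chain: smooth -> merge -> fill -> scale -> window -> match.

    Temperature is left in native units by default (only pollutant values are
    min-max scaled); set ``scale_temperature`` for cross-variable
    comparability.

    Returns a dict with:

    - ``days``: one row per complete daily observation (site, location,
      variable, date, season, outcome, values array of ``points_per_day``).
    - ``scaler``: per-(location, variable) (min, max) used for scaling.
    - ``removed``: long-gap intervals that were truncated, per stream.
    """
    raw = raw.copy()
    raw["timestamp"] = pd.to_datetime(raw["timestamp"])

    # 1. median-smooth each individual sensor stream
    smoothed = []
    for _, grp in raw.groupby(["site", "location", "variable", "sensor"],
                              sort=True):
        grp = grp.sort_values("timestamp").copy()
        grp["value"] = median_smooth(grp["value"].to_numpy(), kernel=kernel)
        smoothed.append(grp)
    raw = pd.concat(smoothed, ignore_index=True)

    # 2-3. merge duplicate sensors, then truncate/interpolate gaps per stream
    streams: dict[tuple, pd.Series] = {}
    removed: dict[tuple, list] = {}
    for key, grp in raw.groupby(["site", "location", "variable"], sort=True):
        merged = merge_duplicate_sensors(grp)
        filled, cut = fill_gaps(merged, max_gap=max_gap)
        streams[key] = filled
        removed[key] = cut

    # 4. min-max scale pollutant groups over all sites and days
    long = pd.concat(
        [s.rename("value").rename_axis("timestamp").reset_index().assign(
            site=k[0], location=k[1], variable=k[2])
         for k, s in streams.items()], ignore_index=True)
    scalable = long["variable"].ne("temperature") | scale_temperature
    scaler: dict[tuple, tuple[float, float]] = {}
    if scalable.any():
        scaled_part, scaler = rescale_minmax(long[scalable])
        long = pd.concat([scaled_part, long[~scalable]], ignore_index=True)

    # 5-6. daily windows, then outcome matching
    day_rows = []
    for key, grp in long.groupby(["site", "location", "variable"], sort=True):
        series = grp.set_index("timestamp")["value"].sort_index()
        days = window_days(series, window_start=window_start,
                           points_per_day=points_per_day)
        days.insert(0, "site", key[0])
        days.insert(1, "location", key[1])
        days.insert(2, "variable", key[2])
        day_rows.append(days)
    days = (pd.concat(day_rows, ignore_index=True) if day_rows
            else pd.DataFrame(columns=["site", "location", "variable",
                                       "date", "season", "values"]))
    days = match_outcomes(days, outcomes)
    return {"days": days, "scaler": scaler, "removed": removed}


def days_to_wide(days: pd.DataFrame) -> pd.DataFrame:
    """Serialize daily observations as one row per day with value columns."""
    if days.empty:
        return pd.DataFrame()
    values = np.vstack(days["values"].to_numpy())
    wide = days.drop(columns=["values"]).reset_index(drop=True)
    value_cols = pd.DataFrame(
        values, columns=[f"v{t:04d}" for t in range(values.shape[1])])
    return pd.concat([wide, value_cols], axis=1)


def wide_to_days(wide: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`days_to_wide`."""
    value_cols = [c for c in wide.columns if c.startswith("v") and c[1:].isdigit()]
    meta = wide[[c for c in wide.columns if c not in value_cols]].copy()
    meta["values"] = list(wide[value_cols].to_numpy(dtype=np.float64))
    return meta
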