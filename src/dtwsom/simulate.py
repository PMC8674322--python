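"""Synthetic minute-level exposure data with known ground truth.

Emulates a residential sensor panel: per household (site), minute-resolution
indoor/outdoor temperature and PM2.5 streams plus a daily binary outcome
(rescue-inhaler use).  Each day is a seasonal prototype shape passed through a
random monotone time warp, additive Gaussian noise and optional missing gaps —
the data-generating story the warping-invariant clustering is built to handle:
the same diurnal pattern recurring at slightly different clock times each day
(e.g. a dinner-time combustion spike in indoor PM2.5).

Temperature days are noon-peaked half-sinusoids whose baseline and amplitude
depend on season; PM days are a low baseline plus Gaussian-shaped spikes
(SD 20 min) centred near morning and evening anchor times with jitter.  The
outcome follows a logistic model in standardized spike count and daily
standard deviation, so the exposure-outcome coupling is tunable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "apply_warp", "generate_dataset", "VARIABLES"]

#: variable name -> (location, measured quantity)
VARIABLES = {
    "outdoor_temperature": ("outdoor", "temperature"),
    "indoor_temperature": ("indoor", "temperature"),
    "outdoor_pm": ("outdoor", "pm"),
    "indoor_pm": ("indoor", "pm"),
}

# (baseline degC, diurnal amplitude degC) per meteorological season;
# continental mid-latitude values so summer > winter in both level and swing.
DEFAULT_SEASON_MODEL = {
    "winter": (-2.0, 6.0),
    "spring": (10.0, 10.0),
    "summer": (22.0, 14.0),
    "fall": (12.0, 9.0),
}

_SEASON_BY_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
}

#: daily window starts at 20:00 local clock (matches evening questionnaires)
WINDOW_START_MINUTE = 20 * 60

_SUNRISE = 6 * 60          # 06:00
_DAYLIGHT = 12 * 60        # half-sinusoid support, peak at noon
_PM_BASELINE = 5.0         # ug/m3
_PM_SPIKE_SD = 20.0        # minutes
_PM_ANCHORS = (7 * 60 + 30, 18 * 60 + 30)  # breakfast / dinner clock minutes


def season_of_month(month: int) -> str:
    """Meteorological season of a calendar month (DJF/MAM/JJA/SON)."""
    return _SEASON_BY_MONTH[month]


@dataclass
class SimConfig:
    """Parameters of the synthetic exposure panel.

    ``warp_magnitude`` is the maximum timestamp displacement, in minutes, of
    the random monotone time map applied to every day.  ``spike_rate`` is the
    expected number of PM spikes per day (Poisson).  ``outcome_logit_coefs``
    is ``(intercept, beta_spike_count, beta_daily_sd)`` on standardized
    day features.  All randomness derives from ``seed``; identical configs
    produce byte-identical output.
    """

    n_sites: int = 2
    n_days: int = 30
    day_length: int = 1440
    variables: tuple[str, ...] = tuple(VARIABLES)
    season_model: dict = field(default_factory=lambda: dict(DEFAULT_SEASON_MODEL))
    warp_magnitude: float = 30.0
    noise_sd: float = 0.02
    spike_rate: float = 2.0
    spike_time_jitter_sd: float = 20.0
    missing_gap_rate: float = 0.0
    outcome_logit_coefs: tuple[float, float, float] = (-0.5, 1.0, 0.5)
    start_date: str = "2017-04-01"
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ValueError("SimConfig.n_sites must be a positive integer")
        if self.n_days < 0:
            raise ValueError("SimConfig.n_days must be nonnegative")
        if self.day_length < 2:
            raise ValueError("SimConfig.day_length must be >= 2")
        for name in self.variables:
            if name not in VARIABLES:
                raise ValueError(f"SimConfig.variables: unknown variable {name!r}")
        for rate_name in ("warp_magnitude", "noise_sd", "spike_rate",
                          "spike_time_jitter_sd", "missing_gap_rate"):
            if getattr(self, rate_name) < 0:
                raise ValueError(f"SimConfig.{rate_name} must be >= 0")
        if self.warp_magnitude >= self.day_length / 2:
            raise ValueError("SimConfig.warp_magnitude must be < day_length / 2")
        for season, (base, amp) in self.season_model.items():
            if season not in DEFAULT_SEASON_MODEL:
                raise ValueError(f"SimConfig.season_model: unknown season {season!r}")
            if amp < 0:
                raise ValueError("SimConfig.season_model amplitudes must be >= 0")
        if len(self.outcome_logit_coefs) != 3:
            raise ValueError("SimConfig.outcome_logit_coefs must have 3 entries")


def _warp_knots(day_length: int, warp_magnitude: float, rng: np.random.Generator,
                n_knots: int = 4, max_tries: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """A random strictly increasing, endpoint-fixed piecewise-linear time map.

    Interior knots at equally spaced times are displaced by
    Uniform(-warp_magnitude, +warp_magnitude); draws violating strict
    monotonicity are rejected and redrawn (cannot occur when knot spacing
    exceeds twice the magnitude, the practical regime).
    """
    T = day_length
    src = np.linspace(0.0, T - 1.0, n_knots + 2)
    for _ in range(max_tries):
        disp = rng.uniform(-warp_magnitude, warp_magnitude, size=n_knots)
        dst = src.copy()
        dst[1:-1] += disp
        if np.all(np.diff(dst) > 0):
            return src, dst
    raise RuntimeError("could not draw a strictly increasing warp map")


def _resample_through_map(values: np.ndarray, src: np.ndarray,
                          dst: np.ndarray) -> np.ndarray:
    """Warp ``values`` through the time map src -> dst, keeping the grid.

    A feature at original time ``u`` appears at warped time ``map(u)``, so the
    output at grid time ``t`` is the input evaluated at ``inverse_map(t)``.
    """
    T = values.shape[0]
    t = np.arange(T, dtype=np.float64)
    inv = np.interp(t, dst, src)  # inverse map: dst is increasing
    return np.interp(inv, t, values)


def apply_warp(series, warp_magnitude: float, seed: int) -> np.ndarray:
    """Resample a gap-free series through a random monotone time map.

    The map is piecewise linear with 4 interior knots, displacements drawn
    uniformly in ``[-warp_magnitude, +warp_magnitude]`` minutes, endpoints
    pinned — so the output has the same length, the same start/end values,
    and every internal feature shifted by at most ``warp_magnitude``.
    ``warp_magnitude = 0`` is the identity.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 1 or series.size < 2:
        raise ValueError("apply_warp expects a 1-D series of length >= 2")
    if not np.all(np.isfinite(series)):
        raise ValueError("apply_warp: series must be gap-free (finite)")
    if warp_magnitude < 0:
        raise ValueError("apply_warp: warp_magnitude must be >= 0")
    if warp_magnitude >= series.size / 2:
        raise ValueError("apply_warp: warp_magnitude >= day_length/2 is degenerate")
    if warp_magnitude == 0:
        return series.copy()
    rng = np.random.default_rng(seed)
    src, dst = _warp_knots(series.size, warp_magnitude, rng)
    return _resample_through_map(series, src, dst)


def temperature_prototype(day_length: int, baseline: float,
                          amplitude: float) -> np.ndarray:
    """Noon-peaked half-sinusoid on the 20:00-anchored daily grid.

    ``baseline + amplitude * sin(pi * (clock - sunrise) / 720)`` during
    daylight, clipped to the baseline at night.  With a 20:00 window start,
    noon falls at sample index ``16h * (day_length / 24h)``.
    """
    step = 1440.0 / day_length
    clock = (WINDOW_START_MINUTE + np.arange(day_length) * step) % 1440.0
    phase = np.pi * (clock - _SUNRISE) / _DAYLIGHT
    diurnal = np.where((clock >= _SUNRISE) & (clock <= _SUNRISE + _DAYLIGHT),
                       np.sin(phase), 0.0)
    return baseline + amplitude * np.clip(diurnal, 0.0, None)


def pm_prototype(day_length: int, spike_clock_minutes: np.ndarray,
                 spike_amplitudes: np.ndarray) -> np.ndarray:
    """Low baseline plus Gaussian-shaped spikes at given clock minutes."""
    step = 1440.0 / day_length
    clock = (WINDOW_START_MINUTE + np.arange(day_length) * step) % 1440.0
    values = np.full(day_length, _PM_BASELINE)
    for centre, amp in zip(spike_clock_minutes, spike_amplitudes):
        # circular clock distance so spikes near midnight wrap correctly
        d = np.abs(clock - centre)
        d = np.minimum(d, 1440.0 - d)
        values += amp * np.exp(-0.5 * (d / _PM_SPIKE_SD) ** 2)
    return values


def _insert_gaps(values: np.ndarray, rate: float, day_length: int,
                 rng: np.random.Generator) -> np.ndarray:
    """NaN out Poisson(rate) gaps per day; ~70% short (<1 h), rest >= 1 h."""
    out = values.copy()
    step = 1440.0 / day_length
    n_gaps = rng.poisson(rate)
    for _ in range(n_gaps):
        if rng.random() < 0.7:
            dur_min = rng.uniform(5, 55)
        else:
            dur_min = rng.uniform(61, 180)
        length = max(1, int(round(dur_min / step)))
        start = rng.integers(0, max(1, day_length - length))
        out[start:start + length] = np.nan
    return out


def generate_dataset(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the synthetic panel.

    Returns
    -------
    records:
        Long-format frame with columns ``timestamp, site, location, variable,
        sensor, value`` at the grid resolution implied by ``day_length``
        (minute-level when 1440).  ``variable`` is the measured quantity
        (``temperature`` / ``pm``); ``location`` is ``indoor`` / ``outdoor``.
    ground_truth:
        One row per (site, date, variable) with prototype id, season, warp
        knot parameters (JSON), spike clock times (JSON) and the site-day
        binary outcome.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    step_min = 1440.0 / config.day_length
    start = pd.Timestamp(config.start_date) + pd.Timedelta(minutes=WINDOW_START_MINUTE)

    rec_frames: list[pd.DataFrame] = []
    gt_rows: list[dict] = []
    # per site-day features feeding the outcome model
    feat_spikes = np.zeros((config.n_sites, config.n_days))
    feat_sd = np.zeros((config.n_sites, config.n_days))

    for s in range(config.n_sites):
        site = f"site{s + 1:02d}"
        for d in range(config.n_days):
            day_start = start + pd.Timedelta(days=d)
            season = season_of_month(day_start.month)
            baseline, amplitude = config.season_model[season]
            timestamps = day_start + pd.to_timedelta(
                np.arange(config.day_length) * step_min, unit="m")
            for var in config.variables:
                location, quantity = VARIABLES[var]
                if quantity == "temperature":
                    b = baseline + (3.0 if location == "indoor" else 0.0)
                    a = amplitude * (0.4 if location == "indoor" else 1.0)
                    proto = temperature_prototype(config.day_length, b, a)
                    proto_id = f"temp_{season}_{location}"
                    spike_clock = np.empty(0)
                else:
                    n_spikes = rng.poisson(config.spike_rate)
                    anchors = rng.choice(_PM_ANCHORS, size=n_spikes)
                    spike_clock = (anchors + rng.normal(
                        0.0, config.spike_time_jitter_sd, size=n_spikes)) % 1440.0
                    amps = rng.uniform(20.0, 60.0, size=n_spikes)
                    proto = pm_prototype(config.day_length, spike_clock, amps)
                    proto_id = f"pm_{location}"
                    feat_spikes[s, d] += n_spikes

                warp_seed = int(rng.integers(0, 2**31))
                if config.warp_magnitude > 0:
                    wrng = np.random.default_rng(warp_seed)
                    src, dst = _warp_knots(config.day_length,
                                           config.warp_magnitude, wrng)
                    values = _resample_through_map(proto, src, dst)
                    knots = dst[1:-1] - src[1:-1]
                else:
                    values = proto.copy()
                    knots = np.empty(0)
                values = values + rng.normal(0.0, config.noise_sd,
                                             size=config.day_length)
                if var == "indoor_pm":
                    feat_sd[s, d] = float(np.std(values))
                if config.missing_gap_rate > 0:
                    values = _insert_gaps(values, config.missing_gap_rate,
                                          config.day_length, rng)

                rec_frames.append(pd.DataFrame({
                    "timestamp": timestamps,
                    "site": site,
                    "location": location,
                    "variable": quantity,
                    "sensor": f"{site}_{location}_{quantity}_1",
                    "value": values,
                }))
                gt_rows.append({
                    "site": site,
                    "date": day_start.date().isoformat(),
                    "variable": var,
                    "prototype_id": proto_id,
                    "season": season,
                    "warp_knot_displacements": json.dumps(
                        np.round(knots, 4).tolist()),
                    "spike_clock_minutes": json.dumps(
                        np.round(spike_clock, 2).tolist()),
                })

    # daily outcomes: logistic in standardized spike count and indoor-PM SD
    c0, c_spk, c_sd = config.outcome_logit_coefs
    if config.n_days > 0:
        z_spk = _standardize(feat_spikes)
        z_sd = _standardize(feat_sd)
        logit = c0 + c_spk * z_spk + c_sd * z_sd
        prob = 1.0 / (1.0 + np.exp(-logit))
        outcome = (rng.random(prob.shape) < prob).astype(int)
    else:
        outcome = np.zeros((config.n_sites, 0), dtype=int)

    if gt_rows:
        ground_truth = pd.DataFrame(gt_rows)
        site_idx = ground_truth["site"].str.slice(4).astype(int) - 1
        day_idx = (pd.to_datetime(ground_truth["date"])
                   - pd.Timestamp(config.start_date)).dt.days
        ground_truth["outcome"] = outcome[site_idx, day_idx]
        records = pd.concat(rec_frames, ignore_index=True)
    else:
        ground_truth = pd.DataFrame(columns=[
            "site", "date", "variable", "prototype_id", "season",
            "warp_knot_displacements", "spike_clock_minutes", "outcome"])
        records = pd.DataFrame(columns=[
            "timestamp", "site", "location", "variable", "sensor", "value"])
    return records, ground_truth


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    return (x - np.mean(x)) / sd if sd > 0 else np.zeros_like(x)
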