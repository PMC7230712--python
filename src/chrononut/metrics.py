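"""Per-day chrononutrition metrics.

Everything here operates on one (subject, day window) at a time or
assembles the full per-day metric table:

* Mifflin-St Jeor basal metabolic rate and day-length-weighted %BMR,
* first-meal latency, last-meal-to-sleep, eating window,
* kcal-weighted circular summaries of intake clock times,
* night (2300-0600) and at-work caloric fractions,
* 4-h clock-time and time-awake caloric bins.

Interval conventions: night and bin intervals are half-open ``[a, b)``;
work-interval membership is closed on both ends.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .intake import ADDITIVE_MACROS, MACRO_COLS, filter_caloric, window_key
from .schedule import DayType, DayWindow

logger = logging.getLogger(__name__)

HOURS_PER_DAY = 24.0
NIGHT_WINDOW = (23.0, 6.0)
CLOCK_BIN_WIDTH = 4.0
N_CLOCK_BINS = 6
#: time-awake bins cover up to the 36-h day-window sanity bound
N_AWAKE_BINS = 9

# Mifflin-St Jeor coefficients: weight, height, age, (male const, female const)
MSJ_ROUNDED = (10.0, 6.25, 5.0, 5.0, -161.0)
MSJ_UNROUNDED = (9.99, 6.25, 4.92, 5.0, -161.0)


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    sex: str  # "male" | "female"
    age_years: float
    height_cm: float
    weight_kg: float
    msf: Optional[float] = None  # mid-sleep on rest days, stored only

    @property
    def bmr_24h(self) -> float:
        return mifflin_st_jeor(self)


@dataclass(frozen=True)
class CircularSummary:
    """Weighted circular summary of intake times on the 24-h clock.

    ``mean_time`` is NaN (flagged undefined) when the resultant length is
    numerically zero.
    """

    mean_time: float
    rho: float
    circ_sd_h: float
    total_weight: float


def mifflin_st_jeor(profile: SubjectProfile, coefficients=MSJ_ROUNDED) -> float:
    """24-h basal metabolic rate (kcal/day).

    ``10*w + 6.25*h - 5*a + 5`` for males, ``- 161`` for females, with the
    rounded coefficients by default.
    """
    if not (profile.age_years > 0 and profile.height_cm > 0 and profile.weight_kg > 0):
        raise ValueError(f"missing or non-positive anthropometrics for {profile.subject_id}")
    cw, ch, ca, male_c, female_c = coefficients
    const = {"male": male_c, "female": female_c}.get(profile.sex)
    if const is None:
        raise ValueError(f"unknown sex {profile.sex!r}")
    bmr = cw * profile.weight_kg + ch * profile.height_cm - ca * profile.age_years + const
    if not 800 <= bmr <= 4000:
        logger.warning("BMR %.0f kcal for %s outside plausibility band", bmr, profile.subject_id)
    return bmr


def pct_bmr(total_kcal: float, bmr_24h: float, day_length_h: float) -> float:
    """Caloric intake as % of BMR weighted for day length.

    ``100 * total_kcal / (bmr_24h * day_length_h / 24)``.
    """
    if bmr_24h <= 0:
        raise ValueError("non-positive BMR")
    if day_length_h <= 0:
        raise ValueError("non-positive day length")
    return 100.0 * total_kcal / (bmr_24h * day_length_h / HOURS_PER_DAY)


def eating_window(
    events: pd.DataFrame, window: DayWindow
) -> tuple[float, float, float]:
    """Timing metrics from qualifying (>5 kcal, pre-filtered) events.

    Returns ``(first_meal_latency_h, last_meal_to_sleep_h, eating_window_h)``
    where latency is the nap-adjusted time awake at the first event,
    last-to-sleep is from the last event to the following main-sleep
    onset, and the eating window is the clock duration from first to last
    event (single event -> 0).  All NaN when no qualifying events.
    """
    if len(events) == 0:
        return (math.nan, math.nan, math.nan)
    ev = events.sort_values("timestamp")
    first = ev.iloc[0]
    last = ev.iloc[-1]
    latency = float(first["time_awake_h"]) if "time_awake_h" in ev.columns else math.nan
    last_to_sleep = (window.sleep_onset_next - last["timestamp"]) / pd.Timedelta(hours=1)
    window_h = (last["timestamp"] - first["timestamp"]) / pd.Timedelta(hours=1)
    return (latency, float(last_to_sleep), float(window_h))


def circular_summary(
    times_h: Sequence[float], weights: Sequence[float]
) -> CircularSummary:
    """Weighted circular mean, resultant length and circular SD.

    Clock times (hours, mod 24) map to angles ``2*pi*t/24``; the resultant
    is the weight-weighted vector sum.  ``rho`` is the mean resultant
    length in [0, 1]; the circular SD is ``sqrt(-2 ln rho)`` converted to
    hours.
    """
    t = np.asarray(times_h, dtype=float)
    w = np.asarray(weights, dtype=float)
    if t.shape != w.shape:
        raise ValueError("times and weights must have the same length")
    if (w < 0).any():
        raise ValueError("negative weights")
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total weight")
    theta = 2.0 * np.pi * (t % HOURS_PER_DAY) / HOURS_PER_DAY
    C = float(np.sum(w * np.cos(theta)))
    S = float(np.sum(w * np.sin(theta)))
    R = math.hypot(C, S)
    rho = R / total
    if rho < 1e-12:
        logger.warning("zero resultant: circular mean undefined")
        return CircularSummary(math.nan, 0.0, math.inf, total)
    mean_time = (math.atan2(S, C) % (2.0 * math.pi)) * HOURS_PER_DAY / (2.0 * math.pi)
    rho = min(rho, 1.0)
    circ_sd_h = (
        math.sqrt(-2.0 * math.log(rho)) * HOURS_PER_DAY / (2.0 * math.pi)
        if rho < 1.0 else 0.0
    )
    return CircularSummary(mean_time, rho, circ_sd_h, total)


def circular_difference_h(later: float, earlier: float) -> float:
    """Signed circular difference ``later - earlier`` in (-12, 12] hours."""
    d = (later - earlier) % HOURS_PER_DAY
    return d - HOURS_PER_DAY if d > 12.0 else d


def in_clock_interval(clock_h: np.ndarray, interval: tuple[float, float]) -> np.ndarray:
    """Membership of clock hours in a half-open interval, wrapping midnight."""
    a, b = interval
    c = np.asarray(clock_h, dtype=float) % HOURS_PER_DAY
    if a <= b:
        return (c >= a) & (c < b)
    return (c >= a) | (c < b)


def fraction_at_night(
    events: pd.DataFrame, night: tuple[float, float] = NIGHT_WINDOW
) -> float:
    """Percent of total kcal consumed in the night window (default 2300-0600).

    An explicit zero is returned when there is no intake at night or no
    intake at all.
    """
    if len(events) == 0 or events["kcal"].sum() <= 0:
        return 0.0
    mask = in_clock_interval(events["clock_time_h"].to_numpy(), night)
    pct = float(100.0 * events.loc[mask, "kcal"].sum() / events["kcal"].sum())
    return min(max(pct, 0.0), 100.0)


def fraction_at_work(
    events: pd.DataFrame, work_interval: Optional[tuple[pd.Timestamp, pd.Timestamp]]
) -> float:
    """Percent of total kcal with timestamps inside the work interval.

    Undefined (NaN) on rest days; zero when there is intake but none at
    work.  Membership is closed on both ends.
    """
    if work_interval is None:
        return math.nan
    if len(events) == 0 or events["kcal"].sum() <= 0:
        return 0.0
    ts = pd.to_datetime(events["timestamp"])
    mask = (ts >= work_interval[0]) & (ts <= work_interval[1])
    pct = float(100.0 * events.loc[mask, "kcal"].sum() / events["kcal"].sum())
    return min(max(pct, 0.0), 100.0)


def bin_distribution(
    events: pd.DataFrame,
    window: DayWindow,
    mode: str = "clock",
    bin_width_h: float = CLOCK_BIN_WIDTH,
) -> np.ndarray:
    """Percent of the day's kcal per 4-h bin.

    ``mode='clock'`` uses six fixed clock bins [00-04), ..., [20-24);
    ``mode='awake'`` bins nap-adjusted time awake [0-4), [4-8), ... up to
    the window length.  Bins are half-open, zero-filled, and sum to 100
    when there is any intake (all-zero otherwise).
    """
    if mode == "clock":
        n_bins = int(round(HOURS_PER_DAY / bin_width_h))
        values = events["clock_time_h"].to_numpy(dtype=float) % HOURS_PER_DAY
    elif mode == "awake":
        n_bins = int(math.ceil(window.day_length_h / bin_width_h))
        values = events["time_awake_h"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown bin mode {mode!r}")
    out = np.zeros(n_bins)
    total = events["kcal"].sum() if len(events) else 0.0
    if total <= 0:
        return out
    idx = np.floor(values / bin_width_h).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    kcal = events["kcal"].to_numpy(dtype=float)
    np.add.at(out, idx, kcal)
    return 100.0 * out / total


def compute_day_metrics(
    events: pd.DataFrame,
    windows: Sequence[DayWindow],
    subjects: dict[str, SubjectProfile],
    min_kcal: float = 5.0,
    min_events: int = 2,
    night: tuple[float, float] = NIGHT_WINDOW,
    excluded_days: Optional[list[dict]] = None,
) -> pd.DataFrame:
    """Assemble the per-(subject, day window) metric table.

    Days with fewer than ``min_events`` intake events are dropped entirely
    (recorded in ``excluded_days``).  Days with events but none exceeding
    ``min_kcal`` keep their caloric totals and get NaN timing metrics.

    Returns one row per retained day window (the ``day_metrics.csv``
    schema): %BMR totals and per-macro values, meal count, timing
    latencies, circular summary, night/work fractions, and clock/awake
    bin percentages.
    """
    assigned = events[events["window_key"].notna()]
    by_key = {window_key(w): w for w in windows}
    rows = []
    for key, w in by_key.items():
        ev = assigned[assigned["window_key"] == key]
        if len(ev) < min_events:
            if excluded_days is not None:
                excluded_days.append({
                    "subject_id": w.subject_id,
                    "date": w.date.date().isoformat(),
                    "reason": f"fewer_than_{min_events}_events",
                    "n_events": len(ev),
                })
            continue
        profile = subjects[w.subject_id]
        bmr = profile.bmr_24h
        row: dict = {
            "subject_id": w.subject_id,
            "date": w.date.date().isoformat(),
            "day_type": w.day_type.value,
            "day_length_h": w.day_length_h,
            "sleep_h": w.sleep_hours,
            "bmr_24h": bmr,
            "meal_count": int(len(ev)),
            "total_kcal": float(ev["kcal"].sum()),
            "total_pct_bmr": pct_bmr(ev["kcal"].sum(), bmr, w.day_length_h),
        }
        for col in MACRO_COLS:
            row[f"{col[:-5]}_pct_bmr"] = pct_bmr(ev[col].sum(), bmr, w.day_length_h)

        total = ev["kcal"].sum()
        for col in MACRO_COLS:
            row[f"{col[:-5]}_pct_total"] = (
                100.0 * ev[col].sum() / total if total > 0 else 0.0
            )

        qualifying = filter_caloric(ev, min_kcal)
        if len(qualifying) > 0:
            latency, to_sleep, win_h = eating_window(qualifying, w)
            summ = circular_summary(
                qualifying["clock_time_h"], qualifying["kcal"]
            )
            row.update({
                "first_meal_latency_h": latency,
                "last_meal_to_sleep_h": to_sleep,
                "eating_window_h": win_h,
                "circ_mean_time_h": summ.mean_time,
                "circ_rho": summ.rho,
                "circ_sd_h": summ.circ_sd_h,
            })
        else:
            row.update({
                "first_meal_latency_h": math.nan,
                "last_meal_to_sleep_h": math.nan,
                "eating_window_h": math.nan,
                "circ_mean_time_h": math.nan,
                "circ_rho": math.nan,
                "circ_sd_h": math.nan,
            })

        row["pct_at_night"] = fraction_at_night(ev, night)
        if w.day_length_h > HOURS_PER_DAY:
            # a >24-h window contains some clock times twice; flag it
            row["night_span_repeats"] = True
        else:
            row["night_span_repeats"] = False
        row["pct_at_work"] = fraction_at_work(
            ev, w.work_interval if w.day_type != DayType.REST else None
        )

        clock_bins = bin_distribution(ev, w, mode="clock")
        for i, v in enumerate(clock_bins):
            row[f"clock_bin_{4 * i:02d}_{4 * (i + 1):02d}"] = v
        awake_bins = bin_distribution(ev, w, mode="awake")
        for i in range(N_AWAKE_BINS):
            row[f"awake_bin_{4 * i}_{4 * (i + 1)}"] = (
                awake_bins[i] if i < len(awake_bins) else math.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
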