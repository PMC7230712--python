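"""Work-schedule and sleep structure: shift classification, main-sleep
resolution, and wake-to-wake day windows.

Conventions
-----------
* Timestamps are timezone-naive local clock times; DST transitions are out
  of scope.
* A shift is *excluded* when its duration exceeds 13.5 h or falls below
  4.5 h (strict inequalities).
* Classification precedence is night > evening > morning: a shift is a
  night shift if it contains the entire 0100-0500 span, else an evening
  shift if its end clock time lies in [2200, 0200], else a morning shift
  if its start clock time lies in [0500, 0900]; anything else is
  unclassified.
* A sleep episode belongs to the calendar day of its onset; within each
  calendar day the longest episode is the main sleep (ties broken by
  earlier onset).
* A day window runs from the wake of one main sleep to the wake of the
  next, and is labeled by the class of the shift starting inside it, or
  ``rest`` when there is none.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: duration bounds (hours) outside of which a shift is excluded
MIN_SHIFT_HOURS = 4.5
MAX_SHIFT_HOURS = 13.5

#: clock-hour span that must be fully contained for a night shift
NIGHT_CORE = (1.0, 5.0)
#: end-of-work clock interval for evening shifts, wrapping midnight
EVENING_END = (22.0, 2.0)
#: start-of-work clock interval for morning shifts
MORNING_START = (5.0, 9.0)

#: sanity bounds (hours) on a wake-to-wake day window
MIN_DAY_LENGTH = 12.0
MAX_DAY_LENGTH = 36.0


class ShiftClass(str, Enum):
    MORNING = "morning"
    EVENING = "evening"
    NIGHT = "night"
    EXCLUDED = "excluded"
    UNCLASSIFIED = "unclassified"


class DayType(str, Enum):
    REST = "rest"
    MORNING = "morning"
    EVENING = "evening"
    NIGHT = "night"


@dataclass(frozen=True)
class ShiftRecord:
    subject_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    shift_class: ShiftClass


@dataclass(frozen=True)
class SleepEpisode:
    subject_id: str
    onset: pd.Timestamp
    wake: pd.Timestamp
    is_main: bool = False

    @property
    def duration_h(self) -> float:
        return (self.wake - self.onset) / pd.Timedelta(hours=1)


@dataclass
class DayWindow:
    """One wake-to-wake analysis day.

    ``start`` is the wake of the preceding main sleep, ``end`` the wake of
    the following one.  ``sleep_onset_next`` (onset of the following main
    sleep) closes the wake period and anchors last-meal-to-sleep metrics.
    ``sleep_hours`` is the total sleep overlapping the window, which
    includes the full following main sleep and any naps.
    """

    subject_id: str
    date: pd.Timestamp
    day_type: DayType
    start: pd.Timestamp
    end: pd.Timestamp
    sleep_onset_next: pd.Timestamp
    naps: list[SleepEpisode] = field(default_factory=list)
    sleep_hours: float = 0.0
    work_interval: Optional[tuple[pd.Timestamp, pd.Timestamp]] = None

    @property
    def day_length_h(self) -> float:
        return (self.end - self.start) / pd.Timedelta(hours=1)


def _clock_hours(ts: pd.Timestamp) -> float:
    return ts.hour + ts.minute / 60.0 + ts.second / 3600.0 + ts.microsecond / 3.6e9


def classify_shift(start: pd.Timestamp, end: pd.Timestamp) -> ShiftClass:
    """Classify a work period by its timing.

    Parameters
    ----------
    start, end : pd.Timestamp
        Work start and end; ``end`` must be after ``start`` and the
        duration below 48 h.

    Returns
    -------
    ShiftClass
    """
    start = pd.Timestamp(start)
    end = pd.Timestamp(end)
    duration_h = (end - start) / pd.Timedelta(hours=1)
    if duration_h <= 0:
        raise ValueError(f"non-positive shift duration: {start} -> {end}")
    if duration_h >= 48:
        raise ValueError(f"implausible shift duration {duration_h:.1f} h")

    if duration_h > MAX_SHIFT_HOURS or duration_h < MIN_SHIFT_HOURS:
        return ShiftClass.EXCLUDED

    # night: the work interval contains the entire 0100-0500 span
    for day_offset in (0, 1):
        core_start = start.normalize() + pd.Timedelta(days=day_offset, hours=NIGHT_CORE[0])
        core_end = start.normalize() + pd.Timedelta(days=day_offset, hours=NIGHT_CORE[1])
        if start <= core_start and end >= core_end:
            return ShiftClass.NIGHT

    end_clock = _clock_hours(end)
    if end_clock >= EVENING_END[0] or end_clock <= EVENING_END[1]:
        return ShiftClass.EVENING

    start_clock = _clock_hours(start)
    if MORNING_START[0] <= start_clock <= MORNING_START[1]:
        return ShiftClass.MORNING

    return ShiftClass.UNCLASSIFIED


def classify_shifts(work: pd.DataFrame) -> pd.DataFrame:
    """Classify every row of a work log (columns ``subject_id, start, end``)."""
    out = work.copy()
    out["start"] = pd.to_datetime(out["start"])
    out["end"] = pd.to_datetime(out["end"])
    out["shift_class"] = [
        classify_shift(s, e).value for s, e in zip(out["start"], out["end"])
    ]
    return out


def resolve_main_sleep(sleep: pd.DataFrame) -> pd.DataFrame:
    """Flag the main sleep per subject and calendar day.

    Within each (subject, onset calendar day) group the longest episode is
    the main sleep; equal durations are broken by earlier onset.  Episodes
    of a subject must be pairwise disjoint.

    Parameters
    ----------
    sleep : pd.DataFrame
        Columns ``subject_id, onset, wake``.

    Returns
    -------
    pd.DataFrame
        Copy with a boolean ``is_main`` column.
    """
    out = sleep.copy()
    out["onset"] = pd.to_datetime(out["onset"])
    out["wake"] = pd.to_datetime(out["wake"])
    if (out["wake"] <= out["onset"]).any():
        bad = out.index[out["wake"] <= out["onset"]].tolist()
        raise ValueError(f"sleep episodes with wake <= onset at rows {bad}")

    out = out.sort_values(["subject_id", "onset"], kind="mergesort").reset_index(drop=True)
    for _, grp in out.groupby("subject_id"):
        overlap = grp["onset"].values[1:] < grp["wake"].values[:-1]
        if overlap.any():
            raise ValueError(f"overlapping sleep episodes for subject {grp['subject_id'].iloc[0]}")

    dur = out["wake"] - out["onset"]
    day = out["onset"].dt.normalize()
    out["is_main"] = False
    for _, grp in out.groupby(["subject_id", day], sort=False):
        # idxmax on duration; ties resolve to the earliest onset because
        # rows are onset-sorted and idxmax returns the first maximum
        out.loc[dur.loc[grp.index].idxmax(), "is_main"] = True
    return out


def build_day_windows(
    shifts: pd.DataFrame,
    sleep: pd.DataFrame,
    diagnostics: Optional[list[dict]] = None,
) -> list[DayWindow]:
    """Construct wake-to-wake day windows for every subject.

    Windows spanning less than 12 h or more than 36 h, and windows whose
    enclosed shift is excluded or unclassified, are skipped with a
    diagnostic record.

    Parameters
    ----------
    shifts : pd.DataFrame
        Classified work log (``subject_id, start, end, shift_class``).
    sleep : pd.DataFrame
        Sleep log with ``is_main`` resolved.
    diagnostics : list, optional
        If given, skipped-window records are appended to it.

    Returns
    -------
    list of DayWindow
    """
    if "shift_class" not in shifts.columns:
        shifts = classify_shifts(shifts)
    if "is_main" not in sleep.columns:
        sleep = resolve_main_sleep(sleep)
    windows: list[DayWindow] = []

    for subject_id, s_sleep in sleep.groupby("subject_id"):
        s_sleep = s_sleep.sort_values("onset")
        mains = s_sleep[s_sleep["is_main"]].reset_index(drop=True)
        s_shifts = shifts[shifts["subject_id"] == subject_id]
        for i in range(len(mains) - 1):
            w_start = mains.loc[i, "wake"]
            w_end = mains.loc[i + 1, "wake"]
            onset_next = mains.loc[i + 1, "onset"]
            length_h = (w_end - w_start) / pd.Timedelta(hours=1)
            if not (MIN_DAY_LENGTH < length_h < MAX_DAY_LENGTH):
                _diag(diagnostics, subject_id, w_start, "day_length_out_of_bounds",
                      day_length_h=length_h, window_end=w_end)
                continue

            enclosed = s_shifts[(s_shifts["start"] >= w_start) & (s_shifts["start"] < w_end)]
            if len(enclosed) == 0:
                day_type = DayType.REST
                work_interval = None
            else:
                if len(enclosed) > 1:
                    logger.warning(
                        "subject %s window starting %s encloses %d shifts; using the first",
                        subject_id, w_start, len(enclosed),
                    )
                row = enclosed.iloc[0]
                cls = ShiftClass(row["shift_class"])
                if cls in (ShiftClass.EXCLUDED, ShiftClass.UNCLASSIFIED):
                    _diag(diagnostics, subject_id, w_start, f"shift_{cls.value}",
                          day_length_h=length_h, window_end=w_end)
                    continue
                day_type = DayType(cls.value)
                work_interval = (row["start"], row["end"])

            naps = [
                SleepEpisode(subject_id, r["onset"], r["wake"], False)
                for _, r in s_sleep[~s_sleep["is_main"]].iterrows()
                if r["onset"] >= w_start and r["onset"] < w_end
            ]
            sleep_h = _overlap_hours(s_sleep, w_start, w_end)
            windows.append(
                DayWindow(
                    subject_id=subject_id,
                    date=w_start.normalize(),
                    day_type=day_type,
                    start=w_start,
                    end=w_end,
                    sleep_onset_next=onset_next,
                    naps=naps,
                    sleep_hours=sleep_h,
                    work_interval=work_interval,
                )
            )
    return windows


def build_day_window(
    subject_id: str,
    target_day: pd.Timestamp,
    shifts: pd.DataFrame,
    sleep: pd.DataFrame,
) -> Optional[DayWindow]:
    """Build the day window whose start falls on ``target_day``.

    Returns ``None`` (with a log diagnostic) when the flanking main sleeps
    do not exist or the window fails validation.
    """
    target_day = pd.Timestamp(target_day).normalize()
    diagnostics: list[dict] = []
    for w in build_day_windows(shifts, sleep, diagnostics):
        if w.subject_id == subject_id and w.start.normalize() == target_day:
            return w
    logger.warning("no constructible day window for subject %s on %s",
                   subject_id, target_day.date())
    return None


def sleep_fraction(window: DayWindow) -> float:
    """Proportion of the day window spent asleep, in [0, 1]."""
    if window.day_length_h <= 0:
        raise ValueError("day window has non-positive length")
    frac = window.sleep_hours / window.day_length_h
    if frac >= 1.0:
        logger.warning("degenerate window for subject %s on %s: slept the whole day",
                       window.subject_id, window.date.date())
    return min(max(frac, 0.0), 1.0)


def windows_to_frame(windows: Sequence[DayWindow]) -> pd.DataFrame:
    """Flatten day windows to the ``day_windows.csv`` schema."""
    rows = []
    for w in windows:
        rows.append({
            "subject_id": w.subject_id,
            "date": w.date.date().isoformat(),
            "day_type": w.day_type.value,
            "window_start": w.start,
            "window_end": w.end,
            "day_length_h": w.day_length_h,
            "sleep_h": w.sleep_hours,
            "work_start": w.work_interval[0] if w.work_interval else pd.NaT,
            "work_end": w.work_interval[1] if w.work_interval else pd.NaT,
        })
    return pd.DataFrame(rows, columns=[
        "subject_id", "date", "day_type", "window_start", "window_end",
        "day_length_h", "sleep_h", "work_start", "work_end",
    ])


def _overlap_hours(sleep: pd.DataFrame, start: pd.Timestamp, end: pd.Timestamp) -> float:
    lo = sleep["onset"].clip(lower=start)
    hi = sleep["wake"].clip(upper=end)
    dur = (hi - lo).clip(lower=pd.Timedelta(0))
    return float(dur.sum() / pd.Timedelta(hours=1))


def _diag(diagnostics, subject_id, window_start, reason, **extra):
    logger.info("skipping window for %s starting %s: %s", subject_id, window_start, reason)
    if diagnostics is not None:
        diagnostics.append({
            "subject_id": subject_id,
            "window_start": window_start,
            "reason": reason,
            **extra,
        })
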