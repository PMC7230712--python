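"""Meal-log ingestion: validation, merging of same-type records into
intake events, and assignment of events to day windows.

Successive records of the same meal type logged within 15 minutes of each
other (chained pairwise in time order) are combined into one intake event
carrying the timestamp of the last record and the summed calories.  Merging
is applied regardless of intervening sleep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .schedule import DayWindow

logger = logging.getLogger(__name__)

MERGE_GAP = pd.Timedelta(minutes=15)

MEAL_TYPES = ("breakfast", "lunch", "dinner", "snack", "beverage_only")
MACRO_COLS = ("carb_kcal", "sugar_kcal", "fat_kcal", "satfat_kcal",
              "protein_kcal", "alcohol_kcal")
#: macro components that partition total kcal (sugar/satfat are subsets)
ADDITIVE_MACROS = ("carb_kcal", "fat_kcal", "protein_kcal", "alcohol_kcal")

MEAL_SCHEMA = ("subject_id", "timestamp", "meal_type", "kcal") + MACRO_COLS


@dataclass(frozen=True)
class IntakeEvent:
    subject_id: str
    timestamp: pd.Timestamp
    meal_type: str
    kcal: float
    n_merged: int


def load_meals(path) -> pd.DataFrame:
    """Read and validate a meal log CSV (``meals.csv`` schema)."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return validate_meal_log(df)


def validate_meal_log(df: pd.DataFrame, tol: float = 1e-3) -> pd.DataFrame:
    """Check the meal-log schema and macro consistency.

    Raises
    ------
    ValueError
        On missing columns, negative calories, sugar exceeding
        carbohydrate (or saturated fat exceeding fat), or additive macro
        kcal departing from total kcal by more than ``tol`` (relative).
    """
    missing = [c for c in MEAL_SCHEMA if c not in df.columns]
    if missing:
        raise ValueError(f"meal log missing columns: {missing}")
    df = df.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    num = ["kcal", *MACRO_COLS]
    if (df[num] < 0).any().any():
        raise ValueError("negative kcal values in meal log")
    if (df["sugar_kcal"] > df["carb_kcal"] * (1 + tol) + tol).any():
        raise ValueError("sugar_kcal exceeds carb_kcal")
    if (df["satfat_kcal"] > df["fat_kcal"] * (1 + tol) + tol).any():
        raise ValueError("satfat_kcal exceeds fat_kcal")
    additive = df[list(ADDITIVE_MACROS)].sum(axis=1)
    rel = (additive - df["kcal"]).abs() / df["kcal"].clip(lower=1.0)
    if (rel > tol).any():
        raise ValueError("macro kcal components do not sum to total kcal")
    bad_type = ~df["meal_type"].isin(MEAL_TYPES)
    if bad_type.any():
        raise ValueError(f"unknown meal types: {sorted(df.loc[bad_type, 'meal_type'].unique())}")
    return df


def merge_intakes(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge same-type records within 15 min into intake events.

    Chains are formed per subject and meal type in time order: a record
    joins the current chain while its gap to the previous same-type record
    is at most 15 minutes.  Events carry the timestamp of the last merged
    record and the summed kcal / macro kcal.

    Parameters
    ----------
    records : pd.DataFrame
        Meal log in the ``meals.csv`` schema.

    Returns
    -------
    events : pd.DataFrame
        One row per intake event with an ``event_id`` and ``n_merged``.
    record_map : pd.DataFrame
        ``record_index`` (original row label) -> ``event_id``.
    """
    if (records["kcal"] < 0).any():
        raise ValueError("negative kcal")
    df = records.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["_record_index"] = df.index
    df = df.sort_values(["subject_id", "meal_type", "timestamp"], kind="mergesort")

    gap = df.groupby(["subject_id", "meal_type"], sort=False)["timestamp"].diff()
    new_chain = gap.isna() | (gap > MERGE_GAP)
    df["_chain"] = new_chain.cumsum()

    agg = {"kcal": "sum", **{c: "sum" for c in MACRO_COLS}}
    grouped = df.groupby("_chain", sort=False)
    events = grouped.agg(
        subject_id=("subject_id", "first"),
        timestamp=("timestamp", "last"),
        meal_type=("meal_type", "first"),
        n_merged=("timestamp", "size"),
        **{k: (k, v) for k, v in agg.items()},
    )
    events = events.sort_values(["subject_id", "timestamp"], kind="mergesort").reset_index()
    events = events.rename(columns={"_chain": "_chain_id"})
    events["event_id"] = np.arange(len(events))
    chain_to_event = dict(zip(events["_chain_id"], events["event_id"]))
    record_map = pd.DataFrame({
        "record_index": df["_record_index"].to_numpy(),
        "event_id": df["_chain"].map(chain_to_event).to_numpy(),
    }).sort_values("record_index").reset_index(drop=True)
    events = events.drop(columns="_chain_id")
    cols = ["event_id", "subject_id", "timestamp", "meal_type", "n_merged",
            "kcal", *MACRO_COLS]
    return events[cols], record_map


def assign_to_window(
    events: pd.DataFrame,
    windows: Sequence[DayWindow],
    diagnostics: Optional[list[dict]] = None,
) -> pd.DataFrame:
    """Attach day-window references and time-awake to intake events.

    ``time_awake_h`` is the elapsed time since the window's wake, minus
    sleep already accrued in naps overlapping ``[window.start, event]``
    (an event during a nap is credited only with the nap portion not yet
    slept).  Events falling in no window are retained with a null
    ``window_key`` and a diagnostic.

    Returns a copy of ``events`` with ``window_key``, ``day_type``,
    ``clock_time_h`` and ``time_awake_h`` columns.
    """
    out = events.copy()
    ts = pd.to_datetime(out["timestamp"])
    out["clock_time_h"] = (
        ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0
    )
    out["window_key"] = None
    out["day_type"] = None
    out["time_awake_h"] = np.nan

    by_subject: dict[str, list[DayWindow]] = {}
    for w in windows:
        by_subject.setdefault(w.subject_id, []).append(w)
    for subj in by_subject:
        by_subject[subj].sort(key=lambda w: w.start)

    for idx, row in out.iterrows():
        t = row["timestamp"]
        subj_windows = by_subject.get(row["subject_id"], [])
        hit = None
        for w in subj_windows:
            if w.start <= t < w.end:
                hit = w
                break
        if hit is None:
            if diagnostics is not None:
                diagnostics.append({
                    "subject_id": row["subject_id"],
                    "timestamp": t,
                    "reason": "no_matching_window",
                })
            logger.debug("event at %s for %s matches no window", t, row["subject_id"])
            continue
        nap_h = 0.0
        for nap in hit.naps:
            lo = max(nap.onset, hit.start)
            hi = min(nap.wake, t)
            if hi > lo:
                nap_h += (hi - lo) / pd.Timedelta(hours=1)
        out.at[idx, "window_key"] = window_key(hit)
        out.at[idx, "day_type"] = hit.day_type.value
        out.at[idx, "time_awake_h"] = (t - hit.start) / pd.Timedelta(hours=1) - nap_h
    return out


def filter_caloric(events: pd.DataFrame, min_kcal: float = 5.0) -> pd.DataFrame:
    """Retain events with kcal strictly above ``min_kcal``.

    Used only for timing metrics (first/last meal, eating window,
    circular statistics); caloric totals always use all events.
    """
    return events[events["kcal"] > min_kcal].copy()


def window_key(window: DayWindow) -> str:
    """Stable identifier for a day window: ``<subject>@<start date>``."""
    return f"{window.subject_id}@{window.start.normalize().date().isoformat()}"
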