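"""Synthetic rotating-shift datasets with known ground truth.

The generator emulates the structure of a field study of rotating-shift
patrol officers: 35-day rosters mixing 9/12-h morning shifts, evening
shifts and night shifts (or 28-day rosters of 12-h day/night shifts),
day-type-conditional sleep timing, and meal logs whose clock times follow
a von Mises mixture restricted to the wake period, with lognormal meal
calories and Dirichlet-compositional macronutrients.

Ground truth (generator component means plus empirical per-day circular
summaries recomputable from the emitted records) is carried alongside so
every downstream stage can be tested without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special

from . import metrics as _metrics
from .intake import MACRO_COLS

HOURS = pd.Timedelta(hours=1)

ROSTER_KINDS = ("cycle35", "cycle28")

#: shift-time catalogue (start hour, end hour relative to the start day)
MORNING_SHIFTS = ((7.0, 16.0), (7.0, 19.0))
EVENING_SHIFTS = ((15.0, 24.0),)
NIGHT_SHIFTS = ((22.5, 31.5), (23.0, 32.0), (19.0, 31.0))
DAY12 = (7.0, 19.0)
NIGHT12 = (19.0, 31.0)

# label sequences; all work runs have length >= 2 and the second day of a
# run is the designated collection day, so collection windows are flanked
# by same-type days
_TEMPLATE_35 = (
    "MMM" "RRR" "EEE" "RRR" "NNN" "RRR" "MMMM" "RRR" "EEE" "RR" "NNN" "RR"
)
_TEMPLATE_28 = "DDDRNNR" * 4

_LABEL_NAMES = {"M": "morning", "D": "morning", "E": "evening", "N": "night", "R": "rest"}


@dataclass(frozen=True)
class MealTimingParams:
    """Meal process for one day type.

    ``components`` is a von Mises mixture over the 24-h clock given as
    ``(mu_hours, kappa, weight)`` triples; weights must sum to one and a
    day's meal count is ``Poisson(n_meals_mean) + 1``.
    """

    components: tuple[tuple[float, float, float], ...]
    n_meals_mean: float
    kcal_log_mu: float
    kcal_log_sigma: float
    macro_alpha: tuple[float, float, float]  # carb, fat, protein

    def validate(self) -> None:
        w = sum(c[2] for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"component weights sum to {w}, not 1")
        if any(c[1] < 0 for c in self.components):
            raise ValueError("negative von Mises concentration")
        if any(a <= 0 for a in self.macro_alpha):
            raise ValueError("macro_alpha must be strictly positive")
        if self.n_meals_mean <= 0:
            raise ValueError("n_meals_mean must be positive")


@dataclass(frozen=True)
class SleepTimingParams:
    """Day-type-conditional sleep anchors.

    ``wake_mean_h`` is the wake clock time on the day itself;
    ``onset_mean_h`` is the sleep onset ending that day's wake period,
    expressed in hours from that day's midnight (values above 24 land on
    the next calendar day).  SDs are minutes of between-day jitter.
    """

    wake_mean_h: float
    wake_sd_min: float
    onset_mean_h: float
    onset_sd_min: float

    def validate(self) -> None:
        if self.wake_sd_min < 0 or self.onset_sd_min < 0:
            raise ValueError("sleep-timing SDs must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    n_subjects: int = 31
    roster_kind: str = "cycle35"
    day_type_params: dict = field(default_factory=lambda: dict(DEFAULT_MEAL_PARAMS))
    sleep_params: dict = field(default_factory=lambda: dict(DEFAULT_SLEEP_PARAMS))
    seed: int = 0
    start_date: str = "2024-01-01"
    nap_probability: float = 0.25
    nap_minutes: float = 45.0
    duplicate_prob: float = 0.15
    recovery_sleep_h: float = 7.25
    female_fraction: float = 6 / 31

    def validate(self) -> None:
        if self.roster_kind not in ROSTER_KINDS:
            raise ValueError(f"unknown roster_kind {self.roster_kind!r}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        present = {_LABEL_NAMES[c] for c in _template(self.roster_kind)}
        for day_type in present:
            if day_type not in self.sleep_params:
                raise ValueError(f"missing sleep parameters for day type {day_type!r}")
            if day_type not in self.day_type_params:
                raise ValueError(f"missing meal parameters for day type {day_type!r}")
            self.sleep_params[day_type].validate()
            self.day_type_params[day_type].validate()


DEFAULT_SLEEP_PARAMS = {
    "rest": SleepTimingParams(8.0, 24.0, 22.0 + 56 / 60, 18.0),
    "morning": SleepTimingParams(5.0 + 32 / 60, 7.0, 22.25, 15.0),
    "evening": SleepTimingParams(8.0 + 34 / 60, 26.0, 24.0 + 1 + 11 / 60, 9.0),
    "night": SleepTimingParams(15.0 + 58 / 60, 39.0, 24.0 + 9 + 14 / 60, 17.0),
}

DEFAULT_MEAL_PARAMS = {
    "rest": MealTimingParams(((15.5, 2.0, 1.0),), 6.5, 5.75, 0.55, (11.0, 9.0, 4.5)),
    "morning": MealTimingParams(((14.2, 2.0, 1.0),), 5.3, 5.89, 0.55, (11.0, 9.0, 4.5)),
    "evening": MealTimingParams(((15.0, 2.2, 1.0),), 4.0, 5.90, 0.55, (11.0, 9.0, 4.5)),
    # a ~0.30-weight nocturnal component mirrors the night-shift pattern
    "night": MealTimingParams(
        ((18.5, 2.5, 0.68), (1.0, 8.0, 0.32)), 4.9, 5.92, 0.55, (11.0, 9.0, 4.5)
    ),
}


@dataclass
class SyntheticDataset:
    subjects: pd.DataFrame
    work: pd.DataFrame
    sleep: pd.DataFrame
    meals: pd.DataFrame
    ground_truth: pd.DataFrame
    day_labels: pd.DataFrame
    config: GeneratorConfig


def default_config(**overrides) -> GeneratorConfig:
    cfg = GeneratorConfig(**overrides)
    cfg.validate()
    return cfg


def recovery_config(
    n_subjects: int = 30, kappa: float = 8.0, seed: int = 0, **overrides
) -> GeneratorConfig:
    """Config with one concentrated meal-time component per day type, for
    parameter-recovery checks (the mixture mean equals the component mu).
    """
    mus = {"rest": 15.0, "morning": 14.0, "evening": 15.5, "night": 23.0}
    params = {
        k: replace(DEFAULT_MEAL_PARAMS[k], components=((mus[k], kappa, 1.0),))
        for k in DEFAULT_MEAL_PARAMS
    }
    return default_config(
        n_subjects=n_subjects, seed=seed, day_type_params=params,
        duplicate_prob=0.0, **overrides,
    )


def _template(roster_kind: str) -> str:
    if roster_kind == "cycle35":
        return _TEMPLATE_35
    if roster_kind == "cycle28":
        return _TEMPLATE_28
    raise ValueError(f"unknown roster_kind {roster_kind!r}")


def mixture_circular_mean(components: Sequence[tuple[float, float, float]]) -> float:
    """Analytic circular mean (hours) of a von Mises mixture over the clock.

    Each component contributes a vector of length ``weight * A(kappa)``
    (``A = I1/I0``) in the direction of its mu.
    """
    C = S = 0.0
    for mu, kappa, w in components:
        a = 1.0 if math.isinf(kappa) else float(special.i1e(kappa) / special.i0e(kappa))
        theta = 2 * math.pi * (mu % 24.0) / 24.0
        C += w * a * math.cos(theta)
        S += w * a * math.sin(theta)
    if math.hypot(C, S) < 1e-12:
        return math.nan
    return (math.atan2(S, C) % (2 * math.pi)) * 24.0 / (2 * math.pi)


# --- roster -----------------------------------------------------------------

def generate_roster(config: GeneratorConfig, subject_index: int = 0) -> pd.DataFrame:
    """Shift records for one subject over a full roster cycle.

    Returns a DataFrame with ``subject_id, start, end, intended_class``;
    rest days contribute no rows.  Shift times come from the catalogue,
    with the variant rotated deterministically by subject and run so both
    9-h and 12-h morning shifts and all night variants appear.
    """
    config.validate()
    template = _template(config.roster_kind)
    base = pd.Timestamp(config.start_date)
    subject_id = _subject_id(subject_index)
    rows = []
    run_counts = {"M": 0, "E": 0, "N": 0, "D": 0}
    prev = "R"
    for day, code in enumerate(template):
        if code != "R" and code != prev:
            run_counts[code] += 1
        prev = code
        if code == "R":
            continue
        if config.roster_kind == "cycle28":
            start_h, end_h = DAY12 if code == "D" else NIGHT12
        elif code == "M":
            variants = MORNING_SHIFTS
            start_h, end_h = variants[(subject_index + run_counts["M"]) % len(variants)]
        elif code == "E":
            start_h, end_h = EVENING_SHIFTS[0]
        else:
            variants = NIGHT_SHIFTS
            start_h, end_h = variants[(subject_index + run_counts["N"]) % len(variants)]
        start = base + pd.Timedelta(days=day, hours=start_h)
        end = base + pd.Timedelta(days=day, hours=end_h)
        rows.append({
            "subject_id": subject_id,
            "start": start,
            "end": end,
            "intended_class": _LABEL_NAMES[code],
        })
    return pd.DataFrame(rows, columns=["subject_id", "start", "end", "intended_class"])


def roster_day_labels(config: GeneratorConfig, subject_index: int = 0) -> pd.DataFrame:
    """Per-calendar-day intended day types, with the second day of each
    work/rest run flagged as the designated collection day."""
    template = _template(config.roster_kind)
    base = pd.Timestamp(config.start_date)
    rows = []
    for day, code in enumerate(template):
        run_pos = 0
        j = day
        while j >= 0 and template[j] == code:
            run_pos += 1
            j -= 1
        rows.append({
            "subject_id": _subject_id(subject_index),
            "date": (base + pd.Timedelta(days=day)).date().isoformat(),
            "day_type": _LABEL_NAMES[code],
            "is_collection": run_pos == 2,
        })
    return pd.DataFrame(rows)


def _subject_id(index: int) -> str:
    return f"S{index + 1:03d}"


# --- sleep ------------------------------------------------------------------

def generate_sleep(
    roster: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator,
    max_retries: int = 25,
) -> pd.DataFrame:
    """Sleep episodes for one subject across the roster.

    One main sleep closes every day's wake period; onsets and wakes are
    drawn from the day-type-conditional anchors.  The first night-shift
    day of a run keeps a rest-like wake (the daytime-sleep anchor applies
    from the second night onward) and later night days may carry a short
    pre-shift nap.  Episodes are pairwise disjoint and a main sleep never
    overlaps the shift it precedes (violating draws are retried, then an
    error is raised).
    """
    if len(roster) == 0:
        raise ValueError("empty roster")
    config.validate()
    subject_id = roster["subject_id"].iloc[0]
    template = _template(config.roster_kind)
    n_days = len(template)
    base = pd.Timestamp(config.start_date)
    labels = [_LABEL_NAMES[c] for c in template]

    shift_start_by_day = {}
    for _, row in roster.iterrows():
        shift_start_by_day[(row["start"].normalize() - base).days] = row["start"]

    def wake_anchor(day: int) -> SleepTimingParams:
        if day >= n_days:
            return config.sleep_params["rest"]
        label = labels[day]
        if label == "night" and (day == 0 or labels[day - 1] != "night"):
            return config.sleep_params["rest"]  # first night of a run
        return config.sleep_params[label]

    # wake_h[d]: wake clock hours on day d; onset_h[d]: onset hours from
    # day d midnight (may exceed 24)
    wake_h = np.empty(n_days + 1)
    onset_h = np.empty(n_days + 1)
    for d in range(n_days + 1):
        p = wake_anchor(d)
        wake_h[d] = p.wake_mean_h + rng.normal(0, p.wake_sd_min) / 60.0
        label = labels[d] if d < n_days else "rest"
        po = config.sleep_params[label]
        onset_h[d] = po.onset_mean_h + rng.normal(0, po.onset_sd_min) / 60.0

    episodes = []
    # leading main sleep so the first day has a preceding wake
    lead = config.sleep_params["rest"]
    lead_onset = base + pd.Timedelta(days=-1, hours=lead.onset_mean_h
                                     + rng.normal(0, lead.onset_sd_min) / 60.0)
    prev_onset = lead_onset
    for d in range(n_days + 1):
        wake = base + pd.Timedelta(days=d, hours=wake_h[d])
        if wake <= prev_onset:
            # recovery sleep after a night run ending into a normal day
            wake = prev_onset + pd.Timedelta(
                hours=config.recovery_sleep_h + rng.normal(0, 0.25)
            )
        shift_start = shift_start_by_day.get(d)
        if shift_start is not None:
            for attempt in range(max_retries + 1):
                if wake < shift_start:
                    break
                if attempt == max_retries:
                    raise ValueError(
                        f"cannot place wake before shift start on day {d} "
                        f"for subject {subject_id}"
                    )
                p = wake_anchor(d)
                wake = base + pd.Timedelta(
                    days=d, hours=p.wake_mean_h + rng.normal(0, p.wake_sd_min) / 60.0
                )
                if wake <= prev_onset:
                    wake = shift_start - pd.Timedelta(minutes=20)
        episodes.append({"subject_id": subject_id, "onset": prev_onset, "wake": wake})
        if d < n_days:
            onset = base + pd.Timedelta(days=d, hours=onset_h[d])
            shift = shift_start_by_day.get(d)
            if shift is not None:
                shift_end = roster.loc[roster["start"] == shift, "end"].iloc[0]
                if onset < shift_end:
                    onset = shift_end + pd.Timedelta(minutes=10)
            if onset <= wake:
                onset = wake + pd.Timedelta(hours=8)
            prev_onset = onset

    # optional naps before the second and later night shifts of a run
    for d in range(n_days):
        if labels[d] != "night" or d == 0 or labels[d - 1] != "night":
            continue
        if rng.random() >= config.nap_probability:
            continue
        shift_start = shift_start_by_day.get(d)
        if shift_start is None:
            continue
        main_wake = next(
            (e["wake"] for e in episodes
             if (e["wake"].normalize() - base).days == d), None
        )
        if main_wake is None:
            continue
        nap_onset = max(
            main_wake + pd.Timedelta(minutes=45),
            shift_start - pd.Timedelta(hours=3.5) + pd.Timedelta(minutes=rng.uniform(-20, 20)),
        )
        nap_wake = nap_onset + pd.Timedelta(minutes=config.nap_minutes)
        if nap_wake > shift_start - pd.Timedelta(minutes=30):
            continue
        episodes.append({"subject_id": subject_id, "onset": nap_onset, "wake": nap_wake})

    df = pd.DataFrame(episodes).sort_values("onset", kind="mergesort").reset_index(drop=True)
    if (df["onset"].values[1:] < df["wake"].values[:-1]).any():
        raise AssertionError("generated overlapping sleep episodes")
    return df


# --- meals ------------------------------------------------------------------

def sample_clock_times(
    n: int,
    components: Sequence[tuple[float, float, float]],
    period_start: pd.Timestamp,
    period_end: pd.Timestamp,
    rng: np.random.Generator,
    max_tries: int = 300,
) -> list[pd.Timestamp]:
    """Draw timestamps whose clock times follow the von Mises mixture,
    restricted (by rejection) to ``[period_start, period_end)``."""
    if period_end <= period_start:
        raise ValueError("empty wake period")
    weights = np.array([c[2] for c in components], dtype=float)
    weights = weights / weights.sum()
    comp_idx = rng.choice(len(components), size=n, p=weights)
    base = period_start.normalize()
    out = []
    for j in comp_idx:
        mu, kappa, _ = components[j]
        placed = None
        for _ in range(max_tries):
            if kappa > 1e6:
                clock = mu % 24.0
            elif kappa <= 0:
                clock = rng.uniform(0.0, 24.0)
            else:
                theta = rng.vonmises(2 * math.pi * (mu % 24.0) / 24.0, kappa)
                clock = (theta % (2 * math.pi)) * 24.0 / (2 * math.pi)
            for k in range(3):
                t = base + pd.Timedelta(days=k, hours=clock)
                if period_start <= t < period_end:
                    placed = t
                    break
            if placed is not None:
                break
        if placed is None:
            placed = period_start + (period_end - period_start) * rng.random()
        out.append(placed)
    return out


def _meal_type_for_clock(clock_h: float) -> str:
    if 5.0 <= clock_h < 10.5:
        return "breakfast"
    if 10.5 <= clock_h < 14.5:
        return "lunch"
    if 14.5 <= clock_h < 21.5:
        return "dinner"
    return "snack"


def generate_meals(
    period_start: pd.Timestamp,
    period_end: pd.Timestamp,
    params: MealTimingParams,
    rng: np.random.Generator,
    subject_id: str = "S001",
    duplicate_prob: float = 0.0,
) -> pd.DataFrame:
    """Raw meal records for one wake period.

    Draws ``Poisson(n_meals_mean) + 1`` meals, times from the restricted
    von Mises mixture, lognormal kcal split by a Dirichlet draw into
    carb/fat/protein kcal (sugar and saturated fat are sub-fractions,
    alcohol kcal is zero), with meal types assigned by clock band.  With
    probability ``duplicate_prob`` a meal gains a same-type companion
    under 15 minutes later to exercise downstream merging.
    """
    params.validate()
    if period_end <= period_start:
        raise ValueError("empty wake period")
    n = int(rng.poisson(params.n_meals_mean)) + 1
    times = sorted(sample_clock_times(n, params.components, period_start, period_end, rng))
    rows = []
    for t in times:
        rows.append(_meal_row(t, params, rng, subject_id))
        if rng.random() < duplicate_prob:
            companion_t = t + pd.Timedelta(minutes=float(rng.uniform(3.0, 12.0)))
            row = _meal_row(companion_t, params, rng, subject_id, kcal_scale=0.3)
            row["meal_type"] = rows[-1]["meal_type"]
            rows.append(row)
    df = pd.DataFrame(rows)
    df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.round("min")
    return df.sort_values("timestamp", kind="mergesort").reset_index(drop=True)


def _meal_row(
    t: pd.Timestamp,
    params: MealTimingParams,
    rng: np.random.Generator,
    subject_id: str,
    kcal_scale: float = 1.0,
) -> dict:
    kcal = float(rng.lognormal(params.kcal_log_mu, params.kcal_log_sigma)) * kcal_scale
    shares = rng.dirichlet(params.macro_alpha)
    carb, fat, protein = (kcal * s for s in shares)
    clock = t.hour + t.minute / 60.0 + t.second / 3600.0
    return {
        "subject_id": subject_id,
        "timestamp": t,
        "meal_type": _meal_type_for_clock(clock),
        "kcal": kcal,
        "carb_kcal": carb,
        "sugar_kcal": carb * float(rng.uniform(0.2, 0.6)),
        "fat_kcal": fat,
        "satfat_kcal": fat * float(rng.uniform(0.25, 0.45)),
        "protein_kcal": protein,
        "alcohol_kcal": 0.0,
    }


# --- subjects and full dataset ----------------------------------------------

def generate_subjects(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_subjects
    n_female = int(round(n * config.female_fraction))
    rows = []
    for i in range(n):
        female = i < n_female
        age = float(np.clip(rng.normal(32.1, 5.4), 25, 44))
        if female:
            height = float(np.clip(rng.normal(166.0, 6.0), 152, 182))
            weight = float(np.clip(rng.normal(66.0, 7.0), 48, 92))
        else:
            height = float(np.clip(rng.normal(178.0, 6.0), 163, 196))
            weight = float(np.clip(rng.normal(82.0, 8.0), 60, 112))
        rows.append({
            "subject_id": _subject_id(i),
            "sex": "female" if female else "male",
            "age_years": round(age, 1),
            "height_cm": round(height, 1),
            "weight_kg": round(weight, 1),
        })
    return pd.DataFrame(rows)


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate the full multi-subject dataset plus ground truth.

    Meals are generated for every day of the roster.  Ground-truth rows
    carry, per subject-day, the generator's analytic mixture mean and the
    empirical kcal-weighted circular summary recomputed from the emitted
    records (>5 kcal), so pipeline estimates can be validated exactly.
    """
    config.validate()
    master = np.random.default_rng(config.seed)
    subj_seeds = master.integers(0, 2**63 - 1, size=config.n_subjects)
    subjects = generate_subjects(config, np.random.default_rng(master.integers(0, 2**63 - 1)))

    work_frames, sleep_frames, meal_frames, truth_rows, label_frames = [], [], [], [], []
    base = pd.Timestamp(config.start_date)
    template = _template(config.roster_kind)
    labels = [_LABEL_NAMES[c] for c in template]

    for i in range(config.n_subjects):
        rng = np.random.default_rng(subj_seeds[i])
        subject_id = _subject_id(i)
        roster = generate_roster(config, i)
        sleep = generate_sleep(roster, config, rng)
        work_frames.append(roster)
        sleep_frames.append(sleep)
        label_frames.append(roster_day_labels(config, i))

        # wake periods: main sleep d's wake -> onset of main sleep closing day d
        mains = sleep.sort_values("onset").reset_index(drop=True)
        # reconstruct per-day wake/onset pairs from consecutive episodes:
        # main episodes alternate [onset_{d-1}, wake_d]; filter naps out by
        # duration (naps are config.nap_minutes long)
        nap_td = pd.Timedelta(minutes=config.nap_minutes)
        main_eps = mains[(mains["wake"] - mains["onset"]) > nap_td * 2].reset_index(drop=True)
        for d in range(len(main_eps) - 1):
            period_start = main_eps.loc[d, "wake"]
            period_end = main_eps.loc[d + 1, "onset"]
            day_index = (period_start.normalize() - base).days
            if day_index < 0 or day_index >= len(labels):
                continue
            day_type = labels[day_index]
            params = config.day_type_params[day_type]
            meals = generate_meals(
                period_start, period_end, params, rng,
                subject_id=subject_id, duplicate_prob=config.duplicate_prob,
            )
            meal_frames.append(meals)
            caloric = meals[meals["kcal"] > 5.0]
            if len(caloric) > 0:
                clock = (
                    caloric["timestamp"].dt.hour
                    + caloric["timestamp"].dt.minute / 60.0
                    + caloric["timestamp"].dt.second / 3600.0
                )
                summ = _metrics.circular_summary(clock, caloric["kcal"])
                emp_mean, emp_rho = summ.mean_time, summ.rho
                first = caloric["timestamp"].min()
                last = caloric["timestamp"].max()
            else:
                emp_mean = emp_rho = math.nan
                first = last = pd.NaT
            truth_rows.append({
                "subject_id": subject_id,
                "date": period_start.normalize().date().isoformat(),
                "day_type": day_type,
                "true_mean_time_h": mixture_circular_mean(params.components),
                "emp_mean_time_h": emp_mean,
                "emp_rho": emp_rho,
                "total_kcal": float(meals["kcal"].sum()),
                "first_meal": first,
                "last_meal": last,
                "n_records": len(meals),
            })

    return SyntheticDataset(
        subjects=subjects,
        work=pd.concat(work_frames, ignore_index=True),
        sleep=pd.concat(sleep_frames, ignore_index=True),
        meals=pd.concat(meal_frames, ignore_index=True),
        ground_truth=pd.DataFrame(truth_rows),
        day_labels=pd.concat(label_frames, ignore_index=True),
        config=config,
    )


def export_dataset(dataset: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Write the dataset as CSVs matching the ingest schemas.

    Emits ``meals.csv, work.csv, sleep.csv, subjects.csv,
    ground_truth.csv`` (plus ``day_labels.csv``); deterministic
    formatting so a fixed seed yields byte-identical files.
    """
    if len(dataset.meals) == 0:
        raise ValueError("refusing to export an empty dataset")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    ts_fmt = "%Y-%m-%d %H:%M:%S"

    meals = dataset.meals.copy()
    meals["timestamp"] = meals["timestamp"].dt.strftime(ts_fmt)
    for col in ("kcal", *MACRO_COLS):
        meals[col] = meals[col].map(lambda v: f"{v:.6f}")
    paths["meals"] = out / "meals.csv"
    meals.to_csv(paths["meals"], index=False)

    work = dataset.work[["subject_id", "start", "end"]].copy()
    work["start"] = work["start"].dt.strftime(ts_fmt)
    work["end"] = work["end"].dt.strftime(ts_fmt)
    paths["work"] = out / "work.csv"
    work.to_csv(paths["work"], index=False)

    sleep = dataset.sleep.copy()
    # emit resolved main/nap flags for readers that want them; ingestion
    # re-derives them independently
    from .schedule import resolve_main_sleep
    sleep = resolve_main_sleep(sleep)
    sleep["onset"] = sleep["onset"].dt.strftime(ts_fmt)
    sleep["wake"] = sleep["wake"].dt.strftime(ts_fmt)
    paths["sleep"] = out / "sleep.csv"
    sleep[["subject_id", "onset", "wake", "is_main"]].to_csv(paths["sleep"], index=False)

    paths["subjects"] = out / "subjects.csv"
    dataset.subjects.to_csv(paths["subjects"], index=False)

    truth = dataset.ground_truth.copy()
    for col in ("first_meal", "last_meal"):
        truth[col] = pd.to_datetime(truth[col]).dt.strftime(ts_fmt)
    for col in ("true_mean_time_h", "emp_mean_time_h", "emp_rho", "total_kcal"):
        truth[col] = truth[col].map(lambda v: f"{v:.6f}" if pd.notna(v) else "")
    paths["ground_truth"] = out / "ground_truth.csv"
    truth.to_csv(paths["ground_truth"], index=False)

    paths["day_labels"] = out / "day_labels.csv"
    dataset.day_labels.to_csv(paths["day_labels"], index=False)
    return paths
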