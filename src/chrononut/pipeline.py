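"""End-to-end orchestration: simulate/ingest -> intake events -> day
windows -> per-day metrics -> statistics -> report tables.

Every meal record is either represented in an intake event assigned to a
valid day window or listed in the exclusion log with a reason, so row
counts are conserved across the run.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import intake as _intake
from . import metrics as _metrics
from . import schedule as _schedule
from . import stats as _stats
from . import synth as _synth

logger = logging.getLogger(__name__)

#: outcome -> BH family, mirroring the report-table groupings (the
#: overall / at-night / at-work distribution families are adjusted
#: separately)
DEFAULT_MODEL_FAMILIES = {
    "intake_pct_bmr": [
        "total_pct_bmr", "carb_pct_bmr", "sugar_pct_bmr", "fat_pct_bmr",
        "satfat_pct_bmr", "protein_pct_bmr", "meal_count",
    ],
    "distribution_overall": [
        "carb_pct_total", "sugar_pct_total", "fat_pct_total",
        "satfat_pct_total", "protein_pct_total",
    ],
    "distribution_night": ["pct_at_night"],
    "distribution_work": ["pct_at_work"],
    "timing": [
        "first_meal_latency_h", "last_meal_to_sleep_h", "eating_window_h",
        "circ_rho",
    ],
}


@dataclass
class PipelineConfig:
    meals_path: Optional[str] = None
    work_path: Optional[str] = None
    sleep_path: Optional[str] = None
    subjects_path: Optional[str] = None
    simulate: Optional[_synth.GeneratorConfig] = None
    min_kcal: float = 5.0
    min_events: int = 2
    night_window: tuple[float, float] = (23.0, 6.0)
    alpha: float = 0.05
    seed: Optional[int] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if isinstance(cfg.night_window, list):
            cfg.night_window = tuple(cfg.night_window)
        if sim is not None:
            sim = dict(sim)
            if "day_type_params" in sim:
                sim["day_type_params"] = {
                    k: _synth.MealTimingParams(
                        components=tuple(tuple(c) for c in v["components"]),
                        n_meals_mean=v["n_meals_mean"],
                        kcal_log_mu=v["kcal_log_mu"],
                        kcal_log_sigma=v["kcal_log_sigma"],
                        macro_alpha=tuple(v["macro_alpha"]),
                    )
                    for k, v in sim["day_type_params"].items()
                }
            if "sleep_params" in sim:
                sim["sleep_params"] = {
                    k: _synth.SleepTimingParams(**v) for k, v in sim["sleep_params"].items()
                }
            cfg.simulate = _synth.default_config(**sim)
        return cfg


@dataclass
class PipelineResult:
    out_dir: Path
    paths: dict = field(default_factory=dict)
    day_metrics: Optional[pd.DataFrame] = None
    stats_results: Optional[pd.DataFrame] = None
    counts: dict = field(default_factory=dict)


def dataset_day_metrics(
    dataset: _synth.SyntheticDataset,
    min_kcal: float = 5.0,
    min_events: int = 2,
) -> pd.DataFrame:
    """Per-day metric table computed straight from an in-memory synthetic
    dataset (no file round-trip); used for parameter-recovery checks."""
    shifts = _schedule.classify_shifts(dataset.work)
    sleep = _schedule.resolve_main_sleep(dataset.sleep[["subject_id", "onset", "wake"]])
    windows = _schedule.build_day_windows(shifts, sleep)
    events, _ = _intake.merge_intakes(dataset.meals)
    events = _intake.assign_to_window(events, windows)
    subjects = {
        r["subject_id"]: _metrics.SubjectProfile(
            r["subject_id"], r["sex"], r["age_years"], r["height_cm"], r["weight_kg"],
        )
        for _, r in dataset.subjects.iterrows()
    }
    return _metrics.compute_day_metrics(
        events, windows, subjects, min_kcal=min_kcal, min_events=min_events
    )


def run_pipeline(config: PipelineConfig, out_dir) -> PipelineResult:
    """Run the full analysis and write the report bundle under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(out_dir=out)

    # --- inputs -------------------------------------------------------------
    if config.simulate is not None:
        sim_cfg = config.simulate
        if config.seed is not None:
            sim_cfg = _synth.default_config(**{**asdict_shallow(sim_cfg), "seed": config.seed})
        dataset = _synth.generate_dataset(sim_cfg)
        sim_dir = out / "simulated"
        _synth.export_dataset(dataset, sim_dir)
        meals = _intake.load_meals(sim_dir / "meals.csv")
        work = pd.read_csv(sim_dir / "work.csv", parse_dates=["start", "end"])
        sleep = pd.read_csv(sim_dir / "sleep.csv", parse_dates=["onset", "wake"])
        subjects_df = pd.read_csv(sim_dir / "subjects.csv")
        result.paths["simulated"] = sim_dir
    else:
        for name in ("meals_path", "work_path", "sleep_path", "subjects_path"):
            if getattr(config, name) is None:
                raise ValueError(f"{name} required when no simulate block is given")
        meals = _intake.load_meals(config.meals_path)
        work = pd.read_csv(config.work_path, parse_dates=["start", "end"])
        sleep = pd.read_csv(config.sleep_path, parse_dates=["onset", "wake"])
        subjects_df = pd.read_csv(config.subjects_path)

    subjects = {
        r["subject_id"]: _metrics.SubjectProfile(
            r["subject_id"], r["sex"], r["age_years"], r["height_cm"], r["weight_kg"],
        )
        for _, r in subjects_df.iterrows()
    }

    # --- schedule -----------------------------------------------------------
    shifts = _schedule.classify_shifts(work)
    resolved_sleep = _schedule.resolve_main_sleep(sleep[["subject_id", "onset", "wake"]])
    window_diags: list[dict] = []
    windows = _schedule.build_day_windows(shifts, resolved_sleep, window_diags)
    windows_df = _schedule.windows_to_frame(windows)

    # --- intake -------------------------------------------------------------
    meals = _intake.validate_meal_log(meals)
    events, record_map = _intake.merge_intakes(meals)
    event_diags: list[dict] = []
    events = _intake.assign_to_window(events, windows, event_diags)

    # exclusion log: any source record whose event landed in no window
    dropped_intervals = _dropped_intervals(window_diags, resolved_sleep)
    unassigned = events[events["window_key"].isna()]
    exclusions = []
    for _, ev in unassigned.iterrows():
        reason = "no_matching_window"
        for subj, lo, hi, why in dropped_intervals:
            if subj == ev["subject_id"] and lo <= ev["timestamp"] < hi:
                reason = why
                break
        for rec_idx in record_map.loc[record_map["event_id"] == ev["event_id"], "record_index"]:
            exclusions.append({
                "record_index": int(rec_idx),
                "subject_id": ev["subject_id"],
                "timestamp": ev["timestamp"],
                "reason": reason,
            })
    exclusions_df = pd.DataFrame(
        exclusions, columns=["record_index", "subject_id", "timestamp", "reason"]
    )

    # --- metrics ------------------------------------------------------------
    excluded_days: list[dict] = []
    day_metrics = _metrics.compute_day_metrics(
        events, windows, subjects,
        min_kcal=config.min_kcal, min_events=config.min_events,
        night=config.night_window, excluded_days=excluded_days,
    )
    result.day_metrics = day_metrics

    # --- statistics ---------------------------------------------------------
    stats_results: list[_stats.TestResult] = []
    contrasts: list[_stats.TestResult] = []
    enough_data = (
        len(day_metrics) >= 4
        and day_metrics["subject_id"].nunique() >= 2
        and day_metrics["day_type"].nunique() >= 2
    )
    if enough_data:
        stats_results, contrasts = _run_stats(day_metrics, subjects_df)
    else:
        logger.warning("insufficient data for the statistics stage; skipping")

    stats_df = _stats.results_to_frame(stats_results)
    contrasts_df = _stats.results_to_frame(contrasts)
    result.stats_results = stats_df

    # --- report tables ------------------------------------------------------
    tables = build_report_tables(day_metrics, subjects_df)

    # --- outputs ------------------------------------------------------------
    events_out = events.copy()
    result.paths["intake_events"] = out / "intake_events.csv"
    events_out.to_csv(result.paths["intake_events"], index=False)
    result.paths["day_windows"] = out / "day_windows.csv"
    windows_df.to_csv(result.paths["day_windows"], index=False)
    result.paths["day_metrics"] = out / "day_metrics.csv"
    day_metrics.to_csv(result.paths["day_metrics"], index=False)
    result.paths["stats_results"] = out / "stats_results.csv"
    stats_df.to_csv(result.paths["stats_results"], index=False)
    result.paths["contrasts"] = out / "contrasts.csv"
    contrasts_df.to_csv(result.paths["contrasts"], index=False)
    result.paths["exclusions"] = out / "exclusions.csv"
    exclusions_df.to_csv(result.paths["exclusions"], index=False)
    result.paths["excluded_days"] = out / "excluded_days.csv"
    pd.DataFrame(excluded_days, columns=["subject_id", "date", "reason", "n_events"]) \
        .to_csv(result.paths["excluded_days"], index=False)
    for name, tbl in tables.items():
        result.paths[name] = out / f"{name}.csv"
        tbl.to_csv(result.paths[name], index=False)

    counts = {
        "meal_records": int(len(meals)),
        "intake_events": int(len(events)),
        "events_assigned": int(events["window_key"].notna().sum()),
        "records_excluded": int(len(exclusions_df)),
        "records_in_assigned_events": int(
            events.loc[events["window_key"].notna(), "n_merged"].sum()
        ),
        "day_windows": int(len(windows)),
        "windows_skipped": int(len(window_diags)),
        "analysis_days": int(len(day_metrics)),
        "days_dropped_min_events": int(len(excluded_days)),
        "subjects": int(subjects_df["subject_id"].nunique()),
    }
    result.counts = counts
    assert counts["records_in_assigned_events"] + counts["records_excluded"] == counts["meal_records"], \
        "row-count conservation violated"

    run_log = {
        "chrononut_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed if config.seed is not None
        else (config.simulate.seed if config.simulate else None),
        "config": _config_repr(config),
        "counts": counts,
    }
    result.paths["run_log"] = out / "run_log.json"
    with open(result.paths["run_log"], "w") as fh:
        json.dump(run_log, fh, indent=2, default=str)

    _write_text_summary(out / "report.txt", counts, tables, stats_df)
    result.paths["report"] = out / "report.txt"
    return result


def _run_stats(day_metrics: pd.DataFrame, subjects_df: pd.DataFrame):
    """Chi-square meal-count tests, Welch BMR-by-sex, mixed models per
    outcome family, and the circular ANOVA of per-day mean intake times."""
    results: list[_stats.TestResult] = []
    contrasts: list[_stats.TestResult] = []

    # meal counts vs number of contributing subject-days per day type
    order = [t for t in ("rest", "morning", "evening", "night")
             if t in set(day_metrics["day_type"])]
    obs = [day_metrics.loc[day_metrics["day_type"] == t, "meal_count"].sum() for t in order]
    weights = [(day_metrics["day_type"] == t).sum() for t in order]
    if len(order) >= 2:
        r = _stats.chi_square_gof(obs, weights)
        r.family_id = "meal_counts"
        r.effect_label = "meal_count_gof:" + "/".join(order)
        results.append(r)
        pairwise = []
        if "rest" in order:
            i0 = order.index("rest")
            for t in order:
                if t == "rest":
                    continue
                i1 = order.index(t)
                rp = _stats.chi_square_gof([obs[i0], obs[i1]], [weights[i0], weights[i1]])
                rp.family_id = "meal_counts_pairwise"
                rp.effect_label = f"meal_count_gof:rest-vs-{t}"
                pairwise.append(rp)
        _stats.apply_bh([r] + pairwise)
        results.extend(pairwise)

    # demographics: BMR by sex (Welch)
    by_sex = {}
    for sex, grp in subjects_df.groupby("sex"):
        bmrs = [
            _metrics.SubjectProfile(r["subject_id"], r["sex"], r["age_years"],
                                    r["height_cm"], r["weight_kg"]).bmr_24h
            for _, r in grp.iterrows()
        ]
        if len(bmrs) >= 2:
            by_sex[sex] = (float(np.mean(bmrs)), float(np.std(bmrs, ddof=1)), len(bmrs))
    if set(by_sex) >= {"male", "female"}:
        m, f = by_sex["male"], by_sex["female"]
        if m[1] > 0 and f[1] > 0:
            r = _stats.welch_t(*m, *f)
            r.family_id = "demographics"
            r.effect_label = "bmr~sex"
            r.p_adj = r.p_raw
            results.append(r)

    # mixed-effects day-type models
    table = day_metrics.merge(subjects_df[["subject_id", "sex", "age_years"]], on="subject_id")
    for family, outcomes in DEFAULT_MODEL_FAMILIES.items():
        fam_results = []
        for outcome in outcomes:
            if outcome not in table.columns:
                continue
            sub = table.dropna(subset=[outcome])
            if sub["day_type"].nunique() < 2 or len(sub) < 8:
                continue
            try:
                fit = _stats.fit_day_type_model(
                    sub, _stats.ModelSpec(outcome=outcome, family_id=family)
                )
            except ValueError as exc:
                logger.warning("model for %s skipped: %s", outcome, exc)
                continue
            fam_results.append(fit.omnibus)
            contrasts.extend(fit.contrasts)
        _stats.apply_bh(fam_results)
        results.extend(fam_results)

    # circular ANOVA of per-day weighted mean intake times across day types
    groups = []
    labels = []
    for t in ("rest", "morning", "evening", "night"):
        vals = day_metrics.loc[day_metrics["day_type"] == t, "circ_mean_time_h"].dropna()
        if len(vals) >= 2:
            groups.append(vals.to_numpy())
            labels.append(t)
    if len(groups) >= 2:
        r = _stats.watson_williams(groups)
        r.family_id = "circular"
        r.effect_label = "circ_mean_time~day_type:" + "/".join(labels)
        r.p_adj = r.p_raw
        results.append(r)

    return results, contrasts


def build_report_tables(day_metrics: pd.DataFrame, subjects_df: pd.DataFrame) -> dict:
    """Tidy report tables: subject summary, per-day-type intake (%BMR),
    distribution percentages (overall / at night / at work), and timing."""
    tables = {}

    rows = []
    profiles = [
        _metrics.SubjectProfile(r["subject_id"], r["sex"], r["age_years"],
                                r["height_cm"], r["weight_kg"])
        for _, r in subjects_df.iterrows()
    ]
    for sex in ("all", "male", "female"):
        sel = [p for p in profiles if sex == "all" or p.sex == sex]
        if not sel:
            continue
        bmrs = [p.bmr_24h for p in sel]
        ages = [p.age_years for p in sel]
        rows.append({
            "group": sex, "n": len(sel),
            "age_mean": float(np.mean(ages)),
            "age_sd": float(np.std(ages, ddof=1)) if len(sel) > 1 else np.nan,
            "bmr_mean": float(np.mean(bmrs)),
            "bmr_sd": float(np.std(bmrs, ddof=1)) if len(sel) > 1 else np.nan,
        })
    tables["table_subjects"] = pd.DataFrame(rows)

    def _daytype_summary(cols):
        out_rows = []
        for t in ("rest", "morning", "evening", "night"):
            grp = day_metrics[day_metrics["day_type"] == t]
            if len(grp) == 0:
                continue
            row = {"day_type": t, "n_days": len(grp)}
            for c in cols:
                if c in grp.columns:
                    row[f"{c}_mean"] = float(grp[c].mean())
                    row[f"{c}_sd"] = float(grp[c].std(ddof=1)) if len(grp) > 1 else np.nan
            out_rows.append(row)
        return pd.DataFrame(out_rows)

    tables["table_intake_bmr"] = _daytype_summary([
        "bmr_24h", "meal_count", "total_pct_bmr", "carb_pct_bmr", "sugar_pct_bmr",
        "fat_pct_bmr", "satfat_pct_bmr", "protein_pct_bmr",
    ])
    tables["table_distribution"] = _daytype_summary([
        "carb_pct_total", "sugar_pct_total", "fat_pct_total", "satfat_pct_total",
        "protein_pct_total", "pct_at_night", "pct_at_work",
    ])
    tables["table_timing"] = _daytype_summary([
        "first_meal_latency_h", "last_meal_to_sleep_h", "eating_window_h",
        "circ_rho", "circ_sd_h",
    ])

    # group circular means need circular averaging, not arithmetic
    circ_rows = []
    for t in ("rest", "morning", "evening", "night"):
        vals = day_metrics.loc[day_metrics["day_type"] == t, "circ_mean_time_h"].dropna()
        if len(vals) == 0:
            continue
        summ = _metrics.circular_summary(vals, np.ones(len(vals)))
        circ_rows.append({
            "day_type": t, "n_days": len(vals),
            "group_circ_mean_h": summ.mean_time,
            "group_circ_rho": summ.rho,
            "group_circ_sd_h": summ.circ_sd_h,
        })
    tables["table_circular"] = pd.DataFrame(circ_rows)
    return tables


def _dropped_intervals(window_diags, sleep):
    """Intervals of skipped windows, to attribute excluded meal records."""
    out = []
    for d in window_diags:
        end = d.get("window_end")
        if end is None:
            continue
        out.append((d["subject_id"], d["window_start"], end, d["reason"]))
    return out


def asdict_shallow(cfg: _synth.GeneratorConfig) -> dict:
    return {
        "n_subjects": cfg.n_subjects, "roster_kind": cfg.roster_kind,
        "day_type_params": cfg.day_type_params, "sleep_params": cfg.sleep_params,
        "seed": cfg.seed, "start_date": cfg.start_date,
        "nap_probability": cfg.nap_probability, "nap_minutes": cfg.nap_minutes,
        "duplicate_prob": cfg.duplicate_prob, "recovery_sleep_h": cfg.recovery_sleep_h,
        "female_fraction": cfg.female_fraction,
    }


def _config_repr(config: PipelineConfig) -> dict:
    d = {k: getattr(config, k) for k in (
        "meals_path", "work_path", "sleep_path", "subjects_path",
        "min_kcal", "min_events", "night_window", "alpha", "seed",
    )}
    if config.simulate is not None:
        d["simulate"] = {
            "n_subjects": config.simulate.n_subjects,
            "roster_kind": config.simulate.roster_kind,
            "seed": config.simulate.seed,
        }
    return d


def _write_text_summary(path: Path, counts: dict, tables: dict, stats_df: pd.DataFrame) -> None:
    lines = ["chrononut pipeline report", "=" * 30, "", "Row counts:"]
    for k, v in counts.items():
        lines.append(f"  {k}: {v}")
    for name, tbl in tables.items():
        lines += ["", name, "-" * len(name), tbl.to_string(index=False)]
    if len(stats_df):
        lines += ["", "statistics", "-" * 10, stats_df.to_string(index=False)]
    Path(path).write_text("\n".join(lines) + "\n")
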