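import math

import numpy as np
import pandas as pd
import pytest

from chrononut import synth
from chrononut.intake import ADDITIVE_MACROS, load_meals
from chrononut.metrics import circular_summary
from chrononut.schedule import classify_shifts
from chrononut.synth import (
    GeneratorConfig,
    MealTimingParams,
    default_config,
    export_dataset,
    generate_dataset,
    generate_meals,
    generate_roster,
    generate_sleep,
    mixture_circular_mean,
    recovery_config,
)


class TestRoster:
    def test_cycle35_has_runs_of_each_shift(self):
        cfg = default_config(n_subjects=1)
        roster = generate_roster(cfg, 0)
        labels = []
        dates = roster["start"].dt.normalize()
        for cls in ("morning", "evening", "night"):
            days = sorted(dates[roster["intended_class"] == cls])
            runs = 1
            best = 1
            for a, b in zip(days, days[1:]):
                runs = runs + 1 if (b - a).days == 1 else 1
                best = max(best, runs)
            assert best >= 2, cls

    def test_cycle28_has_no_evening(self):
        cfg = default_config(n_subjects=1, roster_kind="cycle28")
        roster = classify_shifts(generate_roster(cfg, 0))
        assert (roster["shift_class"] != "evening").all()
        assert set(roster["shift_class"]) == {"morning", "night"}
        durations = (roster["end"] - roster["start"]) / pd.Timedelta(hours=1)
        assert (durations == 12.0).all()

    def test_catalogue_times_only(self):
        cfg = default_config(n_subjects=3)
        catalogue = {(7.0, 9.0), (7.0, 12.0), (15.0, 9.0), (22.5, 9.0), (23.0, 9.0), (19.0, 12.0)}
        for i in range(3):
            roster = generate_roster(cfg, i)
            start_h = roster["start"].dt.hour + roster["start"].dt.minute / 60
            dur = (roster["end"] - roster["start"]) / pd.Timedelta(hours=1)
            assert set(zip(start_h, dur)) <= catalogue

    def test_determinism(self):
        cfg = default_config(n_subjects=2, seed=9)
        a = generate_roster(cfg, 1)
        b = generate_roster(cfg, 1)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_roster_kind(self):
        with pytest.raises(ValueError, match="roster_kind"):
            default_config(roster_kind="cycle99")


def _zero_variance_config(**kw):
    sleep = {
        k: synth.SleepTimingParams(v.wake_mean_h, 0.0, v.onset_mean_h, 0.0)
        for k, v in synth.DEFAULT_SLEEP_PARAMS.items()
    }
    return default_config(sleep_params=sleep, nap_probability=0.0, **kw)


class TestSleep:
    def test_zero_variance_morning_anchor(self):
        cfg = _zero_variance_config(n_subjects=1)
        roster = generate_roster(cfg, 0)
        sleep = generate_sleep(roster, cfg, np.random.default_rng(0))
        base = pd.Timestamp(cfg.start_date)
        # day 1 is the second morning-shift day: wake 0532, onset 2215
        day1 = base + pd.Timedelta(days=1)
        wake = sleep[sleep["wake"].dt.normalize() == day1]["wake"].iloc[0]
        assert wake == day1 + pd.Timedelta(hours=5, minutes=32)
        onset = sleep[(sleep["onset"].dt.normalize() == day1)]["onset"].iloc[0]
        assert onset == day1 + pd.Timedelta(hours=22, minutes=15)

    def test_zero_variance_rest_anchor(self):
        cfg = _zero_variance_config(n_subjects=1)
        roster = generate_roster(cfg, 0)
        sleep = generate_sleep(roster, cfg, np.random.default_rng(0))
        base = pd.Timestamp(cfg.start_date)
        # day 4 is the second rest day of the first rest run
        day4 = base + pd.Timedelta(days=4)
        wake = sleep[sleep["wake"].dt.normalize() == day4]["wake"].iloc[0]
        assert wake == day4 + pd.Timedelta(hours=8)
        onset = sleep[sleep["onset"].dt.normalize() == day4]["onset"].iloc[0]
        assert onset == day4 + pd.Timedelta(hours=22, minutes=56)

    def test_night_shift_daytime_sleep(self):
        cfg = _zero_variance_config(n_subjects=1)
        roster = generate_roster(cfg, 0)
        sleep = generate_sleep(roster, cfg, np.random.default_rng(0))
        # second night-shift day (day 13): daytime sleep onset 0914, wake 1558
        day = pd.Timestamp(cfg.start_date) + pd.Timedelta(days=13)
        eps = sleep[sleep["onset"].dt.normalize() == day]
        assert len(eps) == 1
        assert eps["onset"].iloc[0] == day + pd.Timedelta(hours=9, minutes=14)
        assert eps["wake"].iloc[0] == day + pd.Timedelta(hours=15, minutes=58)

    def test_episodes_disjoint(self):
        cfg = default_config(n_subjects=2, seed=5, nap_probability=1.0)
        for i in range(2):
            roster = generate_roster(cfg, i)
            sleep = generate_sleep(roster, cfg, np.random.default_rng(i)).sort_values("onset")
            assert (sleep["onset"].values[1:] >= sleep["wake"].values[:-1]).all()

    def test_main_sleep_never_overlaps_next_shift(self):
        cfg = default_config(n_subjects=3, seed=6)
        for i in range(3):
            roster = generate_roster(cfg, i)
            sleep = generate_sleep(roster, cfg, np.random.default_rng(100 + i))
            for _, shift in roster.iterrows():
                before = sleep[sleep["wake"] <= shift["start"]]
                covering = sleep[(sleep["onset"] < shift["start"]) & (sleep["wake"] > shift["start"])]
                assert len(covering) == 0

    def test_empty_roster_raises(self):
        cfg = default_config(n_subjects=1)
        with pytest.raises(ValueError, match="empty"):
            generate_sleep(pd.DataFrame(), cfg, np.random.default_rng(0))


class TestMeals:
    def _params(self, components, **kw):
        defaults = dict(
            n_meals_mean=5.0, kcal_log_mu=5.8, kcal_log_sigma=0.5,
            macro_alpha=(11.0, 9.0, 4.5),
        )
        defaults.update(kw)
        return MealTimingParams(components=components, **defaults)

    def test_degenerate_kappa_all_at_mu(self):
        params = self._params(((18.0, math.inf, 1.0),))
        meals = generate_meals(
            pd.Timestamp("2024-01-01 08:00"), pd.Timestamp("2024-01-01 23:00"),
            params, np.random.default_rng(0),
        )
        assert (meals["timestamp"] == pd.Timestamp("2024-01-01 18:00")).all()

    def test_kappa_zero_uniform_rho_small(self):
        params = self._params(((12.0, 0.0, 1.0),), n_meals_mean=2000)
        meals = generate_meals(
            pd.Timestamp("2024-01-01 00:00"), pd.Timestamp("2024-01-02 00:00"),
            params, np.random.default_rng(3),
        )
        clock = meals["timestamp"].dt.hour + meals["timestamp"].dt.minute / 60
        s = circular_summary(clock, np.ones(len(clock)))
        assert s.rho < 0.05

    def test_macro_share_recovery(self):
        # Dirichlet (44, 36, 18)*c concentrations give mean shares 44/36/18%
        params = self._params(((14.0, 1.0, 1.0),), n_meals_mean=4000,
                              macro_alpha=(44.0, 36.0, 18.0))
        meals = generate_meals(
            pd.Timestamp("2024-01-01 06:00"), pd.Timestamp("2024-01-01 23:00"),
            params, np.random.default_rng(4),
        )
        shares = meals[["carb_kcal", "fat_kcal", "protein_kcal"]].div(meals["kcal"], axis=0)
        assert shares.mean()["carb_kcal"] == pytest.approx(0.44, abs=0.01)
        assert shares.mean()["fat_kcal"] == pytest.approx(0.36, abs=0.01)
        assert shares.mean()["protein_kcal"] == pytest.approx(0.18, abs=0.01)

    def test_macro_kcal_sums_to_total(self):
        params = self._params(((14.0, 1.5, 1.0),), n_meals_mean=50)
        meals = generate_meals(
            pd.Timestamp("2024-01-01 06:00"), pd.Timestamp("2024-01-01 23:00"),
            params, np.random.default_rng(5),
        )
        additive = meals[list(ADDITIVE_MACROS)].sum(axis=1)
        assert np.allclose(additive, meals["kcal"], rtol=1e-6)

    def test_poisson_plus_one_never_empty(self):
        params = self._params(((14.0, 1.0, 1.0),), n_meals_mean=0.01)
        for seed in range(10):
            meals = generate_meals(
                pd.Timestamp("2024-01-01 08:00"), pd.Timestamp("2024-01-01 20:00"),
                params, np.random.default_rng(seed),
            )
            assert len(meals) >= 1

    def test_times_inside_wake_period(self):
        params = self._params(((3.0, 0.5, 1.0),), n_meals_mean=200, )
        start, end = pd.Timestamp("2024-01-01 08:00"), pd.Timestamp("2024-01-01 22:00")
        meals = generate_meals(start, end, params, np.random.default_rng(6))
        assert (meals["timestamp"] >= start).all()
        assert (meals["timestamp"] <= end + pd.Timedelta(minutes=1)).all()

    def test_empty_period_raises(self):
        params = self._params(((14.0, 1.0, 1.0),))
        with pytest.raises(ValueError, match="wake period"):
            generate_meals(
                pd.Timestamp("2024-01-01 08:00"), pd.Timestamp("2024-01-01 08:00"),
                params, np.random.default_rng(0),
            )

    def test_component_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="weights"):
            self._params(((14.0, 1.0, 0.5), (20.0, 1.0, 0.2))).validate()


class TestMixtureMean:
    def test_single_component(self):
        assert mixture_circular_mean(((15.0, 8.0, 1.0),)) == pytest.approx(15.0)

    def test_symmetric_mixture(self):
        mean = mixture_circular_mean(((10.0, 4.0, 0.5), (14.0, 4.0, 0.5)))
        assert mean == pytest.approx(12.0, abs=1e-9)

    def test_antipodal_undefined(self):
        assert math.isnan(mixture_circular_mean(((0.0, 4.0, 0.5), (12.0, 4.0, 0.5))))


class TestDatasetExport:
    def test_roundtrip_event_count(self, tmp_path, small_dataset):
        paths = export_dataset(small_dataset, tmp_path / "ds")
        meals = load_meals(paths["meals"])
        assert len(meals) == len(small_dataset.meals)
        sleep = pd.read_csv(paths["sleep"], parse_dates=["onset", "wake"])
        assert len(sleep) == len(small_dataset.sleep)

    def test_fixed_seed_byte_identical(self, tmp_path):
        outs = []
        for sub in ("a", "b"):
            cfg = default_config(n_subjects=2, seed=33)
            ds = generate_dataset(cfg)
            paths = export_dataset(ds, tmp_path / sub)
            outs.append(paths)
        for name in outs[0]:
            assert outs[0][name].read_bytes() == outs[1][name].read_bytes(), name

    def test_different_seeds_differ(self, tmp_path):
        a = generate_dataset(default_config(n_subjects=1, seed=1)).meals
        b = generate_dataset(default_config(n_subjects=1, seed=2)).meals
        assert not a["timestamp"].equals(b["timestamp"])

    def test_empty_dataset_raises(self, tmp_path, small_dataset):
        import dataclasses

        empty = dataclasses.replace(small_dataset, meals=small_dataset.meals.iloc[:0])
        with pytest.raises(ValueError, match="empty"):
            export_dataset(empty, tmp_path / "empty")

    def test_ground_truth_recomputable_from_meals(self, small_dataset):
        truth = small_dataset.ground_truth
        meals = small_dataset.meals
        row = truth.dropna(subset=["emp_mean_time_h"]).iloc[5]
        day_meals = meals[
            (meals["subject_id"] == row["subject_id"])
        ]
        # recompute the empirical circular mean for that day from raw records
        first = pd.Timestamp(f"{row['date']} 00:00")
        sel = day_meals[(day_meals["timestamp"] >= row["first_meal"])
                        & (day_meals["timestamp"] <= row["last_meal"])]
        sel = sel[sel["kcal"] > 5.0]
        clock = sel["timestamp"].dt.hour + sel["timestamp"].dt.minute / 60 \
            + sel["timestamp"].dt.second / 3600
        s = circular_summary(clock, sel["kcal"])
        assert s.mean_time == pytest.approx(row["emp_mean_time_h"], abs=1e-4)
        assert s.rho == pytest.approx(row["emp_rho"], abs=1e-4)

    def test_ground_truth_has_all_day_types(self, small_dataset):
        assert set(small_dataset.ground_truth["day_type"]) == {
            "rest", "morning", "evening", "night",
        }


class TestParameterRecovery:
    def test_high_kappa_recovery(self):
        # concentrated generator: empirical per-day means stay within a
        # tight band of the component mean
        cfg = recovery_config(n_subjects=6, kappa=12.0, seed=17)
        ds = generate_dataset(cfg)
        truth = ds.ground_truth.dropna(subset=["emp_mean_time_h"])
        for day_type, grp in truth.groupby("day_type"):
            mu = grp["true_mean_time_h"].iloc[0]
            s = circular_summary(grp["emp_mean_time_h"], np.ones(len(grp)))
            diff = abs((s.mean_time - mu + 12) % 24 - 12)
            assert diff < 0.5, (day_type, s.mean_time, mu)
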