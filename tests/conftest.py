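import numpy as np
import pandas as pd
import pytest

from chrononut.schedule import DayType, DayWindow, SleepEpisode


def ts(text: str) -> pd.Timestamp:
    return pd.Timestamp(text)


@pytest.fixture
def make_window():
    """Factory for hand-built day windows."""

    def _make(
        start="2024-01-01 08:00",
        end="2024-01-02 08:00",
        onset_next="2024-01-01 23:00",
        day_type=DayType.REST,
        naps=(),
        work_interval=None,
        subject_id="S001",
        sleep_hours=8.0,
    ):
        naps = [
            SleepEpisode(subject_id, pd.Timestamp(a), pd.Timestamp(b), False)
            for a, b in naps
        ]
        return DayWindow(
            subject_id=subject_id,
            date=pd.Timestamp(start).normalize(),
            day_type=day_type,
            start=pd.Timestamp(start),
            end=pd.Timestamp(end),
            sleep_onset_next=pd.Timestamp(onset_next),
            naps=naps,
            sleep_hours=sleep_hours,
            work_interval=(
                (pd.Timestamp(work_interval[0]), pd.Timestamp(work_interval[1]))
                if work_interval else None
            ),
        )

    return _make


def meal_row(subject, when, meal_type="snack", kcal=100.0, carb=50.0, sugar=10.0,
             fat=30.0, satfat=10.0, protein=20.0, alcohol=0.0):
    return {
        "subject_id": subject,
        "timestamp": pd.Timestamp(when),
        "meal_type": meal_type,
        "kcal": kcal,
        "carb_kcal": carb,
        "sugar_kcal": sugar,
        "fat_kcal": fat,
        "satfat_kcal": satfat,
        "protein_kcal": protein,
        "alcohol_kcal": alcohol,
    }


@pytest.fixture
def meal_log_factory():
    def _make(rows):
        return pd.DataFrame([meal_row(*r[:2], **(r[2] if len(r) > 2 else {})) for r in rows])

    return _make


@pytest.fixture(scope="session")
def small_dataset():
    """One small end-to-end synthetic dataset shared across tests."""
    from chrononut import synth

    cfg = synth.default_config(n_subjects=4, seed=11)
    return synth.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory, small_dataset):
    """Full pipeline run over the shared dataset."""
    from chrononut import pipeline, synth

    cfg = pipeline.PipelineConfig(
        simulate=synth.default_config(n_subjects=4, seed=11)
    )
    out = tmp_path_factory.mktemp("small_run")
    return pipeline.run_pipeline(cfg, out)
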