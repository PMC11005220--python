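import numpy as np
import pandas as pd
import pytest

from eeai.simulate import (
    CohortSpec,
    GroupSpec,
    default_ladder_spec,
    profile_at_age,
    simulate_cohort,
    simulate_recording,
)


@pytest.fixture(scope="session")
def ladder_cohort():
    """Small default age-ladder cohort shared across tests (n=3 per age)."""
    spec = default_ladder_spec(n_per_group=3, seed=42)
    recordings, truth = simulate_cohort(spec)
    return spec, recordings, truth


@pytest.fixture(scope="session")
def noiseless_spec():
    return default_ladder_spec(
        seed=0,
        noise_sd_frac=0.0,
        between_animal_sd_frac=0.0,
        rer_animal_sd=0.0,
        rer_sample_sd=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_recording(noiseless_spec):
    return simulate_recording(profile_at_age(20.0), noiseless_spec, animal_seed=0)


@pytest.fixture()
def two_group_spec():
    return CohortSpec(
        groups=[GroupSpec("Young", 20.0, 4), GroupSpec("Aged", 80.0, 4)],
        seed=7,
    )


def make_long_table(
    n_samples: int = 4,
    animals=("m1",),
    interval_min: float = 18.0,
    start="2024-01-01 07:00:00",
    channels=("VO2", "VCO2"),
    shuffle_seed=None,
) -> pd.DataFrame:
    """Tiny well-formed long-format cage table for I/O tests."""
    rows = []
    t0 = pd.Timestamp(start)
    for a in animals:
        for i in range(n_samples):
            row = {
                "animal_id": a,
                "timestamp": t0 + pd.Timedelta(minutes=i * interval_min),
                "group": "Young",
                "age_weeks": 20.0,
                "body_weight_g": 28.0,
            }
            for j, c in enumerate(channels):
                row[c] = 100.0 + 10.0 * i + j
            rows.append(row)
    df = pd.DataFrame(rows)
    if shuffle_seed is not None:
        df = df.sample(frac=1.0, random_state=shuffle_seed).reset_index(drop=True)
    return df


@pytest.fixture()
def tiny_table():
    return make_long_table()
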