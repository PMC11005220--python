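import numpy as np
import pandas as pd
import pytest

from eeai.cage_io import (
    WEIR_CO2,
    WEIR_O2,
    Recording,
    annotate_phases,
    derive_ee,
    interpolate_gaps,
    read_cage_table,
    trim_to_analysis_window,
    write_cage_table,
)
from eeai.errors import (
    CageFormatError,
    DuplicateSampleError,
    InsufficientDataError,
    SamplingError,
)
from .conftest import make_long_table


def constant_recording(hours=72.0, interval=18.0, start="2024-01-01 07:00:00",
                       **channel_values):
    n = int(hours * 60 / interval)
    channels = {k: np.full(n, v, float) for k, v in channel_values.items()}
    return Recording(
        animal_id="m1", group="Young", age_weeks=20.0, body_weight_g=28.0,
        start_time=pd.Timestamp(start), interval_min=interval,
        channels=pd.DataFrame(channels or {"EE": np.full(n, 0.5)}),
    )


class TestReadCageTable:
    def test_minimal_two_row_table(self):
        df = make_long_table(n_samples=2)
        recs = read_cage_table(df.to_csv(index=False))
        assert len(recs) == 1
        rec = recs[0]
        assert rec.n_samples == 2
        assert rec.interval_min == pytest.approx(18.0)
        assert list(rec.channels.columns) == ["VO2", "VCO2"]

    def test_row_order_invariance(self):
        df = make_long_table(n_samples=6, animals=("m1", "m2"))
        sorted_recs = read_cage_table(df.to_csv(index=False))
        shuffled = make_long_table(n_samples=6, animals=("m1", "m2"),
                                   shuffle_seed=3)
        shuffled_recs = read_cage_table(shuffled.to_csv(index=False))
        for a, b in zip(sorted_recs, shuffled_recs):
            assert a.equals(b)

    def test_missing_timestamp_column_errors(self):
        df = make_long_table().drop(columns=["timestamp"])
        with pytest.raises(CageFormatError, match="timestamp"):
            read_cage_table(df.to_csv(index=False))

    def test_duplicate_timestamp_errors(self):
        df = make_long_table(n_samples=3)
        df.loc[2, "timestamp"] = df.loc[1, "timestamp"]
        with pytest.raises(DuplicateSampleError):
            read_cage_table(df.to_csv(index=False))

    def test_non_uniform_sampling_errors(self):
        df = make_long_table(n_samples=5)
        df.loc[3, "timestamp"] += pd.Timedelta(minutes=7)
        with pytest.raises(SamplingError):
            read_cage_table(df.to_csv(index=False))

    def test_round_trip_identity(self, tmp_path):
        df = make_long_table(n_samples=8, animals=("m1", "m2"))
        recs = read_cage_table(df.to_csv(index=False))
        path = tmp_path / "out.csv"
        write_cage_table(recs, path)
        back = read_cage_table(path)
        for a, b in zip(recs, back):
            assert a.equals(b)


class TestTrim:
    def test_default_window(self):
        rec = constant_recording(hours=120.0, EE=0.5)
        out = trim_to_analysis_window(rec)
        assert out.duration_h == pytest.approx(72.0)
        assert out.start_time == rec.start_time + pd.Timedelta(hours=48)
        assert out.group == rec.group and out.age_weeks == rec.age_weeks

    def test_identity_slice(self):
        rec = constant_recording(hours=72.0, EE=0.5)
        out = trim_to_analysis_window(rec, adaptation_h=0.0, window_h=72.0)
        assert out.equals(rec)

    def test_idempotent(self):
        rec = constant_recording(hours=120.0, EE=0.5)
        once = trim_to_analysis_window(rec)
        twice = trim_to_analysis_window(once, adaptation_h=0.0, window_h=72.0)
        assert once.equals(twice)

    def test_too_short_reports_available_hours(self):
        rec = constant_recording(hours=100.0, EE=0.5)
        with pytest.raises(InsufficientDataError) as err:
            trim_to_analysis_window(rec)
        # 100 h is not a whole number of 18-min samples: 333 samples = 99.9 h
        assert err.value.available_h == pytest.approx(100.0, abs=0.3)


class TestPhases:
    def test_lights_on_boundaries(self):
        rec = constant_recording(start="2024-01-01 07:00:00", EE=0.5,
                                 hours=24.0)
        labels = annotate_phases(rec)
        # 07:00 is the first light sample; 19:00 (sample 40) is dark
        assert labels[0] == "light"
        assert labels[40] == "dark"

    def test_balanced_counts_72h(self):
        rec = constant_recording(hours=72.0, EE=0.5)
        labels = annotate_phases(rec)
        assert len(labels) == 240
        assert (labels == "light").sum() == 120
        assert (labels == "dark").sum() == 120

    def test_24h_periodicity(self):
        rec = constant_recording(hours=72.0, start="2024-01-01 10:30:00", EE=1.0)
        labels = annotate_phases(rec)
        per_day = int(24 * 60 / rec.interval_min)
        assert (labels[:per_day] == labels[per_day:2 * per_day]).all()

    def test_phase_decided_by_sample_start(self):
        # sample starting 18:54 still lies in [07:00, 19:00) -> light;
        # the next sample (19:12) is dark
        rec = constant_recording(start="2024-01-01 18:54:00", hours=24.0, EE=0.5)
        labels = annotate_phases(rec)
        assert labels[0] == "light"
        assert labels[1] == "dark"


class TestDeriveEE:
    def test_weir_arithmetic(self):
        rec = constant_recording(VO2=100.0, VCO2=80.0)
        out = derive_ee(rec)
        # (3.941*100 + 1.106*80)/1000 = 0.48258 kcal/h
        assert out.channels["EE"].iloc[0] == pytest.approx(0.48258, abs=1e-9)
        assert out.channels["RER"].iloc[0] == pytest.approx(0.8)

    @pytest.mark.parametrize("vco2,rer", [(100.0, 1.0), (70.0, 0.7)])
    def test_rer_fuel_regimes(self, vco2, rer):
        # RER 1 = pure carbohydrate oxidation, 0.7 = pure fat oxidation
        rec = constant_recording(VO2=100.0, VCO2=vco2)
        out = derive_ee(rec)
        assert out.channels["RER"].iloc[0] == pytest.approx(rer)

    def test_zero_vo2_gives_missing_rer(self):
        n = 240
        channels = pd.DataFrame(
            {"VO2": np.r_[0.0, np.full(n - 1, 100.0)],
             "VCO2": np.full(n, 80.0)}
        )
        rec = constant_recording()
        rec.channels = channels
        out = derive_ee(rec)
        assert np.isnan(out.channels["RER"].iloc[0])
        assert np.isfinite(out.channels["RER"].iloc[1:]).all()

    def test_rer_consistency_invariant(self):
        rng = np.random.default_rng(5)
        channels = pd.DataFrame(
            {"VO2": rng.uniform(80, 120, 240), "VCO2": rng.uniform(60, 110, 240)}
        )
        rec = constant_recording()
        rec.channels = channels
        out = derive_ee(rec)
        out.validate()  # RER == VCO2/VO2 within 1e-6 wherever VO2 > 0


class TestGapPolicy:
    def test_small_gap_interpolated(self):
        s = np.arange(100, dtype=float)
        s[10] = np.nan
        out = interpolate_gaps(s)
        assert out[10] == pytest.approx(10.0)

    def test_large_gap_rejected(self):
        s = np.arange(100, dtype=float)
        s[:10] = np.nan
        with pytest.raises(InsufficientDataError):
            interpolate_gaps(s)
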