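"""Reading, validation, windowing and phase annotation of metabolic-cage traces.

A :class:`Recording` holds one animal's multi-channel indirect-calorimetry
trace (VO2, VCO2, RER, EE plus activity, feeding and drinking channels) at a
uniform sampling interval, together with the metadata the downstream clock
needs (group label, chronological age, body weight, light schedule).

Input is a long-format delimited table — one row per (animal, timestamp) —
with per-animal metadata either in-table or supplied as a sidecar mapping.
Samples are half-open intervals ``[t, t + interval)``; a sample's light/dark
phase is decided by its start time.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CageFormatError,
    DuplicateSampleError,
    InsufficientDataError,
    SamplingError,
)

#: Canonical channel names and units, in instrument export order.
CHANNELS: tuple[str, ...] = (
    "VO2",   # ml/h
    "VCO2",  # ml/h
    "RER",   # dimensionless, VCO2/VO2
    "EE",    # kcal/h
    "XT",    # x-axis beam-break counts per sample
    "YT",    # y-axis beam-break counts per sample
    "Z",     # z-axis (rearing) beam-break counts per sample
    "DistD", # distance moved per sample, cm
    "Speed", # mean locomotion speed, cm/s
    "Drink", # water intake per sample, ml
    "Feed",  # food intake per sample, g
    "SumR",  # right wheel turns per sample
    "SumL",  # left wheel turns per sample
)

#: Weir equation coefficients: EE [kcal/h] = (a*VO2 + b*VCO2)/1000, gas in ml/h.
WEIR_O2 = 3.941
WEIR_CO2 = 1.106

#: Maximum tolerated fraction of missing samples per channel.
MAX_GAP_FRAC = 0.05


@dataclass
class Dialect:
    """Descriptor for an instrument-style delimited export.

    ``aliases`` maps export column headers onto canonical names (e.g.
    ``{"O2 Consumption": "VO2", "Weight": "body_weight_g"}``); ``decimal`` and
    ``sep`` follow pandas conventions (decimal-comma exports use
    ``decimal=","``, ``sep=";"``).
    """

    sep: str = ","
    decimal: str = "."
    aliases: Mapping[str, str] = field(default_factory=dict)
    timestamp_col: str = "timestamp"
    animal_col: str = "animal_id"


@dataclass
class Recording:
    """One animal's metabolic-cage trace plus metadata."""

    animal_id: str
    group: str
    age_weeks: float
    body_weight_g: float
    start_time: pd.Timestamp
    interval_min: float
    channels: pd.DataFrame  # columns ⊆ CHANNELS, equal length
    lights_on_hour: float = 7.0
    photoperiod_h: tuple[float, float] = (12.0, 12.0)
    extras: pd.DataFrame | None = None  # pass-through of unknown columns

    def __post_init__(self) -> None:
        if self.interval_min <= 0:
            raise ValueError("interval_min must be positive")
        if self.age_weeks <= 0:
            raise ValueError("age_weeks must be positive")
        if self.body_weight_g <= 0:
            raise ValueError("body_weight_g must be positive")
        self.start_time = pd.Timestamp(self.start_time)
        self.channels = self.channels.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.channels)

    @property
    def duration_h(self) -> float:
        return self.n_samples * self.interval_min / 60.0

    def time_min(self) -> np.ndarray:
        """Sample start times in minutes from the first sample."""
        return np.arange(self.n_samples, dtype=float) * self.interval_min

    def minutes_after_lights_on(self) -> np.ndarray:
        """Each sample's clock time as minutes past lights-on, in [0, 1440)."""
        start_clock = (
            self.start_time.hour * 60.0
            + self.start_time.minute
            + self.start_time.second / 60.0
        )
        offset = start_clock - self.lights_on_hour * 60.0
        return (offset + self.time_min()) % 1440.0

    def validate(self) -> None:
        """Check the container invariants; raise ``ValueError`` on violation."""
        lens = {len(self.channels[c]) for c in self.channels.columns}
        if len(lens) > 1:
            raise ValueError("channel series have unequal lengths")
        if self.n_samples < 1:
            raise ValueError("recording has no samples")
        for c in ("VO2", "VCO2", "XT", "YT", "Z", "DistD", "Drink", "Feed",
                  "SumR", "SumL"):
            if c in self.channels and np.nanmin(self.channels[c].to_numpy()) < 0:
                raise ValueError(f"channel {c} has negative values")
        if "RER" in self.channels and "VO2" in self.channels and "VCO2" in self.channels:
            vo2 = self.channels["VO2"].to_numpy(float)
            vco2 = self.channels["VCO2"].to_numpy(float)
            rer = self.channels["RER"].to_numpy(float)
            ok = (vo2 > 0) & np.isfinite(rer)
            tol = 1e-6 * np.maximum(1.0, np.abs(rer[ok]))
            if np.any(np.abs(rer[ok] - vco2[ok] / vo2[ok]) > tol):
                raise ValueError("RER inconsistent with VCO2/VO2")

    def equals(self, other: "Recording") -> bool:
        return (
            self.animal_id == other.animal_id
            and self.group == other.group
            and self.age_weeks == other.age_weeks
            and self.body_weight_g == other.body_weight_g
            and self.start_time == other.start_time
            and self.interval_min == other.interval_min
            and list(self.channels.columns) == list(other.channels.columns)
            and np.array_equal(
                self.channels.to_numpy(), other.channels.to_numpy(), equal_nan=True
            )
        )


def read_cage_table(
    source,
    dialect: Dialect | None = None,
    metadata: Mapping[str, Mapping] | None = None,
) -> list[Recording]:
    """Parse a long-format cage export into one :class:`Recording` per animal.

    Parameters
    ----------
    source
        Path, file object, or string containing a delimited table with a
        header. Must name a timestamp column, an animal-id column, and at
        least one known channel (after dialect aliasing).
    dialect
        Optional :class:`Dialect` describing separators and column aliases.
    metadata
        Per-animal sidecar mapping ``{animal_id: {"group": ..., "age_weeks":
        ..., "body_weight_g": ...}}``; in-table columns of the same names take
        precedence over the sidecar.
    """
    dialect = dialect or Dialect()
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep=dialect.sep, decimal=dialect.decimal)
    df = df.rename(columns=dict(dialect.aliases))

    for col, label in ((dialect.timestamp_col, "timestamp"),
                       (dialect.animal_col, "animal id")):
        if col not in df.columns:
            raise CageFormatError(f"missing mandatory {label} column {col!r}")
    present = [c for c in CHANNELS if c in df.columns]
    if not present:
        raise CageFormatError(
            f"no known channel column found (expected one of {CHANNELS})"
        )

    df[dialect.timestamp_col] = pd.to_datetime(df[dialect.timestamp_col])
    meta_cols = [c for c in ("group", "age_weeks", "body_weight_g")
                 if c in df.columns]
    known = {dialect.timestamp_col, dialect.animal_col, *present, *meta_cols}
    extra_cols = [c for c in df.columns if c not in known]

    recordings = []
    for animal_id, sub in df.groupby(dialect.animal_col, sort=True):
        sub = sub.sort_values(dialect.timestamp_col).reset_index(drop=True)
        times = sub[dialect.timestamp_col]
        if times.duplicated().any():
            dup = times[times.duplicated()].iloc[0]
            raise DuplicateSampleError(
                f"animal {animal_id!r}: duplicate timestamp {dup}"
            )
        if len(sub) > 1:
            steps = times.diff().dropna().dt.total_seconds().to_numpy() / 60.0
            interval = float(np.median(steps))
            if np.any(np.abs(steps - interval) > 0.01 * interval + 1e-9):
                raise SamplingError(
                    f"animal {animal_id!r}: non-uniform sampling "
                    f"(steps {steps.min():.3f}–{steps.max():.3f} min)"
                )
        else:
            interval = 18.0

        meta = dict(metadata.get(str(animal_id), {})) if metadata else {}
        for c in meta_cols:
            meta[c] = sub[c].iloc[0]
        missing = [k for k in ("group", "age_weeks", "body_weight_g")
                   if k not in meta]
        if missing:
            raise CageFormatError(
                f"animal {animal_id!r}: missing metadata {missing} "
                "(supply in-table or via sidecar)"
            )
        recordings.append(
            Recording(
                animal_id=str(animal_id),
                group=str(meta["group"]),
                age_weeks=float(meta["age_weeks"]),
                body_weight_g=float(meta["body_weight_g"]),
                start_time=times.iloc[0],
                interval_min=interval,
                channels=sub[present].astype(float),
                extras=sub[extra_cols].reset_index(drop=True) if extra_cols else None,
            )
        )
    return recordings


def write_cage_table(recordings: Sequence[Recording], path) -> None:
    """Write recordings back to the canonical long-format CSV (round-trippable)."""
    frames = []
    for rec in recordings:
        df = rec.channels.copy()
        df.insert(0, "animal_id", rec.animal_id)
        df.insert(
            1,
            "timestamp",
            rec.start_time + pd.to_timedelta(rec.time_min(), unit="m"),
        )
        df["group"] = rec.group
        df["age_weeks"] = rec.age_weeks
        df["body_weight_g"] = rec.body_weight_g
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_metadata(recordings: Sequence[Recording], path) -> None:
    meta = {
        rec.animal_id: {
            "group": rec.group,
            "age_weeks": rec.age_weeks,
            "body_weight_g": rec.body_weight_g,
            "lights_on_hour": rec.lights_on_hour,
            "interval_min": rec.interval_min,
            "start_time": str(rec.start_time),
        }
        for rec in recordings
    }
    Path(path).write_text(json.dumps(meta, indent=2))


def trim_to_analysis_window(
    rec: Recording, adaptation_h: float = 48.0, window_h: float = 72.0
) -> Recording:
    """Drop the acclimation period and keep the analysis window.

    The instrument protocol records continuously; the first ``adaptation_h``
    hours are cage-acclimation and are discarded, then the next ``window_h``
    hours (default three full days) are analysed.
    """
    needed = adaptation_h + window_h
    if rec.duration_h + 1e-9 < needed:
        raise InsufficientDataError(
            f"recording spans {rec.duration_h:.1f} h; "
            f"{needed:.1f} h required ({adaptation_h} h adaptation "
            f"+ {window_h} h window)",
            available_h=rec.duration_h,
        )
    start = int(round(adaptation_h * 60.0 / rec.interval_min))
    count = int(round(window_h * 60.0 / rec.interval_min))
    out = replace(
        rec,
        start_time=rec.start_time + pd.Timedelta(minutes=start * rec.interval_min),
        channels=rec.channels.iloc[start : start + count].reset_index(drop=True),
        extras=(
            rec.extras.iloc[start : start + count].reset_index(drop=True)
            if rec.extras is not None
            else None
        ),
    )
    return out


def annotate_phases(rec: Recording) -> np.ndarray:
    """Label each sample ``"light"`` or ``"dark"`` by its start clock time.

    Light is the half-open window ``[lights_on, lights_on + light_hours)``
    (default 07:00–19:00); everything else is dark.
    """
    mins = rec.minutes_after_lights_on()
    light_min = rec.photoperiod_h[0] * 60.0
    return np.where(mins < light_min, "light", "dark")


def derive_ee(rec: Recording, method: str = "weir") -> Recording:
    """Compute EE (kcal/h) from VO2/VCO2 and fill RER = VCO2/VO2.

    Uses the Weir equation ``EE = (3.941·VO2 + 1.106·VCO2)/1000`` with gas
    exchange in ml/h. RER is left missing (NaN) wherever VO2 ≤ 0; it is never
    silently set to zero.
    """
    if method != "weir":
        raise ValueError(f"unknown EE method {method!r}")
    if "VO2" not in rec.channels or "VCO2" not in rec.channels:
        raise CageFormatError("derive_ee requires VO2 and VCO2 channels")
    vo2 = rec.channels["VO2"].to_numpy(float)
    vco2 = rec.channels["VCO2"].to_numpy(float)
    channels = rec.channels.copy()
    channels["EE"] = (WEIR_O2 * vo2 + WEIR_CO2 * vco2) / 1000.0
    rer = np.full_like(vo2, np.nan)
    pos = vo2 > 0
    rer[pos] = vco2[pos] / vo2[pos]
    channels["RER"] = rer
    return replace(rec, channels=channels)


def channel_gap_fraction(rec: Recording, channel: str) -> float:
    """Fraction of missing samples in a channel (NaN counts as missing)."""
    s = rec.channels[channel].to_numpy(float)
    return float(np.mean(~np.isfinite(s)))


def interpolate_gaps(series: np.ndarray, max_gap_frac: float = MAX_GAP_FRAC) -> np.ndarray:
    """Linear-interpolate missing samples for rhythm fitting.

    Channels missing more than ``max_gap_frac`` of samples are rejected
    (``InsufficientDataError``) rather than imputed.
    """
    s = np.asarray(series, float)
    bad = ~np.isfinite(s)
    if not bad.any():
        return s
    if bad.mean() > max_gap_frac:
        raise InsufficientDataError(
            f"channel missing {100 * bad.mean():.1f}% of samples "
            f"(> {100 * max_gap_frac:.0f}% policy limit)"
        )
    idx = np.arange(len(s), dtype=float)
    out = s.copy()
    out[bad] = np.interp(idx[bad], idx[~bad], s[~bad])
    return out
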