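"""Per-animal feature extraction: daily averages plus circadian parameters.

Each animal is reduced to 14 candidate predictors of age:

====================  =============================================
Weight                body weight, g
Adjphase              EE cosinor peak time, min after lights-on
VO2, VCO2             daily-mean gas exchange, ml/h
EE                    daily-mean energy expenditure, kcal/h
RER                   daily-mean respiratory exchange ratio
Z                     rearing beam breaks per day
Feed, Drink           intake per day (g, ml)
Amplitude             EE cosinor amplitude, kcal/h
XT_YT                 horizontal beam breaks per day (XT + YT)
DistD                 distance per day, cm
SumR_L                wheel turns per day (SumR + SumL)
Speed                 daily-mean locomotion speed, cm/s
====================  =============================================

Rate-like channels are averaged over all samples; cumulative/event channels
are totalled per 24 h.  The classification follows instrument semantics and
is configurable.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cage_io import Recording, annotate_phases
from .errors import AssemblyError, WindowingError
from .rhythms import RhythmParams

#: The 14 clock candidate predictors, in canonical (reporting) order.
FEATURE_COLUMNS: tuple[str, ...] = (
    "Weight", "Adjphase", "VO2", "EE", "RER", "VCO2", "Z", "Feed",
    "Amplitude", "XT_YT", "Drink", "DistD", "SumR_L", "Speed",
)

#: Channels averaged per sample (rates) vs totalled per day (events/volumes).
RATE_CHANNELS: tuple[str, ...] = ("VO2", "VCO2", "RER", "EE", "Speed")
CUMULATIVE_CHANNELS: tuple[str, ...] = (
    "XT", "YT", "Z", "DistD", "Drink", "Feed", "SumR", "SumL",
)


def daily_means(
    rec: Recording,
    rate_channels: Sequence[str] = RATE_CHANNELS,
    cumulative_channels: Sequence[str] = CUMULATIVE_CHANNELS,
) -> dict[str, float]:
    """Daily-average value per channel over a whole-day window.

    Rate channels (kcal/h, ml/h, cm/s, RER) are arithmetic means over all
    samples; cumulative channels (counts, cm, g, ml per sample) are summed
    and divided by the number of days.  Missing samples (NaN) are excluded
    from means; for cumulative channels the total is rescaled by the fraction
    observed so gaps do not bias daily totals downward.
    """
    n_days = rec.duration_h / 24.0
    if abs(n_days - round(n_days)) * 24.0 * 60.0 > rec.interval_min + 1e-9:
        raise WindowingError(
            f"window of {rec.duration_h:.2f} h is not a whole number of days"
        )
    n_days = max(round(n_days), 1)
    out: dict[str, float] = {}
    for c in rec.channels.columns:
        x = rec.channels[c].to_numpy(float)
        finite = np.isfinite(x)
        if c in rate_channels:
            out[c] = float(np.mean(x[finite])) if finite.any() else np.nan
        elif c in cumulative_channels:
            if finite.any():
                total = float(np.sum(x[finite])) / (finite.mean())
                out[c] = total / n_days
            else:
                out[c] = np.nan
    return out


def phase_means(rec: Recording) -> pd.DataFrame:
    """Light/dark-resolved daily means (reporting only, not clock features)."""
    phases = annotate_phases(rec)
    rows = {}
    for phase in ("light", "dark"):
        sub = rec.channels.loc[phases == phase].reset_index(drop=True)
        sub_rec = Recording(
            animal_id=rec.animal_id, group=rec.group, age_weeks=rec.age_weeks,
            body_weight_g=rec.body_weight_g, start_time=rec.start_time,
            interval_min=rec.interval_min, channels=sub,
            lights_on_hour=rec.lights_on_hour,
        )
        # half-day windows: totals scaled to per-12-h; rates are plain means
        n_days = rec.duration_h / 24.0
        means = {}
        for c in sub.columns:
            x = sub[c].to_numpy(float)
            finite = np.isfinite(x)
            if c in RATE_CHANNELS:
                means[c] = float(np.mean(x[finite])) if finite.any() else np.nan
            else:
                means[c] = (
                    float(np.sum(x[finite])) / finite.mean() / n_days
                    if finite.any() else np.nan
                )
        rows[phase] = means
    return pd.DataFrame(rows).T


def build_feature_table(
    recordings: Sequence[Recording],
    rhythm_fits: Mapping[str, RhythmParams],
) -> pd.DataFrame:
    """Assemble the 14-predictor feature table, one row per animal.

    ``rhythm_fits`` maps animal_id to the EE cosinor fit supplying Amplitude
    and Adjphase.  Rows are ordered by animal_id; label columns ``age_weeks``
    and ``group`` follow the 14 features.
    """
    rows = []
    for rec in sorted(recordings, key=lambda r: r.animal_id):
        if rec.animal_id not in rhythm_fits:
            raise AssemblyError(f"no EE rhythm fit for animal {rec.animal_id!r}")
        fit = rhythm_fits[rec.animal_id]
        means = daily_means(rec)
        row = {
            "animal_id": rec.animal_id,
            "Weight": rec.body_weight_g,
            "Adjphase": fit.adjphase_min,
            "VO2": means.get("VO2", np.nan),
            "EE": means.get("EE", np.nan),
            "RER": means.get("RER", np.nan),
            "VCO2": means.get("VCO2", np.nan),
            "Z": means.get("Z", np.nan),
            "Feed": means.get("Feed", np.nan),
            "Amplitude": fit.amplitude,
            "XT_YT": means.get("XT", np.nan) + means.get("YT", np.nan),
            "Drink": means.get("Drink", np.nan),
            "DistD": means.get("DistD", np.nan),
            "SumR_L": means.get("SumR", np.nan) + means.get("SumL", np.nan),
            "Speed": means.get("Speed", np.nan),
            "age_weeks": rec.age_weeks,
            "group": rec.group,
        }
        rows.append(row)
    table = pd.DataFrame(rows).set_index("animal_id")
    feats = table[list(FEATURE_COLUMNS)]
    if feats.isna().any().any():
        bad = feats.columns[feats.isna().any()].tolist()
        missing = feats.index[feats.isna().any(axis=1)].tolist()
        raise AssemblyError(
            f"missing feature values in columns {bad} for animals {missing}"
        )
    return table
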