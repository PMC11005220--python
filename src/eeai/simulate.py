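"""In-silico metabolic-cage cohorts with age-dependent energy-metabolism traits.

The generator emulates a C57BL/6-style aging study: groups at 6, 20, 56, 64
and 80 weeks recorded for 72 h at 18-min intervals under a 12:12 photoperiod
(lights on 07:00), with a near-daily energy-expenditure rhythm (default
period 1423 min).  Aging is encoded as

* mean EE halving from 6 to 80 weeks (mesor ladder 0.60 -> 0.30 kcal/h),
* RER flat at 0.75 through 56 weeks, rising to 0.85 by 80 weeks,
* rhythm amplitude damping (30% -> 15% of mesor) and a 60-min phase delay,
* body weight increasing (20.5 -> 35.5 g) and locomotor activity halving.

EE is a pure cosine plus stationary AR(1) Gaussian noise; VO2 and VCO2 are
derived from EE and RER by inverting the Weir relation so the three channels
are mutually consistent.  Activity, feeding and drinking are nonnegative
event-like draws weighted 3:1 toward the dark phase (mice are nocturnal).

An intervention arm is modelled as a pure effective-age shift: every profile
parameter is taken at ``age - intervention_shift_weeks`` while the group keeps
its chronological-age label, giving downstream clock evaluation an exact
ground truth for the rejuvenation delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .cage_io import CHANNELS, WEIR_CO2, WEIR_O2, Recording
from .errors import ParameterError

#: Age ladder of the emulated study design (weeks).
LADDER_AGES = (6.0, 20.0, 56.0, 64.0, 80.0)

# Per-age generator anchors.  EE halves from 6 to 80 wk; RER rises after
# 56 wk to 0.85 at 80 wk; amplitude/phase/weight/activity ladders are free
# parameters of the generator (see docs/methods.md).
_EE_KCAL_H = (0.60, 0.52, 0.40, 0.36, 0.30)
_RER = (0.75, 0.75, 0.75, 0.78, 0.85)
_AMP_FRAC = (0.30, 0.272, 0.199, 0.182, 0.15)
_ACROPHASE_MIN = (990.0, 1001.0, 1030.0, 1037.0, 1050.0)
_WEIGHT_G = (20.5, 28.0, 33.0, 34.0, 35.5)
_ACTIVITY = (1.00, 0.90, 0.70, 0.60, 0.50)
_FEED_G_DAY = (4.0, 3.8, 3.4, 3.2, 3.0)
_DRINK_ML_DAY = (5.0, 4.8, 4.4, 4.2, 4.0)

#: Activity-channel daily totals at activity_scale 1 (young adult).
_ACTIVITY_BASE = {
    "XT": 8000.0,   # beam breaks/day
    "YT": 6000.0,
    "Z": 1500.0,
    "DistD": 40000.0,  # cm/day
    "SumR": 4000.0,    # wheel turns/day
    "SumL": 4000.0,
}
_DARK_LIGHT_WEIGHT = 3.0  # dark:light event-rate ratio


@dataclass
class AgeProfile:
    """Generating parameters for one age (or effective age)."""

    age_weeks: float
    mean_EE_kcal_h: float
    mean_RER: float
    rhythm_amplitude_frac: float
    acrophase_min: float        # peak time, minutes after lights-on
    activity_scale: float
    feed_g_day: float
    drink_ml_day: float
    body_weight_g: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rhythm_amplitude_frac <= 1.0:
            raise ParameterError(
                f"rhythm_amplitude_frac {self.rhythm_amplitude_frac} not in [0, 1]"
            )
        if not 0.65 <= self.mean_RER <= 1.05:
            raise ParameterError(f"mean_RER {self.mean_RER} not in [0.65, 1.05]")
        if self.mean_EE_kcal_h <= 0:
            raise ParameterError("mean_EE_kcal_h must be positive")


@dataclass
class GroupSpec:
    label: str
    age_weeks: float
    n: int
    intervention_shift_weeks: float = 0.0


@dataclass
class CohortSpec:
    """Study-design parameters shared by every simulated animal."""

    groups: list[GroupSpec] = field(default_factory=list)
    period_min: float = 1423.0
    interval_min: float = 18.0
    duration_h: float = 72.0
    noise_sd_frac: float = 0.05       # AR(1) stationary sd, fraction of mesor
    ar1_rho: float = 0.3
    between_animal_sd_frac: float = 0.05  # animal-level mesor scatter
    rer_animal_sd: float = 0.01
    rer_sample_sd: float = 0.02
    lights_on_hour: float = 7.0
    start_clock_hour: float = 7.0     # recordings start at lights-on
    seed: int = 0

    def validate(self) -> None:
        if self.period_min <= 0:
            raise ParameterError("period_min must be positive")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ParameterError("ar1_rho must be in [0, 1)")
        if self.duration_h * 60.0 < 2.0 * self.period_min:
            raise ParameterError(
                "duration must cover at least 2 full circadian periods"
            )
        for g in self.groups:
            if g.n < 1:
                raise ParameterError(f"group {g.label!r} has n = {g.n} < 1")


def default_age_profiles() -> dict[float, AgeProfile]:
    """Generator profiles at the study's five ladder ages."""
    return {age: profile_at_age(age) for age in LADDER_AGES}


_INTERP = {
    name: PchipInterpolator(LADDER_AGES, vals)
    for name, vals in [
        ("ee", _EE_KCAL_H),
        ("rer", _RER),
        ("amp", _AMP_FRAC),
        ("acro", _ACROPHASE_MIN),
        ("weight", _WEIGHT_G),
        ("activity", _ACTIVITY),
        ("feed", _FEED_G_DAY),
        ("drink", _DRINK_ML_DAY),
    ]
}


def profile_at_age(age_weeks: float) -> AgeProfile:
    """Profile at any age by monotone (PCHIP) interpolation of the ladder.

    Ages outside [6, 80] weeks are clamped to the ladder ends.
    """
    a = float(np.clip(age_weeks, LADDER_AGES[0], LADDER_AGES[-1]))
    return AgeProfile(
        age_weeks=float(age_weeks),
        mean_EE_kcal_h=float(_INTERP["ee"](a)),
        mean_RER=float(_INTERP["rer"](a)),
        rhythm_amplitude_frac=float(_INTERP["amp"](a)),
        acrophase_min=float(_INTERP["acro"](a)),
        activity_scale=float(_INTERP["activity"](a)),
        feed_g_day=float(_INTERP["feed"](a)),
        drink_ml_day=float(_INTERP["drink"](a)),
        body_weight_g=float(_INTERP["weight"](a)),
    )


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    eps = np.empty(n)
    eps[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    shocks = rng.normal(0.0, innov_sd, size=n - 1)
    for k in range(1, n):
        eps[k] = rho * eps[k - 1] + shocks[k - 1]
    return eps


def _phase_weights(minutes_after_lights_on: np.ndarray) -> np.ndarray:
    """Per-sample event weights, dark:light = 3:1, normalised to mean 1."""
    dark = minutes_after_lights_on >= 720.0
    w = np.where(dark, _DARK_LIGHT_WEIGHT, 1.0)
    return w / w.mean()


def simulate_recording(
    profile: AgeProfile, spec: CohortSpec, animal_seed: int,
    animal_id: str = "m0", group: str = "sim",
) -> Recording:
    """Simulate one animal's 72-h multi-channel trace.

    Deterministic given ``(spec.seed, animal_seed)``.  The EE channel is
    ``M*(1 + A*cos(2*pi*(t - phi)/tau)) + eps`` with AR(1) ``eps``; VO2 is
    recovered as ``1000*EE/(3.941 + 1.106*RER)`` and VCO2 as ``RER*VO2`` so
    the Weir equation applied to the generated gas channels returns EE
    exactly.
    """
    spec.validate()
    rng = np.random.default_rng([int(spec.seed) % 2**31, int(animal_seed) % 2**31])
    n = int(round(spec.duration_h * 60.0 / spec.interval_min))
    t = np.arange(n, dtype=float) * spec.interval_min
    start_offset = (spec.start_clock_hour - spec.lights_on_hour) * 60.0 % 1440.0
    mins_alo = (start_offset + t) % 1440.0

    mesor = profile.mean_EE_kcal_h * (
        1.0 + rng.normal(0.0, spec.between_animal_sd_frac)
    )
    mesor = max(mesor, 0.05 * profile.mean_EE_kcal_h)
    amp = profile.rhythm_amplitude_frac * mesor
    phase_min = profile.acrophase_min - start_offset  # peak in series time
    cosine = np.cos(2.0 * np.pi * (t - phase_min) / spec.period_min)
    ee = mesor + amp * cosine + _ar1(
        rng, n, spec.ar1_rho, spec.noise_sd_frac * mesor
    )
    ee = np.maximum(ee, 1e-6)

    rer_offset = rng.normal(0.0, spec.rer_animal_sd)
    rer = profile.mean_RER + rer_offset + _ar1(
        rng, n, spec.ar1_rho, spec.rer_sample_sd
    )
    rer = np.clip(rer, 0.65, 1.05)

    vo2 = 1000.0 * ee / (WEIR_O2 + WEIR_CO2 * rer)
    vco2 = rer * vo2

    w = _phase_weights(mins_alo)
    channels: dict[str, np.ndarray] = {
        "VO2": vo2, "VCO2": vco2, "RER": rer, "EE": ee,
    }
    per_sample_frac = spec.interval_min / 1440.0
    for name, base in _ACTIVITY_BASE.items():
        lam = base * profile.activity_scale * per_sample_frac * w
        channels[name] = rng.poisson(lam).astype(float)
    channels["Speed"] = channels["DistD"] / (spec.interval_min * 60.0)
    # feeding/drinking: Poisson event counts x fixed bout size, dark-weighted
    for name, daily, bout in (
        ("Feed", profile.feed_g_day, 0.15),   # g per feeding bout
        ("Drink", profile.drink_ml_day, 0.20),  # ml per drinking bout
    ):
        lam = (daily / bout) * per_sample_frac * w
        channels[name] = rng.poisson(lam).astype(float) * bout

    start_day = pd.Timestamp("2024-01-01") + pd.Timedelta(hours=spec.start_clock_hour)
    return Recording(
        animal_id=animal_id,
        group=group,
        age_weeks=profile.age_weeks,
        body_weight_g=float(
            max(profile.body_weight_g + rng.normal(0.0, 1.0), 10.0)
        ),
        start_time=start_day,
        interval_min=spec.interval_min,
        channels=pd.DataFrame({c: channels[c] for c in CHANNELS}),
        lights_on_hour=spec.lights_on_hour,
    )


def simulate_cohort(spec: CohortSpec) -> tuple[list[Recording], pd.DataFrame]:
    """Simulate every group in ``spec``; returns recordings plus a truth table.

    Intervention groups draw their generating profile at ``age -
    intervention_shift_weeks`` (the effective age) but keep the chronological
    ``age_weeks`` label on the Recording, mirroring a treated arm whose
    metabolic phenotype is younger than its calendar age.
    """
    spec.validate()
    recordings: list[Recording] = []
    truth_rows = []
    animal_counter = 0
    for g in spec.groups:
        effective_age = g.age_weeks - g.intervention_shift_weeks
        profile = profile_at_age(effective_age)
        for i in range(g.n):
            animal_id = f"{g.label}_{i:02d}"
            rec = simulate_recording(
                profile, spec, animal_seed=animal_counter,
                animal_id=animal_id, group=g.label,
            )
            rec.age_weeks = float(g.age_weeks)  # chronological label
            recordings.append(rec)
            truth_rows.append(
                {
                    "animal_id": animal_id,
                    "group": g.label,
                    "age_weeks": g.age_weeks,
                    "effective_age_weeks": effective_age,
                    "intervention_shift_weeks": g.intervention_shift_weeks,
                    "animal_seed": animal_counter,
                    "mean_EE_kcal_h": profile.mean_EE_kcal_h,
                    "mean_RER": profile.mean_RER,
                    "rhythm_amplitude_frac": profile.rhythm_amplitude_frac,
                    "acrophase_min": profile.acrophase_min,
                }
            )
            animal_counter += 1
    return recordings, pd.DataFrame(truth_rows)


def default_ladder_spec(
    n_per_group: int = 4, seed: int = 0, **overrides
) -> CohortSpec:
    """The study-design cohort: five untreated age groups, n per group."""
    groups = [
        GroupSpec(label=f"{int(a)}w", age_weeks=a, n=n_per_group)
        for a in LADDER_AGES
    ]
    return CohortSpec(groups=groups, seed=seed, **overrides)
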