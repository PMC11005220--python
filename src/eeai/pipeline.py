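"""End-to-end orchestration: trajectory analysis, clock build, intervention
evaluation, and the test-selection rule for group comparisons.

Group comparisons follow a screen-then-test rule: every group is screened for
normality (Shapiro–Wilk) and the set for homogeneity of variances (Levene);
only if all screens pass at alpha = 0.05 is one-way ANOVA used (with
Sidak-adjusted pairwise t-tests when more than two groups), otherwise
Kruskal–Wallis.  Both screen outcomes are always reported, so a reader can
judge borderline branch choices.  No multiplicity correction is applied
across parameters — each metabolic parameter is tested on its own.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .cage_io import Recording
from .clock import ClockFit, predict_ee_age, train_sparse_clock
from .errors import SchemaError
from .features import build_feature_table, daily_means, phase_means
from .ordination import distance_matrix, nmds, pcoa
from .rhythms import DEFAULT_PERIOD_GRID, cosinor_fit, periodogram_top_periods
from .simulate import CohortSpec, simulate_cohort

ALPHA = 0.05


@dataclass
class GroupComparison:
    """One parameter's group-comparison entry."""

    parameter: str
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    normality_p: dict[str, float]
    variance_p: float | None
    test_name: str                 # "anova" | "kruskal" | "descriptive"
    statistic: float | None
    p_value: float | None
    pairwise_sidak: list[dict] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def compare_groups(
    values: Mapping[str, Sequence[float]],
    alpha: float = ALPHA,
    parameter: str = "",
) -> GroupComparison:
    """Screen-then-test comparison of one parameter across groups.

    Parametric (ANOVA) iff every group passes Shapiro–Wilk and Levene's test
    passes, all at ``alpha``; otherwise Kruskal–Wallis.  Groups with n < 3 or
    zero overall variance yield a descriptive-only entry.
    """
    groups = {k: np.asarray(v, float) for k, v in values.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    means = {k: float(np.mean(v)) for k, v in groups.items()}
    sds = {k: float(np.std(v, ddof=1)) if len(v) > 1 else np.nan
           for k, v in groups.items()}
    ns = {k: int(len(v)) for k, v in groups.items()}
    flags: list[str] = []

    if any(n < 3 for n in ns.values()):
        flags.append("group with n < 3: descriptive only")
        return GroupComparison(parameter, means, sds, ns, {}, None,
                               "descriptive", None, None, flags=flags)
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        flags.append("zero variance in all groups: descriptive only")
        return GroupComparison(parameter, means, sds, ns, {}, None,
                               "descriptive", None, None, flags=flags)

    norm_p: dict[str, float] = {}
    for k, v in groups.items():
        if np.ptp(v) == 0:
            norm_p[k] = 0.0
            flags.append(f"group {k!r} is constant; normality screen fails")
        else:
            norm_p[k] = float(stats.shapiro(v).pvalue)
    try:
        lev_p = float(stats.levene(*groups.values()).pvalue)
    except ValueError:
        lev_p = 0.0
        flags.append("variance screen degenerate")

    parametric = all(p > alpha for p in norm_p.values()) and lev_p > alpha
    pairwise = []
    if parametric:
        stat, p = stats.f_oneway(*groups.values())
        test_name = "anova"
        if len(groups) > 2:
            pairs = list(itertools.combinations(groups, 2))
            m = len(pairs)
            for a, b in pairs:
                t = stats.ttest_ind(groups[a], groups[b])
                p_adj = 1.0 - (1.0 - t.pvalue) ** m  # Sidak
                pairwise.append(
                    {"a": a, "b": b, "t": float(t.statistic),
                     "p_raw": float(t.pvalue), "p_sidak": float(min(p_adj, 1.0))}
                )
    else:
        stat, p = stats.kruskal(*groups.values())
        test_name = "kruskal"
    return GroupComparison(
        parameter, means, sds, ns, norm_p, lev_p, test_name,
        float(stat), float(p), pairwise_sidak=pairwise, flags=flags,
    )


def fit_rhythms(
    recordings: Sequence[Recording],
    channel: str = "EE",
    period_min: float | None = None,
    grid: tuple[float, float, float] = DEFAULT_PERIOD_GRID,
    per_mouse_period: bool = False,
) -> tuple[dict, pd.DataFrame]:
    """Periodogram + cosinor fit of one channel for every animal.

    By default all animals are fitted at the cohort consensus period (the
    median of per-animal top-1 periods, or ``period_min`` when given);
    ``per_mouse_period`` fits each animal at its own top-1 period instead.
    """
    top1: dict[str, float] = {}
    tops: dict[str, list[float]] = {}
    for rec in recordings:
        series = rec.channels[channel].to_numpy(float)
        _, top = periodogram_top_periods(series, rec.interval_min, grid=grid)
        tops[rec.animal_id] = top
        top1[rec.animal_id] = top[0]
    consensus = (
        float(period_min)
        if period_min is not None
        else float(np.median(list(top1.values())))
    )
    fits = {}
    rows = []
    for rec in recordings:
        tau = top1[rec.animal_id] if per_mouse_period else consensus
        t0 = float(rec.minutes_after_lights_on()[0])
        fit = cosinor_fit(
            rec.channels[channel].to_numpy(float),
            rec.interval_min, tau, t0_min=t0,
        )
        fits[rec.animal_id] = fit
        rows.append(
            {
                "animal_id": rec.animal_id,
                "group": rec.group,
                "age_weeks": rec.age_weeks,
                "period_min": fit.period_min,
                "top1_period_min": top1[rec.animal_id],
                "top_periods": ";".join(f"{p:.0f}" for p in tops[rec.animal_id]),
                "amplitude": fit.amplitude,
                "adjphase_min": fit.adjphase_min,
                "mesor": fit.mesor,
                "rsq": fit.rsq,
            }
        )
    return fits, pd.DataFrame(rows).set_index("animal_id")


def _provenance(config: Mapping, seed: int) -> dict:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": int(seed),
        "eeai_version": __version__,
    }


def run_trajectory(
    recordings: Sequence[Recording],
    config: Mapping | None = None,
    seed: int = 0,
) -> dict:
    """Age-trajectory analysis: daily means, rhythms, ordination, group tests.

    Returns a JSON-able report with per-animal features, per-age summaries,
    the EE decline ratio between the oldest and youngest groups, PCoA
    coordinates, and screen-then-test comparisons per parameter.  Animals
    whose EE channel cannot be rhythm-fitted are flagged in ``qc`` and
    excluded rather than aborting the run.
    """
    config = dict(config or {})
    qc: list[str] = []
    usable = []
    for rec in recordings:
        try:
            daily_means(rec)
            rec.channels["EE"].to_numpy(float)
            usable.append(rec)
        except Exception as exc:  # noqa: BLE001 — QC, keep going
            qc.append(f"{rec.animal_id}: {type(exc).__name__}: {exc}")
    fits, rhythm_table = fit_rhythms(usable, period_min=config.get("period_min"))
    table = build_feature_table(usable, fits)

    by_age = table.groupby("age_weeks")
    summaries = by_age.mean(numeric_only=True)
    ages = sorted(table["age_weeks"].unique())
    trend = {}
    if len(ages) >= 2:
        ee_young = table.loc[table.age_weeks == ages[0], "EE"].mean()
        ee_old = table.loc[table.age_weeks == ages[-1], "EE"].mean()
        trend = {
            "youngest_weeks": float(ages[0]),
            "oldest_weeks": float(ages[-1]),
            "ee_ratio_old_over_young": float(ee_old / ee_young),
            "ee_decline_percent": float(100.0 * (1.0 - ee_old / ee_young)),
        }

    comparisons = []
    if len(ages) >= 2 and all(
        (table.age_weeks == a).sum() >= 1 for a in ages
    ):
        for param in ("VO2", "VCO2", "EE", "RER", "Amplitude", "Adjphase",
                      "Weight"):
            values = {
                str(a): table.loc[table.age_weeks == a, param].to_numpy()
                for a in ages
            }
            comparisons.append(compare_groups(values, parameter=param).to_dict())

    ord_result = None
    if len(table) >= 3:
        d = distance_matrix(table[table.columns.intersection(
            ["Weight", "Adjphase", "VO2", "EE", "RER", "VCO2", "Z", "Feed",
             "Amplitude", "XT_YT", "Drink", "DistD", "SumR_L", "Speed"])])
        res = pcoa(d, dims=2)
        ord_result = {
            "coordinates": {
                i: list(map(float, xy))
                for i, xy in zip(table.index, res.coordinates)
            },
            "proportion_explained": [
                float(x)
                for x in (
                    res.proportion_explained
                    if res.proportion_explained is not None
                    else []
                )
            ],
        }

    return {
        "provenance": _provenance(config, seed),
        "qc": qc,
        "features": table.reset_index().to_dict(orient="records"),
        "rhythms": rhythm_table.reset_index().to_dict(orient="records"),
        "age_summaries": summaries.reset_index().to_dict(orient="records"),
        "trend": trend,
        "pcoa": ord_result,
        "comparisons": comparisons,
    }


def run_intervention_eval(
    clock: ClockFit,
    table: pd.DataFrame,
    aged_control_group: str,
    config: Mapping | None = None,
    seed: int = 0,
) -> dict:
    """Score treated and control arms with a trained clock.

    Reports per-group EE age (mean ± SD), the rejuvenation delta of every
    group against the aged control, and a screen-then-test comparison of the
    predicted ages across groups.
    """
    config = dict(config or {})
    per_animal, summary, deltas = predict_ee_age(clock, table)
    if aged_control_group not in summary.index:
        raise SchemaError(
            f"aged control group {aged_control_group!r} absent from table"
        )
    aged_mean = float(summary.loc[aged_control_group, "mean"])
    rejuvenation = {
        str(g): aged_mean - float(summary.loc[g, "mean"])
        for g in summary.index
        if g != aged_control_group
    }
    values = {
        str(g): per_animal.loc[per_animal.group == g, "ee_age_weeks"].to_numpy()
        for g in summary.index
    }
    comparison = (
        compare_groups(values, parameter="ee_age_weeks").to_dict()
        if len(values) >= 2 else None
    )
    return {
        "provenance": _provenance(config, seed),
        "per_animal": per_animal.reset_index().to_dict(orient="records"),
        "group_summary": summary.reset_index().to_dict(orient="records"),
        "deltas": deltas.to_dict(orient="records"),
        "rejuvenation_vs_aged_weeks": rejuvenation,
        "comparison": comparison,
    }


def run_clock_build(
    recordings: Sequence[Recording],
    seed: int = 0,
    period_min: float | None = None,
    **clock_kwargs,
) -> tuple[ClockFit, pd.DataFrame]:
    """Features + rhythms + sparse clock in one call (untreated animals)."""
    fits, _ = fit_rhythms(recordings, period_min=period_min)
    table = build_feature_table(recordings, fits)
    clock = train_sparse_clock(table, seed=seed, **clock_kwargs)
    return clock, table


def simulate_and_report(spec: CohortSpec, config: Mapping | None = None) -> dict:
    """Convenience wrapper: simulate a cohort and run the trajectory report."""
    recordings, truth = simulate_cohort(spec)
    report = run_trajectory(recordings, config=config, seed=spec.seed)
    report["truth"] = truth.to_dict(orient="records")
    return report


def phase_feature_table(recordings: Sequence[Recording]) -> pd.DataFrame:
    """Light/dark-resolved parameter means per animal (ordination input)."""
    rows = []
    for rec in recordings:
        pm = phase_means(rec)
        for phase in pm.index:
            row = {"animal_id": rec.animal_id, "group": rec.group,
                   "age_weeks": rec.age_weeks, "phase": phase}
            row.update({c: pm.loc[phase, c] for c in pm.columns})
            rows.append(row)
    return pd.DataFrame(rows)
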