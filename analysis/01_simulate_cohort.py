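"""Simulate the study cohorts: a five-age ladder plus intervention arms.

Writes the canonical cage table, per-animal metadata, and the generator's
ground truth under scratch/cohort/ (raw traces are bulky and fully
regenerable from the fixed seed, so they stay out of version control).  The ladder (6, 20, 56, 64, 80 weeks,
n=4) drives the trajectory analysis and clock training; the evaluation arms
(young and aged controls plus a treated arm whose metabolic profile is
generated 27 weeks younger than its calendar age) are scored by the clock in
05_intervention_eval.py and are never used for training.
"""

from pathlib import Path

from eeai.cage_io import write_cage_table, write_metadata
from eeai.simulate import CohortSpec, GroupSpec, default_ladder_spec, simulate_cohort

SEED = 20240
OUT = Path("scratch/cohort")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    ladder = default_ladder_spec(n_per_group=4, seed=SEED)
    recs, truth = simulate_cohort(ladder)
    write_cage_table(recs, OUT / "ladder_cage_table.csv")
    write_metadata(recs, OUT / "ladder_metadata.json")
    truth.to_json(OUT / "ladder_truth.json", orient="records", indent=2)
    print(f"ladder: {len(recs)} animals at ages "
          f"{sorted(set(r.age_weeks for r in recs))}")

    arms = CohortSpec(
        groups=[
            GroupSpec("Young", 20.0, 4),
            GroupSpec("Aged", 80.0, 4),
            GroupSpec("Treated", 80.0, 4, intervention_shift_weeks=27.0),
        ],
        seed=SEED + 1,
    )
    arm_recs, arm_truth = simulate_cohort(arms)
    write_cage_table(arm_recs, OUT / "arms_cage_table.csv")
    write_metadata(arm_recs, OUT / "arms_metadata.json")
    arm_truth.to_json(OUT / "arms_truth.json", orient="records", indent=2)
    print(f"evaluation arms: {len(arm_recs)} animals "
          "(Young 20w, Aged 80w, Treated 80w with effective age 53w)")


if __name__ == "__main__":
    main()
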