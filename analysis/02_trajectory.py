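"""Age-trajectory analysis of the simulated ladder cohort.

Reads results/cohort/, runs daily-means extraction, circadian rhythm fitting
at the cohort consensus period, PCoA, and screen-then-test group comparisons;
writes the full JSON report and a per-age summary CSV under results/.

The headline check: mean daily EE should fall by roughly half from the
6-week to the 80-week group, with RER rising from ~0.75 to ~0.85.
"""

import json
from pathlib import Path

import pandas as pd

from eeai.cage_io import read_cage_table
from eeai.pipeline import run_trajectory

SEED = 20240
COHORT = Path("scratch/cohort")
OUT = Path("results")


def load_ladder():
    meta = json.loads((COHORT / "ladder_metadata.json").read_text())
    sidecar = {k: {kk: v[kk] for kk in ("group", "age_weeks", "body_weight_g")}
               for k, v in meta.items()}
    return read_cage_table(COHORT / "ladder_cage_table.csv", metadata=sidecar)


def main() -> None:
    recordings = load_ladder()
    report = run_trajectory(recordings, seed=SEED)
    (OUT / "trajectory.json").write_text(json.dumps(report, indent=2, default=str))

    summaries = pd.DataFrame(report["age_summaries"])
    summaries.to_csv(OUT / "age_summaries.csv", index=False)

    trend = report["trend"]
    print(f"EE decline {trend['youngest_weeks']:.0f}->"
          f"{trend['oldest_weeks']:.0f} wk: {trend['ee_decline_percent']:.1f}%")
    rer = summaries.set_index("age_weeks")["RER"]
    print(f"RER: {rer.loc[20.0]:.3f} at 20 wk -> {rer.loc[80.0]:.3f} at 80 wk")
    for comp in report["comparisons"]:
        print(f"{comp['parameter']:>10}: {comp['test_name']} "
              f"p={comp['p_value']:.2e}" if comp["p_value"] is not None
              else f"{comp['parameter']:>10}: descriptive")


if __name__ == "__main__":
    main()
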