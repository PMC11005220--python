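"""Ordination of metabolic profiles: PCoA of the ladder, NMDS of the arms.

Distances are Euclidean on z-scored per-phase parameter means.  The dark
phase (the active period of a nocturnal animal) separates young from aged
profiles more cleanly than the light phase, which the per-phase NMDS makes
visible; stress values are printed alongside.
Outputs: results/ordination/*.csv (coordinates + stress/variance explained).
"""

import json
from pathlib import Path

import pandas as pd

from eeai.cage_io import read_cage_table
from eeai.ordination import distance_matrix, nmds, pcoa
from eeai.pipeline import phase_feature_table

SEED = 20240
COHORT = Path("scratch/cohort")
OUT = Path("results/ordination")


def load(prefix: str):
    meta = json.loads((COHORT / f"{prefix}_metadata.json").read_text())
    sidecar = {k: {kk: v[kk] for kk in ("group", "age_weeks", "body_weight_g")}
               for k, v in meta.items()}
    return read_cage_table(COHORT / f"{prefix}_cage_table.csv", metadata=sidecar)


def per_phase_matrix(recordings, phase: str) -> pd.DataFrame:
    table = phase_feature_table(recordings)
    table = table[table.phase == phase].set_index("animal_id")
    return table.drop(columns=["phase", "group", "age_weeks"]), table["group"]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    ladder = load("ladder")
    X, groups = per_phase_matrix(ladder, "dark")
    res = pcoa(distance_matrix(X), dims=2)
    coords = pd.DataFrame(res.coordinates, columns=["axis1", "axis2"],
                          index=X.index)
    coords["group"] = groups
    coords.to_csv(OUT / "ladder_pcoa_dark.csv")
    print("ladder PCoA (dark phase): variance explained "
          f"{[round(float(v), 3) for v in res.proportion_explained]}")

    arms = load("arms")
    for phase in ("dark", "light"):
        X, groups = per_phase_matrix(arms, phase)
        res = nmds(distance_matrix(X), dims=2, seed=SEED)
        coords = pd.DataFrame(res.coordinates, columns=["axis1", "axis2"],
                              index=X.index)
        coords["group"] = groups
        coords["stress"] = res.stress
        coords.to_csv(OUT / f"arms_nmds_{phase}.csv")
        print(f"arms NMDS ({phase} phase): stress {res.stress:.4f}")


if __name__ == "__main__":
    main()
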