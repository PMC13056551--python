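#!/usr/bin/env python
"""Exposure groups, cohort summary and timepoint-window design.

Partitions patients into Azithro / Other-Abx / No-Abx, prints the group
percentages, and selects the early (1 +/- 1 day of exposure) and late
(5 +/- 1 day) single-timepoint windows with day-matched, 50%-rarefied
No-Abx comparators.

Reads results/data/, writes results/design.csv.
"""

from pathlib import Path

import pandas as pd

from airway_resistome.cohort_design import build_design, summarize_cohort
from airway_resistome.cli import _load_exposures
from airway_resistome.core_data import read_sample_metadata

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    meta = read_sample_metadata(ROOT / "data" / "metadata.csv")
    bio = meta[~meta["is_negative_control"]]
    exposures = _load_exposures(ROOT / "data" / "exposures.csv")
    print("cohort summary:")
    print(summarize_cohort(exposures.values()).to_string(index=False))

    design = build_design(bio, exposures, seed=SEED)
    design.to_csv(ROOT / "design.csv", index=False)
    included = design[design["included"]]
    print("\nwindow x group sample counts:")
    print(included.groupby(["window", "group"]).size().unstack(fill_value=0))
    n_re = int(design["reassigned_to_no_abx"].sum())
    print(f"\n{n_re} treated-group samples collected pre-dose moved to No-Abx")


if __name__ == "__main__":
    main()
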