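#!/usr/bin/env python
"""Generate the synthetic study dataset all downstream steps consume.

Draws a multi-site cohort (default here: 150 patients, a desk-scale version
of the study design), six nasal-swab timepoints over 28 days, 26 water
controls across four processing batches, and the taxon/ARG report tables
with batch-specific contamination and an exposure-dependent MLS enrichment.

Writes results/data/{metadata.csv, taxon_report.tsv, arg_report.tsv,
exposures.csv, manifest.json}.
"""

from pathlib import Path

from airway_resistome.synthetic_data import SimConfig, write_dataset

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
N_PATIENTS = 150
SEED = 1


def main() -> None:
    cfg = SimConfig(n_patients=N_PATIENTS, seed=SEED)
    data = write_dataset(cfg, OUT)
    meta = data["meta"]
    n_bio = int((~meta["is_negative_control"]).sum())
    n_ctrl = int(meta["is_negative_control"].sum())
    print(f"wrote {n_bio} biological samples and {n_ctrl} water controls to {OUT}")
    print(
        f"{len(data['taxon_records'])} taxon records, "
        f"{len(data['arg_records'])} ARG records"
    )


if __name__ == "__main__":
    main()
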