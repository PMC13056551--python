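#!/usr/bin/env python
"""Negative-binomial decontamination of the taxon and ARG report tables.

Fits the contamination null (per batch:feature control means, one shared
dispersion) from the 26 water controls and retains only features whose
counts in biological samples sit significantly above it (BH FDR < 0.1).
The microbiome and resistome are corrected in two separate runs.

Reads results/data/, writes results/decontam/.
"""

from pathlib import Path

from airway_resistome.core_data import (
    read_arg_report,
    read_sample_metadata,
    read_taxon_report,
    write_arg_report,
    write_taxon_report,
)
from airway_resistome.pipeline import decontaminate_records

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    meta = read_sample_metadata(ROOT / "data" / "metadata.csv")
    out = ROOT / "decontam"
    out.mkdir(parents=True, exist_ok=True)
    for label, records, writer in (
        ("taxa", read_taxon_report(ROOT / "data" / "taxon_report.tsv"), write_taxon_report),
        ("args", read_arg_report(ROOT / "data" / "arg_report.tsv"), write_arg_report),
    ):
        kept, result, null = decontaminate_records(records, meta, fdr=0.1)
        writer(kept, out / f"{label}_decontaminated.tsv")
        audit = result.decisions
        audit.to_csv(out / f"{label}_decontam_audit.tsv", sep="\t", index=False)
        n_bio = (~meta["is_negative_control"]).sum()
        removed = audit[~audit["retained"]]
        print(
            f"{label}: theta = {null.theta:.3g}; "
            f"{len(kept)} of {sum(1 for r in records if r.sample_id in set(meta.loc[~meta['is_negative_control'], 'sample_id']))} "
            f"biological records retained; "
            f"{removed['feature'].nunique()} features removed somewhere "
            f"across {n_bio} samples"
        )


if __name__ == "__main__":
    main()
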