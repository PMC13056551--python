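#!/usr/bin/env python
"""Per-sample spurious-hit filters on the decontaminated reports.

Taxa must show >= 10 NT alignments, >= 1 NR alignment and >= 50 bases of
alignment; ARGs with < 5% coverage breadth are dropped when also rare in the
cohort (<= 5% of samples-with-ARGs) or weakly supported (DPM <= 1 and <= 10
alignments).

Reads results/decontam/, writes results/filtered/.
"""

from pathlib import Path

from airway_resistome.core_data import (
    read_arg_report,
    read_sample_metadata,
    read_taxon_report,
    write_arg_report,
    write_taxon_report,
)
from airway_resistome.qc_filters import arg_prevalence, filter_args, filter_taxa

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    meta = read_sample_metadata(ROOT / "data" / "metadata.csv")
    totals = dict(zip(meta["sample_id"], meta["total_reads"]))
    out = ROOT / "filtered"
    out.mkdir(parents=True, exist_ok=True)

    taxa = read_taxon_report(ROOT / "decontam" / "taxa_decontaminated.tsv")
    taxa_kept, _ = filter_taxa(taxa)
    write_taxon_report(taxa_kept, out / "taxa_filtered.tsv")
    print(f"taxa: {len(taxa_kept)}/{len(taxa)} records pass the alignment rules")

    args = read_arg_report(ROOT / "decontam" / "args_decontaminated.tsv")
    prevalence = arg_prevalence(args)
    args_kept, _ = filter_args(args, prevalence, totals)
    write_arg_report(args_kept, out / "args_filtered.tsv")
    print(f"args: {len(args_kept)}/{len(args)} records pass the coverage/support rules")


if __name__ == "__main__":
    main()
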