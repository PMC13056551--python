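#!/usr/bin/env python
"""Taxa x MLS-gene Spearman correlation network.

Correlates the 30 most abundant genera (RPM) with MLS gene expression
(DPM) across all filtered samples; BH-adjusts over all pairs and keeps
edges with rho > 0.2 and q < 0.05.

Reads results/{data,filtered}, writes results/network_edges.csv.
"""

from pathlib import Path

from airway_resistome.association_stats import spearman_network
from airway_resistome.core_data import (
    pivot_to_table,
    read_arg_report,
    read_sample_metadata,
    read_taxon_report,
)
from airway_resistome.resistome_metrics import MLS_CLASS

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    meta = read_sample_metadata(ROOT / "data" / "metadata.csv")
    totals = dict(zip(meta["sample_id"], meta["total_reads"]))
    taxa = read_taxon_report(ROOT / "filtered" / "taxa_filtered.tsv")
    args = [
        r
        for r in read_arg_report(ROOT / "filtered" / "args_filtered.tsv")
        if r.drug_class == MLS_CLASS
    ]
    taxa_rpm = pivot_to_table(taxa, "RPM", total_reads=totals)
    arg_dpm = pivot_to_table(args, "DPM", total_reads=totals)
    common = taxa_rpm.values.index.intersection(arg_dpm.values.index)
    out = spearman_network(taxa_rpm.values.loc[common], arg_dpm.values.loc[common])
    out.to_csv(ROOT / "network_pairs.csv", index=False)
    edges = out[out["edge"]].sort_values("rho", ascending=False)
    edges.to_csv(ROOT / "network_edges.csv", index=False)
    print(
        f"{len(edges)} edges (rho > 0.2, q < 0.05) among {len(out)} "
        f"taxon x gene pairs over {len(common)} samples"
    )
    if not edges.empty:
        print(edges[["taxon", "gene", "rho", "q"]].round(3).to_string(index=False))


if __name__ == "__main__":
    main()
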