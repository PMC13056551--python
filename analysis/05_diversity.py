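#!/usr/bin/env python
"""Alpha/beta diversity of the filtered microbiome and resistome.

Computes per-sample Shannon diversity (genus RPM for the microbiome,
gene DPM for the resistome), Bray-Curtis dissimilarities, a 2-D PCoA
embedding, and a one-factor PERMANOVA contrasting azithromycin-exposed
versus unexposed samples.

Reads results/filtered/, writes results/diversity/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from airway_resistome.cli import _load_exposures
from airway_resistome.core_data import (
    pivot_to_table,
    read_arg_report,
    read_sample_metadata,
    read_taxon_report,
)
from airway_resistome.diversity import (
    alpha_diversity,
    bray_curtis_matrix,
    pcoa,
    permanova_oneway,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    meta = read_sample_metadata(ROOT / "data" / "metadata.csv")
    totals = dict(zip(meta["sample_id"], meta["total_reads"]))
    exposures = _load_exposures(ROOT / "data" / "exposures.csv")
    out = ROOT / "diversity"
    out.mkdir(parents=True, exist_ok=True)

    taxa = read_taxon_report(ROOT / "filtered" / "taxa_filtered.tsv")
    taxa_rpm = pivot_to_table(taxa, "RPM", total_reads=totals)
    alpha = alpha_diversity(taxa_rpm)
    alpha.to_csv(out / "alpha_taxa.csv")
    print(f"microbiome Shannon over {len(alpha)} samples: "
          f"median {alpha.median():.2f} (IQR {alpha.quantile(.25):.2f}-{alpha.quantile(.75):.2f})")

    args = read_arg_report(ROOT / "filtered" / "args_filtered.tsv")
    arg_dpm = pivot_to_table(args, "DPM", total_reads=totals)
    alpha_res = alpha_diversity(arg_dpm)
    alpha_res.to_csv(out / "alpha_resistome.csv")

    d = bray_curtis_matrix(taxa_rpm)
    d.to_frame().to_csv(out / "bray_curtis_taxa.tsv", sep="\t")
    emb = pcoa(d, k=2)
    emb.coordinates.to_csv(out / "pcoa_taxa.csv")
    print(f"PCoA axes explain {100 * emb.proportion_explained[:2].sum():.1f}% "
          "of the positive spectrum")

    sm = meta.set_index("sample_id")
    labels = []
    for sid in d.ids:
        exp = exposures[sm.loc[sid, "patient_id"]]
        e = exp.cumulative_exposure(int(sm.loc[sid, "day_from_admission"]), exp.azithro_days)
        labels.append("azithro" if e > 0 else "control")
    labels = np.array(labels)
    f, p = permanova_oneway(d, labels, n_perm=999, seed=SEED)
    print(f"PERMANOVA (azithro-exposed vs unexposed): F = {f:.2f}, p = {p:.3g} "
          f"({(labels == 'azithro').sum()} vs {(labels == 'control').sum()} samples)")
    pd.DataFrame({"pseudo_F": [f], "p": [p]}).to_csv(out / "permanova_taxa.csv", index=False)


if __name__ == "__main__":
    main()
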