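#!/usr/bin/env python
"""Single-timepoint group comparisons at the early and late windows.

For each metric (total bacterial RPM, total fungal RPM, microbiome Shannon,
MLS richness) and each window, fits the linear mixed model (group +
age quintile + sex + trajectory group + days from admission + steroids,
site random intercept), reports BH-adjusted group contrasts and arithmetic
fold changes, and adds the pairwise rank-sum p-values used for the
distribution-level comparisons.

Reads results/{data,filtered,design.csv}, writes results/single_timepoint.csv.
"""

import warnings
from pathlib import Path

import pandas as pd

from airway_resistome.association_stats import (
    fit_group_model,
    fold_change,
    pairwise_rank_test,
)
from airway_resistome.cli import _load_exposures
from airway_resistome.core_data import (
    read_arg_report,
    read_sample_metadata,
    read_taxon_report,
)
from airway_resistome.pipeline import compute_sample_metrics

ROOT = Path(__file__).resolve().parents[1] / "results"
METRICS = ["total_bacterial_rpm", "total_fungal_rpm", "shannon", "mls_richness"]
COVARIATES = ["age_quintile", "sex", "trajectory_group", "day_from_admission", "steroids_ever"]


def main() -> None:
    meta = read_sample_metadata(ROOT / "data" / "metadata.csv")
    exposures = _load_exposures(ROOT / "data" / "exposures.csv")
    taxa = read_taxon_report(ROOT / "filtered" / "taxa_filtered.tsv")
    args = read_arg_report(ROOT / "filtered" / "args_filtered.tsv")
    metrics = compute_sample_metrics(taxa, args, meta, exposures)
    design = pd.read_csv(ROOT / "design.csv")

    rows = []
    for window in ("early", "late"):
        sel = design[design["included"] & (design["window"] == window)]
        frame = metrics.merge(sel[["sample_id", "group"]], on="sample_id")
        for metric in METRICS:
            sub = frame.dropna(subset=[metric])
            if sub["group"].nunique() < 2:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = fit_group_model(sub, metric, covariates=COVARIATES)
            contrasts = res.table[res.table["term"].str.startswith("group[")]
            no_abx = sub.loc[sub["group"] == "No-Abx", metric]
            for term, est, p, q in zip(
                contrasts["term"], contrasts["estimate"], contrasts["p"], contrasts["q"]
            ):
                grp = term[len("group["):-1]
                other = sub.loc[sub["group"] == grp, metric]
                fc = fold_change(other, no_abx) if no_abx.mean() > 0 else float("nan")
                rank_p = pairwise_rank_test(other, no_abx)
                rows.append(
                    {
                        "window": window, "metric": metric, "contrast": f"{grp} vs No-Abx",
                        "estimate": est, "p": p, "q": q, "fold_change": fc,
                        "rank_sum_p": rank_p, "n": len(sub),
                    }
                )
    out = pd.DataFrame(rows)
    out.to_csv(ROOT / "single_timepoint.csv", index=False)
    print(out.round(4).to_string(index=False))
    sig = out[(out["q"] < 0.05)]
    print(f"\n{len(sig)} group contrasts significant at q < 0.05")


if __name__ == "__main__":
    main()
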