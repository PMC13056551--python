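"""End-to-end driver: simulate -> decontaminate -> QC filter -> metrics -> models.

One :class:`~airway_resistome.synthetic_data.SimConfig` drives the whole
chain; the returned report carries the per-sample metric table, the
single-timepoint design, the exposure-trend fit for MLS richness and the
decontamination audit.  Each stage is also importable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import association_stats, cohort_design, decontam, diversity, qc_filters, resistome_metrics
from .core_data import ArgRecord, FeatureTable, TaxonRecord, pivot_to_table
from .synthetic_data import SimConfig, simulate_all

__all__ = [
    "PipelineReport",
    "run_pipeline",
    "decontaminate_records",
    "compute_sample_metrics",
]


@dataclass
class PipelineReport:
    meta: pd.DataFrame
    design: pd.DataFrame
    metrics: pd.DataFrame  # per-sample metric table
    taxa_decontam: decontam.DecontamResult
    arg_decontam: decontam.DecontamResult
    trend: association_stats.AssociationResult
    network: pd.DataFrame


def _control_tables(records, meta: pd.DataFrame) -> dict[str, FeatureTable]:
    ctrl = meta[meta["is_negative_control"]]
    tables = {}
    for batch, sub in ctrl.groupby("batch"):
        ids = sorted(sub["sample_id"])
        batch_records = [r for r in records if r.sample_id in set(ids)]
        table = pivot_to_table(batch_records, "reads")
        # controls with no observed features still count toward the fit
        base = table.values.reindex(index=ids, fill_value=0.0)
        if base.empty and base.columns.empty:
            base = pd.DataFrame(index=ids, dtype=float)
        tables[batch] = FeatureTable(base, "reads")
    return tables


def decontaminate_records(records, meta: pd.DataFrame, fdr: float = 0.1):
    """Fit the control null and drop non-retained (sample, feature) pairs."""
    bio_ids = set(meta.loc[~meta["is_negative_control"], "sample_id"])
    controls = _control_tables(records, meta)
    null = decontam.fit_null(controls)
    bio_records = [r for r in records if r.sample_id in bio_ids]
    table = pivot_to_table(bio_records, "reads")
    batches = dict(zip(meta["sample_id"], meta["batch"]))
    result, _ = decontam.apply_decontam(table, null, batches, fdr=fdr)
    kept_pairs = result.retained_pairs()
    kept = [
        r
        for r in bio_records
        if (r.sample_id, r.taxon_id if isinstance(r, TaxonRecord) else r.gene)
        in kept_pairs
    ]
    return kept, result, null


def compute_sample_metrics(taxa_kept, args_kept, meta: pd.DataFrame, exposures) -> pd.DataFrame:
    """Per-sample metric table from filtered records: abundance, diversity,
    resistome summaries and exposure covariates.

    Clinical covariates come from the metadata frame when present (the
    on-disk round-trip keeps them there); exposure day sets come from
    ``exposures``.
    """
    bio = meta[~meta["is_negative_control"]]
    has_covariates = "trajectory_group" in meta.columns
    taxa_by_sample: dict[str, list[TaxonRecord]] = {}
    for r in taxa_kept:
        taxa_by_sample.setdefault(r.sample_id, []).append(r)
    args_by_sample: dict[str, list[ArgRecord]] = {}
    for r in args_kept:
        args_by_sample.setdefault(r.sample_id, []).append(r)

    rows = []
    for s in bio.itertuples(index=False):
        trecs = taxa_by_sample.get(s.sample_id, [])
        arecs = args_by_sample.get(s.sample_id, [])
        bact_rpm = sum(
            r.reads for r in trecs if r.kingdom == "bacteria"
        ) * 1e6 / s.total_reads
        fung_rpm = sum(
            r.reads for r in trecs if r.kingdom == "fungi"
        ) * 1e6 / s.total_reads
        rpm_vec = np.array([r.reads for r in trecs], dtype=float)
        shannon_taxa = diversity.shannon(rpm_vec) if rpm_vec.sum() > 0 else np.nan
        profile = resistome_metrics.profile_sample(s.sample_id, arecs, s.total_reads)
        exp = exposures[s.patient_id]
        day = int(s.day_from_admission)
        rows.append(
            {
                "sample_id": s.sample_id,
                "patient_id": s.patient_id,
                "site_id": s.site_id,
                "day_from_admission": day,
                "total_bacterial_rpm": bact_rpm,
                "total_fungal_rpm": fung_rpm,
                "shannon": shannon_taxa,
                "mls_richness": profile.mls_richness,
                "mls_proportion": profile.class_proportion.get(
                    resistome_metrics.MLS_CLASS, np.nan
                )
                if not profile.total_dpm_zero
                else np.nan,
                "azithro_days": exp.cumulative_exposure(day, exp.azithro_days),
                "trajectory_group": int(s.trajectory_group)
                if has_covariates
                else exp.trajectory_group,
                "sex": s.sex if has_covariates else exp.sex,
                "age_quintile": int(s.age_quintile)
                if has_covariates
                else exp.age_quintile,
                "steroids_ever": bool(s.steroids_ever)
                if has_covariates
                else exp.steroids_ever,
                **{
                    f"{drug}_days": exp.cumulative_exposure(
                        day, exp.other_abx_days.get(drug, frozenset())
                    )
                    for drug in cohort_design.CO_ANTIBIOTICS
                },
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(cfg: SimConfig, fdr: float = 0.1) -> PipelineReport:
    data = simulate_all(cfg)
    meta = data["meta"]
    exposures = data["exposures"]
    totals = dict(zip(meta["sample_id"], meta["total_reads"]))

    # decontamination: microbiome and resistome handled separately
    taxa_kept, taxa_result, _ = decontaminate_records(data["taxon_records"], meta, fdr)
    args_kept, arg_result, _ = decontaminate_records(data["arg_records"], meta, fdr)

    # per-sample QC filters
    taxa_kept, _ = qc_filters.filter_taxa(taxa_kept)
    prevalence = qc_filters.arg_prevalence(args_kept)
    args_kept, _ = qc_filters.filter_args(args_kept, prevalence, totals)

    bio = meta[~meta["is_negative_control"]]
    metrics = compute_sample_metrics(taxa_kept, args_kept, meta, exposures)

    design = cohort_design.build_design(bio, exposures, seed=cfg.seed + 17)

    trend = association_stats.fit_exposure_trend(
        metrics,
        metric="mls_richness",
        co_abx_cols=[f"{d}_days" for d in cohort_design.CO_ANTIBIOTICS],
    )

    # taxa x MLS-gene correlation network on the filtered data
    taxa_rpm = pivot_to_table(taxa_kept, "RPM", total_reads=totals)
    mls_records = [
        r for r in args_kept if r.drug_class == resistome_metrics.MLS_CLASS
    ]
    if mls_records and len(taxa_rpm.samples) >= 5:
        arg_dpm = pivot_to_table(mls_records, "DPM", total_reads=totals)
        common = taxa_rpm.values.index.intersection(arg_dpm.values.index)
        network = association_stats.spearman_network(
            taxa_rpm.values.loc[common], arg_dpm.values.loc[common]
        )
    else:
        network = pd.DataFrame(
            columns=["taxon", "gene", "rho", "p", "undefined", "q", "edge"]
        )
    return PipelineReport(
        meta=meta,
        design=design,
        metrics=metrics,
        taxa_decontam=taxa_result,
        arg_decontam=arg_result,
        trend=trend,
        network=network,
    )
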