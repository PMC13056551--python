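"""Resistome summaries: MLS richness, class proportions, persistence windows.

All summaries operate on ARG records that have already passed
decontamination and QC filtering, so "detectably expressed" reduces to
DPM > 0.  MLS is the macrolide/lincosamide/streptogramin class, the class
to which azithromycin belongs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_data import ArgRecord, compute_dpm

__all__ = [
    "MLS_CLASS",
    "ResistomeProfile",
    "profile_sample",
    "mls_richness",
    "class_proportions",
    "persistence_window",
]

MLS_CLASS = "MLS"


@dataclass
class ResistomeProfile:
    """Per-sample resistome summary on the DPM scale."""

    sample_id: str
    gene_dpm: dict[str, float]
    class_dpm: dict[str, float]
    mls_richness: int
    class_proportion: dict[str, float]  # empty when total DPM == 0
    total_dpm_zero: bool = False


def _records_to_dpm(
    records: Sequence[ArgRecord], total_reads: int
) -> tuple[dict[str, float], dict[str, str]]:
    gene_dpm: dict[str, float] = {}
    gene_class: dict[str, str] = {}
    for r in records:
        gene_dpm[r.gene] = float(compute_dpm(r.mean_depth, total_reads))
        gene_class[r.gene] = r.drug_class
    return gene_dpm, gene_class


def mls_richness(records: Sequence[ArgRecord], total_reads: int) -> int:
    """Number of distinct MLS genes with DPM > 0 in one sample."""
    gene_dpm, gene_class = _records_to_dpm(records, total_reads)
    return sum(
        1 for g, dpm in gene_dpm.items() if gene_class[g] == MLS_CLASS and dpm > 0
    )


def class_proportions(records: Sequence[ArgRecord], total_reads: int) -> dict[str, float]:
    """Fraction of the sample's total ARG DPM contributed by each drug class.

    A sample with zero total DPM has no defined composition; an empty dict
    is returned (never silent zeros).
    """
    gene_dpm, gene_class = _records_to_dpm(records, total_reads)
    class_dpm: dict[str, float] = {}
    for g, dpm in gene_dpm.items():
        class_dpm[gene_class[g]] = class_dpm.get(gene_class[g], 0.0) + dpm
    total = sum(class_dpm.values())
    if total == 0:
        return {}
    return {c: v / total for c, v in class_dpm.items()}


def profile_sample(
    sample_id: str, records: Sequence[ArgRecord], total_reads: int
) -> ResistomeProfile:
    gene_dpm, gene_class = _records_to_dpm(records, total_reads)
    class_dpm: dict[str, float] = {}
    for g, dpm in gene_dpm.items():
        class_dpm[gene_class[g]] = class_dpm.get(gene_class[g], 0.0) + dpm
    total = sum(class_dpm.values())
    props = {c: v / total for c, v in class_dpm.items()} if total > 0 else {}
    rich = sum(
        1 for g, dpm in gene_dpm.items() if gene_class[g] == MLS_CLASS and dpm > 0
    )
    return ResistomeProfile(
        sample_id=sample_id,
        gene_dpm=gene_dpm,
        class_dpm=class_dpm,
        mls_richness=rich,
        class_proportion=props,
        total_dpm_zero=total == 0,
    )


def persistence_window(
    patient_samples: pd.DataFrame,
    cessation_day: int | None,
    lo: int = 7,
    hi: int = 10,
) -> pd.DataFrame:
    """Samples collected ``lo``-``hi`` days after the last azithromycin dose.

    ``patient_samples`` needs ``sample_id`` and ``day_from_admission``
    columns; ``cessation_day`` is the patient's last azithromycin day.
    Used for the paired comparison against late-window samples; a patient
    without azithromycin exposure has no cessation day and is an error.
    """
    if cessation_day is None:
        raise ValueError("patient has no azithromycin exposure; no cessation day")
    delta = patient_samples["day_from_admission"].astype(int) - int(cessation_day)
    return patient_samples[(delta >= lo) & (delta <= hi)].reset_index(drop=True)
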