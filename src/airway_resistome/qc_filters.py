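"""Per-sample spurious-hit filters applied after decontamination.

Taxon rule (retain iff all hold):
  nt_alignments >= 10, nr_alignments >= 1, nt_alignment_length >= 50.

ARG rule (exclude iff):
  coverage_breadth < 5%  AND
  ( cohort prevalence of the gene <= 5%  OR  (DPM <= 1 AND alignments <= 10) ).

Prevalence is the fraction of samples-with-ARGs (samples having at least one
ARG record after decontamination) in which the gene appears; it is computed
once, before filtering, not iteratively on survivors.  Boundary semantics
follow the inequalities above verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .core_data import ArgRecord, TaxonRecord, compute_dpm

__all__ = [
    "FilterDecision",
    "filter_taxa",
    "filter_args",
    "arg_prevalence",
]


@dataclass(frozen=True)
class FilterDecision:
    """Outcome of the QC rules for one record."""

    key: tuple[str, str]  # (sample_id, taxon_id or gene)
    retained: bool
    failed_rules: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.retained != (len(self.failed_rules) == 0):
            raise ValueError("retained iff no failed rules")


def filter_taxa(
    records: Sequence[TaxonRecord],
) -> tuple[list[TaxonRecord], list[FilterDecision]]:
    """Apply the three alignment-quality rules to every taxon record."""
    retained: list[TaxonRecord] = []
    decisions: list[FilterDecision] = []
    for r in records:
        failed = []
        if r.nt_alignments < 10:
            failed.append("nt_alignments")
        if r.nr_alignments < 1:
            failed.append("nr_alignments")
        if r.nt_alignment_length < 50:
            failed.append("nt_alignment_length")
        ok = not failed
        decisions.append(FilterDecision((r.sample_id, r.taxon_id), ok, tuple(failed)))
        if ok:
            retained.append(r)
    return retained, decisions


def arg_prevalence(records: Sequence[ArgRecord]) -> dict[str, float]:
    """Fraction of samples-with-ARGs in which each gene appears."""
    samples = {r.sample_id for r in records}
    if not samples:
        return {}
    seen: dict[str, set[str]] = {}
    for r in records:
        seen.setdefault(r.gene, set()).add(r.sample_id)
    return {gene: len(s) / len(samples) for gene, s in seen.items()}


def filter_args(
    records: Sequence[ArgRecord],
    cohort_arg_prevalence: Mapping[str, float],
    total_reads: Mapping[str, int],
) -> tuple[list[ArgRecord], list[FilterDecision]]:
    """Exclude low-coverage ARG hits that are rare or weakly supported.

    ``cohort_arg_prevalence`` maps gene -> fraction of samples-with-ARGs
    carrying it (see :func:`arg_prevalence`); ``total_reads`` supplies the
    per-sample DPM denominator.
    """
    retained: list[ArgRecord] = []
    decisions: list[FilterDecision] = []
    for r in records:
        if r.gene not in cohort_arg_prevalence:
            raise KeyError(f"gene {r.gene!r} missing from the prevalence map")
        failed = []
        if r.coverage_breadth < 0.05:
            prev = cohort_arg_prevalence[r.gene]
            dpm = float(compute_dpm(r.mean_depth, total_reads[r.sample_id]))
            if prev <= 0.05:
                failed.append("low_coverage_rare")
            if dpm <= 1.0 and r.alignments <= 10:
                failed.append("low_coverage_low_support")
        ok = not failed
        decisions.append(FilterDecision((r.sample_id, r.gene), ok, tuple(failed)))
        if ok:
            retained.append(r)
    return retained, decisions
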