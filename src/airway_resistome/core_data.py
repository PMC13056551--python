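"""Data model, report-table I/O and abundance transforms.

Two report dialects are supported, both plain TSV:

* taxon reports (CZ-ID style): one row per (sample, taxon, rank) with NT/NR
  alignment counts and the NT alignment length used by the QC filters;
* ARG reports (CARD-RGI style): one row per (sample, gene) with read count,
  alignment count, coverage breadth and mean per-base depth.

Coverage breadth is stored internally as a fraction in [0, 1]; the report
dialect prints percent, converted at I/O only.

Abundance units
---------------
RPM (reads per million): ``reads * 1e6 / total_reads``.
DPM (depth per million):  ``mean_depth * 1e6 / total_reads``, where
``mean_depth`` is the read depth averaged over the gene's length, so DPM
also corrects for gene-length differences between ARGs.  ``total_reads``
is the per-sample post-host-removal microbial read count carried in the
sample metadata (the upstream pipeline subsamples to 2 million reads).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaxonRecord",
    "ArgRecord",
    "SampleInfo",
    "FeatureTable",
    "SchemaError",
    "ValidationError",
    "read_taxon_report",
    "write_taxon_report",
    "read_arg_report",
    "write_arg_report",
    "read_sample_metadata",
    "write_sample_metadata",
    "compute_rpm",
    "compute_dpm",
    "pivot_to_table",
]

RANKS = ("species", "genus")
KINGDOMS = ("bacteria", "fungi", "viruses", "other")
BATCHES = ("1", "2", "3A", "3B")
VALUE_KINDS = ("reads", "RPM", "DPM")


class SchemaError(ValueError):
    """A report file is missing a required column or holds an unparseable value."""


class ValidationError(ValueError):
    """Records violate an invariant (duplicate keys, out-of-range values)."""


@dataclass(frozen=True)
class TaxonRecord:
    """One taxon observation in one sample."""

    sample_id: str
    taxon_id: str
    name: str
    rank: str
    kingdom: str
    reads: int
    nt_alignments: int
    nr_alignments: int
    nt_alignment_length: float

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValidationError(f"unknown rank {self.rank!r}")
        if self.kingdom not in KINGDOMS:
            raise ValidationError(f"unknown kingdom {self.kingdom!r}")
        for attr in ("reads", "nt_alignments", "nr_alignments", "nt_alignment_length"):
            if getattr(self, attr) < 0:
                raise ValidationError(f"{attr} must be non-negative")


@dataclass(frozen=True)
class ArgRecord:
    """One antimicrobial-resistance-gene observation in one sample.

    ``mean_depth`` is reads/base averaged over the gene's length;
    ``coverage_breadth`` is the covered fraction of gene positions.
    """

    sample_id: str
    gene: str
    drug_class: str
    reads: int
    alignments: int
    coverage_breadth: float
    mean_depth: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage_breadth <= 1.0:
            raise ValidationError(
                f"coverage_breadth {self.coverage_breadth} outside [0, 1]"
            )
        if self.reads < 0 or self.alignments < 0 or self.mean_depth < 0:
            raise ValidationError("counts and depth must be non-negative")
        if (self.mean_depth == 0) != (self.reads == 0):
            raise ValidationError("mean_depth is zero iff reads is zero")


@dataclass(frozen=True)
class SampleInfo:
    """Per-sample metadata; ``total_reads`` is the normalization denominator."""

    sample_id: str
    patient_id: str | None
    site_id: str | None
    batch: str
    day_from_admission: int
    total_reads: int
    is_negative_control: bool = False

    def __post_init__(self) -> None:
        if self.batch not in BATCHES:
            raise ValidationError(f"unknown batch {self.batch!r}")
        if self.total_reads <= 0:
            raise ValidationError("total_reads must be positive")
        if self.is_negative_control and self.patient_id is not None:
            raise ValidationError("negative controls carry no patient_id")
        if self.day_from_admission < 0:
            raise ValidationError("day_from_admission must be non-negative")


@dataclass
class FeatureTable:
    """Dense samples x features matrix of one value kind (reads, RPM or DPM)."""

    values: pd.DataFrame  # index = sample ids, columns = feature ids
    value_kind: str
    feature_meta: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(f"value_kind must be one of {VALUE_KINDS}")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValidationError("sample and feature identifiers must be unique")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("feature table values must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(
            self.values.loc[list(sample_ids)].copy(), self.value_kind, self.feature_meta
        )


# ---------------------------------------------------------------------------
# report I/O

_TAXON_COLUMNS = [
    "sample_id", "taxon_id", "name", "rank", "kingdom",
    "reads", "nt_alignments", "nr_alignments", "nt_alignment_length",
]
_ARG_COLUMNS = [
    "sample_id", "gene", "drug_class", "reads", "alignments",
    "coverage_breadth_pct", "mean_depth",
]


def _read_table(path: str | Path, required: list[str], sep: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def _numeric(df: pd.DataFrame, col: str, kind: type, path: Path | str) -> pd.Series:
    try:
        out = df[col].astype(float if kind is float else int)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: column {col!r} holds unparseable numerics") from exc
    return out


def read_taxon_report(path: str | Path) -> list[TaxonRecord]:
    """Read a taxon report TSV into validated records.

    Raises :class:`SchemaError` for missing columns or unparseable numerics
    and :class:`ValidationError` for duplicate (sample, taxon, rank) keys.
    """
    df = _read_table(path, _TAXON_COLUMNS, sep="\t")
    for col, kind in (("reads", int), ("nt_alignments", int),
                      ("nr_alignments", int), ("nt_alignment_length", float)):
        df[col] = _numeric(df, col, kind, path)
    key = df[["sample_id", "taxon_id", "rank"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0].tolist()
        raise ValidationError(f"{path}: duplicate (sample, taxon, rank) key {dup}")
    return [
        TaxonRecord(
            sample_id=r.sample_id, taxon_id=r.taxon_id, name=r.name, rank=r.rank,
            kingdom=r.kingdom, reads=int(r.reads), nt_alignments=int(r.nt_alignments),
            nr_alignments=int(r.nr_alignments),
            nt_alignment_length=float(r.nt_alignment_length),
        )
        for r in df.itertuples(index=False)
    ]


def write_taxon_report(records: Iterable[TaxonRecord], path: str | Path) -> None:
    df = pd.DataFrame([vars(r) if not hasattr(r, "__dataclass_fields__") else
                       {f.name: getattr(r, f.name) for f in fields(r)}
                       for r in records], columns=_TAXON_COLUMNS[:5] + _TAXON_COLUMNS[5:])
    df.to_csv(path, sep="\t", index=False)


def read_arg_report(path: str | Path) -> list[ArgRecord]:
    """Read a CARD-RGI-style ARG report TSV; percent breadth becomes a fraction."""
    df = _read_table(path, _ARG_COLUMNS, sep="\t")
    for col, kind in (("reads", int), ("alignments", int),
                      ("coverage_breadth_pct", float), ("mean_depth", float)):
        df[col] = _numeric(df, col, kind, path)
    key = df[["sample_id", "gene"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0].tolist()
        raise ValidationError(f"{path}: duplicate (sample, gene) key {dup}")
    return [
        ArgRecord(
            sample_id=r.sample_id, gene=r.gene, drug_class=r.drug_class,
            reads=int(r.reads), alignments=int(r.alignments),
            coverage_breadth=float(r.coverage_breadth_pct) / 100.0,
            mean_depth=float(r.mean_depth),
        )
        for r in df.itertuples(index=False)
    ]


def write_arg_report(records: Iterable[ArgRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "sample_id": r.sample_id, "gene": r.gene, "drug_class": r.drug_class,
            "reads": r.reads, "alignments": r.alignments,
            "coverage_breadth_pct": r.coverage_breadth * 100.0,
            "mean_depth": r.mean_depth,
        })
    pd.DataFrame(rows, columns=_ARG_COLUMNS).to_csv(path, sep="\t", index=False)


_META_COLUMNS = [
    "sample_id", "patient_id", "site_id", "batch", "day_from_admission",
    "total_reads", "is_negative_control",
]


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-sample metadata CSV (SampleInfo columns plus covariates)."""
    df = _read_table(path, _META_COLUMNS, sep=",")
    df["day_from_admission"] = _numeric(df, "day_from_admission", int, path)
    df["total_reads"] = _numeric(df, "total_reads", int, path)
    df["is_negative_control"] = df["is_negative_control"].map(
        {"True": True, "False": False, "1": True, "0": False}
    )
    if df["is_negative_control"].isna().any():
        raise SchemaError(f"{path}: is_negative_control must be boolean")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample_id")
    # clinical covariates ride along when present
    for col in ("age_quintile", "trajectory_group"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    if "steroids_ever" in df.columns:
        df["steroids_ever"] = df["steroids_ever"].map(
            {"True": True, "False": False, "1": True, "0": False, "": None}
        )
    return df


def write_sample_metadata(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata frame missing column(s) {missing}")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# abundance transforms

def compute_rpm(reads, total_reads):
    """Reads per million: ``reads * 1e6 / total_reads`` (vectorized)."""
    total = np.asarray(total_reads, dtype=float)
    if np.any(total <= 0):
        raise ValueError("total_reads must be positive")
    return np.asarray(reads, dtype=float) * 1e6 / total


def compute_dpm(mean_depth, total_reads):
    """Depth per million: ``mean_depth * 1e6 / total_reads`` (vectorized)."""
    total = np.asarray(total_reads, dtype=float)
    if np.any(total <= 0):
        raise ValueError("total_reads must be positive")
    depth = np.asarray(mean_depth, dtype=float)
    if np.any(depth < 0):
        raise ValueError("mean_depth must be non-negative")
    return depth * 1e6 / total


def pivot_to_table(
    records: Sequence[TaxonRecord] | Sequence[ArgRecord],
    value_kind: str = "reads",
    *,
    total_reads: dict[str, int] | None = None,
) -> FeatureTable:
    """Pivot records into a dense samples x features table.

    Missing (sample, feature) pairs become exact zeros.  ``value_kind``:

    * ``"reads"`` — raw read counts;
    * ``"RPM"``   — reads per million (requires ``total_reads`` per sample);
    * ``"DPM"``   — ARG depth per million (requires ``total_reads``).
    """
    if value_kind not in VALUE_KINDS:
        raise ValidationError(f"value_kind must be one of {VALUE_KINDS}")
    rows = []
    for r in records:
        feature = r.taxon_id if isinstance(r, TaxonRecord) else r.gene
        if value_kind == "reads":
            value = float(r.reads)
        else:
            if total_reads is None:
                raise ValueError(f"{value_kind} pivot requires total_reads per sample")
            denom = total_reads[r.sample_id]
            if value_kind == "RPM":
                value = float(compute_rpm(r.reads, denom))
            else:
                if not isinstance(r, ArgRecord):
                    raise ValidationError("DPM tables are built from ARG records")
                value = float(compute_dpm(r.mean_depth, denom))
        rows.append((r.sample_id, feature, value))
    if not rows:
        return FeatureTable(pd.DataFrame(dtype=float), value_kind)
    df = pd.DataFrame(rows, columns=["sample_id", "feature", "value"])
    if df.duplicated(["sample_id", "feature"]).any():
        pair = df[df.duplicated(["sample_id", "feature"])].iloc[0]
        raise ValidationError(
            f"conflicting duplicate records for ({pair.sample_id}, {pair.feature})"
        )
    wide = df.pivot(index="sample_id", columns="feature", values="value").fillna(0.0)
    wide.index.name = None
    wide.columns.name = None
    return FeatureTable(wide, value_kind)
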