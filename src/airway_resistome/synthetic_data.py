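"""Synthetic cohort, report-table and negative-control generator.

Emulates the post-pipeline data layout of a longitudinal nasal-swab
metatranscriptomic study of hospitalized COVID-19 patients:

* a multi-site cohort partitioned into azithromycin-treated, other-antibiotic
  and no-antibiotic groups, with short azithromycin courses (median 2 days)
  started shortly after admission and ceftriaxone the most frequent co-drug;
* six sampling timepoints with target days 0, 4, 7, 14, 21 and 28 and
  visit attrition;
* four processing batches with batch-specific reagent contamination:
  contaminant features are drawn negative-binomially (per batch:feature mean,
  one shared dispersion) in both biological samples and the water controls,
  while genuine biology never appears in controls;
* per-patient log-normal taxon abundances with AR(1) temporal
  autocorrelation on the log scale;
* an exposure-dependent multiplicative enrichment of MLS-class ARG depth
  (``azithro_effect`` per cumulative azithromycin day) and a mild
  exposure-dependent suppression of total bacterial reads;
* alignment metadata constructed so a configurable fraction of records
  deliberately fails each downstream QC rule.

Everything is driven by one integer seed; identical configs and seeds give
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_design import CO_ANTIBIOTICS, PatientExposure
from .core_data import (
    ArgRecord,
    TaxonRecord,
    write_arg_report,
    write_sample_metadata,
    write_taxon_report,
)

__all__ = ["SimConfig", "simulate_cohort", "simulate_reports", "simulate_all", "write_dataset"]

# gene -> (drug class, gene length in bases); MLS members include the genes
# most prevalent in upper-airway resistomes (ermA, msrA, ermB, ermC, mphC)
GENE_TABLE: dict[str, tuple[str, int]] = {
    "ermA": ("MLS", 732),
    "ermB": ("MLS", 738),
    "ermC": ("MLS", 735),
    "msrA": ("MLS", 1467),
    "mphC": ("MLS", 900),
    "mefA": ("MLS", 1218),
    "tetM": ("tetracycline", 1920),
    "tetW": ("tetracycline", 1920),
    "blaZ": ("beta-lactam", 846),
    "mecA": ("beta-lactam", 2007),
    "aph3-IIIa": ("aminoglycoside", 795),
    "aac6-aph2": ("aminoglycoside", 1440),
    "vanA": ("glycopeptide", 1032),
    "dfrC": ("diaminopyrimidine", 486),
}

# per-gene (overt carriage probability, baseline mean log depth when carried);
# MLS genes sit lower at baseline so that, unexposed, they make up roughly a
# quarter of total resistome depth, as in upper-airway resistomes
GENE_PROFILE: dict[str, tuple[float, float]] = {
    "ermA": (0.45, np.log(0.55)), "msrA": (0.40, np.log(0.55)),
    "ermB": (0.25, np.log(0.4)), "ermC": (0.20, np.log(0.4)),
    "mphC": (0.18, np.log(0.4)), "mefA": (0.15, np.log(0.4)),
    "tetM": (0.30, np.log(4.0)), "tetW": (0.18, np.log(3.0)),
    "blaZ": (0.35, np.log(4.0)), "mecA": (0.15, np.log(3.0)),
    "aph3-IIIa": (0.12, np.log(2.5)), "aac6-aph2": (0.10, np.log(2.5)),
    "vanA": (0.03, np.log(1.5)), "dfrC": (0.12, np.log(2.5)),
}
GENE_CARRIAGE: dict[str, float] = {g: p for g, (p, _) in GENE_PROFILE.items()}

# host genus whose abundance co-varies with each gene's expression (the
# correlation-network structure: staphylococcal and streptococcal ARGs track
# their hosts)
GENE_HOST: dict[str, str] = {
    "ermA": "Staphylococcus", "msrA": "Staphylococcus", "mphC": "Staphylococcus",
    "ermC": "Staphylococcus", "blaZ": "Staphylococcus", "mecA": "Staphylococcus",
    "ermB": "Streptococcus", "mefA": "Streptococcus", "tetM": "Streptococcus",
    "tetW": "Prevotella", "aph3-IIIa": "Enterobacter", "aac6-aph2": "Klebsiella",
    "vanA": "Lactobacillus", "dfrC": "Corynebacterium",
}

# upper-airway genera with mean log10 relative read count and kingdom
GENUS_TABLE: list[tuple[str, float, str]] = [
    ("Staphylococcus", 4.2, "bacteria"), ("Corynebacterium", 4.5, "bacteria"),
    ("Dolosigranulum", 4.0, "bacteria"), ("Moraxella", 3.8, "bacteria"),
    ("Streptococcus", 3.9, "bacteria"), ("Haemophilus", 3.4, "bacteria"),
    ("Neisseria", 3.0, "bacteria"), ("Fusobacterium", 2.6, "bacteria"),
    ("Klebsiella", 2.4, "bacteria"), ("Pseudomonas", 2.5, "bacteria"),
    ("Prevotella", 2.8, "bacteria"), ("Veillonella", 2.7, "bacteria"),
    ("Rothia", 2.9, "bacteria"), ("Gemella", 2.5, "bacteria"),
    ("Lactobacillus", 2.3, "bacteria"), ("Anaerococcus", 2.4, "bacteria"),
    ("Finegoldia", 2.3, "bacteria"), ("Peptoniphilus", 2.2, "bacteria"),
    ("Cutibacterium", 3.2, "bacteria"), ("Enterobacter", 1.9, "bacteria"),
    ("Serratia", 1.8, "bacteria"), ("Acinetobacter", 2.0, "bacteria"),
    ("Candida", 2.2, "fungi"), ("Malassezia", 2.6, "fungi"),
    ("Aspergillus", 1.6, "fungi"), ("Rhodotorula", 1.4, "fungi"),
]

CONTAMINANT_GENERA = [
    "Ralstonia", "Bradyrhizobium", "Sphingomonas", "Methylobacterium",
    "Burkholderia", "Delftia", "Cupriavidus", "Mesorhizobium",
    "Phyllobacterium", "Herbaspirillum", "Acidovorax", "Aquabacterium",
]
CONTAMINANT_ARGS = ["sul1", "aadA1", "qacEdelta1"]
CONTAMINANT_ARG_CLASSES = {
    "sul1": "sulfonamide", "aadA1": "aminoglycoside", "qacEdelta1": "disinfectant",
}

BATCHES = ("1", "2", "3A", "3B")


@dataclass
class SimConfig:
    """Study-scale defaults mirror the cohort the pipeline was built for."""

    n_patients: int = 1164
    n_sites: int = 15
    n_negative_controls: int = 26
    sampling_days: tuple[int, ...] = (0, 4, 7, 14, 21, 28)
    total_reads_target: int = 2_000_000
    total_reads_noise_sd: int = 50_000
    # Azithro / Other-Abx / No-Abx enrolment fractions (366/324/474 of 1,164)
    group_probabilities: tuple[float, float, float] = (366 / 1164, 324 / 1164, 474 / 1164)
    visit_retention: float = 0.80
    incomplete_dates_rate: float = 0.02
    contamination_theta: float = 2.0
    contamination_log_mu: float = 2.5  # mean of log batch:feature contamination means
    contamination_log_sd: float = 1.0
    ar1_rho: float = 0.6
    taxon_log_sd: float = 0.8
    azithro_effect: float = 1.4  # MLS DPM multiplier per cumulative exposure day
    bacterial_effect: float = 0.96  # bacterial read multiplier per exposure day
    effect_cap_days: int = 5
    qc_fail_fraction: float = 0.05
    read_length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.group_probabilities) - 1.0) > 1e-9:
            raise ValueError("group probabilities must sum to 1")
        if self.azithro_effect <= 0 or self.bacterial_effect <= 0:
            raise ValueError("effect multipliers must be positive")
        if self.n_patients < 1 or self.n_negative_controls < 2:
            raise ValueError("need at least 1 patient and 2 negative controls")


def _draw_course(rng: np.random.Generator) -> tuple[int, int]:
    """(start day, duration) of an antibiotic course; median duration 2 days."""
    start = int(min(rng.geometric(0.45) - 1, 10))
    duration = int(min(rng.geometric(0.35), 35))
    return start, duration


def simulate_cohort(cfg: SimConfig):
    """Draw patients, exposures and the sample/negative-control metadata.

    Returns ``(meta, exposures)``: a sample-metadata frame (biological
    samples and water controls, with clinical covariates) and a dict of
    :class:`~airway_resistome.cohort_design.PatientExposure` per patient.
    """
    rng = np.random.default_rng(cfg.seed)
    groups = ("Azithro", "Other-Abx", "No-Abx")
    exposures: dict[str, PatientExposure] = {}
    meta_rows = []
    pat_rows = []
    for i in range(cfg.n_patients):
        pid = f"P{i:05d}"
        group = groups[rng.choice(3, p=cfg.group_probabilities)]
        site = f"site{rng.integers(cfg.n_sites)}"
        batch = BATCHES[rng.choice(4, p=(0.3, 0.3, 0.2, 0.2))]
        azithro: set[int] = set()
        other: dict[str, frozenset[int]] = {}
        if group == "Azithro":
            start, dur = _draw_course(rng)
            azithro = set(range(start, start + dur))
            # ceftriaxone and vancomycin dominate co-administration
            for drug, prob in zip(CO_ANTIBIOTICS, (0.194, 0.772, 0.08, 0.07, 0.04, 0.03)):
                if rng.random() < prob:
                    s2, d2 = _draw_course(rng)
                    other[drug] = frozenset(range(s2, s2 + d2))
        elif group == "Other-Abx":
            n_drugs = 1 + int(rng.random() < 0.35)
            drugs = rng.choice(
                len(CO_ANTIBIOTICS),
                size=n_drugs,
                replace=False,
                p=(0.22, 0.42, 0.10, 0.12, 0.06, 0.08),
            )
            for di in drugs:
                s2, d2 = _draw_course(rng)
                other[CO_ANTIBIOTICS[di]] = frozenset(range(s2, s2 + d2))
        exposures[pid] = PatientExposure(
            patient_id=pid,
            azithro_days=frozenset(azithro),
            other_abx_days=other,
            complete_dates=bool(rng.random() >= cfg.incomplete_dates_rate),
            age_quintile=int(rng.integers(1, 6)),
            sex=("F", "M")[int(rng.integers(2))],
            trajectory_group=int(rng.choice(5, p=(0.3, 0.25, 0.2, 0.15, 0.1)) + 1),
            steroids_ever=bool(rng.random() < 0.5),
            site_id=site,
        )
        pat_rows.append((pid, site, batch))
        for v, day in enumerate(cfg.sampling_days):
            if v > 0 and rng.random() > cfg.visit_retention:
                continue
            total = int(
                max(rng.normal(cfg.total_reads_target, cfg.total_reads_noise_sd), 5e5)
            )
            meta_rows.append(
                {
                    "sample_id": f"{pid}_d{day:02d}",
                    "patient_id": pid,
                    "site_id": site,
                    "batch": batch,
                    "day_from_admission": day,
                    "total_reads": total,
                    "is_negative_control": False,
                }
            )
    # 26 water controls spread over the four batches
    per_batch = np.full(4, cfg.n_negative_controls // 4)
    per_batch[: cfg.n_negative_controls % 4] += 1
    ctrl_i = 0
    for b, nb in zip(BATCHES, per_batch):
        for _ in range(nb):
            total = int(
                max(rng.normal(cfg.total_reads_target, cfg.total_reads_noise_sd), 5e5)
            )
            meta_rows.append(
                {
                    "sample_id": f"NC{ctrl_i:03d}",
                    "patient_id": "",
                    "site_id": "",
                    "batch": b,
                    "day_from_admission": 0,
                    "total_reads": total,
                    "is_negative_control": True,
                }
            )
            ctrl_i += 1
    meta = pd.DataFrame(meta_rows)
    cov = pd.DataFrame(
        {
            "patient_id": [p for p, _, _ in pat_rows],
            "age_quintile": [exposures[p].age_quintile for p, _, _ in pat_rows],
            "sex": [exposures[p].sex for p, _, _ in pat_rows],
            "trajectory_group": [exposures[p].trajectory_group for p, _, _ in pat_rows],
            "steroids_ever": [exposures[p].steroids_ever for p, _, _ in pat_rows],
        }
    )
    meta = meta.merge(cov, on="patient_id", how="left")
    return meta, exposures


def _contamination_means(rng: np.random.Generator, cfg: SimConfig, features: list[str]):
    """Per (batch, feature) contamination mean counts, drawn log-normally."""
    mus = {}
    for b in BATCHES:
        for f in features:
            # some cells are clean: contamination is batch-specific
            if rng.random() < 0.25:
                mus[(b, f)] = 0.0
            else:
                mus[(b, f)] = float(
                    np.exp(rng.normal(cfg.contamination_log_mu, cfg.contamination_log_sd))
                )
    return mus


def _nb_draw(rng, mu, theta, size=None):
    if mu <= 0:
        return np.zeros(size or 1, dtype=int) if size else 0
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p, size=size)


def simulate_reports(cfg: SimConfig, meta: pd.DataFrame, exposures: dict):
    """Generate taxon and ARG report records for all samples and controls."""
    rng = np.random.default_rng(cfg.seed + 1)
    contam_taxa = [f"c_{g}" for g in CONTAMINANT_GENERA]
    taxa_mu = _contamination_means(rng, cfg, contam_taxa)
    arg_mu = _contamination_means(rng, cfg, CONTAMINANT_ARGS)

    # per-patient, per-genus AR(1) log-abundance trajectories
    patients = sorted({p for p in meta["patient_id"] if p})
    genus_base: dict[str, np.ndarray] = {}
    for pid in patients:
        genus_base[pid] = rng.normal(0.0, cfg.taxon_log_sd, size=len(GENUS_TABLE))
    # every patient carries every gene at some latent expression level:
    # overtly carried genes sit well above the detection limit, the rest at a
    # sub-detection level that exposure-driven induction can push above it
    gene_base: dict[str, dict[str, float]] = {}
    for pid in patients:
        levels = {}
        for gene, (prob, log_mean) in GENE_PROFILE.items():
            if rng.random() < prob:
                levels[gene] = float(rng.normal(log_mean, 1.0))
            else:
                levels[gene] = float(rng.normal(np.log(0.03), 0.8))
        gene_base[pid] = levels

    taxon_records: list[TaxonRecord] = []
    arg_records: list[ArgRecord] = []
    state: dict[str, np.ndarray] = {}

    bio = meta[~meta["is_negative_control"]].sort_values(
        ["patient_id", "day_from_admission"]
    )
    for row in bio.itertuples(index=False):
        pid = row.patient_id
        exp = exposures[pid]
        day = int(row.day_from_admission)
        e_azi = min(exp.cumulative_exposure(day, exp.azithro_days), cfg.effect_cap_days)
        z_prev = state.get(pid)
        eps = rng.normal(0.0, cfg.taxon_log_sd, size=len(GENUS_TABLE))
        z = (
            eps
            if z_prev is None
            else cfg.ar1_rho * z_prev + np.sqrt(1 - cfg.ar1_rho**2) * eps
        )
        state[pid] = z

        # genuine taxa
        for gi, (genus, log10_mean, kingdom) in enumerate(GENUS_TABLE):
            lam = 10.0**log10_mean * np.exp(genus_base[pid][gi] + z[gi])
            if kingdom == "bacteria":
                lam *= cfg.bacterial_effect**e_azi
            reads = int(rng.poisson(lam))
            if reads == 0:
                continue
            taxon_records.append(
                _taxon_record(rng, cfg, row.sample_id, genus, kingdom, reads)
            )
        # contaminant taxa
        for genus in contam_taxa:
            reads = int(_nb_draw(rng, taxa_mu[(row.batch, genus)], cfg.contamination_theta))
            if reads:
                taxon_records.append(
                    _taxon_record(rng, cfg, row.sample_id, genus, "bacteria", reads)
                )
        # genuine ARGs, with the MLS exposure effect; a gene is detected only
        # when its depth yields at least one read over the gene's length.
        # Expression co-varies with the host genus's current abundance.
        genus_index = {g: i for i, (g, _, _) in enumerate(GENUS_TABLE)}
        for gene, log_depth in sorted(gene_base[pid].items()):
            drug_class, length = GENE_TABLE[gene]
            hi = genus_index[GENE_HOST[gene]]
            host_dev = genus_base[pid][hi] + z[hi]
            depth = float(np.exp(log_depth + 0.8 * host_dev + rng.normal(0.0, 0.4)))
            if drug_class == "MLS":
                depth *= cfg.azithro_effect**e_azi
            reads = int(round(depth * length / cfg.read_length))
            if reads < 1:
                continue
            arg_records.append(
                _arg_record(
                    rng, cfg, row.sample_id, gene, drug_class, length, depth, reads=reads
                )
            )
        # contaminant ARGs
        for gene in CONTAMINANT_ARGS:
            reads = int(_nb_draw(rng, arg_mu[(row.batch, gene)], cfg.contamination_theta))
            if reads:
                depth = reads * cfg.read_length / 1000.0
                arg_records.append(
                    _arg_record(
                        rng, cfg, row.sample_id, gene,
                        CONTAMINANT_ARG_CLASSES[gene], 1000, depth, reads=reads,
                    )
                )

    # water controls: contaminants only, never genuine biology
    for row in meta[meta["is_negative_control"]].itertuples(index=False):
        for genus in contam_taxa:
            reads = int(_nb_draw(rng, taxa_mu[(row.batch, genus)], cfg.contamination_theta))
            if reads:
                taxon_records.append(
                    _taxon_record(rng, cfg, row.sample_id, genus, "bacteria", reads, clean=True)
                )
        for gene in CONTAMINANT_ARGS:
            reads = int(_nb_draw(rng, arg_mu[(row.batch, gene)], cfg.contamination_theta))
            if reads:
                depth = reads * cfg.read_length / 1000.0
                arg_records.append(
                    _arg_record(
                        rng, cfg, row.sample_id, gene,
                        CONTAMINANT_ARG_CLASSES[gene], 1000, depth, reads=reads, clean=True,
                    )
                )
    return taxon_records, arg_records


def _taxon_record(rng, cfg, sample_id, genus, kingdom, reads, clean=False):
    nt = max(int(round(reads * rng.uniform(0.8, 1.0))), 10)
    nr = max(int(rng.poisson(max(reads * 0.05, 1.0))), 1)
    length = float(rng.uniform(60, 160))
    if not clean and rng.random() < cfg.qc_fail_fraction:
        rule = rng.integers(3)
        if rule == 0:
            nt = int(rng.integers(0, 10))
        elif rule == 1:
            nr = 0
        else:
            length = float(rng.uniform(20, 49))
    return TaxonRecord(
        sample_id=sample_id,
        taxon_id=f"t_{genus}",
        name=genus,
        rank="genus",
        kingdom=kingdom,
        reads=reads,
        nt_alignments=nt,
        nr_alignments=nr,
        nt_alignment_length=length,
    )


def _arg_record(rng, cfg, sample_id, gene, drug_class, length, depth, reads=None, clean=False):
    if reads is None:
        reads = max(int(round(depth * length / cfg.read_length)), 1)
    depth = max(depth, 1e-6) if reads > 0 else 0.0
    alignments = max(int(round(reads * rng.uniform(0.9, 1.1))), 1)
    coverage = float(np.clip(1.0 - np.exp(-depth * 0.8) + rng.normal(0, 0.05), 0.06, 1.0))
    if not clean and rng.random() < cfg.qc_fail_fraction:
        coverage = float(rng.uniform(0.005, 0.049))
        if rng.random() < 0.5:
            alignments = int(rng.integers(1, 11))
            reads = max(min(reads, alignments), 1)
            depth = min(depth, reads * cfg.read_length / length)
    return ArgRecord(
        sample_id=sample_id,
        gene=gene,
        drug_class=drug_class,
        reads=reads,
        alignments=alignments,
        coverage_breadth=coverage,
        mean_depth=depth,
    )


def simulate_all(cfg: SimConfig):
    """Cohort + reports in one call; returns a dict of all artifacts."""
    meta, exposures = simulate_cohort(cfg)
    taxon_records, arg_records = simulate_reports(cfg, meta, exposures)
    return {
        "meta": meta,
        "exposures": exposures,
        "taxon_records": taxon_records,
        "arg_records": arg_records,
    }


def write_dataset(cfg: SimConfig, out_dir: str | Path) -> dict:
    """Write metadata CSV, taxon/ARG report TSVs and a config-hash manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = simulate_all(cfg)
    write_sample_metadata(data["meta"], out / "metadata.csv")
    write_taxon_report(data["taxon_records"], out / "taxon_report.tsv")
    write_arg_report(data["arg_records"], out / "arg_report.tsv")
    exp_rows = []
    for pid, exp in data["exposures"].items():
        n_before = len(exp_rows)
        for d in sorted(exp.azithro_days):
            exp_rows.append((pid, "azithromycin", d, exp.complete_dates))
        for drug, days in exp.other_abx_days.items():
            for d in sorted(days):
                exp_rows.append((pid, drug, d, exp.complete_dates))
        if len(exp_rows) == n_before:  # keep antibiotic-free patients on file
            exp_rows.append((pid, "none", "", exp.complete_dates))
    pd.DataFrame(
        exp_rows, columns=["patient_id", "antibiotic", "day", "complete_dates"]
    ).to_csv(out / "exposures.csv", index=False)
    cfg_dict = asdict(cfg)
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=list).encode()
        ).hexdigest(),
        "n_samples": int(len(data["meta"])),
        "n_taxon_records": len(data["taxon_records"]),
        "n_arg_records": len(data["arg_records"]),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))
    return data
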