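"""Generator determinism, study-structure properties and the CLI chain."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from airway_resistome.cli import main as cli_main
from airway_resistome.core_data import read_arg_report, read_taxon_report
from airway_resistome.synthetic_data import (
    CONTAMINANT_ARGS,
    CONTAMINANT_GENERA,
    GENE_TABLE,
    SimConfig,
    simulate_all,
    simulate_cohort,
    write_dataset,
)


class TestDeterminism:
    def test_same_seed_identical(self, tmp_path):
        cfg = SimConfig(n_patients=15, seed=42)
        write_dataset(cfg, tmp_path / "a")
        write_dataset(cfg, tmp_path / "b")
        for name in ("metadata.csv", "taxon_report.tsv", "arg_report.tsv", "exposures.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_different_seed_differs(self):
        a = simulate_all(SimConfig(n_patients=15, seed=1))
        b = simulate_all(SimConfig(n_patients=15, seed=2))
        assert a["taxon_records"] != b["taxon_records"]


class TestCohortStructure:
    def test_degenerate_probabilities(self):
        cfg = SimConfig(
            n_patients=20, seed=0, group_probabilities=(1.0, 0.0, 0.0),
            incomplete_dates_rate=0.0,
        )
        _, exposures = simulate_cohort(cfg)
        assert all(e.azithro_days for e in exposures.values())

    def test_group_fractions_converge(self):
        cfg = SimConfig(n_patients=5000, seed=3, incomplete_dates_rate=0.0)
        _, exposures = simulate_cohort(cfg)
        n_azi = sum(1 for e in exposures.values() if e.azithro_days)
        n_other = sum(
            1 for e in exposures.values() if not e.azithro_days and e.other_abx_days
        )
        n_none = 5000 - n_azi - n_other
        for frac, p in zip(
            (n_azi / 5000, n_other / 5000, n_none / 5000), cfg.group_probabilities
        ):
            assert abs(frac - p) < 0.02

    def test_course_duration_median_two_days(self):
        cfg = SimConfig(n_patients=4000, seed=5)
        _, exposures = simulate_cohort(cfg)
        durations = [len(e.azithro_days) for e in exposures.values() if e.azithro_days]
        assert np.median(durations) == 2

    def test_ceftriaxone_most_common_co_drug(self):
        cfg = SimConfig(n_patients=2000, seed=7)
        _, exposures = simulate_cohort(cfg)
        counts: dict[str, int] = {}
        for e in exposures.values():
            if e.azithro_days:
                for drug in e.other_abx_days:
                    counts[drug] = counts.get(drug, 0) + 1
        assert max(counts, key=counts.get) == "ceftriaxone"

    def test_twenty_six_controls_across_four_batches(self):
        meta, _ = simulate_cohort(SimConfig(n_patients=10, seed=0))
        ctrl = meta[meta["is_negative_control"]]
        assert len(ctrl) == 26
        assert set(ctrl["batch"]) == {"1", "2", "3A", "3B"}
        assert ctrl["patient_id"].eq("").all()

    def test_six_sampling_timepoints(self):
        meta, _ = simulate_cohort(SimConfig(n_patients=200, seed=1))
        days = set(meta.loc[~meta["is_negative_control"], "day_from_admission"])
        assert days == {0, 4, 7, 14, 21, 28}


class TestReportStructure:
    def test_controls_contain_only_contaminants(self, small_dataset):
        meta = small_dataset["meta"]
        ctrl_ids = set(meta.loc[meta["is_negative_control"], "sample_id"])
        contam_taxa = {f"t_c_{g}" for g in CONTAMINANT_GENERA}
        for r in small_dataset["taxon_records"]:
            if r.sample_id in ctrl_ids:
                assert r.taxon_id in contam_taxa
        for r in small_dataset["arg_records"]:
            if r.sample_id in ctrl_ids:
                assert r.gene in CONTAMINANT_ARGS

    def test_effect_confined_to_mls_class(self):
        """Exposure shifts MLS DPM but leaves other genuine classes alone."""
        from airway_resistome.association_stats import pairwise_rank_test

        cfg = SimConfig(n_patients=400, seed=9, incomplete_dates_rate=0.0)
        data = simulate_all(cfg)
        meta = data["meta"].set_index("sample_id")
        exposures = data["exposures"]
        mls_sum: dict[str, float] = {}
        other_sum: dict[str, float] = {}
        for r in data["arg_records"]:
            if r.gene in CONTAMINANT_ARGS:
                continue
            dpm = r.mean_depth * 1e6 / meta.loc[r.sample_id, "total_reads"]
            bucket = mls_sum if GENE_TABLE[r.gene][0] == "MLS" else other_sum
            bucket[r.sample_id] = bucket.get(r.sample_id, 0.0) + dpm
        mls_exposed, mls_naive, other_exposed, other_naive = [], [], [], []
        for sid, row in meta[~meta["is_negative_control"]].iterrows():
            exp = exposures[row["patient_id"]]
            e = exp.cumulative_exposure(int(row["day_from_admission"]), exp.azithro_days)
            (mls_exposed if e >= 3 else mls_naive).append(mls_sum.get(sid, 0.0))
            (other_exposed if e >= 3 else other_naive).append(other_sum.get(sid, 0.0))
        assert pairwise_rank_test(mls_exposed, mls_naive) < 1e-4
        assert pairwise_rank_test(other_exposed, other_naive) > 0.01

    def test_null_effect_symmetry(self):
        """azithro_effect = 1 leaves MLS DPM distributions indistinguishable."""
        from airway_resistome.association_stats import pairwise_rank_test

        cfg = SimConfig(
            n_patients=400, seed=13, azithro_effect=1.0, incomplete_dates_rate=0.0
        )
        data = simulate_all(cfg)
        meta = data["meta"].set_index("sample_id")
        exposures = data["exposures"]
        mls_sum: dict[str, float] = {}
        for r in data["arg_records"]:
            if r.gene in CONTAMINANT_ARGS or GENE_TABLE[r.gene][0] != "MLS":
                continue
            dpm = r.mean_depth * 1e6 / meta.loc[r.sample_id, "total_reads"]
            mls_sum[r.sample_id] = mls_sum.get(r.sample_id, 0.0) + dpm
        exposed, naive = [], []
        for sid, row in meta[~meta["is_negative_control"]].iterrows():
            exp = exposures[row["patient_id"]]
            e = exp.cumulative_exposure(int(row["day_from_admission"]), exp.azithro_days)
            (exposed if e >= 3 else naive).append(mls_sum.get(sid, 0.0))
        assert pairwise_rank_test(exposed, naive) > 0.01

    def test_contaminant_cell_means_converge(self):
        """Control-sample means estimate the injected batch:feature means."""
        from airway_resistome.synthetic_data import _contamination_means

        cfg = SimConfig(n_patients=1, n_negative_controls=400, seed=21)
        meta, exposures = simulate_cohort(cfg)
        rng = np.random.default_rng(cfg.seed + 1)
        contam_taxa = [f"c_{g}" for g in CONTAMINANT_GENERA]
        taxa_mu = _contamination_means(rng, cfg, contam_taxa)
        from airway_resistome.synthetic_data import simulate_reports

        taxon_records, _ = simulate_reports(cfg, meta, exposures)
        ctrl_ids = set(meta.loc[meta["is_negative_control"], "sample_id"])
        sums: dict[str, float] = {g: 0.0 for g in contam_taxa}
        for r in taxon_records:
            if r.sample_id in ctrl_ids:
                sums[r.taxon_id[2:]] += r.reads
        by_batch = meta[meta["is_negative_control"]].groupby("batch").size()
        for genus in contam_taxa:
            expected = sum(
                taxa_mu[(b, genus)] * n for b, n in by_batch.items()
            ) / len(ctrl_ids)
            if expected > 1:
                observed = sums[genus] / len(ctrl_ids)
                assert observed == pytest.approx(expected, rel=0.35)


def test_cli_chain_smoke(tmp_path):
    """simulate -> decontam -> qc-filter -> cohort -> diversity -> resistome."""
    runner = CliRunner()
    data_dir = tmp_path / "data"
    res = runner.invoke(
        cli_main,
        ["simulate", "--seed", "1", "--n-patients", "12", "--out", str(data_dir)],
    )
    assert res.exit_code == 0, res.output
    assert read_taxon_report(data_dir / "taxon_report.tsv")
    assert read_arg_report(data_dir / "arg_report.tsv")

    dec_dir = tmp_path / "decontam"
    res = runner.invoke(
        cli_main,
        [
            "decontam",
            "--taxa", str(data_dir / "taxon_report.tsv"),
            "--args", str(data_dir / "arg_report.tsv"),
            "--meta", str(data_dir / "metadata.csv"),
            "--out", str(dec_dir),
        ],
    )
    assert res.exit_code == 0, res.output

    filt_dir = tmp_path / "filtered"
    res = runner.invoke(
        cli_main,
        [
            "qc-filter",
            "--taxa", str(dec_dir / "taxa_decontaminated.tsv"),
            "--args", str(dec_dir / "args_decontaminated.tsv"),
            "--meta", str(data_dir / "metadata.csv"),
            "--out", str(filt_dir),
        ],
    )
    assert res.exit_code == 0, res.output

    res = runner.invoke(
        cli_main,
        [
            "cohort",
            "--meta", str(data_dir / "metadata.csv"),
            "--exposures", str(data_dir / "exposures.csv"),
            "--window", "early",
            "--seed", "1",
            "--out", str(tmp_path / "design.csv"),
        ],
    )
    assert res.exit_code == 0, res.output

    res = runner.invoke(
        cli_main,
        [
            "diversity",
            "--taxa", str(filt_dir / "taxa_filtered.tsv"),
            "--meta", str(data_dir / "metadata.csv"),
            "--metric", "shannon",
            "--out", str(tmp_path / "alpha.csv"),
        ],
    )
    assert res.exit_code == 0, res.output

    res = runner.invoke(
        cli_main,
        [
            "resistome",
            "--args", str(filt_dir / "args_filtered.tsv"),
            "--meta", str(data_dir / "metadata.csv"),
            "--out", str(tmp_path / "profiles.csv"),
        ],
    )
    assert res.exit_code == 0, res.output
    profiles = pd.read_csv(tmp_path / "profiles.csv")
    assert {"mls_richness", "mls_proportion"} <= set(profiles.columns)
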