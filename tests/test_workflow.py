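from pathlib import Path

import pandas as pd
import pytest
from click.testing import CliRunner

from librank import consensus
from librank.chemio import Library, generate_fixture_library, write_library
from librank.cli import main as cli_main
from librank.workflow import WorkflowConfig, run_workflow


@pytest.fixture(scope="module")
def good_and_bad():
    good, _ = generate_fixture_library({"clean": 24}, seed=100, name="good")
    bad, _ = generate_fixture_library(
        {"clean": 12, "alert-matching": 5, "mixture": 3, "duplicate-pair": 2},
        seed=101,
        name="bad",
    )
    return good, bad


class TestRunWorkflow:
    def test_dominating_library_ranks_first(self, good_and_bad):
        good, bad = good_and_bad
        res = run_workflow(WorkflowConfig(seed=1), libraries=[good, bad])
        final = dict(zip(res.consensus["library"], res.consensus["final_rank"]))
        assert res.best_library == "good"
        assert final["good"] == 1

    def test_identical_libraries_tie(self, good_and_bad):
        good, _ = good_and_bad
        twin = Library("twin", list(good.records), provenance=good.provenance)
        res = run_workflow(WorkflowConfig(seed=1), libraries=[good, twin])
        final = dict(zip(res.consensus["library"], res.consensus["final_rank"]))
        assert final == {"good": 1, "twin": 1}

    def test_rerun_byte_identical(self, good_and_bad, tmp_path):
        good, bad = good_and_bad
        for d in ("a", "b"):
            run_workflow(WorkflowConfig(seed=7), libraries=[good, bad], out_dir=tmp_path / d)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name

    def test_optional_blocks_skipped_without_inputs(self, good_and_bad):
        good, bad = good_and_bad
        res = run_workflow(WorkflowConfig(seed=1), libraries=[good, bad])
        assert res.similarity is None and res.overlap is None
        assert set(res.consensus.columns) >= {"admet_rank", "promiscuity_rank", "diversity_rank"}

    def test_consensus_reproducible_from_emitted_csvs(self, good_and_bad, tmp_path):
        """No hidden state: the consensus recomputed offline from the report
        CSVs equals the consensus column the workflow wrote."""
        good, bad = good_and_bad
        res = run_workflow(WorkflowConfig(seed=2), libraries=[good, bad], out_dir=tmp_path)
        admet = pd.read_csv(tmp_path / "admet.csv")
        alerts = pd.read_csv(tmp_path / "alerts.csv")
        diversity = pd.read_csv(tmp_path / "diversity.csv")

        def table(df, col):
            return consensus.CriterionTable(col, dict(zip(df["library"], df[col])))

        blocks = [
            consensus.block_consensus(
                [table(admet, c) for c in ["fail_lipinski_pct", "fail_veber_pct", "logbb_below_zero_pct"]]
            ).block_ranks,
            consensus.block_consensus([table(alerts, "promiscuous_pct")]).block_ranks,
            consensus.block_consensus(
                [table(diversity, c) for c in diversity.columns if c.startswith("mean_similarity_")]
            ).block_ranks,
        ]
        _, final = consensus.total_consensus(blocks)
        written = dict(zip(res.consensus["library"], res.consensus["final_rank"]))
        assert final == written

    def test_similarity_block_included_with_actives(self, good_and_bad):
        good, bad = good_and_bad
        ref = good.records[0].smiles
        cfg = WorkflowConfig(seed=1, reference_actives=[ref], similarity_dialects=["ECFP_4"])
        res = run_workflow(cfg, libraries=[good, bad])
        assert res.similarity is not None
        assert "similarity_rank" in res.consensus.columns


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = WorkflowConfig(libraries=[{"name": "a", "path": "a.smi"}], seed=9)
        cfg.to_yaml(tmp_path / "c.yml")
        back = WorkflowConfig.from_yaml(tmp_path / "c.yml")
        assert back == cfg

    def test_unknown_key_rejected(self, tmp_path):
        (tmp_path / "c.yml").write_text("librariez: []\n")
        with pytest.raises(Exception, match="librariez"):
            WorkflowConfig.from_yaml(tmp_path / "c.yml")

    def test_defaults_match_selected_descriptors(self):
        cfg = WorkflowConfig()
        assert cfg.diversity_dialects == ["ECFP_2", "MDL_keys", "PHRFC_2"]
        assert cfg.similarity_dialects == ["ECFP_4", "ECFP_6", "MDL_keys", "PHFP_3"]
        assert cfg.overlap_threshold == 0.7


class TestCLI:
    def write_libs(self, tmp_path):
        a, _ = generate_fixture_library({"clean": 10}, seed=1, name="liba")
        b, _ = generate_fixture_library({"clean": 8, "alert-matching": 2}, seed=2, name="libb")
        write_library(a, tmp_path / "a.smi")
        write_library(b, tmp_path / "b.smi")
        return tmp_path / "a.smi", tmp_path / "b.smi"

    def test_no_arguments_usage_exit(self):
        result = CliRunner().invoke(cli_main, [])
        assert result.exit_code == 2

    def test_unknown_flag_usage_exit(self):
        result = CliRunner().invoke(cli_main, ["curate", "--bogus"])
        assert result.exit_code == 2

    def test_rank_single_library_data_error(self, tmp_path):
        a, _ = self.write_libs(tmp_path)
        (tmp_path / "c.yml").write_text(f"libraries:\n  - {{name: a, path: {a}}}\n")
        result = CliRunner().invoke(cli_main, ["rank", "--config", str(tmp_path / "c.yml"), "--out", str(tmp_path / "o")])
        assert result.exit_code == 1

    def test_run_writes_report_bundle(self, tmp_path):
        a, b = self.write_libs(tmp_path)
        (tmp_path / "c.yml").write_text(
            f"libraries:\n  - {{name: a, path: {a}}}\n  - {{name: b, path: {b}}}\nseed: 3\n"
        )
        out = tmp_path / "out"
        result = CliRunner().invoke(cli_main, ["run", "--config", str(tmp_path / "c.yml"), "--out", str(out)])
        assert result.exit_code == 0, result.output
        for name in ["curation.csv", "admet.csv", "alerts.csv", "diversity.csv", "consensus.csv", "summary.txt"]:
            assert (out / name).exists()
        assert "best library" in result.output

    def test_curate_command(self, tmp_path):
        a, _ = self.write_libs(tmp_path)
        out = tmp_path / "cur"
        result = CliRunner().invoke(cli_main, ["curate", str(a), "--out", str(out)])
        assert result.exit_code == 0
        assert (out / "curation.csv").exists()

    def test_benchmark_descriptors_diversity(self, tmp_path):
        from librank.chemio import generate_labeled_records

        records, labels = generate_labeled_records(5, 6, seed=3)
        rows = [
            {"record_id": r.record_id, "smiles": r.smiles, "label": lab}
            for r, lab in zip(records, labels)
        ]
        pd.DataFrame(rows).to_csv(tmp_path / "labeled.csv", index=False)
        out = tmp_path / "bench.csv"
        result = CliRunner().invoke(
            cli_main,
            ["benchmark-descriptors", "--labeled", str(tmp_path / "labeled.csv"),
             "--mode", "diversity", "--dialect", "ECFP_2", "--dialect", "MDL_keys",
             "--sizes", "5,10", "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        bench = pd.read_csv(out)
        assert set(bench["dialect"]) == {"ECFP_2", "MDL_keys"}
        assert bench["mean_coverage_pct"].is_monotonic_decreasing

    def test_build_qsar_command(self, tmp_path):
        from librank.admet import LogBBModel
        from librank.gfa import make_planted_dataset

        data = make_planted_dataset(150, 6, {"x1": 2.0, "x4": -1.5}, noise_sd=0.1, seed=9)
        df = data.X.copy()
        df["logbb"] = data.y
        df.to_csv(tmp_path / "d.csv", index=False)
        out = tmp_path / "model.txt"
        result = CliRunner().invoke(
            cli_main,
            ["build-qsar", "--data", str(tmp_path / "d.csv"), "--response", "logbb",
             "--out", str(out), "--scramble-repeats", "2", "--seed", "4"],
        )
        assert result.exit_code == 0, result.output
        model = LogBBModel.load(out)
        names = {n for n, _ in model.linear_terms} | {n for n, *_ in model.spline_terms}
        assert {"x1", "x4"} <= names
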