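"""The model/results front end, the run-directory pipeline and the CLI."""

import json
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from crossclust import SubtypeConcordance, SyntheticConfig
from crossclust.cli import main as cli_main
from crossclust.pipeline import PipelineConfig, render_reports, run_pipeline, write_synthetic_inputs

SMALL = SyntheticConfig(
    n_datasets=2, samples_per_dataset=50, n_genes=300, k_true=2,
    signature_size=30, effect_size=2.0, seed=17,
)


@pytest.fixture(scope="module")
def fitted():
    from crossclust import generate_multistudy

    datasets, truth = generate_multistudy(SMALL)
    model = SubtypeConcordance(
        list(datasets), n_per_dataset=60, k_list=(2,), nmf_inits=4,
        reference="study_1",
        reference_label_map={1: "mesenchymal-like", 2: "proliferative-like"},
    )
    return model, model.fit(seed=3), truth


class TestModelResults:
    def test_fit_produces_assignments_and_concordance(self, fitted):
        model, results, _ = fitted
        assert set(results.assignments) == {
            (name, alg, 2)
            for name in ("study_1", "study_2")
            for alg in ("kmeans", "nmf")
        }
        assert set(results.concordance) == {("kmeans", 2), ("nmf", 2)}

    def test_reference_labels_cover_every_cluster(self, fitted):
        _, results, _ = fitted
        labels = results.concordance[("kmeans", 2)].reference_labels
        assert set(labels) == {
            (name, c) for name in ("study_1", "study_2") for c in (1, 2)
        }
        assert set(labels.values()) == {"mesenchymal-like", "proliferative-like"}

    def test_summary_mentions_datasets_and_ranges(self, fitted):
        _, results, _ = fitted
        text = results.summary()
        assert "study_1" in text and "study_2" in text
        assert "kmeans, k = 2" in text and "nmf, k = 2" in text
        assert "r = " in text

    def test_matched_range_table_bounds(self, fitted):
        _, results, _ = fitted
        table = results.matched_range_table("kmeans", 2)
        assert ((table["r_min"] >= -1) & (table["r_max"] <= 1)).all()
        assert (table["r_min"] <= table["r_max"]).all()

    def test_refit_is_deterministic(self, fitted):
        model, results, _ = fitted
        again = model.fit(seed=3)
        for key, asg in results.assignments.items():
            pd.testing.assert_series_equal(asg.labels, again.assignments[key].labels)

    def test_heatmap_renders(self, fitted, tmp_path):
        _, results, _ = fitted
        target = tmp_path / "heat.png"
        results.plot_correlation_heatmaps("kmeans", 2, target)
        assert target.stat().st_size > 0


@pytest.fixture(scope="module")
def run_dir(tmp_path_factory):
    root = tmp_path_factory.mktemp("pipe")
    mapping = write_synthetic_inputs(SMALL, root / "inputs")
    config = PipelineConfig(
        datasets=mapping,
        output_dir=str(root / "run"),
        keep_histologies=["serous"],
        keep_grades=["high"],
        n_per_dataset=60,
        k_list=[2],
        k_range=[2, 3],
        nmf_inits=4,
        consensus_runs=4,
        null_replicates=1,
        seed=5,
    )
    return config, run_pipeline(config)


class TestPipeline:
    def test_artifact_inventory(self, run_dir):
        config, out = run_dir
        expected = [
            "ingest/report.json",
            "ingest/study_1.tsv",
            "selection/gene_set.json",
            "clustering/assignments.tsv",
            "tscores/study_1.kmeans.k2.tsv",
            "tscores/study_2.nmf.k2.tsv",
            "concordance/kmeans.k2.ranges.tsv",
            "concordance/kmeans.k2.matching.json",
            "crosstabs/study_1.kmeans.k2.tsv",
            "profiles/cophenetic.json",
            "null/summary.json",
            "manifest.json",
        ]
        for rel in expected:
            assert (out / rel).exists(), rel

    def test_manifest_records_config_hash_and_seed(self, run_dir):
        config, out = run_dir
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["config_hash"] == config.config_hash()
        assert manifest["seed"] == 5

    def test_rerun_is_byte_identical(self, run_dir, tmp_path):
        config, out = run_dir
        config2 = replace(config, output_dir=str(tmp_path / "run2"))
        out2 = run_pipeline(config2)
        for rel in (
            "clustering/assignments.tsv",
            "tscores/study_1.kmeans.k2.tsv",
            "concordance/kmeans.k2.ranges.tsv",
        ):
            assert (out / rel).read_bytes() == (out2 / rel).read_bytes(), rel

    def test_reports_render_figures(self, run_dir):
        _, out = run_dir
        figures = render_reports(out)
        assert any("correlations" in f.name for f in figures)
        assert any("cophenetic" in f.name for f in figures)
        assert any("null" in f.name for f in figures)


class TestCLI:
    def test_simulate_then_run_all(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "sim"
        res = runner.invoke(
            cli_main,
            ["simulate", "--out", str(out), "--seed", "2", "--n-datasets", "2",
             "--samples", "40", "--genes", "200", "--k-true", "2"],
        )
        assert res.exit_code == 0, res.output
        cfg_path = out / "config.yaml"
        cfg = yaml.safe_load(cfg_path.read_text())
        cfg.update(
            n_per_dataset=40, k_list=[2], k_range=[2], nmf_inits=3,
            consensus_runs=3, run_profiles=False,
        )
        cfg_path.write_text(yaml.safe_dump(cfg))
        res = runner.invoke(cli_main, ["run-all", "--config", str(cfg_path)])
        assert res.exit_code == 0, res.output
        assert (out / "run" / "manifest.json").exists()

    def test_stagewise_ingest_select(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "sim"
        runner.invoke(
            cli_main,
            ["simulate", "--out", str(out), "--seed", "2", "--n-datasets", "2",
             "--samples", "40", "--genes", "200", "--k-true", "2"],
        )
        cfg_path = out / "config.yaml"
        cfg = yaml.safe_load(cfg_path.read_text())
        cfg.update(n_per_dataset=40)
        cfg_path.write_text(yaml.safe_dump(cfg))
        assert runner.invoke(cli_main, ["ingest", "--config", str(cfg_path)]).exit_code == 0
        res = runner.invoke(cli_main, ["select", "--config", str(cfg_path)])
        assert res.exit_code == 0
        assert "union gene set" in res.output

    def test_bad_config_is_a_usage_error(self, tmp_path):
        runner = CliRunner()
        bad = tmp_path / "bad.yaml"
        bad.write_text("not_a_key: 1\n")
        res = runner.invoke(cli_main, ["run-all", "--config", str(bad)])
        assert res.exit_code == 2

    def test_missing_stage_inputs_is_a_data_error(self, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "c.yaml"
        cfg.write_text(
            yaml.safe_dump(
                {"datasets": {"x": {"matrix": "missing.tsv"}},
                 "output_dir": str(tmp_path / "run")}
            )
        )
        res = runner.invoke(cli_main, ["select", "--config", str(cfg)])
        assert res.exit_code == 1
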