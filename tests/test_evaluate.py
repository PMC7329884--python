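import itertools
import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import geopheno as gp
from geopheno.cli import main as cli_main

from oracles import pair_counting_ari, partition_to_labels, set_partitions

MIN = 60_000
HOUR = 60 * MIN


class TestAdjustedRandIndex:
    def test_identical_partitions(self):
        labels = np.array([0, 0, 1, 1, 2, 2, 3, 3, 4, 4])
        assert gp.adjusted_rand_index(labels, labels) == pytest.approx(1.0)

    def test_pairs_vs_one_block_coarsening_is_zero(self):
        assert gp.adjusted_rand_index([0, 0, 1, 1], [0, 0, 0, 0]) == pytest.approx(0.0)

    def test_exhaustive_partitions_of_four_match_pair_counting(self):
        items = list(range(4))
        partitions = [partition_to_labels(p, items) for p in set_partitions(items)]
        for a, b in itertools.product(partitions, repeat=2):
            assert gp.adjusted_rand_index(a, b) == pytest.approx(
                pair_counting_ari(a, b), abs=1e-12
            )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_partitions_of_eight_match_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, 8)
        b = rng.integers(0, 3, 8)
        assert gp.adjusted_rand_index(a, b) == pytest.approx(
            pair_counting_ari(a, b), abs=1e-12
        )

    def test_independent_random_partitions_near_zero(self):
        rng = np.random.default_rng(6)
        vals = [
            gp.adjusted_rand_index(rng.integers(0, 5, 200), rng.integers(0, 5, 200))
            for _ in range(30)
        ]
        assert abs(np.mean(vals)) < 0.02

    def test_mismatched_items_rejected(self):
        with pytest.raises(ValueError):
            gp.adjusted_rand_index([0, 1], [0, 1, 2])


class TestEpisodeStateAccuracy:
    def truth(self):
        return pd.DataFrame(
            {
                "kind": ["dwell", "travel", "dwell", "travel"],
                "place_id": [0, -1, 1, -1],
                "start_ms": [0, 4 * HOUR, 5 * HOUR, 9 * HOUR],
                "end_ms": [4 * HOUR, 5 * HOUR, 9 * HOUR, 10 * HOUR],
            }
        )

    def sps(self, intervals):
        return pd.DataFrame(
            {
                "arrival_ms": [a for a, _ in intervals],
                "departure_ms": [b for _, b in intervals],
            }
        )

    def test_perfect_detection(self):
        sps = self.sps([(0, 4 * HOUR), (5 * HOUR, 9 * HOUR)])
        assert gp.episode_state_accuracy(self.truth(), sps) == 100.0

    def test_half_overlap_rule(self):
        # first dwell covered only 25% -> missed; second covered 75% -> hit;
        # travel episodes untouched -> correct: 3 of 4
        sps = self.sps([(0, 1 * HOUR), (5 * HOUR, 8 * HOUR)])
        assert gp.episode_state_accuracy(self.truth(), sps) == 75.0

    def test_staypoint_swallowing_travel_costs_the_travel_episode(self):
        sps = self.sps([(0, 10 * HOUR)])
        # both dwells covered, both travels >= 50% covered -> 2 of 4
        assert gp.episode_state_accuracy(self.truth(), sps) == 50.0

    def test_no_staypoints_scores_travel_only(self):
        assert gp.episode_state_accuracy(self.truth(), self.sps([])) == 50.0


class TestCohortReport:
    def test_mean_drops_by_subject_deficit(self):
        report = gp.EvaluationReport(
            staypoint_accuracy_pct={f"s{i}": 100.0 for i in range(5)}
        )
        assert report.mean_staypoint_accuracy == 100.0
        report.staypoint_accuracy_pct["s4"] = 80.0
        assert report.mean_staypoint_accuracy == pytest.approx(100.0 - 20.0 / 5)

    def test_simulated_cohort_report_bounds(self, sim_result):
        result, truth = sim_result
        scores = gp.evaluate_subject(result, truth)
        assert 0.0 <= scores["staypoint_accuracy_pct"] <= 100.0
        assert 0.0 <= scores["clustering_accuracy_pct"] <= 100.0
        assert -1.0 <= scores["ari"] <= 1.0
        assert scores["home_correct"] is True


class TestRunPipeline:
    def write_cohort(self, tmp_path, n=2, seed=9):
        paths = []
        for trace, _ in gp.simulate_cohort(n, seed):
            p = tmp_path / f"{trace.subject_id}.csv"
            gp.write_trace(trace, p)
            paths.append(p)
        return paths

    def test_outputs_and_manifest(self, tmp_path):
        paths = self.write_cohort(tmp_path)
        out = gp.run_pipeline(gp.PipelineConfig(), paths, tmp_path / "run")
        assert out["staypoints"].exists()
        assert out["phenotypes"].exists()
        manifest = json.loads(out["manifest"].read_text())
        assert manifest["n_subjects"] == 2
        assert set(manifest["inputs"]) == {p.name for p in paths}
        assert manifest["config"]["theta_d_m"] == 350.0

    def test_rerun_is_byte_identical(self, tmp_path):
        paths = self.write_cohort(tmp_path)
        gp.run_pipeline(gp.PipelineConfig(), paths, tmp_path / "a")
        gp.run_pipeline(gp.PipelineConfig(), paths, tmp_path / "b")
        for name in ("staypoints.csv", "clusters.csv", "phenotypes.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_bad_subject_skipped(self, tmp_path):
        paths = self.write_cohort(tmp_path, n=1)
        bad = tmp_path / "bad.csv"
        bad.write_text("not,a,trace\n1,2,3\n")
        out = gp.run_pipeline(gp.PipelineConfig(), paths + [bad], tmp_path / "run")
        assert len(out["failures"]) == 1
        assert len(out["results"]) == 1


class TestCli:
    def test_config_error_exit_code_2(self, tmp_path):
        cfg = tmp_path / "bad.yaml"
        cfg.write_text("not_a_real_option: 5\n")
        trace = tmp_path / "t.csv"
        gp.write_trace(gp.simulate_subject(1, gp.SimConfig(n_days=2))[0], trace)
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["detect", "--config", str(cfg), "--in", str(trace), "--out",
             str(tmp_path / "o.csv")],
        )
        assert res.exit_code == 2

    def test_detect_and_phenotype_roundtrip(self, tmp_path):
        trace_path = tmp_path / "t.csv"
        gp.write_trace(gp.simulate_subject(4, gp.SimConfig(n_days=4))[0], trace_path)
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["detect", "--in", str(trace_path), "--out", str(tmp_path / "sp.csv")],
        )
        assert res.exit_code == 0, res.output
        sps = pd.read_csv(tmp_path / "sp.csv")
        assert len(sps) > 0
        res = runner.invoke(
            cli_main,
            ["phenotype", "--in", str(trace_path), "--out", str(tmp_path / "ph.csv")],
        )
        assert res.exit_code == 0, res.output
        ph = pd.read_csv(tmp_path / "ph.csv")
        assert "home_stay_pct" in ph.columns

    def test_simulate_then_evaluate(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["simulate", "--seed", "3", "--n-subjects", "2", "--out-dir",
             str(tmp_path / "sim")],
        )
        assert res.exit_code == 0, res.output
        res = runner.invoke(
            cli_main,
            ["evaluate", "--traces", str(tmp_path / "sim"), "--out",
             str(tmp_path / "report.json")],
        )
        assert res.exit_code == 0, res.output
        report = json.loads((tmp_path / "report.json").read_text())
        assert report["staypoint_accuracy"]["mean"] > 80.0
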