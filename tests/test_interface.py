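"""File I/O, the end-to-end pipeline, and the command-line interface."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from muncut.cli import main
from muncut.data import Partition
from muncut.evaluate import accuracy, adjacency
from muncut.io import (
    LayerParseError,
    read_layer_matrix,
    read_partition,
    write_layer_matrix,
    write_partition,
)
from muncut.pipeline import fit_muncut, muncut
from tests.conftest import make_channel_data


class TestIO:
    def test_round_trip_lossless(self, tmp_path, rng):
        M = rng.normal(size=(5, 3))
        names = ["a", "b", "c"]
        path = tmp_path / "layer.csv"
        write_layer_matrix(path, M, names)
        M2, names2 = read_layer_matrix(path)
        np.testing.assert_array_equal(M, M2)
        assert names2 == names

    def test_well_formed_tab_separated(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("g1\tg2\n1.0\t2.0\n3.0\t4.0\n5.5\t6.5\n")
        M, names = read_layer_matrix(path)
        assert M.shape == (3, 2)
        assert names == ["g1", "g2"]

    def test_missing_value_reported_with_location(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("g1,g2\n1.0,2.0\n3.0,NA\n")
        with pytest.raises(LayerParseError, match=r"row 2.*'g2'"):
            read_layer_matrix(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("")
        with pytest.raises(LayerParseError):
            read_layer_matrix(path)

    def test_partition_round_trip(self, tmp_path):
        part = Partition(np.array([0, 1, 1, 0, 2, 2]),
                         np.array(["P", "P", "G", "G", "C", "C"]), K=3)
        path = tmp_path / "part.csv"
        write_partition(path, part, [f"v{i}" for i in range(6)])
        back, names = read_partition(path)
        np.testing.assert_array_equal(back.labels, part.labels)
        np.testing.assert_array_equal(back.layer_of, part.layer_of)
        assert names == [f"v{i}" for i in range(6)]


@pytest.fixture(scope="module")
def channel_setup():
    data = make_channel_data(n=60, vars_per_channel=3, channels=3, noise=0.05, seed=0)
    per_layer = np.repeat(np.arange(3), 3)
    truth = Partition(np.tile(per_layer, 3), data.layer_of(), K=3)
    return data, truth


class TestPipeline:
    def test_end_to_end_recovers_channels(self, channel_setup):
        data, truth = channel_setup
        result = fit_muncut(data, K=3, B=2000, gamma=0.5, seed=0)
        assert accuracy(adjacency(truth), adjacency(result.partition)) == 0.0

    def test_seed_reproducibility(self, channel_setup):
        data, _ = channel_setup
        r1 = fit_muncut(data, K=3, B=500, seed=5)
        r2 = fit_muncut(data, K=3, B=500, seed=5)
        np.testing.assert_array_equal(r1.partition.labels, r2.partition.labels)
        assert r1.objective == r2.objective

    def test_array_wrapper_matches_dataclass_path(self, channel_setup):
        data, _ = channel_setup
        r1 = fit_muncut(data, K=3, B=400, seed=1)
        r2 = muncut(data.Z, data.Y, data.X, K=3, B=400, seed=1)
        np.testing.assert_array_equal(r1.partition.labels, r2.partition.labels)

    def test_unknown_distance_rejected(self, channel_setup):
        data, _ = channel_setup
        with pytest.raises(ValueError):
            fit_muncut(data, K=3, dist="cosine")


class TestCLI:
    def write_layers(self, data, tmp_path):
        paths = {}
        for tag, M, names in [("Z", data.Z, data.z_names),
                              ("Y", data.Y, data.y_names),
                              ("X", data.X, data.x_names)]:
            p = tmp_path / f"{tag}.csv"
            write_layer_matrix(p, M, names)
            paths[tag] = str(p)
        return paths

    def test_fit_simulate_evaluate_round_trip(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        res = runner.invoke(main, ["simulate", "--scenario", "I", "--n", "50",
                                   "--q", "10", "--seed", "3",
                                   "--out", str(sim_dir)])
        assert res.exit_code == 0, res.output
        out_dir = tmp_path / "run"
        res = runner.invoke(main, [
            "fit", "--z", str(sim_dir / "Z.csv"), "--y", str(sim_dir / "Y.csv"),
            "--x", str(sim_dir / "X.csv"), "--K", "4", "--B", "500",
            "--seed", "1", "--out", str(out_dir)])
        assert res.exit_code == 0, res.output
        assert (out_dir / "partition.csv").exists()
        assert (out_dir / "trace.csv").exists()
        run_info = json.loads((out_dir / "run.json").read_text())
        assert run_info["K"] == 4
        res = runner.invoke(main, ["evaluate", "--truth", str(sim_dir / "truth.csv"),
                                   "--estimate", str(out_dir / "partition.csv")])
        assert res.exit_code == 0, res.output
        assert "M_accuracy" in res.output

    def test_evaluate_truth_against_itself_is_zero(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        runner.invoke(main, ["simulate", "--n", "30", "--q", "10",
                             "--out", str(sim_dir)])
        res = runner.invoke(main, ["evaluate", "--truth", str(sim_dir / "truth.csv"),
                                   "--estimate", str(sim_dir / "truth.csv")])
        assert res.exit_code == 0
        assert "M_accuracy 0.000000" in res.output

    def test_fit_reproducible_outputs(self, tmp_path, channel_setup):
        data, _ = channel_setup
        paths = self.write_layers(data, tmp_path)
        runner = CliRunner()
        outs = []
        for name in ("r1", "r2"):
            out = tmp_path / name
            res = runner.invoke(main, ["fit", "--z", paths["Z"], "--y", paths["Y"],
                                       "--x", paths["X"], "--K", "3", "--B", "300",
                                       "--seed", "7", "--out", str(out)])
            assert res.exit_code == 0, res.output
            outs.append((out / "partition.csv").read_text())
        assert outs[0] == outs[1]

    def test_benchmark_smoke(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "bench.csv"
        res = runner.invoke(main, ["benchmark", "--n", "40", "--q", "10",
                                   "--h", "0.5", "--replicates", "1",
                                   "--B", "500", "--out", str(out)])
        assert res.exit_code == 0, res.output
        import pandas as pd

        table = pd.read_csv(out)
        for col in ["MuNCut", "KM", "SC", "HC", "KM*", "SC*", "HC*", "LC", "FGC"]:
            assert col in table.columns
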