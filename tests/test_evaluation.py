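import json

import numpy as np
import pandas as pd
import pytest

from varselbench.evaluation import (
    EvaluationRecord,
    RunSpec,
    plot_benchmark,
    ratio_random,
    ratio_selected,
    records_to_frame,
    run_benchmark,
    write_results,
)
from varselbench.dataset import Dataset
from varselbench.selection import result_from_support
from varselbench.synthetic import SyntheticSpec


def spiked_dataset(n_original=75, n_probes=75):
    n_cols = n_original + n_probes
    origin = np.array(
        ["original"] * n_original + ["random_probe"] * n_probes, dtype=object
    )
    return Dataset(
        X=np.random.default_rng(0).random((10, n_cols)),
        y=np.arange(10.0),
        names=[f"c{i}" for i in range(n_cols)],
        origin=origin,
    )


class TestRatios:
    def test_ratio_selected_examples(self):
        ds = spiked_dataset()
        support = np.zeros(150, bool)
        support[:30] = True  # 30 of 75 originals
        sel = result_from_support("lasso", support)
        assert ratio_selected(sel, ds) == pytest.approx(0.4)
        assert ratio_selected(result_from_support("m", np.zeros(150, bool)), ds) == 0.0
        all_orig = np.concatenate([np.ones(75, bool), np.zeros(75, bool)])
        assert ratio_selected(result_from_support("m", all_orig), ds) == 1.0

    def test_ratio_random_examples(self):
        ds = spiked_dataset()
        support = np.zeros(150, bool)
        support[75:90] = True  # 15 probes, 75 originals
        assert ratio_random(result_from_support("m", support), ds) == pytest.approx(0.2)
        probes_all = np.concatenate([np.zeros(75, bool), np.ones(75, bool)])
        assert ratio_random(result_from_support("m", probes_all), ds) == 1.0

    def test_unspiked_dataset_rejected(self):
        ds = spiked_dataset(n_probes=0)
        with pytest.raises(ValueError, match="random_probe"):
            ratio_random(result_from_support("m", np.zeros(75, bool)), ds)


@pytest.fixture(scope="module")
def tiny_runspec():
    return RunSpec(
        selectors={
            "lasso": {},
            "gapls": {"population_size": 8, "generations": 2,
                      "max_pls_components": 3},
        },
        synthetic=SyntheticSpec(
            n_samples=80, n_informative=3, n_noise=9,
            coefficients=np.array([3.0, 2.0, 1.0]), seed=0,
        ),
        n_repeats=3,
        base_seed=5,
        suite_profile=None,
    )


@pytest.fixture(scope="module")
def tiny_records(tiny_runspec):
    return run_benchmark(tiny_runspec)


class TestRunBenchmark:
    def test_cardinality_and_counts(self, tiny_records):
        assert len(tiny_records) == 6  # 2 selectors x 3 repeats
        for rec in tiny_records:
            assert rec.error == ""
            assert 0.0 <= rec.ratio_selected <= 1.0
            assert 0.0 <= rec.ratio_random <= 1.0
            assert rec.n_original == 12

    def test_end_to_end_determinism(self, tiny_runspec, tiny_records):
        again = run_benchmark(tiny_runspec)
        assert records_to_frame(again).equals(records_to_frame(tiny_records))

    def test_suite_runs_when_profile_set(self, tiny_runspec):
        import dataclasses

        spec = dataclasses.replace(
            tiny_runspec, selectors={"lasso": {}}, n_repeats=1,
            suite_profile="fast",
        )
        (rec,) = run_benchmark(spec)
        assert np.isfinite(rec.mae_p10) and rec.mae_p10 > 0

    def test_failing_selector_recorded_not_raised(self, tiny_runspec):
        import dataclasses

        spec = dataclasses.replace(
            tiny_runspec,
            selectors={"lasso": {}, "boruta": {"max_iter": 1}},  # invalid: < 5
            n_repeats=1,
        )
        recs = run_benchmark(spec)
        by_method = {r.method: r for r in recs}
        assert by_method["lasso"].error == ""
        assert "max_iter" in by_method["boruta"].error


class TestOutputs:
    def test_write_results_round_trip(self, tiny_records, tmp_path):
        path = write_results(
            tiny_records, tmp_path / "results.csv", run_config={"base_seed": 5}
        )
        df = pd.read_csv(path)
        assert len(df) == 6
        orig = records_to_frame(tiny_records)
        np.testing.assert_allclose(
            df["ratio_selected"], orig["ratio_selected"]
        )
        sidecar = json.loads(path.with_suffix(".config.json").read_text())
        assert sidecar["run_config"]["base_seed"] == 5
        assert "scikit-learn" in sidecar["versions"]

    def test_plot_benchmark_three_panels(self, tiny_records, tmp_path):
        fig = plot_benchmark(tiny_records, save_to=tmp_path / "panels.png")
        assert len(fig.axes) == 3
        assert (tmp_path / "panels.png").exists()


class TestCli:
    def test_simulate_select_run(self, tmp_path):
        from click.testing import CliRunner

        from varselbench.cli import main

        runner = CliRunner()
        data = tmp_path / "synth.csv"
        spec_yaml = tmp_path / "spec.yaml"
        spec_yaml.write_text(
            "n_samples: 80\nn_informative: 3\nn_noise: 9\n"
            "coefficients: [3.0, 2.0, 1.0]\n"
        )
        r = runner.invoke(
            main, ["simulate", "--spec", str(spec_yaml), "--seed", "1",
                   "--out", str(data)],
        )
        assert r.exit_code == 0, r.output
        assert data.exists() and data.with_suffix(".truth.json").exists()

        sel_out = tmp_path / "sel.json"
        r = runner.invoke(
            main, ["select", "--method", "lasso", "--data", str(data),
                   "--target", "y", "--seed", "1", "--out", str(sel_out)],
        )
        assert r.exit_code == 0, r.output
        sel = json.loads(sel_out.read_text())
        assert sel["method"] == "lasso" and isinstance(sel["selected"], list)

        run_yaml = tmp_path / "run.yaml"
        run_yaml.write_text(
            "selectors:\n  lasso: {}\n"
            "synthetic:\n  n_samples: 80\n  n_informative: 3\n  n_noise: 9\n"
            "  coefficients: [3.0, 2.0, 1.0]\n"
            "n_repeats: 1\nsuite_profile: null\n"
        )
        out_dir = tmp_path / "results"
        r = runner.invoke(
            main, ["run", "--config", str(run_yaml), "--seed", "2",
                   "--out", str(out_dir)],
        )
        assert r.exit_code == 0, r.output
        df = pd.read_csv(out_dir / "results.csv")
        assert list(df["method"]) == ["lasso"]
        assert (out_dir / "selections" / "lasso_repeat0.json").exists()
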