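"""End-to-end runs, report bundle contract, method/weight comparison, CLI."""

import json

import pandas as pd
import pytest
from typer.testing import CliRunner

from oaburden.cli import app
from oaburden.reporting import (RunConfig, compare_methods, load_run_config,
                                run)
from oaburden.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="module")
def inputs(tmp_path_factory):
    root = tmp_path_factory.mktemp("inputs")
    syn = generate(SyntheticConfig(n_cases=1500, seed=11, p_oa_death=0.003))
    return syn.write(root)


def _config(inputs, out_dir, **kwargs):
    return RunConfig(
        records=inputs["records"], deaths=inputs["deaths"],
        denominators=inputs["denominators"], out_dir=out_dir, **kwargs,
    )


class TestRun:
    def test_bundle_files_written(self, inputs, tmp_path):
        bundle = run(_config(inputs, tmp_path / "out"))
        for key in ("table_incidence", "table_daly_grid", "table_knee_hip", "summary"):
            assert bundle.paths[key].exists()
        summary = json.loads(bundle.paths["summary"].read_text())
        assert set(summary["total_dalys"]) == {
            "harvard1994_who", "harvard1994_minsa", "gbd2015_who", "gbd2015_minsa",
        }
        assert sum(summary["exclusions"].values()) == (
            summary["input_rows"] - summary["selected_patients"]
        )

    def test_single_cell_grid(self, inputs, tmp_path):
        bundle = run(_config(inputs, tmp_path / "out", methods=("gbd2015",),
                             weights=(0.165,)))
        assert list(bundle.summary["total_dalys"]) == ["gbd2015_who"]
        grid = pd.read_csv(bundle.paths["table_daly_grid"])
        assert [c for c in grid.columns if c.startswith("dalys_") and
                not c.startswith("dalys_per_1000")] == ["dalys_gbd2015_who"]

    def test_missing_denominators_file(self, inputs, tmp_path):
        cfg = _config(inputs, tmp_path / "out")
        cfg.denominators = tmp_path / "nowhere.csv"
        with pytest.raises(FileNotFoundError, match="nowhere.csv"):
            run(cfg)

    def test_byte_identical_reruns(self, inputs, tmp_path):
        b1 = run(_config(inputs, tmp_path / "o1"))
        b2 = run(_config(inputs, tmp_path / "o2"))
        for key in b1.paths:
            assert b1.paths[key].read_bytes() == b2.paths[key].read_bytes()

    def test_knee_hip_detail_covers_both_types(self, inputs, tmp_path):
        bundle = run(_config(inputs, tmp_path / "out"))
        assert set(bundle.knee_hip["oa_type"]) == {"knee", "hip"}

    def test_yaml_config_round_trip(self, inputs, tmp_path):
        cfg_path = tmp_path / "run.yaml"
        cfg_path.write_text(
            "records: {records}\ndeaths: {deaths}\n"
            "denominators: {denominators}\nout_dir: {out}\nyear: 2016\n"
            "methods: [harvard1994, gbd2015]\nweights: [0.165, 0.28]\n".format(
                records=inputs["records"], deaths=inputs["deaths"],
                denominators=inputs["denominators"], out=tmp_path / "out",
            )
        )
        cfg = load_run_config(cfg_path)
        assert cfg.methods == ("harvard1994", "gbd2015")
        run(cfg)


class TestCompare:
    def test_weight_ratio_exact_without_deaths(self, tmp_path):
        syn = generate(SyntheticConfig(n_cases=800, seed=13, p_oa_death=0.0))
        paths = syn.write(tmp_path / "in")
        bundle = run(RunConfig(
            records=paths["records"], deaths=paths["deaths"],
            denominators=paths["denominators"], out_dir=tmp_path / "out",
        ))
        ratios = compare_methods(bundle)
        for method, ratio in ratios["minsa_over_who"].items():
            assert ratio == pytest.approx(0.28 / 0.165, abs=1e-6), method

    def test_printed_totals_reproduce_headline_ratio(self):
        summary = {
            "methods": ["harvard1994", "gbd2015"],
            "weights": {"who": 0.165},
            "total_dalys": {"harvard1994_who": 399_884, "gbd2015_who": 1_037_865},
        }
        ratios = compare_methods(summary)
        assert ratios["gbd_over_harvard"]["who"] == pytest.approx(2.60, abs=0.01)

    def test_single_method_is_an_error(self):
        summary = {
            "methods": ["gbd2015"], "weights": {"who": 0.165},
            "total_dalys": {"gbd2015_who": 1.0},
        }
        with pytest.raises(ValueError, match="both methodologies"):
            compare_methods(summary)


class TestCli:
    runner = CliRunner()

    def test_generate_run_compare(self, tmp_path):
        r = self.runner.invoke(app, [
            "generate", "--out", str(tmp_path / "in"), "--n-cases", "400",
            "--seed", "3",
        ])
        assert r.exit_code == 0, r.output
        r = self.runner.invoke(app, [
            "run", "--records", str(tmp_path / "in" / "records.csv"),
            "--deaths", str(tmp_path / "in" / "deaths.csv"),
            "--denominators", str(tmp_path / "in" / "denominators.csv"),
            "--out", str(tmp_path / "out"),
        ])
        assert r.exit_code == 0, r.output
        r = self.runner.invoke(app, [
            "compare", "--summary", str(tmp_path / "out" / "summary.json"),
        ])
        assert r.exit_code == 0, r.output
        assert "minsa_over_who" in r.output

    def test_run_missing_file_exits_nonzero(self, tmp_path):
        r = self.runner.invoke(app, [
            "run", "--records", str(tmp_path / "no.csv"),
            "--deaths", str(tmp_path / "no.csv"),
            "--denominators", str(tmp_path / "no.csv"),
            "--out", str(tmp_path / "out"),
        ])
        assert r.exit_code != 0
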