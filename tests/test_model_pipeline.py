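import json

import numpy as np
import pytest
from click.testing import CliRunner

from dynhubs import (
    HubDynamicsModel,
    InvalidConfigError,
    InvalidInputError,
    ParseError,
    PipelineConfig,
    SyntheticConfig,
    generate_cohort,
    generate_region_table,
    generate_subject,
    run_pipeline,
)
from dynhubs import io as dio
from dynhubs.cli import main as cli_main

SMALL = SyntheticConfig(n_regions=20, n_timepoints=60, n_subjects_per_group=3, seed=2)


@pytest.fixture(scope="module")
def small_cohort():
    return generate_cohort(SMALL)


class TestIO:
    def test_roundtrip_is_bitwise_exact(self, tmp_path):
        ts, _ = generate_subject(SMALL, "NC", 17)
        path = tmp_path / "s.tsv"
        dio.save_timeseries(ts, path)
        ts.region_table.to_tsv(tmp_path / "rt.tsv")
        loaded = dio.load_timeseries(path, tmp_path / "rt.tsv")
        assert np.array_equal(loaded.data, ts.data)

    def test_header_mismatch_names_first_bad_column(self, tmp_path):
        ts, _ = generate_subject(SMALL, "NC", 17)
        path = tmp_path / "s.tsv"
        dio.save_timeseries(ts, path)
        other = generate_region_table(20, seed=5)
        renamed = other.to_dataframe()
        renamed.loc[1, "region_name"] = "WRONG"
        renamed.to_csv(tmp_path / "rt.tsv", sep="\t", index=False)
        with pytest.raises(ParseError, match="column 2"):
            dio.load_timeseries(path, tmp_path / "rt.tsv")

    def test_missing_cell_names_row_and_column(self, tmp_path):
        ts, _ = generate_subject(SMALL, "NC", 17)
        path = tmp_path / "s.tsv"
        dio.save_timeseries(ts, path)
        lines = path.read_text().splitlines()
        cells = lines[3].split("\t")
        cells[4] = ""
        lines[3] = "\t".join(cells)
        path.write_text("\n".join(lines) + "\n")
        ts.region_table.to_tsv(tmp_path / "rt.tsv")
        with pytest.raises(ParseError, match="row 4.*column 5"):
            dio.load_timeseries(path, tmp_path / "rt.tsv")

    def test_cohort_write_then_load(self, tmp_path, small_cohort):
        dio.write_cohort(small_cohort, tmp_path)
        subjects = dio.load_cohort_subjects(tmp_path)
        assert len(subjects) == 6
        by_id = {s.subject_id: s for s in subjects}
        for orig in small_cohort.subjects:
            assert np.array_equal(by_id[orig.subject_id].data, orig.data)
            assert by_id[orig.subject_id].group == orig.group


class TestPipelineConfig:
    def test_unknown_keys_rejected(self):
        with pytest.raises(InvalidConfigError, match="unknown config keys"):
            PipelineConfig.from_dict({"densityy": 0.2})
        with pytest.raises(InvalidConfigError, match="unknown synthetic"):
            PipelineConfig.from_dict({"synthetic": {"n_regionss": 5}})

    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            "density: 0.12\nseed: 9\nsynthetic:\n  n_regions: 15\n  n_timepoints: 30\n"
        )
        cfg = PipelineConfig.from_yaml(path)
        assert cfg.density == 0.12
        assert cfg.synthetic.n_regions == 15

    def test_out_of_range_values_rejected(self):
        with pytest.raises(InvalidConfigError):
            PipelineConfig(density=0.0)
        with pytest.raises(InvalidConfigError):
            PipelineConfig(cut_scale="other")


class TestModel:
    def test_fit_produces_all_stage_outputs(self, small_cohort):
        model = HubDynamicsModel.from_cohort(small_cohort)
        results = model.fit()
        assert len(results.per_subject) == 6
        r = next(iter(results.per_subject.values()))
        assert r.bc.values.shape == (20, 60)
        assert np.all((0 <= r.bc.values) & (r.bc.values <= 1))
        assert set(results.group_candidates) == {"NC", "SZ"}
        assert results.stats is not None
        frame = results.stats_frame()
        assert {"metric", "level", "t", "p", "p_fdr"} <= set(frame.columns)
        # one global + five RSN BC rows at least
        assert (frame["level"] == "rsn").sum() == len(
            small_cohort.region_table.rsn_labels
        )

    def test_summary_is_readable_text(self, small_cohort):
        results = HubDynamicsModel.from_cohort(small_cohort).fit()
        text = results.summary()
        assert "Hub Dynamics Results" in text
        assert "consensus candidate hubs" in text
        assert "Group comparisons" in text

    def test_mixed_region_tables_rejected(self, small_cohort):
        other_cfg = SMALL.replace(rsn_proportions={"SMN": 0.5, "DMN": 0.5})
        odd, _ = generate_subject(other_cfg, "NC", 3)
        with pytest.raises(InvalidInputError, match="region table"):
            HubDynamicsModel(list(small_cohort.subjects) + [odd])

    def test_single_subject_group_fails_stats_naming_group(self):
        cfg = SMALL.replace(n_subjects_per_group=1)
        cohort = generate_cohort(cfg)
        model = HubDynamicsModel.from_cohort(cohort)
        with pytest.raises(InvalidInputError, match="group NC"):
            model.fit(run_stats=True)
        # without the stats stage the fit completes
        assert model.fit(run_stats=False).stats is None


class TestRunPipeline:
    def test_smoke_produces_declared_outputs(self, tmp_path):
        config = PipelineConfig(
            output_dir=str(tmp_path / "out"),
            seed=4,
            synthetic=SMALL.replace(n_subjects_per_group=2),
        )
        report = run_pipeline(config)
        out = tmp_path / "out"
        assert (out / "report.json").exists()
        assert (out / "stats.tsv").exists()
        for g in ("NC", "SZ"):
            assert (out / f"snd_{g}.tsv").exists()
            assert (out / f"consensus_candidates_{g}.tsv").exists()
        sdirs = list((out / "subjects").iterdir())
        assert len(sdirs) == 4
        for sdir in sdirs:
            for name in (
                "bc_timeseries.tsv",
                "bc_summary.tsv",
                "hubs.tsv",
                "activity.tsv",
                "spatial_overlap.tsv",
            ):
                assert (sdir / name).exists(), name
        on_disk = {str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()}
        declared = set(report["files"])
        assert declared <= on_disk

    def test_report_json_is_deterministic(self, tmp_path):
        base = SMALL.replace(n_subjects_per_group=2)
        reports = []
        for sub in ("a", "b"):
            config = PipelineConfig(
                output_dir=str(tmp_path / sub), seed=4, synthetic=base
            )
            run_pipeline(config)
            data = json.loads((tmp_path / sub / "report.json").read_text())
            data["config"]["output_dir"] = "X"
            reports.append(data)
        assert reports[0] == reports[1]


class TestCli:
    def test_simulate_then_run(self, tmp_path):
        runner = CliRunner()
        cohort_dir = tmp_path / "cohort"
        res = runner.invoke(
            cli_main,
            [
                "simulate",
                "--out", str(cohort_dir),
                "--n-regions", "15",
                "--n-timepoints", "40",
                "--n-subjects-per-group", "2",
                "--seed", "3",
            ],
        )
        assert res.exit_code == 0, res.output
        assert (cohort_dir / "manifest.tsv").exists()
        res = runner.invoke(
            cli_main,
            [
                "run",
                "--input-dir", str(cohort_dir),
                "--out", str(tmp_path / "out"),
                "--seed", "3",
            ],
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "out" / "report.json").exists()

    def test_hubs_subcommand(self, tmp_path):
        runner = CliRunner()
        cohort_dir = tmp_path / "cohort"
        generate_cohort(
            SMALL.replace(n_subjects_per_group=1), out_dir=cohort_dir
        )
        subject = next(cohort_dir.glob("NC_*.tsv"))
        res = runner.invoke(
            cli_main,
            [
                "hubs",
                "--subject", str(subject),
                "--region-table", str(cohort_dir / "region_table.tsv"),
                "--out", str(tmp_path / "hubs"),
            ],
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "hubs" / "bc_timeseries.tsv").exists()
        assert (tmp_path / "hubs" / "activity.tsv").exists()

    def test_bad_config_key_is_a_clean_error(self, tmp_path):
        cfg = tmp_path / "c.yaml"
        cfg.write_text("nonsense_key: 1\n")
        res = CliRunner().invoke(cli_main, ["run", "--config", str(cfg)])
        assert res.exit_code != 0
        assert "unknown config keys" in res.output
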