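import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from mixedlink.cli import main as cli_main
from mixedlink.io import read_sample_table
from mixedlink.model import ModelSpec
from mixedlink.pipeline import StudyConfig, run_study_pipeline
from mixedlink.synthetic import simulate_dataset


@pytest.fixture(scope="module")
def study_frame():
    """A 124-row synthetic study table with known Marked/Unknown counts."""
    df = simulate_dataset(model=2, n=124, seed=21)
    # pin the rare-level counts the 3-class restriction must drop
    atrophy = np.array(["Mild"] * 40 + ["Moderate"] * 30 + ["Negative"] * 28
                       + ["Marked"] * 3 + ["Unknown"] * 23)
    df = df.copy()
    df["atrophy"] = atrophy
    return df


class TestReadSampleTable:
    def test_five_class_schema(self, study_frame):
        table = read_sample_table(study_frame, "tnsc+atrophy5")
        assert table.n == 124 and table.d == 5
        assert table.covariate_names == ["tnsc", "mild", "moderate", "negative", "unknown"]
        assert table.category_labels == ["Normal", "MIM", "IM"]

    def test_three_class_drops_marked_and_unknown(self, study_frame):
        table = read_sample_table(study_frame, "tnsc+atrophy3")
        assert table.n == 124 - 3 - 23 == 98
        assert table.d == 3
        assert table.n_dropped == 26

    def test_tnsc_only(self, study_frame):
        table = read_sample_table(study_frame[["sample_id", "tnsc", "im_label"]], "tnsc")
        assert table.d == 1

    def test_case_insensitive_labels(self, study_frame):
        noisy = study_frame.copy()
        noisy["im_label"] = noisy["im_label"].str.upper()
        noisy["atrophy"] = noisy["atrophy"].str.lower()
        table = read_sample_table(noisy, "tnsc+atrophy5")
        assert table.n == 124

    def test_unknown_level_names_row(self, study_frame):
        bad = study_frame.copy()
        bad.loc[17, "atrophy"] = "severe"
        with pytest.raises(ValueError, match="17"):
            read_sample_table(bad, "tnsc+atrophy5")

    def test_missing_column_rejected(self, study_frame):
        with pytest.raises(ValueError, match="atrophy"):
            read_sample_table(study_frame.drop(columns=["atrophy"]), "tnsc+atrophy5")

    def test_empty_rejected(self, study_frame):
        with pytest.raises(ValueError):
            read_sample_table(study_frame.iloc[:0], "tnsc")

    def test_csv_round_trip(self, study_frame, tmp_path):
        path = tmp_path / "samples.csv"
        study_frame.to_csv(path, index=False)
        table = read_sample_table(path, "tnsc+atrophy5")
        assert table.n == 124


@pytest.fixture(scope="module")
def pipeline_report(study_frame, tmp_path_factory):
    out = tmp_path_factory.mktemp("report")
    config = StudyConfig(
        data=study_frame,
        covariate_set="tnsc+atrophy3",
        criterion="AIC",
        out_dir=out,
        baseline_specs={"mlogit": ModelSpec("baseline", ("logit", "logit"), "npo")},
        cv_partitions=2,
        cv_folds=5,
    )
    with pytest.warns(RuntimeWarning):
        report = run_study_pipeline(config)
    return config, report, out


class TestPipeline:
    def test_ranking_shape_and_identity(self, pipeline_report):
        _, report, _ = pipeline_report
        grouped = report["ranking"]
        assert len(grouped) == 8
        n = report["n"]
        np.testing.assert_allclose(
            grouped["BIC"], grouped["AIC"] + (np.log(n) - 2.0) * grouped["p"], atol=1e-8
        )
        assert report["n"] == 98 and report["n_dropped"] == 26

    def test_winner_and_slope_report(self, pipeline_report):
        _, report, _ = pipeline_report
        slope = report["tnsc_slope"]
        assert np.isfinite(slope["estimate"])
        assert slope["ci_lower"] < slope["estimate"] < slope["ci_upper"]

    def test_cv_block(self, pipeline_report):
        _, report, _ = pipeline_report
        assert report["cv_ce"].shape == (2, 2)
        assert set(report["cv_pvalues"].columns) == {"winner", "mlogit"}

    def test_outputs_written(self, pipeline_report):
        _, _, out = pipeline_report
        for name in ("ranking.tsv", "ranking_full.tsv", "winner.json", "cv_ce.tsv", "cv_pvalues.tsv"):
            assert (out / name).exists()

    def test_criterion_bic_reorders_only(self, study_frame):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = run_study_pipeline(StudyConfig(data=study_frame, covariate_set="tnsc"))
            b = run_study_pipeline(
                StudyConfig(data=study_frame, covariate_set="tnsc", criterion="BIC")
            )
        bic_sorted = b["ranking_full"]
        conv = bic_sorted[bic_sorted["converged"]]
        assert np.all(np.diff(conv["BIC"]) >= -1e-9)
        # same fits underneath: identical AIC multisets
        assert sorted(a["ranking_full"]["AIC"]) == pytest.approx(
            sorted(b["ranking_full"]["AIC"]), abs=1e-9
        )


class TestCLI:
    def test_simulate_fit_cv(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data.csv"
        res = runner.invoke(cli_main, ["simulate", "--model", "1", "--n", "150",
                                       "--seed", "3", "--out", str(data)])
        assert res.exit_code == 0, res.output
        assert pd.read_csv(data).shape[0] == 150

        res = runner.invoke(cli_main, ["fit", "--spec", "cumulative:po:loglog,logit",
                                       "--data", str(data)])
        assert res.exit_code == 0, res.output
        assert "tnsc slope" in res.output

        ce_out = tmp_path / "ce.tsv"
        res = runner.invoke(cli_main, [
            "cv", "--spec", "cumulative:po:loglog,logit",
            "--spec", "baseline:npo:logit,logit",
            "--data", str(data), "--folds", "4", "--partitions", "2",
            "--out", str(ce_out),
        ])
        assert res.exit_code == 0, res.output
        assert ce_out.exists() and (tmp_path / "ce_pvalues.tsv").exists()

    def test_tnsc_command(self, tmp_path):
        from mixedlink.synthetic import simulate_beta_matrix, synthetic_epitoc_params

        params = synthetic_epitoc_params(nc=8, seed=1)
        betas = simulate_beta_matrix(params, np.array([5000.0, 8000.0]), seed=2)
        bpath, ppath, opath = tmp_path / "b.csv", tmp_path / "p.csv", tmp_path / "t.csv"
        betas.to_csv(bpath)
        pd.DataFrame({"cpg_id": params.cpg_ids, "delta": params.delta}).to_csv(
            ppath, index=False
        )
        runner = CliRunner()
        res = runner.invoke(cli_main, ["tnsc", "--betas", str(bpath), "--params",
                                       str(ppath), "--out", str(opath)])
        assert res.exit_code == 0, res.output
        out = pd.read_csv(opath)
        np.testing.assert_allclose(out["tnsc"], [5000.0, 8000.0], atol=1e-6)
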