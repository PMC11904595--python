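"""Model/Results layer, pipeline orchestration, CLI and file round trips."""

import os

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from golgiredox import io
from golgiredox.cli import main as cli_main
from golgiredox.exceptions import ConfigError, InsufficientDataError
from golgiredox.imaging import CellRatioRecord, FieldOfView
from golgiredox.models import GrxPrmModel, RoGfpRedoxModel, TraqGshModel, combine_pool
from golgiredox.nernst import RedoxConstants, e_gsh_from_oxd, midpoint_at_ph, ROGFP1_IE
from golgiredox.pipeline import (
    PipelineConfig,
    make_table1_report,
    run_pipeline,
)
from golgiredox.prm import XICTrace
from golgiredox.synth import XicScenario, simulate_xic_pair

FAST = dict(
    n_boot=200,
    sim_n_cells=16,
    sim_replicates=1,
    sim_traqg_cells_per_fov=16,
    sim_traqg_fovs=1,
)


def analytic_ratio_frame(oxd=0.922, r_red=0.2, r_ox=2.0, span=0.5, n=12):
    """Per-cell table with exact condition ratios (no imaging noise)."""
    from golgiredox.nernst import ratio_from_oxd

    r_basal = ratio_from_oxd(oxd, r_red, r_ox, span)
    rows = []
    for cond, ratio, den in [
        ("basal", r_basal, 1.0 - oxd + oxd * span),
        ("DTT", r_red, 1.0),
        ("H2O2", r_ox, span),
    ]:
        for i in range(n):
            rows.append(
                dict(
                    cell_id=i,
                    condition=cond,
                    ratio=ratio,
                    mean_den=1000.0 * den,
                    mean_num=1000.0 * den * ratio,
                )
            )
    return pd.DataFrame(rows)


class TestRoGfpModel:
    def test_exact_ratios_recover_potential(self):
        consts = RedoxConstants()
        df = analytic_ratio_frame(oxd=0.922)
        model = RoGfpRedoxModel(df, constants=consts)
        res = model.fit(n_boot=200, seed=0)
        e0 = midpoint_at_ph(ROGFP1_IE, 6.2, consts)
        expected = e_gsh_from_oxd(0.922, e0, consts)
        assert res.e_gsh == pytest.approx(expected, abs=1e-6)
        assert res.calibration.span_445 == pytest.approx(0.5, rel=1e-9)
        assert res.oxd.oxd == pytest.approx(0.922, abs=1e-9)

    def test_summary_reports_key_quantities(self):
        res = RoGfpRedoxModel(analytic_ratio_frame()).fit(n_boot=200, seed=0)
        text = res.summary()
        for token in ("E_GSH", "OxD", "Mann-Whitney", "span"):
            assert token in text

    def test_missing_condition_rejected(self):
        df = analytic_ratio_frame()
        df = df[df["condition"] != "DTT"]
        with pytest.raises(InsufficientDataError):
            RoGfpRedoxModel(df)

    def test_pool_composition(self):
        res = RoGfpRedoxModel(analytic_ratio_frame()).fit(n_boot=200, seed=0)
        pool = res.pool(16.0)
        assert pool.gs_total == pytest.approx(
            pool.gsh + 2 * pool.gssg, rel=1e-12
        )
        assert pool.q == pytest.approx(res.q)


class TestGrxPrmModel:
    def test_fit_and_summary(self):
        light, heavy = simulate_xic_pair(XicScenario(true_sh_to_ssg=0.08, snr=1e6, seed=0))
        res = GrxPrmModel(light, heavy).fit()
        assert res.sh_to_ssg == pytest.approx(0.08, rel=0.01)
        assert res.r_gs == pytest.approx(234 * 0.08, rel=0.01)
        assert "R_GS" in res.summary()


class TestPipeline:
    def test_invalid_ph_rejected_before_compute(self):
        with pytest.raises(ConfigError, match="pH"):
            PipelineConfig(mode="rogfp", ph=12.0)

    def test_invalid_mode_rejected(self):
        with pytest.raises(ConfigError, match="mode"):
            PipelineConfig(mode="everything")

    def test_missing_input_path_rejected(self):
        with pytest.raises(ConfigError, match="does not exist"):
            PipelineConfig(mode="prm", xic_csv="/nonexistent/file.csv")

    def test_prm_mode_emits_rgs_row(self):
        res = run_pipeline(PipelineConfig(mode="prm", seed=0))
        row = res.summary.loc[res.summary["quantity"] == "R_GS"]
        assert len(row) == 1
        assert row["method"].iloc[0] == "sCGrx1p"

    def test_rerun_is_bit_identical(self):
        cfg = dict(mode="all", seed=7, **FAST)
        s1 = run_pipeline(PipelineConfig(**cfg)).summary
        s2 = run_pipeline(PipelineConfig(**cfg)).summary
        pd.testing.assert_frame_equal(s1, s2)

    def test_joint_rows_satisfy_pool_identity(self):
        res = run_pipeline(PipelineConfig(mode="all", seed=7, **FAST))
        s = res.summary.set_index("quantity")["value"]
        q, r_gs, gs = s["Q_M"], s["R_GS"], s["GS_total_M"]
        assert gs == pytest.approx(q / r_gs + 2 * q / r_gs**2, rel=1e-12)

    def test_artifacts_written(self, tmp_path):
        out = tmp_path / "run"
        run_pipeline(PipelineConfig(mode="all", seed=7, out_dir=str(out), **FAST))
        for name in (
            "summary.csv",
            "summary.txt",
            "log.txt",
            "rogfp_cell_records.csv",
            "redox_per_cell.csv",
        ):
            assert (out / name).exists()
        per_cell = pd.read_csv(out / "redox_per_cell.csv")
        assert {"cell_id", "condition", "ratio", "oxd", "e_gsh_mV", "q_M",
                "r_gs", "gsh_M", "gssg_M", "gs_total_M"} <= set(per_cell.columns)


class TestReport:
    def test_empty_summary_rejected(self):
        with pytest.raises(ValueError):
            make_table1_report(pd.DataFrame())

    def test_single_row(self):
        df = pd.DataFrame(
            [dict(dataset="x", quantity="E_GSH_mV", value=-157.0,
                  lower=-160.0, upper=-154.0, method="roGFP")]
        )
        text = make_table1_report(df)
        assert "-157.0 mV" in text
        assert "roGFP" in text

    def test_full_joint_table_has_five_quantities(self):
        res = run_pipeline(PipelineConfig(mode="all", seed=7, **FAST))
        assert list(res.summary["quantity"]) == [
            "E_GSH_mV", "Q_M", "R_GS", "GS_total_M", "GSH_M",
        ]
        text = make_table1_report(res.summary)
        assert text.count("\n") == len(res.summary) + 1


class TestIO:
    def test_fov_tiff_round_trip(self, tmp_path, rng):
        fov = FieldOfView(
            channels=(rng.random((32, 32)), rng.random((32, 32))),
            condition="basal",
            replicate_id="R1",
        )
        path = str(tmp_path / "f.tiff")
        io.write_fov_tiff(path, fov)
        back = io.read_fov_tiff(path, condition="basal", replicate_id="R1")
        assert np.allclose(back.numerator, fov.numerator, atol=1e-6)

    def test_records_csv_round_trip(self, tmp_path):
        records = [
            CellRatioRecord(cell_id=1, golgi_area=55, mean_num=10.0,
                            mean_den=5.0, ratio=2.0, condition="basal",
                            replicate_id="R1")
        ]
        path = str(tmp_path / "r.csv")
        io.write_records_csv(path, records)
        assert io.read_records_csv(path) == records

    def test_xic_csv_round_trip(self, tmp_path):
        light, heavy = simulate_xic_pair(XicScenario(seed=1))
        path = str(tmp_path / "x.csv")
        io.write_xic_csv(path, {("y14", "light"): light, ("y14", "heavy"): heavy})
        back = io.read_xic_csv(path)
        assert np.allclose(back[("y14", "light")].intensity, light.intensity)

    def test_calibration_csv_per_fov_aggregation(self, tmp_path):
        df = pd.DataFrame(
            dict(gsh_M=[1e-3] * 3 + [2e-3] * 3,
                 ratio=[2.0, 2.1, 1.9, 3.0, 3.1, 2.9],
                 field_id=list("abcdef"))
        )
        path = str(tmp_path / "cal.csv")
        df.to_csv(path, index=False)
        points = io.read_calibration_csv(path)
        assert len(points) == 2
        assert points[0].ratio_mean == pytest.approx(2.0)
        assert points[0].n_fov == 3

    def test_flat_config_round_trip(self, tmp_path):
        cfg = dict(mode="prm", seed=3, ph=6.2)
        path = str(tmp_path / "c.yaml")
        io.write_flat_config(path, cfg)
        assert io.load_flat_config(path) == cfg


class TestCli:
    def test_simulate_then_analyze_and_report(self, tmp_path):
        runner = CliRunner()
        sim_dir = str(tmp_path / "sim")
        cfg_path = str(tmp_path / "cfg.yaml")
        io.write_flat_config(cfg_path, FAST)
        res = runner.invoke(
            cli_main,
            ["simulate", "--config", cfg_path, "--seed", "2", "--out-dir", sim_dir],
        )
        assert res.exit_code == 0, res.output
        assert os.path.exists(os.path.join(sim_dir, "rogfp_manifest.csv"))

        out_dir = str(tmp_path / "res")
        res = runner.invoke(
            cli_main,
            ["rogfp", "--config", cfg_path, "--seed", "2",
             "--manifest", os.path.join(sim_dir, "rogfp_manifest.csv"),
             "--block", "64", "--out-dir", out_dir],
        )
        assert res.exit_code == 0, res.output
        assert "E_GSH" in res.output

        res = runner.invoke(
            cli_main, ["report", os.path.join(out_dir, "summary.csv")]
        )
        assert res.exit_code == 0
        assert "E_GSH" in res.output

    def test_prm_from_csv(self, tmp_path):
        runner = CliRunner()
        light, heavy = simulate_xic_pair(XicScenario(true_sh_to_ssg=0.06, seed=4))
        xic = str(tmp_path / "x.csv")
        io.write_xic_csv(xic, {("y14", "light"): light, ("y14", "heavy"): heavy})
        res = runner.invoke(cli_main, ["prm", "--xic", xic])
        assert res.exit_code == 0, res.output
        assert "R_GS" in res.output

    def test_invalid_config_is_clean_error(self, tmp_path):
        runner = CliRunner()
        cfg_path = str(tmp_path / "bad.yaml")
        io.write_flat_config(cfg_path, dict(ph=12.0))
        res = runner.invoke(cli_main, ["rogfp", "--config", cfg_path])
        assert res.exit_code == 1
        assert "error" in res.output or "error" in (res.stderr or "")
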