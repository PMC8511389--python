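import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from canomix.cli import main as cli_main
from canomix.design import DesignMatrix, lhs_maximin, pure_bounds
from canomix.mixture import PLANT_BOUNDS
from canomix.project import (
    RunRecord,
    load_record,
    replay_record,
    run_campaign,
    run_from_config,
    save_record,
)

CLIMATE = {"n_days": 360, "seed": 1}


def tiny_pure_design(n=4, seed=6):
    bounds, names = pure_bounds()
    return lhs_maximin(n, bounds, seed=seed, dim_names=names, kind="pure")


def tiny_campaign(design, **kw):
    kw.setdefault("campaign_seed", 11)
    kw.setdefault("n_plants", 12)
    return run_campaign(design, CLIMATE, **kw)


class TestRunCampaign:
    @pytest.fixture(scope="class")
    def baseline(self):
        table, _ = tiny_campaign(tiny_pure_design())
        return table

    def test_all_rows_succeed_with_outputs(self, baseline):
        assert list(baseline["status"]) == ["ok"] * 4
        assert baseline[["n_ears", "l_perc", "f_tot"]].notna().all().all()

    def test_rerun_is_identical(self, baseline):
        again, _ = tiny_campaign(tiny_pure_design())
        pd.testing.assert_frame_equal(baseline, again)

    def test_worker_count_does_not_change_results(self, baseline):
        parallel, _ = tiny_campaign(tiny_pure_design(), n_jobs=2)
        pd.testing.assert_frame_equal(baseline, parallel)

    def test_row_seeds_differ_across_rows(self, baseline):
        # two distinct design rows with distinct seeds: outputs differ
        assert baseline["f_tot"].nunique() > 1

    def test_failing_row_is_flagged_not_fatal(self):
        # second row's differential pushes a genotype outside plant-scale
        # bounds: that row fails, the others still run
        bounds, names = pure_bounds()
        good = np.array([100.0, 40.0, 20.0, 0.55, 0.4])
        pts = np.vstack(
            [
                np.concatenate([good, np.zeros(5)]),
                np.concatenate([good, [200.0, 0, 0, 0, 0]]),
            ]
        )
        design = DesignMatrix(
            points=pts,
            bounds=np.array([(0.0, 300.0)] * 10),  # loose container bounds
            dim_names=tuple(f"x{i}" for i in range(10)),
            seed=0,
            kind="mixture",
        )
        table, _ = tiny_campaign(design)
        assert table.loc[0, "status"] == "ok"
        assert table.loc[1, "status"] == "failed"
        assert "plant-scale" in table.loc[1, "error"]
        assert np.isnan(table.loc[1, "f_tot"])

    def test_records_kept_on_request(self):
        design = tiny_pure_design(n=2)
        _, records = tiny_campaign(design, keep_records=True)
        assert len(records) == 2
        assert all(r.kind == "pure" for r in records)


PURE_CONFIG = {
    "kind": "pure",
    "genotype": {"h_ms": 100.0, "phi_b": 40.0, "lmax_b": 21.0,
                 "gai_c": 0.55, "par_t": 0.4},
    "climate": CLIMATE,
    "seed": 5,
    "n_plants": 12,
}


class TestRecords:
    def test_save_load_round_trip(self, tmp_path):
        outputs = run_from_config(PURE_CONFIG)
        record = RunRecord.new("pure", PURE_CONFIG, outputs)
        path = tmp_path / "record.json"
        save_record(record, path)
        back = load_record(path)
        assert back == record

    def test_replay_reproduces_outputs(self, tmp_path):
        outputs = run_from_config(PURE_CONFIG)
        record = RunRecord.new("pure", PURE_CONFIG, outputs)
        save_record(record, tmp_path / "r.json")
        replayed = replay_record(load_record(tmp_path / "r.json"))
        assert replayed == outputs

    def test_tampered_config_warns(self, tmp_path):
        record = RunRecord.new("pure", PURE_CONFIG, {"f_tot": 1.0})
        path = tmp_path / "r.json"
        save_record(record, path)
        payload = json.loads(path.read_text())
        payload["config"]["seed"] = 999
        path.write_text(json.dumps(payload))
        with pytest.warns(UserWarning, match="digest mismatch"):
            load_record(path)

    def test_schema_mismatch_rejected(self, tmp_path):
        record = RunRecord.new("pure", PURE_CONFIG, {"f_tot": 1.0})
        path = tmp_path / "r.json"
        save_record(record, path)
        payload = json.loads(path.read_text())
        payload["schema_version"] = 99
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="schema version"):
            load_record(path)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown run kind"):
            run_from_config({**PURE_CONFIG, "kind": "monoculture"})


class TestCliSmoke:
    def test_synth_climate_writes_csv(self, tmp_path):
        out = tmp_path / "climate.csv"
        result = CliRunner().invoke(
            cli_main, ["synth-climate", "--days", "30", "--seed", "1",
                       "--out", str(out)]
        )
        assert result.exit_code == 0, result.output
        df = pd.read_csv(out)
        assert list(df.columns) == ["day", "temp_c", "par_mol_m2_d"]
        assert len(df) == 30

    def test_design_writes_stratified_csv(self, tmp_path):
        out = tmp_path / "design.csv"
        result = CliRunner().invoke(
            cli_main, ["design", "--kind", "pure", "-n", "8", "--seed", "2",
                       "--out", str(out)]
        )
        assert result.exit_code == 0, result.output
        df = pd.read_csv(out)
        assert df.shape == (8, 5)
        lo, hi = PLANT_BOUNDS["h_ms"]
        assert df["H_MS"].between(lo, hi).all()

    def test_simulate_writes_outputs_and_record(self, tmp_path):
        cfg = tmp_path / "run.yaml"
        cfg.write_text(
            "kind: pure\n"
            "n_plants: 12\n"
            "climate: {n_days: 360, seed: 1}\n"
            "genotype: {h_ms: 100, phi_b: 40, lmax_b: 21, gai_c: 0.55, par_t: 0.4}\n"
        )
        outdir = tmp_path / "run"
        result = CliRunner().invoke(
            cli_main,
            ["simulate", "--config", str(cfg), "--seed", "5", "--out", str(outdir)],
        )
        assert result.exit_code == 0, result.output
        outputs = json.loads((outdir / "outputs.json").read_text())
        assert set(outputs) == {"n_ears", "l_perc", "f_tot"}
        record = load_record(outdir / "record.json")
        assert record.kind == "pure"
        assert replay_record(record) == outputs
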