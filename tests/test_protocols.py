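"""Protocol drivers: determinism, output contracts, configuration."""

import numpy as np
import pandas as pd
import pytest

from cardiomef.protocols import (ExperimentSpec, ConfigError,
                                 run_single_cell_stretch,
                                 run_ventricle_preload, save_state_h5)
from cardiomef.config import (load_config, save_config, config_hash,
                              default_hf_modifiers, build_sac_params,
                              build_cell_params, numerics)


def tiny_tissue_spec(out_dir=None):
    return ExperimentSpec(protocol="ventricle_preload", preload_percents=(0,),
                          n_rings=6, nodes_per_ring=8, tissue_duration=120.0,
                          equilibration=1000.0, out_dir=out_dir)


class TestSpecValidation:
    def test_empty_lambda_list_rejected(self):
        with pytest.raises(ConfigError):
            ExperimentSpec(lambdas=())

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ConfigError):
            ExperimentSpec(dt=0.0)


@pytest.fixture(scope="module")
def single_cell_result(tmp_path_factory):
    out = tmp_path_factory.mktemp("sc")
    spec = ExperimentSpec(lambdas=(1.0, 1.2), duration=400.0,
                          equilibration=1500.0, out_dir=str(out))
    return run_single_cell_stretch(spec), out


class TestSingleCellProtocol:
    def test_unstretched_reference_included(self, single_cell_result):
        res, _ = single_cell_result
        assert 1.0 in res["traces"]

    def test_one_trace_per_lambda_on_identical_grids(self, single_cell_result):
        res, _ = single_cell_result
        t0 = res["traces"][1.0].t
        for tr in res["traces"].values():
            np.testing.assert_array_equal(tr.t, t0)

    def test_marker_table_schema(self, single_cell_result):
        res, _ = single_cell_result
        cols = set(res["markers"].columns)
        assert {"stretch_ratio", "AT_ms", "RT_ms", "APD_ms",
                "repolarization_failed"} <= cols

    def test_outputs_carry_provenance_headers(self, single_cell_result):
        _, out = single_cell_result
        path = out / "ap_lambda_1.00.csv"
        head = path.read_text().splitlines()[:5]
        assert head[0].startswith("# cardiomef")
        assert any(line.startswith("# config_hash:") for line in head)
        df = pd.read_csv(path, comment="#")
        assert list(df.columns) == ["time_ms", "Vm_mV", "Cai_mM"]


class TestVentricleProtocol:
    def test_bit_identical_reruns(self, tmp_path):
        outs = []
        for sub in ("a", "b"):
            d = tmp_path / sub
            run_ventricle_preload(tiny_tissue_spec(str(d)), include_hf=False)
            outs.append((d / "preload_apd_table.csv").read_bytes())
        assert outs[0] == outs[1]

    def test_table_schema_with_na_for_missing_arm(self, tmp_path):
        out = run_ventricle_preload(tiny_tissue_spec(str(tmp_path)),
                                    include_hf=False)
        tab = out["table"]
        assert list(tab.columns) == ["stretch_ratio", "min_apd_control",
                                     "min_apd_hf", "max_apd_control",
                                     "max_apd_hf"]
        assert tab["min_apd_hf"].isna().all()
        text = (tmp_path / "preload_apd_table.csv").read_text()
        assert "NA" in text


class TestConfig:
    def test_default_hf_factors_match_packaged_yaml(self):
        mods = default_hf_modifiers()
        assert mods.f_ito == 0.25
        assert mods.f_inaca == 1.65
        assert not mods.is_identity

    def test_yaml_round_trip(self, tmp_path):
        cfg = {"sac": {"enabled": True, "g_sac": 0.05},
               "cell": {"g_na": 10.0},
               "numerics": {"dt": 0.01}}
        p = tmp_path / "cfg.yaml"
        save_config(cfg, p)
        back = load_config(p)
        assert back == cfg
        assert build_sac_params(back).g_sac == 0.05
        assert build_cell_params(back).g_na == 10.0
        assert numerics(back)["dt"] == 0.01

    def test_sac_disable_flag(self):
        assert build_sac_params({"sac": {"enabled": False}}) is None

    def test_unknown_keys_rejected(self):
        with pytest.raises(KeyError):
            build_cell_params({"cell": {"g_bogus": 1.0}})

    def test_config_hash_stable_and_order_independent(self):
        a = {"x": 1, "y": {"b": 2, "a": 3}}
        b = {"y": {"a": 3, "b": 2}, "x": 1}
        assert config_hash(a) == config_hash(b)
        assert config_hash(a) != config_hash({"x": 2})


class TestStateDump:
    def test_h5_round_trip(self, tmp_path):
        import h5py
        p = tmp_path / "state.h5"
        save_state_h5(p, {"vm": np.arange(5.0)}, {"dt": 0.02})
        with h5py.File(p) as h5:
            np.testing.assert_array_equal(h5["vm"][:], np.arange(5.0))
            assert h5.attrs["dt"] == 0.02


class TestCli:
    def test_fixture_command_writes_trace(self, tmp_path):
        from click.testing import CliRunner
        from cardiomef.cli import main
        out = tmp_path / "fx.csv"
        r = CliRunner().invoke(main, ["fixture", "--at", "12", "--rt", "300",
                                      "--out", str(out)])
        assert r.exit_code == 0, r.output
        df = pd.read_csv(out)
        assert {"time_ms", "Vm_mV"} == set(df.columns)

    def test_twitch_command(self, tmp_path):
        from click.testing import CliRunner
        from cardiomef.cli import main
        cai = tmp_path / "cai.csv"
        n = 5000
        t = np.arange(n) * 0.02
        pd.DataFrame({"time_ms": t,
                      "Cai_mM": 5e-5 + 8e-4 * np.exp(-0.5 * ((t - 30) / 15) ** 2)
                      }).to_csv(cai, index=False)
        out = tmp_path / "tw.csv"
        r = CliRunner().invoke(main, ["twitch", str(cai), "--out", str(out)])
        assert r.exit_code == 0, r.output
        df = pd.read_csv(out)
        assert df["force"].max() > 0.0
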