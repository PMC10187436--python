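from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import yaml

from plcdmix.workbench import (
    ConfigError,
    config_from_dict,
    config_to_dict,
    load_config,
    load_manifest,
    report,
    run_pipeline,
    save_config,
)


def toy_config_dict(**over):
    d = {
        "species": [
            {"name": "A", "type": "homopolymer", "bead_type": "A",
             "length": 4, "n_chains": 4},
            {"name": "B", "type": "homopolymer", "bead_type": "B",
             "length": 4, "n_chains": 4},
        ],
        "model": {"scenario": "equal", "e_base": -1.0},
        "box": 12,
        "init_box": 6,
        "temperatures": [1.5],
        "total_steps": 150_000,
        "sample_stride": 10_000,
        "n_replicates": 2,
        "seed": 5,
    }
    d.update(over)
    return d


def test_config_roundtrip(tmp_path):
    cfg = config_from_dict(toy_config_dict())
    path = tmp_path / "c.yaml"
    save_config(cfg, path)
    cfg2 = load_config(path)
    assert [sp.name for sp in cfg2.species] == ["A", "B"]
    assert cfg2.box == cfg.box and cfg2.total_steps == cfg.total_steps
    assert np.allclose(cfg2.model.contact_energy, cfg.model.contact_energy)


def test_config_errors_carry_field_paths():
    with pytest.raises(ConfigError, match="n_replicates"):
        config_from_dict(toy_config_dict(n_replicates=0))
    with pytest.raises(ConfigError, match=r"species\[0\]\.length"):
        d = toy_config_dict()
        del d["species"][0]["length"]
        config_from_dict(d)
    with pytest.raises(ConfigError, match="temperatures"):
        d = toy_config_dict()
        del d["temperatures"]
        config_from_dict(d)
    with pytest.raises(ConfigError, match="model"):
        config_from_dict(toy_config_dict(model={}))


def test_scenario_shortcut_config():
    cfg = config_from_dict({"scenario": "mix_equal", "scale": "mini", "seed": 1,
                            "temperatures": [14.0], "n_replicates": 2,
                            "total_steps": 1000})
    assert len(cfg.species) == 2 and cfg.total_steps == 1000


@pytest.fixture(scope="module")
def pipeline_out(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("pipe")
    manifest = run_pipeline(config_from_dict(toy_config_dict()), outdir)
    return outdir, manifest


def test_pipeline_writes_manifest_and_outputs(pipeline_out):
    outdir, manifest = pipeline_out
    assert (Path(outdir) / "manifest.yaml").exists()
    m = load_manifest(Path(outdir) / "manifest.yaml")
    assert m["seeds"] == manifest["seeds"]
    assert len(m["seeds"]) == 2  # one per replicate
    assert len(set(m["seeds"].values())) == 2  # distinct
    for key, path in m["outputs"]["trajectories"].items():
        assert Path(path).exists()
    # crosslink table always produced; this tiny hot system may be
    # single-phase, in which case the binodal is skipped with a note
    assert any(k.startswith("crosslink") for k in m["outputs"]["analysis"])
    assert "binodal" in m["outputs"]["analysis"] or m["notes"]


def test_pipeline_rerun_is_deterministic(tmp_path, pipeline_out):
    outdir1, m1 = pipeline_out
    outdir2 = tmp_path / "again"
    m2 = run_pipeline(config_from_dict(toy_config_dict()), outdir2, resume=False)
    for key in m1["outputs"]["energy_traces"]:
        b1 = Path(m1["outputs"]["energy_traces"][key]).read_bytes()
        b2 = Path(m2["outputs"]["energy_traces"][key]).read_bytes()
        assert b1 == b2


def test_pipeline_resume_reuses_trajectories(pipeline_out):
    outdir, m1 = pipeline_out
    t0 = {k: Path(v).stat().st_mtime for k, v in m1["outputs"]["trajectories"].items()}
    m2 = run_pipeline(config_from_dict(toy_config_dict()), outdir, resume=True)
    for k, v in m2["outputs"]["trajectories"].items():
        assert Path(v).stat().st_mtime == t0[k]


def test_report_renders_from_tsvs(pipeline_out, tmp_path):
    outdir, manifest = pipeline_out
    figures = report(Path(outdir) / "manifest.yaml", tmp_path / "figs")
    assert figures
    assert any(p.endswith(".png") for p in figures)


def test_report_rejects_empty_manifest(tmp_path):
    mpath = tmp_path / "m.yaml"
    with open(mpath, "w") as fh:
        yaml.safe_dump({"outputs": {"analysis": {}}}, fh)
    with pytest.raises(ValueError, match="missing"):
        report(mpath, tmp_path / "figs")


def test_cli_entrypoints(tmp_path):
    from click.testing import CliRunner
    from plcdmix.workbench import cli

    runner = CliRunner()
    cfg_path = tmp_path / "cfg.yaml"
    res = runner.invoke(cli, ["scenario", "mix_equal", "--scale", "mini",
                              "-o", str(cfg_path)])
    assert res.exit_code == 0, res.output
    assert cfg_path.exists()
    loaded = yaml.safe_load(cfg_path.read_text())
    assert loaded["temperatures"]
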