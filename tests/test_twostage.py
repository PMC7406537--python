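"""Definition files and the end-to-end two-stage driver."""

import copy

import numpy as np
import pandas as pd
import pytest

from mixls import RunConfig, load_def, run_two_stage, save_def
from mixls.errors import DataError, SpecificationError


def test_definition_file_round_trip(tmp_path):
    cfg = RunConfig(
        data="study.csv", id_column="subj", outcome="mood",
        mean=["dow", "sex"], bs_var=["sex"], ws_var=["sex", "dow"],
        random_slopes=[], ncov=2, random_scale=False, missing_code=-9.0,
        decompose=["stress"], quad_points=15, adaptive=False, tol=1e-6,
        max_iter=50, ridge=0.01, stage2_outcome="bmi",
        stage2_type="ordinal", stage2_regressors=["age", "sex"],
        interact_location=["age"], interact_slope=[],
        interact_scale=["age", "sex"], three_way=["age"],
        location_by_scale=False, suppress_interactions=False, seed=123,
        n_imputations=77, save_draws=True, out_prefix="out/run1")
    path = tmp_path / "run.def"
    save_def(cfg, path)
    assert load_def(path) == cfg            # lossless round trip
    # defaults round-trip too (None fields serialize as blank)
    save_def(RunConfig(), path)
    assert load_def(path) == RunConfig()


def test_definition_file_unknown_key(tmp_path):
    path = tmp_path / "bad.def"
    path.write_text("data = x.csv\nтурбо = 9\n")
    with pytest.raises(SpecificationError, match="unknown definition key"):
        load_def(path)


def test_run_artifacts(twostage_run):
    result, cfg = twostage_run
    arts = result["artifacts"]
    for key in ("stage1_report", "ebvar", "definition", "stage2_report"):
        assert arts[key].exists(), key
    s1 = arts["stage1_report"].read_text()
    assert "Descriptive statistics (occasion level)" in s1
    assert "Sub-model 1" in s1 and "Sub-model 3" in s1
    assert "Log Likelihood" in s1
    eb = pd.read_csv(arts["ebvar"])
    assert len(eb) == 60
    assert {"eb_Locat_1", "eb_Scale", "pv_Locat_1_Locat_1"} <= set(eb.columns)
    s2 = arts["stage2_report"].read_text()
    assert "Average Log Likelihood" in s2
    for label in ("sex", "Locat_1", "Scale*sex", "Locat_1*Scale",
                  "Residual_Variance"):
        assert label in s2
    # the definition file written alongside reproduces the configuration
    assert load_def(arts["definition"]) == cfg


def test_run_reports_are_reproducible(twostage_cfg, twostage_run, tmp_path):
    """Same configuration and seed => byte-identical reports."""
    run_cfg, _ = twostage_cfg
    result, _ = twostage_run
    cfg = copy.deepcopy(run_cfg)
    cfg.out_prefix = str(tmp_path / "again")
    result2 = run_two_stage(cfg)
    for key in ("stage1_report", "stage2_report", "ebvar"):
        assert (result["artifacts"][key].read_bytes()
                == result2["artifacts"][key].read_bytes()), key


def test_stage2_estimates_sane(twostage_run):
    result, _ = twostage_run
    res2 = result["stage2"]
    assert res2.n_imputations == 25
    # generated with positive Locat_1 and Scale effects; pooled estimates
    # should at least carry the right sign
    assert float(res2.estimate("Locat_1")["estimate"]) > 0
    assert float(res2.estimate("Scale")["estimate"]) > 0
    assert float(res2.estimate("Residual_Variance")["estimate"]) > 0
    with pytest.raises(KeyError):
        res2.estimate("nope")


def test_stage2_bypass(twostage_cfg, tmp_path):
    run_cfg, _ = twostage_cfg
    cfg = copy.deepcopy(run_cfg)
    cfg.stage2_outcome = None
    cfg.n_imputations = 2
    cfg.out_prefix = str(tmp_path / "bypass")
    result = run_two_stage(cfg)
    assert "stage2" not in result
    assert "stage2_report" not in result["artifacts"]
    assert result["artifacts"]["ebvar"].exists()


def test_save_draws_and_decompose(twostage_cfg, tmp_path):
    run_cfg, _ = twostage_cfg
    cfg = copy.deepcopy(run_cfg)
    cfg.decompose = ["dow"]
    cfg.mean = ["dow_BS", "dow_WS", "sex"]
    cfg.save_draws = True
    cfg.n_imputations = 3
    cfg.out_prefix = str(tmp_path / "dec")
    result = run_two_stage(cfg)
    draws = pd.read_csv(result["artifacts"]["draws"])
    assert len(draws) == 3 * 60
    assert {"imputation", "id", "Locat_1", "Scale"} <= set(draws.columns)


def test_failed_run_writes_log(twostage_cfg, tmp_path):
    run_cfg, _ = twostage_cfg
    cfg = copy.deepcopy(run_cfg)
    cfg.outcome = "ghost"
    cfg.out_prefix = str(tmp_path / "boom")
    with pytest.raises(DataError):
        run_two_stage(cfg)
    log = (tmp_path / "boom.log").read_text()
    assert "ghost" in log and "Traceback" in log
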