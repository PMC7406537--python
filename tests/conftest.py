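"""Shared fixtures: small simulated datasets and fitted models.

Stage-1 fits are expensive relative to the rest of the suite, so fitted
models are session-scoped and the datasets are deliberately small; every
fixture is fully seeded so the suite is deterministic.
"""

import copy

import pytest

from mixls import (RunConfig, Stage2Truth, default_mels_config,
                   default_memls_config, make_stage1_model, run_two_stage,
                   simulate_stage1, simulate_two_stage)


@pytest.fixture(scope="session")
def mels_sim():
    cfg = default_mels_config(n_subjects=80, occasions=10, seed=3)
    data, truth = simulate_stage1(cfg)
    return cfg, data, truth


@pytest.fixture(scope="session")
def mels_fit(mels_sim):
    cfg, data, _ = mels_sim
    model = make_stage1_model(data, cfg, quad_points=7)
    return model, model.fit()


@pytest.fixture(scope="session")
def memls_sim():
    cfg = default_memls_config(n_subjects=60, occasions=12, seed=5)
    data, truth = simulate_stage1(cfg)
    return cfg, data, truth


@pytest.fixture(scope="session")
def memls_fit(memls_sim):
    cfg, data, _ = memls_sim
    model = make_stage1_model(data, cfg, quad_points=7)
    return model, model.fit()


@pytest.fixture(scope="session")
def twostage_cfg(tmp_path_factory):
    """A small two-stage dataset on disk plus a matching RunConfig."""
    root = tmp_path_factory.mktemp("twostage")
    cfg = default_mels_config(
        n_subjects=60, occasions=8, seed=9,
        stage2=Stage2Truth(
            outcome="s2y", outcome_type="continuous",
            coefficients={"Intercept": 1.0, "sex": 0.5, "Locat_1": 0.8,
                          "Scale": 0.6},
            residual_sd=1.0, regressors=["sex"],
            interactions={"sex": {"location", "scale"}}))
    data, subject, _ = simulate_two_stage(cfg)
    frame = data.frame.merge(subject[["id", "s2y"]], on="id")
    csv = root / "sim.csv"
    frame.to_csv(csv, index=False)
    run_cfg = RunConfig(
        data=str(csv), id_column="id", outcome="y",
        mean=["dow", "sex"], bs_var=["sex"], ws_var=["sex"], ncov=1,
        quad_points=7,
        stage2_outcome="s2y", stage2_type="continuous",
        stage2_regressors=["sex"], interact_location=["sex"],
        interact_scale=["sex"], seed=11, n_imputations=25,
        out_prefix=str(root / "runA"))
    return run_cfg, root


@pytest.fixture(scope="session")
def twostage_run(twostage_cfg):
    run_cfg, _ = twostage_cfg
    cfg = copy.deepcopy(run_cfg)
    return run_two_stage(cfg), cfg
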