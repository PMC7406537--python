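"""Synthetic two-stage intensive-longitudinal data.

The generator reproduces the generative structure the stage-1 models assume
— subject-specific standardized location and scale effects, log-linear BS
and WS variance models, heteroscedastic normal occasion errors — plus a
subject-level stage-2 outcome driven by those effects.  Defaults emulate an
EMA-style design: several hundred subjects, a few dozen prompts each,
a time-invariant binary covariate (``sex``), a day-of-week covariate coded
0..6 (``dow``) and a weekend indicator (``weekend`` ~ Bernoulli(2/7)).

``recovery_experiment`` is the package's principal validation harness:
simulate -> fit -> score bias / RMSE / Wald coverage per parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import LongitudinalData
from .errors import SpecificationError
from .mels import MELS
from .memls import MEMLS
from .stage2 import Stage2Spec, build_stage2_design

__all__ = ["Covariate", "Stage2Truth", "SimulationConfig",
           "simulate_stage1", "simulate_stage2_outcome",
           "simulate_two_stage", "make_stage1_model", "true_param_vector",
           "recovery_experiment", "default_mels_config",
           "default_memls_config"]


@dataclass
class Covariate:
    """Covariate generator: ``kind`` in {bernoulli, uniform_int, normal},
    ``level`` in {subject, occasion}."""

    kind: str
    level: str
    params: tuple

    def draw(self, rng, size):
        if self.kind == "bernoulli":
            return rng.binomial(1, self.params[0], size).astype(float)
        if self.kind == "uniform_int":
            lo, hi = self.params
            return rng.integers(lo, hi + 1, size).astype(float)
        if self.kind == "normal":
            mu, sd = self.params
            return rng.normal(mu, sd, size)
        raise SpecificationError(f"unknown covariate kind {self.kind!r}")


@dataclass
class Stage2Truth:
    """True stage-2 model: coefficients keyed by design-column label
    (``Intercept``, regressor names, ``Locat_1``.., ``Scale``, interaction
    labels like ``Scale*age``)."""

    outcome: str = "s2y"
    outcome_type: str = "continuous"
    coefficients: dict = field(default_factory=dict)
    residual_sd: float = 1.0
    thresholds: tuple = ()      # ordinal only (K-1 increasing cutpoints)
    regressors: list = field(default_factory=list)
    interactions: dict = field(default_factory=dict)
    include_location_by_scale: bool = True

    def spec(self):
        return Stage2Spec(
            outcome=self.outcome, outcome_type=self.outcome_type,
            regressors=list(self.regressors),
            interactions=dict(self.interactions),
            include_location_by_scale=self.include_location_by_scale)


@dataclass
class SimulationConfig:
    """Generative truth for a two-stage dataset.

    For the random-intercept model set ``random_slopes=()`` and use
    ``alpha``; with slopes, ``sigma_upsilon`` (r x r covariance) and
    ``tau_ups`` (standardized-basis association) replace ``alpha`` /
    ``tau_l`` / ``tau_q``.
    """

    n_subjects: int = 500
    occasions: int = 40                  # fixed; or ("poisson", mean) min 1
    covariates: dict = field(default_factory=dict)
    beta: dict = field(default_factory=dict)        # mean model
    alpha: dict = field(default_factory=dict)       # log BS variance (MELS)
    tau: dict = field(default_factory=dict)         # log WS variance
    tau_l: float = 0.0
    tau_q: float = 0.0
    sigma_omega: float = 0.4
    random_slopes: tuple = ()
    sigma_upsilon: np.ndarray | None = None
    tau_ups: np.ndarray | None = None
    stage2: Stage2Truth | None = None
    missing_rate: float = 0.0
    missing_code: float = -999.0
    id_col: str = "id"
    outcome: str = "y"
    seed: int = 1

    @property
    def is_memls(self):
        return len(self.random_slopes) > 0

    def mean_names(self):
        return [k for k in self.beta if k != "Intercept"]

    def bs_names(self):
        return [k for k in self.alpha if k != "Intercept"]

    def ws_names(self):
        return [k for k in self.tau if k != "Intercept"]


def default_mels_config(**overrides):
    """Study-conditions default: EMA-like positive-affect generator with a
    random intercept, log-linear BS/WS variance models, a negative linear
    location effect on the WS variance and a random scale effect."""
    cfg = SimulationConfig(
        n_subjects=500, occasions=40,
        covariates={
            "sex": Covariate("bernoulli", "subject", (0.5,)),
            "dow": Covariate("uniform_int", "occasion", (0, 6)),
        },
        beta={"Intercept": 40.0, "dow": 0.4, "sex": -0.7},
        alpha={"Intercept": 4.3, "sex": -0.15},
        tau={"Intercept": 4.7, "sex": -0.05},
        tau_l=-0.15, tau_q=0.0, sigma_omega=0.4,
    )
    return replace(cfg, **overrides)


def default_memls_config(**overrides):
    """EMA-like generator with random intercept + weekend slope (unstructured
    covariance), location-scale association in the Cholesky basis, and a
    random scale effect."""
    cfg = SimulationConfig(
        n_subjects=300, occasions=40,
        covariates={
            "sex": Covariate("bernoulli", "subject", (0.5,)),
            "weekend": Covariate("bernoulli", "occasion", (2.0 / 7.0,)),
        },
        beta={"Intercept": 42.0, "weekend": 1.7, "sex": -0.7},
        tau={"Intercept": 4.7},
        random_slopes=("weekend",),
        sigma_upsilon=np.array([[72.0, -10.0], [-10.0, 14.0]]),
        tau_ups=np.array([-0.13, -0.04]),
        sigma_omega=0.4,
    )
    return replace(cfg, **overrides)


def _draw_occasions(cfg, rng):
    if isinstance(cfg.occasions, int):
        return np.full(cfg.n_subjects, cfg.occasions, dtype=int)
    kind, mean = cfg.occasions
    if kind != "poisson":
        raise SpecificationError("occasions must be an int or ('poisson', m)")
    return np.maximum(rng.poisson(mean, cfg.n_subjects), 1)


def simulate_stage1(config, seed=None):
    """Generate the occasion-level dataset and the latent truth table.

    Returns
    -------
    data : LongitudinalData
    truth : DataFrame
        Per subject: id, standardized effects (``Locat_1``.. and
        ``Scale``), and the raw location effect(s).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ni = _draw_occasions(cfg, rng)
    n = cfg.n_subjects
    rows = int(ni.sum())
    subj_idx = np.repeat(np.arange(n), ni)
    frame = pd.DataFrame({cfg.id_col: subj_idx + 1})
    for name, cov in cfg.covariates.items():
        if cov.level == "subject":
            frame[name] = cov.draw(rng, n)[subj_idx]
        else:
            frame[name] = cov.draw(rng, rows)

    def design(coefs):
        out = np.full(rows, coefs.get("Intercept", 0.0))
        for k, v in coefs.items():
            if k != "Intercept":
                out = out + v * np.asarray(frame[k], float)
        return out

    xb = design(cfg.beta)
    wt = design(cfg.tau)
    truth = {cfg.id_col: np.arange(1, n + 1)}
    if cfg.is_memls:
        r = 1 + len(cfg.random_slopes)
        Sig = np.asarray(cfg.sigma_upsilon, float)
        if Sig.shape != (r, r):
            raise SpecificationError("sigma_upsilon must be r x r")
        S = np.linalg.cholesky(Sig)
        s = rng.standard_normal((n, r))
        ups = s @ S.T                        # (n, r) raw effects
        Z = np.column_stack(
            [np.ones(rows)] + [np.asarray(frame[v], float)
                               for v in cfg.random_slopes])
        loc_part = np.einsum("nk,nk->n", Z, ups[subj_idx])
        theta_w = rng.standard_normal(n)
        tau_ups = np.zeros(r) if cfg.tau_ups is None \
            else np.asarray(cfg.tau_ups, float)
        ls2 = wt + (s @ tau_ups)[subj_idx] + cfg.sigma_omega * \
            theta_w[subj_idx]
        for k in range(r):
            truth[f"Locat_{k+1}"] = s[:, k]
            truth[f"ups_{k+1}"] = ups[:, k]
        truth["Scale"] = theta_w
    else:
        ua = design(cfg.alpha)
        theta1 = rng.standard_normal(n)
        theta_w = rng.standard_normal(n)
        ups_rows = np.exp(0.5 * ua) * theta1[subj_idx]
        loc_part = ups_rows
        ls2 = wt + cfg.tau_l * ups_rows + cfg.tau_q * ups_rows ** 2 \
            + cfg.sigma_omega * theta_w[subj_idx]
        truth["Locat_1"] = theta1
        # raw effect is occasion-varying only if alpha has covariates that
        # vary within subject; report the subject-level value
        ups_subj = np.exp(0.5 * np.array(
            [ua[subj_idx == i].mean() for i in range(n)])) * theta1
        truth["ups_1"] = ups_subj
        truth["Scale"] = theta_w
    if np.max(ls2) > 50:
        raise SpecificationError(
            "WS log-variance exceeds overflow guard (max exponent "
            f"{np.max(ls2):.1f}); rescale the variance-model coefficients")
    y = xb + loc_part + rng.standard_normal(rows) * np.exp(0.5 * ls2)
    frame[cfg.outcome] = y
    if cfg.missing_rate > 0:
        miss = rng.random(rows) < cfg.missing_rate
        frame.loc[miss, cfg.outcome] = cfg.missing_code
    cols = [cfg.id_col, cfg.outcome] + list(cfg.covariates)
    frame = frame[cols]
    if cfg.missing_rate > 0:
        keep = frame[cfg.outcome] != cfg.missing_code
        frame = frame.loc[keep].reset_index(drop=True)
    data = LongitudinalData(frame, cfg.id_col)
    return data, pd.DataFrame(truth)


def simulate_stage2_outcome(truth, config, seed=None):
    """Subject-level outcome from the latent effects.

    ``truth`` is the table from :func:`simulate_stage1` (standardized
    effects); subject-level covariates are re-derived from it by the
    caller via the data container.  Returns the outcome array.
    """
    cfg = config
    s2 = cfg.stage2
    if s2 is None:
        raise SpecificationError("config has no stage-2 truth")
    rng = np.random.default_rng(
        (cfg.seed + 104729) if seed is None else seed)
    effect_names = [c for c in truth.columns
                    if c.startswith("Locat") or c == "Scale"]
    effects = np.asarray(truth[effect_names], float)
    X, labels = build_stage2_design(truth, effects, effect_names, s2.spec())
    coefs = np.array([s2.coefficients.get(lab, 0.0) for lab in labels])
    eta = X @ coefs
    n = len(eta)
    if s2.outcome_type == "continuous":
        return eta + rng.standard_normal(n) * s2.residual_sd
    if s2.outcome_type == "dichotomous":
        pr = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        return rng.binomial(1, pr, n).astype(float)
    # ordinal proportional-odds draw
    cuts = np.asarray(s2.thresholds, float)
    u = rng.random(n)
    cdf = 1.0 / (1.0 + np.exp(-(cuts[None, :] - eta[:, None])))
    return (u[:, None] > cdf).sum(axis=1).astype(float)


def simulate_two_stage(config, seed=None):
    """Full generator: occasion data, latent truth, subject-level frame
    with the stage-2 outcome and subject-level covariates."""
    cfg = config
    data, truth = simulate_stage1(cfg, seed=seed)
    subject = data.subject_table(
        [k for k, c in cfg.covariates.items() if c.level == "subject"])
    if cfg.stage2 is not None:
        missing_truth = truth.merge(
            subject[[cfg.id_col]], on=cfg.id_col, how="right")
        for name in cfg.stage2.regressors:
            missing_truth[name] = np.asarray(subject[name], float)
        y2 = simulate_stage2_outcome(missing_truth, cfg, seed=None if
                                     seed is None else seed + 104729)
        subject[cfg.stage2.outcome] = y2
        truth = missing_truth
    return data, subject, truth


def make_stage1_model(data, config, quad_points=None, adaptive=True,
                      **kwargs):
    """Stage-1 model object matching the generative specification."""
    cfg = config
    if cfg.is_memls:
        return MEMLS(data, cfg.outcome, mean=cfg.mean_names(),
                     random_slopes=list(cfg.random_slopes),
                     ws_var=cfg.ws_names(),
                     ncov=1 if cfg.tau_ups is not None else 0,
                     quad_points=quad_points, adaptive=adaptive, **kwargs)
    qp = 11 if quad_points is None else quad_points
    ncov = 2 if cfg.tau_q != 0 else (1 if cfg.tau_l != 0 else 0)
    return MELS(data, cfg.outcome, mean=cfg.mean_names(),
                bs_var=cfg.bs_names(), ws_var=cfg.ws_names(), ncov=ncov,
                quad_points=qp, adaptive=adaptive, **kwargs)


def true_param_vector(model, config):
    """Generative truth arranged as the model's internal parameter vector."""
    cfg = config
    names = model.param_names()
    out = []
    for nm in names:
        block, _, label = nm.partition(".")
        if block == "beta":
            out.append(cfg.beta.get(label, 0.0))
        elif block == "alpha":
            out.append(cfg.alpha.get(label, 0.0))
        elif block == "tau":
            out.append(cfg.tau.get(label, 0.0))
        elif block == "tau_l":
            out.append(cfg.tau_l)
        elif block == "tau_q":
            out.append(cfg.tau_q)
        elif block == "sigma_omega":
            out.append(cfg.sigma_omega)
        elif block == "chol":
            from .memls import params_from_chol
            S = np.linalg.cholesky(np.asarray(cfg.sigma_upsilon, float))
            idx = [f"chol.{i}" for i in
                   ["".join(str(q + 1) for q in p) for p in
                    [(i, j) for i in range(S.shape[0])
                     for j in range(i + 1)]]]
            out.append(params_from_chol(S)[idx.index(nm)])
        elif block == "tau_ups":
            effect = ["Intercept"] + list(cfg.random_slopes)
            out.append(float(np.asarray(cfg.tau_ups)[effect.index(label)]))
        else:
            raise SpecificationError(f"unknown parameter block {nm!r}")
    return np.array(out, float)


def recovery_experiment(config, replicates=20, quad_points=7, seed=1,
                        max_failures=5):
    """Simulate -> fit -> score, repeated.

    Returns a DataFrame per internal parameter with the truth, mean
    estimate, bias, Monte-Carlo SE of the bias, RMSE and 95% Wald coverage,
    plus the list of per-replicate estimate vectors.  Replicates that fail
    to converge are recorded and excluded, up to ``max_failures``.
    """
    if replicates < 1:
        raise SpecificationError("need at least one replicate")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31 - 1)) or 1
             for s in ss.spawn(replicates)]
    ests, ses, fails = [], [], []
    truth = None
    names = None
    for rep, s in enumerate(seeds):
        data, _ = simulate_stage1(config, seed=s)
        model = make_stage1_model(data, config, quad_points=quad_points)
        if truth is None:
            truth = true_param_vector(model, config)
            names = model.param_names()
        try:
            res = model.fit()
        except Exception as exc:        # noqa: BLE001 — recorded, not fatal
            fails.append((rep, repr(exc)))
            if len(fails) > max_failures:
                raise
            continue
        ests.append(res.params)
        ses.append(np.sqrt(np.diag(res.asymp_cov)))
    est = np.array(ests)
    se = np.array(ses)
    k = len(est)
    lo, hi = est - 1.96 * se, est + 1.96 * se
    cover = ((lo <= truth) & (truth <= hi)).mean(axis=0)
    bias = est.mean(axis=0) - truth
    mcse = est.std(axis=0, ddof=1) / np.sqrt(k)
    rmse = np.sqrt(((est - truth) ** 2).mean(axis=0))
    report = pd.DataFrame({
        "parameter": names, "truth": truth, "mean_estimate": est.mean(axis=0),
        "bias": bias, "mc_se": mcse, "rmse": rmse, "coverage95": cover})
    report.attrs["n_replicates"] = k
    report.attrs["failures"] = fails
    report.attrs["estimates"] = est
    report.attrs["ses"] = se
    return report
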