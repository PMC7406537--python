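"""Stage-2 regression of a subject-level outcome on stage-1 random effects.

For each imputed set of plausible values a linear (continuous outcome) or
logistic/proportional-odds (dichotomous/ordinal outcome) regression is
fitted; results are pooled over imputations by Rubin's rules:

    pooled estimate = mean over imputations
    pooled variance = mean within-variance + (1 + 1/M) * between-variance

The design grammar mirrors the two-stage workflow: main effects of the
subject-level regressors, the random location effect(s) and the random
scale, per-regressor two-way interactions with location and scale, an
automatic location-by-scale interaction, and an optional three-way
regressor x intercept x scale term (three-way terms always use the random
*intercept* component).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import ConvergenceError, RankError, SpecificationError

__all__ = ["Stage2Spec", "Stage2Results", "build_stage2_design",
           "fit_linear", "fit_logistic_ordinal", "pool_rubin", "fit_stage2"]

OUTCOME_TYPES = ("continuous", "dichotomous", "ordinal")


@dataclass
class Stage2Spec:
    """Stage-2 model definition.

    ``interactions`` maps a regressor name to a set drawn from
    ``{"location", "slope", "scale", "three_way"}``: interaction with the
    random intercept, with the random slope(s), with the random scale, and
    the three-way regressor x intercept x scale term.
    """

    outcome: str
    outcome_type: str = "continuous"
    regressors: list = field(default_factory=list)
    interactions: dict = field(default_factory=dict)
    include_location_by_scale: bool = True
    include_slope_by_scale: bool = False   # advanced: Locat_k*Scale, k >= 2
    suppress_all_interactions: bool = False

    def __post_init__(self):
        if self.outcome_type not in OUTCOME_TYPES:
            raise SpecificationError(
                f"outcome_type must be one of {OUTCOME_TYPES}")
        known = {"location", "slope", "scale", "three_way"}
        for name, flags in self.interactions.items():
            if name not in self.regressors:
                raise SpecificationError(
                    f"interaction for unknown regressor {name!r}")
            bad = set(flags) - known
            if bad:
                raise SpecificationError(f"unknown interaction flags {bad}")


def build_stage2_design(subject_frame, effects, effect_names, spec):
    """One-row-per-subject design matrix for a single imputation.

    Parameters
    ----------
    subject_frame : DataFrame
        Subject-level data containing the regressors.
    effects : (N, d) array
        One imputation's random-effect values (or EB means), columns
        ordered as ``effect_names`` (``Locat_1``..``Locat_r`` then
        ``Scale``).
    """
    n = len(subject_frame)
    if effects.shape[0] != n:
        raise SpecificationError(
            "effects are not aligned with the subject table "
            f"({effects.shape[0]} vs {n} subjects)")
    loc_names = [s for s in effect_names if s.startswith("Locat")]
    has_scale = "Scale" in effect_names
    scale = effects[:, effect_names.index("Scale")] if has_scale else None
    cols, labels = [np.ones(n)], ["Intercept"]
    reg = {}
    for name in spec.regressors:
        if name not in subject_frame.columns:
            raise SpecificationError(f"unknown stage-2 regressor {name!r}")
        reg[name] = np.asarray(subject_frame[name], float)
        cols.append(reg[name])
        labels.append(name)
    wants = {name: set(spec.interactions.get(name, ()))
             for name in spec.regressors}
    if not spec.suppress_all_interactions:
        for flags in wants.values():
            if ("scale" in flags or "three_way" in flags) and not has_scale:
                raise SpecificationError(
                    "scale interactions requested but the stage-1 model "
                    "has no random scale effect")
    for k, lname in enumerate(loc_names):
        lvals = effects[:, effect_names.index(lname)]
        cols.append(lvals)
        labels.append(lname)
        if spec.suppress_all_interactions:
            continue
        flag = "location" if k == 0 else "slope"
        for name in spec.regressors:
            if flag in wants[name]:
                cols.append(lvals * reg[name])
                labels.append(f"{lname}*{name}")
    if has_scale:
        cols.append(scale)
        labels.append("Scale")
        if not spec.suppress_all_interactions:
            for name in spec.regressors:
                if "scale" in wants[name]:
                    cols.append(scale * reg[name])
                    labels.append(f"Scale*{name}")
            loc1 = effects[:, effect_names.index(loc_names[0])]
            if spec.include_location_by_scale:
                cols.append(loc1 * scale)
                labels.append(f"{loc_names[0]}*Scale")
            for name in spec.regressors:
                if "three_way" in wants[name]:
                    cols.append(loc1 * scale * reg[name])
                    labels.append(f"L*S*{name}")
            if spec.include_slope_by_scale:
                for lname in loc_names[1:]:
                    lvals = effects[:, effect_names.index(lname)]
                    cols.append(lvals * scale)
                    labels.append(f"{lname}*Scale")
    X = np.column_stack(cols)
    # collinearity screen (constant regressors etc.)
    nonint = X[:, 1:]
    if nonint.shape[1]:
        const = np.all(nonint == nonint[0:1, :], axis=0)
        if const.any():
            import warnings
            warnings.warn(
                f"stage-2 column {labels[1 + int(np.flatnonzero(const)[0])]!r}"
                " is constant (collinear with the intercept)",
                UserWarning, stacklevel=2)
    return X, labels


@dataclass
class ImputationFit:
    labels: list
    params: np.ndarray
    cov: np.ndarray
    loglik: float


def _check_rank(X, labels):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        from scipy.linalg import qr
        _, R, piv = qr(X, mode="economic", pivoting=True)
        dep = [labels[j] for j in piv[rank:]]
        raise RankError(f"stage-2 design is rank deficient; dependent "
                        f"columns: {dep}")


def fit_linear(X, y, labels=None):
    """Gaussian ML regression; appends a ``Residual_Variance`` row."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, k = X.shape
    if n <= k:
        raise SpecificationError(
            f"need more subjects ({n}) than design columns ({k})")
    labels = labels or [f"x{j}" for j in range(k)]
    _check_rank(X, labels)
    res = sm.OLS(y, X).fit()
    sigma2 = max(float(res.ssr / n), 1e-12)
    xtx_inv = np.linalg.inv(X.T @ X)
    cov = sigma2 * xtx_inv
    loglik = float(-0.5 * n * (np.log(2 * np.pi * sigma2) + res.ssr
                               / (n * sigma2)))
    params = np.append(res.params, sigma2)
    covf = np.zeros((k + 1, k + 1))
    covf[:k, :k] = cov
    covf[k, k] = 2.0 * sigma2 ** 2 / n
    return ImputationFit(labels + ["Residual_Variance"], params, covf,
                         loglik)


def fit_logistic_ordinal(X, y, labels=None, gtol=1e-8, maxiter=200):
    """Binary or proportional-odds logistic ML fit.

    Binary outcomes (2 categories) use standard logistic regression with
    the intercept column; ordinal outcomes (K >= 3) use the
    proportional-odds model, in which the intercept is absorbed into K-1
    strictly increasing thresholds (reported as ``Threshold_k``, replacing
    the Intercept row).  Categories are auto-recoded to consecutive
    integers.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    labels = labels or [f"x{j}" for j in range(X.shape[1])]
    _check_rank(X, labels)
    yr = np.round(np.asarray(y, float)).astype(int)
    if np.max(np.abs(np.asarray(y, float) - yr)) > 1e-8:
        raise SpecificationError(
            "dichotomous/ordinal outcome must be integer-coded")
    cats = np.unique(yr)
    if len(cats) < 2:
        raise SpecificationError(
            "outcome has a single observed category; a logistic model "
            "cannot be fitted — check the category coding")
    recode = {c: k for k, c in enumerate(cats)}
    yk = np.vectorize(recode.get)(yr)
    try:
        if len(cats) == 2:
            res = sm.Logit(yk, X).fit(method="newton", tol=gtol,
                                      maxiter=maxiter, disp=0)
            if not res.mle_retvals.get("converged", True):
                raise ConvergenceError(
                    "logistic regression did not converge — possible "
                    "complete separation of the outcome")
            return ImputationFit(labels, np.asarray(res.params),
                                 np.asarray(res.cov_params()),
                                 float(res.llf))
        if labels[0] != "Intercept":
            raise SpecificationError(
                "ordinal design must carry a leading intercept column "
                "(absorbed into the thresholds)")
        Xo = X[:, 1:]
        mod = OrderedModel(yk, Xo, distr="logit")
        res = mod.fit(method="bfgs", gtol=gtol, maxiter=max(maxiter, 500),
                      disp=0)
        kx = Xo.shape[1]
        params = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        # transform internal threshold parameters (t1, log-diffs) to the
        # actual strictly increasing thresholds, delta-method covariance
        kt = len(cats) - 1
        beta = params[:kx]
        tpar = params[kx:]
        thresholds = np.concatenate([[tpar[0]],
                                     tpar[0] + np.cumsum(np.exp(tpar[1:]))])
        J = np.eye(kx + kt)
        for a in range(kt):
            for b in range(1, a + 1):
                J[kx + a, kx + b] = np.exp(tpar[b])
        covt = J @ cov @ J.T
        out_params = np.concatenate([thresholds, beta])
        out_cov = np.zeros((kt + kx, kt + kx))
        out_cov[:kt, :kt] = covt[kx:, kx:]
        out_cov[kt:, kt:] = covt[:kx, :kx]
        out_cov[:kt, kt:] = covt[kx:, :kx]
        out_cov[kt:, :kt] = covt[:kx, kx:]
        out_labels = ([f"Threshold_{a+1}" for a in range(kt)]
                      + labels[1:])
        return ImputationFit(out_labels, out_params, out_cov,
                             float(res.llf))
    except PerfectSeparationError as exc:
        raise ConvergenceError(
            "complete separation detected: some combination of regressors "
            "perfectly predicts the outcome") from exc


def pool_rubin(fits):
    """Rubin's rules over per-imputation fits.

    Returns a DataFrame (name, estimate, se, z, p) plus the average
    log-likelihood and its SD across imputations.
    """
    if len(fits) < 2:
        raise SpecificationError("pooling requires at least 2 fits")
    labels = fits[0].labels
    for f in fits[1:]:
        if f.labels != labels:
            raise SpecificationError(
                "imputation fits have mismatched column labels")
    m = len(fits)
    est = np.array([f.params for f in fits])
    wvar = np.array([np.diag(f.cov) for f in fits])
    qbar = est.mean(axis=0)
    wbar = wvar.mean(axis=0)
    b = est.var(axis=0, ddof=1)
    tvar = wbar + (1.0 + 1.0 / m) * b
    se = np.sqrt(tvar)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, qbar / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame({"name": labels, "estimate": qbar, "se": se,
                          "z": z, "p": p})
    lls = np.array([f.loglik for f in fits])
    return table, float(lls.mean()), float(lls.std(ddof=1))


class Stage2Results:
    """Rubin-pooled stage-2 fit.

    Attributes
    ----------
    table : DataFrame with pooled (estimate, se, z, p) per column.
    avg_loglik, loglik_sd : mean and SD of the per-imputation
        log-likelihoods.
    aic, bic : on the ``LL - p`` / ``LL - p ln(N)/2`` convention with
        p the number of design columns and N the number of subjects.
    fits : the per-imputation fits.
    """

    def __init__(self, spec, table, avg_loglik, loglik_sd, fits, n_subjects,
                 n_design_columns):
        self.spec = spec
        self.table = table
        self.avg_loglik = avg_loglik
        self.loglik_sd = loglik_sd
        self.fits = fits
        self.n_imputations = len(fits)
        self.n_subjects = n_subjects
        p = n_design_columns
        self.aic = avg_loglik - p
        self.bic = avg_loglik - 0.5 * p * np.log(n_subjects)

    def estimate(self, name):
        rows = self.table[self.table["name"] == name]
        if len(rows) == 0:
            raise KeyError(name)
        return rows.iloc[0]

    def summary(self):
        from .report import format_stage2_results
        return format_stage2_results(self)

    def __repr__(self):
        return (f"<Stage2Results {self.spec.outcome_type}: avg loglik="
                f"{self.avg_loglik:.3f} over {self.n_imputations} "
                "imputations>")


def fit_stage2(subject_frame, draws, spec, id_col="id"):
    """Fit the stage-2 model once per imputation and pool.

    Parameters
    ----------
    subject_frame : DataFrame
        One row per subject with the outcome and regressors; must be
        aligned with (same subjects, same order as) ``draws``.
    draws : PlausibleDraws
    spec : Stage2Spec
    """
    if id_col in subject_frame.columns:
        ids = np.asarray(subject_frame[id_col])
        if len(ids) != len(draws.ids) or np.any(ids != np.asarray(draws.ids)):
            raise SpecificationError(
                "subject table and plausible draws are not aligned by ID")
    if spec.outcome not in subject_frame.columns:
        raise SpecificationError(
            f"stage-2 outcome {spec.outcome!r} not in subject table")
    y = np.asarray(subject_frame[spec.outcome], float)
    fits = []
    ncols = None
    for mdx in range(draws.n_imputations):
        X, labels = build_stage2_design(subject_frame, draws.draws[mdx],
                                        draws.names, spec)
        ncols = X.shape[1]
        if spec.outcome_type == "continuous":
            fits.append(fit_linear(X, y, labels))
        else:
            fits.append(fit_logistic_ordinal(X, y, labels))
    table, avg_ll, ll_sd = pool_rubin(fits)
    return Stage2Results(spec, table, avg_ll, ll_sd, fits,
                         n_subjects=len(subject_frame),
                         n_design_columns=ncols)
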