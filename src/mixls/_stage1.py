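"""Shared machinery for the stage-1 location-scale models.

Both stage-1 models (random intercept + random scale; multiple random
location effects + random scale) share the same estimation skeleton:

* a marginal log-likelihood over standardized random effects theta ~ N(0, I),
  approximated by tensor Gauss–Hermite quadrature; in adaptive mode each
  objective evaluation recenters/rescales every subject's nodes at the
  posterior mean/covariance of theta, iterated to a fixed point (moment
  adaption stays smooth in the parameters and tolerates multimodal
  posteriors, unlike mode-based adaption);
* a chain of three nested submodels — (1) the standard multilevel model,
  (2) + WS-variance covariates and location-association terms, (3) + random
  scale — each warm-started from the previous one;
* Wald summaries from the inverse negated finite-difference Hessian of the
  analytic score at the MLE;
* empirical-Bayes posterior moments of the standardized effects computed as
  normalized quadrature-weighted moments on the final adapted grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (ConvergenceError, NumericError, RankError,
                     SpecificationError)
from .optimize import fd_hessian, newton_maximize
from .quadrature import FrozenGrid, adapt_grid, prior_grid

__all__ = ["Stage1Results", "EBEstimates", "wald_summaries"]

_SD_FLOOR = 1e-3  # positivity floor for the random-scale SD


class AdaptionDiverged(Exception):
    """Internal: the moment-adaption fixed point failed to converge."""


def wald_summaries(estimates, cov):
    """Per-parameter (se, z, p) from an asymptotic covariance matrix."""
    diag = np.diag(cov)
    if np.any(diag < 0):
        raise NumericError(
            "negative diagonal in the asymptotic covariance — the "
            "information matrix is not positive definite (a symptom of "
            "non-convergence or a boundary solution)")
    se = np.sqrt(diag)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, estimates / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return se, z, p


@dataclass
class EBEstimates:
    """Per-subject posterior moments of the standardized random effects."""

    ids: np.ndarray
    means: np.ndarray          # (N, d)
    covs: np.ndarray           # (N, d, d)
    n_obs: np.ndarray          # (N,)
    names: list                # d component labels, location(s) then scale

    @property
    def n_subjects(self):
        return len(self.ids)

    @property
    def dim(self):
        return self.means.shape[1]

    def to_frame(self):
        """ebvar-style table: ID, posterior means, lower-triangle posterior
        covariances, n_i."""
        out = {"id": self.ids}
        for k, name in enumerate(self.names):
            out[f"eb_{name}"] = self.means[:, k]
        for i in range(self.dim):
            for j in range(i + 1):
                out[f"pv_{self.names[i]}_{self.names[j]}"] = self.covs[:, i, j]
        out["n_obs"] = self.n_obs
        return pd.DataFrame(out)

    def save(self, path):
        self.to_frame().to_csv(path, index=False)


def posterior_moments(l_cond, grid):
    """Normalized quadrature moments of a posterior.

    Parameters
    ----------
    l_cond : (N, Q) array
        Conditional log-likelihood of each subject's data at each node
        (all-zero rows give back the prior moments).
    grid : FrozenGrid

    Returns
    -------
    means (N, d), covs (N, d, d)
    """
    a = grid.logw + l_cond
    m = a.max(axis=1, keepdims=True)
    if not np.all(np.isfinite(m)):
        bad = int(np.flatnonzero(~np.isfinite(m[:, 0]))[0])
        raise NumericError(
            f"all quadrature weights underflowed for subject index {bad}")
    w = np.exp(a - m)
    w /= w.sum(axis=1, keepdims=True)
    nodes = np.broadcast_to(grid.nodes, (len(l_cond),) + grid.nodes.shape[1:])
    means = np.einsum("nq,nqd->nd", w, nodes)
    second = np.einsum("nq,nqd,nqe->nde", w, nodes, nodes)
    covs = second - np.einsum("nd,ne->nde", means, means)
    covs = 0.5 * (covs + np.transpose(covs, (0, 2, 1)))
    return means, covs


@dataclass
class _GridCache:
    """A frozen grid together with its row-expanded node views."""

    grid: FrozenGrid
    theta_rows: np.ndarray     # (rows, Q, d)
    logw: np.ndarray           # (N or 1, Q)


class Stage1Results:
    """Maximum-likelihood fit of a stage-1 location-scale model.

    Attributes
    ----------
    params : ndarray
        Internal parameter vector (see ``model.param_names(stage)``).
    loglik, aic, bic : float
        Maximized marginal log-likelihood and the information criteria on
        the ``LL - p`` / ``LL - p ln(N)/2`` convention (N = subjects).
    asymp_cov : ndarray
        Inverse of the negated observed information at the MLE (internal
        parameterization).
    table : pandas.DataFrame
        Reported parameter table (section, name, estimate, se, z, p); for
        models with a random-effect covariance matrix the entries are the
        variances/covariances with delta-method standard errors.
    submodel_chain : list of Stage1Results
        The nested submodel fits, in fitting order (final fit last).
    """

    def __init__(self, model, stage, params, loglik, asymp_cov, info,
                 grid_cache):
        self.model = model
        self.stage = stage
        self.stage_label = stage["label"]
        self.params = np.asarray(params, float)
        self.loglik = float(loglik)
        self.asymp_cov = asymp_cov
        self.converged = info["converged"]
        self.iterations = info["iterations"]
        self.grad_norm = info["grad_norm"]
        self._grid_cache = grid_cache
        self.n_subjects = model.data.n_subjects
        self.n_obs = model.data.n_obs
        p = len(self.params)
        self.df_model = p
        self.aic = self.loglik - p
        self.bic = self.loglik - 0.5 * p * np.log(self.n_subjects)
        self.table = model._param_table(stage, self.params, asymp_cov)
        self.submodel_chain = [self]
        self._eb = None

    # -- convenience lookups ----------------------------------------------
    def estimate(self, name, section=None):
        """Reported estimate by row name (optionally disambiguated by
        section); returns the table row as a Series."""
        t = self.table
        sel = t["name"] == name
        if section is not None:
            sel &= t["section"] == section
        rows = t[sel]
        if len(rows) == 0:
            raise KeyError(name)
        return rows.iloc[0]

    @property
    def se(self):
        return np.asarray(self.table["se"])

    @property
    def zvalues(self):
        return np.asarray(self.table["z"])

    @property
    def pvalues(self):
        return np.asarray(self.table["p"])

    def empirical_bayes(self):
        """EB posterior means/covariances of the standardized effects."""
        if self._eb is None:
            self._eb = self.model._empirical_bayes(
                self.params, self.stage, self._grid_cache)
        return self._eb

    def save_ebvar(self, path):
        self.empirical_bayes().save(path)

    def summary(self):
        from .report import format_stage1_results
        return format_stage1_results(self)

    def __repr__(self):
        return (f"<Stage1Results {self.stage_label}: loglik={self.loglik:.3f}"
                f", {self.df_model} params, converged={self.converged}>")


class BaseLocationScaleModel:
    """Common estimation engine; subclasses define the parameterization."""

    def __init__(self, data, outcome, ws_var=(), quad_points=11,
                 adaptive=True, tol=1e-5, ll_tol=1e-6, max_iter=100,
                 ridge=0.0, random_scale=True):
        self.data = data
        self.outcome = outcome
        self.y = data.column(outcome)
        self.ws_var = list(ws_var)
        self.W = data.design(self.ws_var)
        self.quad_points = int(quad_points)
        self.adaptive = bool(adaptive)
        if self.adaptive and self.quad_points < 7:
            warnings.warn(
                "fewer than 7 adaptive quadrature points per dimension: "
                "the quadrature error is then sensitive to the grid "
                "placement, which biases the score and can impede "
                "convergence; use at least 7 points for estimation",
                UserWarning, stacklevel=3)
        self.tol = tol
        self.ll_tol = ll_tol
        self.max_iter = max_iter
        self.ridge = ridge
        self.random_scale = bool(random_scale)
        self._starts = data.row_starts
        self._ni = data.occasions_per_subject
        self._subj_idx = np.repeat(np.arange(data.n_subjects), self._ni)

    # -- subclass interface -------------------------------------------------
    def _stages(self):
        raise NotImplementedError

    def _start_params(self, stage_index, previous):
        raise NotImplementedError

    def _eval(self, params, stage, cache, want_grad):
        raise NotImplementedError

    def _cond_loglik_rows(self, params, stage, theta_rows):
        raise NotImplementedError

    def _param_table(self, stage, params, cov):
        raise NotImplementedError

    # -- design validation ---------------------------------------------------
    def _check_design(self, M, names, what):
        if M.shape[1] == 0:
            return
        if M.shape[1] > 1:
            nonint = M[:, 1:]
            const = np.all(nonint == nonint[0:1, :], axis=0)
            if const.any():
                k = int(np.flatnonzero(const)[0])
                raise RankError(
                    f"{what} regressor {names[k]!r} is constant across the "
                    "dataset (collinear with the intercept)")
        if np.linalg.matrix_rank(M) < M.shape[1]:
            raise RankError(f"{what} design matrix is rank deficient "
                            "(collinear regressors)")

    # -- grid handling -------------------------------------------------------
    def _cache(self, grid):
        nodes = grid.nodes
        if grid.per_subject():
            theta_rows = nodes[self._subj_idx]
        else:
            theta_rows = np.broadcast_to(
                nodes, (self.data.n_obs,) + nodes.shape[1:])
        return _GridCache(grid, theta_rows, grid.logw)

    def _repeat_rows(self, per_subject):
        return np.repeat(per_subject, self._ni, axis=0)

    def _moments(self, params, stage, cache):
        """Posterior moments of theta on the cache's grid."""
        logf = self._cond_loglik_rows(params, stage, cache.theta_rows)
        l_iq = np.add.reduceat(logf, self._starts, axis=0)
        return posterior_moments(l_iq, cache.grid)

    def _grid_at(self, params, stage, base, warm=None, max_cycles=50,
                 tol=1e-9, adaptive=None, strict=False):
        """Adapted grid for ``params``: recenter/rescale each subject's
        nodes at the posterior mean/covariance, iterated to a fixed point.

        Moment-based adaption (rather than mode-based) stays smooth in the
        parameters and degrades gracefully when a subject's posterior is
        multimodal — the grid then straddles the modes instead of latching
        onto one of them.  ``warm`` carries the previous fixed point so
        nearby parameter values re-adapt in a cycle or two.
        """
        if not (self.adaptive if adaptive is None else adaptive):
            return self._cache(base), None
        if warm is None:
            means, covs = self._moments(params, stage, self._cache(base))
        else:
            means, covs = warm
        for _ in range(max_cycles):
            cache = self._cache(adapt_grid(base, means, covs))
            new_means, new_covs = self._moments(params, stage, cache)
            delta = max(float(np.max(np.abs(new_means - means))),
                        float(np.max(np.abs(new_covs - covs))))
            means, covs = new_means, new_covs
            if delta < tol:
                break
        else:
            if strict and delta > 1e-3:
                # the fixed point diverges here (typically an extreme
                # association parameter makes a posterior that the grid
                # chases into the tail): the quadrature value would be
                # meaningless, so signal the caller to reject the point
                raise AdaptionDiverged(delta)
        cache = self._cache(adapt_grid(base, means, covs))
        return cache, (means, covs)

    # -- public likelihood ----------------------------------------------------
    def loglike(self, params, quad_points=None, adaptive=None):
        """Marginal log-likelihood of the *final* (full) submodel at
        ``params`` (see :meth:`param_names` for the ordering)."""
        params = np.asarray(params, float)
        if not np.all(np.isfinite(params)):
            raise SpecificationError("non-finite parameter value")
        stage = self._stages()[-1]
        if len(params) != stage["n_params"]:
            raise SpecificationError(
                f"expected {stage['n_params']} parameters, got {len(params)}")
        qp = self.quad_points if quad_points is None else int(quad_points)
        ad = self.adaptive if adaptive is None else bool(adaptive)
        base = prior_grid(qp, stage["dim"])
        cache, _ = self._grid_at(params, stage, base, adaptive=ad)
        ll, _ = self._eval(params, stage, cache, want_grad=False)
        return ll

    def score(self, params, quad_points=None, adaptive=None):
        """Analytic score of the final submodel (frozen-grid objective)."""
        params = np.asarray(params, float)
        stage = self._stages()[-1]
        qp = self.quad_points if quad_points is None else int(quad_points)
        ad = self.adaptive if adaptive is None else bool(adaptive)
        base = prior_grid(qp, stage["dim"])
        cache, _ = self._grid_at(params, stage, base, adaptive=ad)
        return self._eval(params, stage, cache, want_grad=True)[1]

    def param_names(self, stage=None):
        stage = self._stages()[-1] if stage is None else stage
        return list(stage["names"])

    # -- fitting ----------------------------------------------------------------
    def fit(self, max_outer=60):
        """Fit the three-submodel chain; returns the final fit with
        ``submodel_chain`` holding all fitted submodels in order."""
        chain = []
        prev = None
        for si, stage in enumerate(self._stages()):
            x0 = self._start_params(si, prev)
            res = self._fit_stage(stage, x0, max_outer)
            chain.append(res)
            prev = res
        final = chain[-1]
        final.submodel_chain = chain
        return final

    def _fit_stage(self, stage, x0, max_outer):
        lower = stage.get("lower")
        x = np.asarray(x0, float)
        qp = self.quad_points
        # escalation loop: a grid this coarse can admit several
        # self-consistent adapted placements in some regions, which makes
        # the approximate objective discontinuous there and can trap the
        # optimizer on an artifact; refining the grid removes the
        # multiplicity, so a stalled fit is retried with more points
        for attempt in range(3):
            x, ll, info, cache = self._run_newton(stage, x, qp, lower)
            if info["converged"]:
                break
            qp += 4
            warnings.warn(
                f"{stage['label']}: optimizer stalled at {qp - 4} "
                f"quadrature points per dimension; retrying with {qp}",
                UserWarning, stacklevel=3)
        else:
            raise ConvergenceError(
                f"{stage['label']} did not converge even after refining "
                f"the quadrature grid to {qp - 4} points per dimension "
                f"(projected gradient norm {info['grad_norm']:.3g})",
                params=x, grad_norm=info["grad_norm"],
                iterations=info["iterations"])
        info["quad_points"] = qp
        asymp_cov = self._invert_information(
            fd_hessian(lambda p: self._eval(p, stage, cache,
                                            want_grad=True)[1], x))
        return Stage1Results(self, stage, x, ll, asymp_cov, info, cache)

    def _run_newton(self, stage, x0, qp, lower):
        base = prior_grid(qp, stage["dim"])
        x = np.asarray(x0, float)
        cache, _ = self._grid_at(x, stage, base)
        hess_grad = None
        if not self.adaptive:
            def fun(p):
                return self._eval(p, stage, cache, want_grad=False)[0]

            def grad(p):
                return self._eval(p, stage, cache, want_grad=True)[1]

        else:
            # fully adaptive objective: every evaluation recenters the grid
            # at the posterior moments under the candidate parameters.  The
            # fixed point is always reached from the prior-centered cold
            # start so the objective is a deterministic function of the
            # parameters — warm-starting from whatever grid the previous
            # evaluation left behind is faster but history-dependent: in
            # regions with several self-consistent grid placements it can
            # land on a spurious one and feed the line search values from
            # different attractors.  The analytic score treats the freshly
            # adapted nodes as fixed; the neglected adaption-movement term
            # is second-order small at quadrature convergence.  The FD
            # Hessian reuses the most recent grid (no re-adaption) — the
            # optimizer's damping absorbs that approximation.
            holder = {"cache": cache}

            def _adapted(p, want_grad):
                c, _ = self._grid_at(p, stage, base, max_cycles=200,
                                     strict=True)
                holder["cache"] = c
                return self._eval(p, stage, c, want_grad=want_grad)

            def fun(p):
                try:
                    return _adapted(p, False)[0]
                except AdaptionDiverged:
                    return -np.inf   # reject the candidate in line search

            def grad(p):
                try:
                    return _adapted(p, True)[1]
                except AdaptionDiverged:
                    # current iterate was reachable, so its stored grid is
                    # a valid (frozen) fallback for the gradient
                    return self._eval(p, stage, holder["cache"],
                                      want_grad=True)[1]

            def hess_grad(p):
                return self._eval(p, stage, holder["cache"],
                                  want_grad=True)[1]

        x, ll, info = newton_maximize(
            fun, grad, x, tol=self.tol, ll_tol=self.ll_tol,
            max_iter=self.max_iter, ridge=self.ridge, lower=lower,
            hess_grad=hess_grad, on_fail="return")
        if self.adaptive:
            cache, _ = self._grid_at(x, stage, base, max_cycles=200)
        return x, ll, info, cache

    def _invert_information(self, hessian):
        neg = -hessian
        try:
            cov = np.linalg.inv(neg)
        except np.linalg.LinAlgError:
            raise RankError(
                "singular information matrix at the solution — check for "
                "collinear regressors or a variance parameter on its "
                "boundary") from None
        if np.any(np.diag(cov) <= 0):
            warnings.warn(
                "information matrix not positive definite (likely a "
                "boundary solution); using a pseudo-inverse for standard "
                "errors", UserWarning, stacklevel=2)
            evals, evecs = np.linalg.eigh(0.5 * (neg + neg.T))
            evals = np.clip(evals, 1e-10, None)
            cov = (evecs / evals) @ evecs.T
        return cov

    # -- empirical Bayes ---------------------------------------------------------
    def _empirical_bayes(self, params, stage, cache):
        logf = self._cond_loglik_rows(params, stage, cache.theta_rows)
        l_iq = np.add.reduceat(logf, self._starts, axis=0)
        means, covs = posterior_moments(l_iq, cache.grid)
        return EBEstimates(
            ids=self.data.subject_ids, means=means, covs=covs,
            n_obs=self._ni.copy(), names=stage["effect_names"])

    def empirical_bayes(self, params, quad_points=None):
        """EB posteriors of the full model at user-supplied parameters."""
        params = np.asarray(params, float)
        stage = self._stages()[-1]
        qp = self.quad_points if quad_points is None else int(quad_points)
        base = prior_grid(qp, stage["dim"])
        cache, _ = self._grid_at(params, stage, base)
        return self._empirical_bayes(params, stage, cache)


def ols_start(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def variance_decomposition(resid, starts, ni):
    """Moment-based split of residual variance into BS and WS parts."""
    subj_mean = np.add.reduceat(resid, starts) / ni
    within = resid - np.repeat(subj_mean, ni)
    vw = max(float(within @ within / max(len(resid) - len(ni), 1)), 1e-4)
    vb = max(float(np.var(subj_mean, ddof=1) - vw / np.mean(ni)), 1e-2 * vw)
    return vb, vw


SD_FLOOR = _SD_FLOOR
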