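"""Mixed-effects multiple location-scale model (random intercept + slopes
+ random scale).

The model for occasion j of subject i is

    y_ij = x_ij' beta + z_ij' ups_i + eps_ij,   eps_ij ~ N(0, s2_eps_ij)
    ups_i = S s_i,   s_i ~ N(0, I_r),   Sigma_ups = S S'
    s2_eps_ij = exp(w_ij' tau + tau_ups' s_i + sigma_omega * theta_i),
    theta_i ~ N(0, 1)

with r = 1 + #random slopes location effects whose unstructured covariance
is parameterized by its Cholesky factor S (log-diagonal internally), and an
optional association between location and scale acting on the standardized
(Cholesky-basis) effects s_i (the NCOV option: 0 none, 1 association).
Reported "Random (location) Effect Variances and Covariances" are entries of
Sigma_ups with delta-method standard errors.  BS variances cannot be
modeled by covariates when random slopes are present.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._stage1 import (BaseLocationScaleModel, SD_FLOOR, ols_start,
                      variance_decomposition, wald_summaries)
from .errors import SpecificationError
from .optimize import fd_hessian  # noqa: F401  (re-exported for diagnostics)
from .quadrature import LOG2PI

__all__ = ["MEMLS"]


def _tri_indices(r):
    """Row-major lower-triangle index pairs: (0,0),(1,0),(1,1),..."""
    return [(i, j) for i in range(r) for j in range(i + 1)]


def chol_from_params(s_params, r):
    """Lower-triangular factor from the internal vector (log-diagonal)."""
    S = np.zeros((r, r))
    for v, (i, j) in zip(s_params, _tri_indices(r)):
        S[i, j] = np.exp(v) if i == j else v
    return S


def params_from_chol(S):
    r = S.shape[0]
    return np.array([np.log(S[i, i]) if i == j else S[i, j]
                     for i, j in _tri_indices(r)])


class MEMLS(BaseLocationScaleModel):
    """Mixed-effects multiple location-scale model.

    Parameters
    ----------
    data : LongitudinalData
    outcome : str
    mean : sequence of str
        Mean-model regressors (intercept implied).
    random_slopes : sequence of str
        Level-1 regressors with subject-specific slopes; the random
        intercept is always included, so r = 1 + len(random_slopes).
    ws_var : sequence of str
        Log WS-variance regressors (intercept implied).
    ncov : {0, 1}
        Association between the standardized location effects and the log
        WS variance.
    quad_points : int or None
        Points per dimension; default 11 for 2 integration dimensions and
        7 for 3 (grid-size policy).
    """

    MAX_DIM = 3

    def __init__(self, data, outcome, mean=(), random_slopes=(), ws_var=(),
                 ncov=1, random_scale=True, quad_points=None, adaptive=True,
                 tol=1e-5, ll_tol=1e-6, max_iter=100, ridge=0.0):
        if ncov not in (0, 1):
            raise SpecificationError("ncov must be 0 or 1 for MEMLS")
        if not random_slopes:
            raise SpecificationError(
                "MEMLS requires at least one random-slope regressor; use "
                "MELS for a random-intercept-only model")
        self.slope_names = list(random_slopes)
        r = 1 + len(self.slope_names)
        dim = r + (1 if random_scale else 0)
        if dim > self.MAX_DIM:
            raise SpecificationError(
                f"{dim} integration dimensions exceed the supported "
                f"{self.MAX_DIM}; reduce the number of random slopes or "
                "disable random scale")
        if quad_points is None:
            quad_points = 11 if dim <= 2 else 7
        super().__init__(data, outcome, ws_var=ws_var,
                         quad_points=quad_points, adaptive=adaptive, tol=tol,
                         ll_tol=ll_tol, max_iter=max_iter, ridge=ridge,
                         random_scale=random_scale)
        self.ncov = int(ncov)
        self.r = r
        self.mean_names = list(mean)
        self.X = data.design(self.mean_names)
        self.Z = data.design(self.slope_names)
        self._check_design(self.X, self.mean_names, "mean")
        self._check_design(self.Z, self.slope_names, "random-slope")
        self._check_design(self.W, self.ws_var, "WS-variance")

    # ------------------------------------------------------------------ stages
    def _stages(self):
        px, nt_full, r = self.X.shape[1], self.W.shape[1], self.r
        ns = r * (r + 1) // 2
        beta_names = ["Intercept"] + self.mean_names
        effect = ["Intercept"] + self.slope_names

        def stage(label, n_tau, ncov, scale):
            n = px + ns + n_tau + (r if ncov else 0) + (1 if scale else 0)
            names = [f"beta.{s}" for s in beta_names]
            names += [f"chol.{i+1}{j+1}" for i, j in _tri_indices(r)]
            names += [f"tau.{s}"
                      for s in (["Intercept"] + self.ws_var)[:n_tau]]
            if ncov:
                names += [f"tau_ups.{s}" for s in effect]
            if scale:
                names.append("sigma_omega")
            lower = None
            if scale:
                lower = np.full(n, -np.inf)
                lower[-1] = SD_FLOOR
            return {
                "label": label, "n_params": n, "names": names, "px": px,
                "ns": ns, "n_tau": n_tau, "ncov": ncov, "scale": scale,
                "dim": r + (1 if scale else 0), "r": r, "lower": lower,
                "effect_names": [f"Locat_{k+1}" for k in range(r)]
                + (["Scale"] if scale else []),
            }

        stages = [
            stage("submodel 1 (standard multilevel model)", 1, 0, False),
            stage("submodel 2 (+ WS-variance covariates / association)",
                  nt_full, self.ncov, False),
        ]
        if self.random_scale:
            stages.append(stage("submodel 3 (+ random scale)",
                                nt_full, self.ncov, True))
        return stages

    def _unpack(self, params, stage):
        px, ns, nt, r = stage["px"], stage["ns"], stage["n_tau"], stage["r"]
        k = 0
        beta = params[k:k + px]; k += px
        S = chol_from_params(params[k:k + ns], r); k += ns
        tau = params[k:k + nt]; k += nt
        tau_ups = np.zeros(r)
        if stage["ncov"]:
            tau_ups = params[k:k + r]; k += r
        sw = params[k] if stage["scale"] else 0.0
        return beta, S, tau, tau_ups, sw

    def _start_params(self, stage_index, previous):
        stages = self._stages()
        stage = stages[stage_index]
        r = stage["r"]
        if stage_index == 0:
            beta = ols_start(self.X, self.y)
            resid = self.y - self.X @ beta
            vb, vw = variance_decomposition(resid, self._starts, self._ni)
            S = np.zeros((r, r))
            S[0, 0] = np.sqrt(vb)
            for k in range(1, r):
                S[k, k] = 0.5 * np.sqrt(vw)
            return np.concatenate([beta, params_from_chol(S), [np.log(vw)]])
        prev = previous.params
        prev_stage = stages[stage_index - 1]
        px, ns = stage["px"], stage["ns"]
        head = prev[:px + ns]
        tau_prev = prev[px + ns:px + ns + prev_stage["n_tau"]]
        tau = np.zeros(stage["n_tau"])
        tau[:len(tau_prev)] = tau_prev
        out = [head, tau]
        k = px + ns + prev_stage["n_tau"]
        if stage["ncov"]:
            if prev_stage["ncov"]:
                out.append(prev[k:k + r])
            else:
                out.append(np.zeros(r))
        if stage["scale"]:
            out.append([0.1])
        return np.concatenate(out)

    # --------------------------------------------------------------- likelihood
    def _pieces(self, params, stage, theta_rows):
        beta, S, tau, tau_ups, sw = self._unpack(params, stage)
        r = stage["r"]
        s_loc = theta_rows[..., :r]                      # (rows, Q, r)
        M = self.Z @ S                                   # (rows, r)
        mu = (self.X @ beta)[:, None] + np.einsum("nk,nqk->nq", M, s_loc)
        ls2 = np.broadcast_to(
            (self.W[:, :stage["n_tau"]] @ tau)[:, None], mu.shape).copy()
        if stage["ncov"]:
            ls2 += np.einsum("k,nqk->nq", tau_ups, s_loc)
        if stage["scale"]:
            ls2 += sw * theta_rows[..., r]
        resid = self.y[:, None] - mu
        ls2 = np.clip(ls2, -650.0, 650.0)
        inv_s2 = np.exp(-ls2)
        e = np.minimum(resid * resid * inv_s2, 1e12)
        logf = -0.5 * (LOG2PI + ls2 + e)
        return dict(beta=beta, S=S, tau=tau, tau_ups=tau_ups, sw=sw, M=M,
                    s_loc=s_loc, resid=resid, inv_s2=inv_s2, e=e, logf=logf)

    def _cond_loglik_rows(self, params, stage, theta_rows):
        return self._pieces(params, stage, theta_rows)["logf"]

    def _eval(self, params, stage, cache, want_grad):
        pz = self._pieces(params, stage, cache.theta_rows)
        l_iq = np.add.reduceat(pz["logf"], self._starts, axis=0)
        a = cache.logw + l_iq
        m = a.max(axis=1, keepdims=True)
        expa = np.exp(a - m)
        ssum = expa.sum(axis=1)
        ll = float((m[:, 0] + np.log(ssum)).sum())
        if not want_grad:
            return ll, None
        r = stage["r"]
        p_iq = expa / ssum[:, None]
        P = self._repeat_rows(p_iq)
        d_mu = pz["resid"] * pz["inv_s2"]
        d_ls = 0.5 * (pz["e"] - 1.0)
        PF = P * d_mu
        PD = P * d_ls
        s_loc = pz["s_loc"]
        g = [self.X.T @ PF.sum(axis=1)]
        # Cholesky block: dmu/dS_kl = Z_k * s_l, chain exp for the diagonal
        T = np.einsum("nq,nqk->nk", PF, s_loc)          # (rows, r)
        GS = self.Z.T @ T                                # (r, r)
        S = pz["S"]
        g_chol = [GS[i, j] * (S[i, i] if i == j else 1.0)
                  for i, j in _tri_indices(r)]
        g.append(g_chol)
        g.append(self.W[:, :stage["n_tau"]].T @ PD.sum(axis=1))
        if stage["ncov"]:
            g.append(np.einsum("nq,nqk->k", PD, s_loc))
        if stage["scale"]:
            g.append([float((PD * cache.theta_rows[..., r]).sum())])
        return ll, np.concatenate([np.atleast_1d(np.asarray(v, float))
                                   for v in g])

    # ------------------------------------------------------------------ report
    def sigma_upsilon(self, params=None, stage=None):
        """Random location-effect covariance matrix Sigma = S S'."""
        stage = self._stages()[-1] if stage is None else stage
        if params is None:
            raise SpecificationError("params required")
        _, S, *_ = self._unpack(np.asarray(params, float), stage)
        return S @ S.T

    def _param_table(self, stage, params, cov):
        se, z, p = wald_summaries(params, cov)
        px, ns, nt, r = stage["px"], stage["ns"], stage["n_tau"], stage["r"]
        effect = ["Intercept"] + self.slope_names
        rows = []
        for k, name in enumerate(["Intercept"] + self.mean_names):
            rows.append(("BETA (regression coefficients)", name,
                         params[k], se[k], z[k], p[k]))
        # delta method: vech(Sigma) from the internal Cholesky block
        _, S, *_ = self._unpack(params, stage)
        tri = _tri_indices(r)

        def vech_sigma(sp):
            Sm = chol_from_params(sp, r)
            Sig = Sm @ Sm.T
            return np.array([Sig[i, j] for i, j in tri])

        sp = params[px:px + ns]
        h = 1e-6
        J = np.empty((ns, ns))
        for k in range(ns):
            e = np.zeros(ns)
            e[k] = h * max(1.0, abs(sp[k]))
            J[:, k] = (vech_sigma(sp + e) - vech_sigma(sp - e)) / (2 * e[k])
        cov_s = cov[px:px + ns, px:px + ns]
        var_sig = np.diag(J @ cov_s @ J.T)
        sig = vech_sigma(sp)
        se_sig = np.sqrt(np.maximum(var_sig, 0.0))
        from scipy import stats as _st
        for k, (i, j) in enumerate(tri):
            name = effect[i] if i == j else f"Covariance{j+1}{i+1}"
            zz = sig[k] / se_sig[k] if se_sig[k] > 0 else 0.0
            rows.append(("Random (location) Effect Variances and Covariances",
                         name, sig[k], se_sig[k], zz,
                         2 * _st.norm.sf(abs(zz))))
        for k in range(nt):
            idx = px + ns + k
            rows.append(("TAU (WS variance parameters: log-linear model)",
                         (["Intercept"] + self.ws_var)[k],
                         params[idx], se[idx], z[idx], p[idx]))
        k0 = px + ns + nt
        if stage["ncov"]:
            for k in range(r):
                idx = k0 + k
                rows.append((
                    "Random location effects on WS variance "
                    "(log-linear model)", effect[k],
                    params[idx], se[idx], z[idx], p[idx]))
            k0 += r
        if stage["scale"]:
            rows.append(("Random scale standard deviation", "Std Dev",
                         params[k0], se[k0], z[k0], p[k0]))
        return pd.DataFrame(
            rows, columns=["section", "name", "estimate", "se", "z", "p"])
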