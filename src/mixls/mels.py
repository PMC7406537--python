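"""Mixed-effects location-scale model (random intercept + random scale).

The model for occasion j of subject i is

    y_ij = x_ij' beta + ups_ij + eps_ij,      eps_ij ~ N(0, s2_eps_ij)
    ups_ij = exp(u_ij' alpha / 2) * theta_1i,  theta_1i ~ N(0, 1)
    s2_eps_ij = exp(w_ij' tau + tau_l*ups_ij + tau_q*ups_ij^2
                    + sigma_omega * theta_2i),  theta_2i ~ N(0, 1)

i.e. log-linear sub-models for the between-subject (BS) and within-subject
(WS) variances, an optional linear/quadratic effect of the location effect
on the WS variance (the NCOV option: 0 none, 1 linear, 2 linear+quadratic),
and a random scale effect giving each subject their own WS variance.  The
exponential links keep both variances strictly positive.  Effects are
integrated out over their standardized N(0,1) representation, which keeps
the quadrature grid parameter-free and accommodates an occasion-varying
BS-variance design.

Estimation is maximum likelihood via Newton–Raphson with moment-adaptive
Gauss–Hermite quadrature (see ``_stage1``), fitting three nested submodels
in sequence, each warm-starting the next.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._stage1 import (BaseLocationScaleModel, SD_FLOOR, ols_start,
                      variance_decomposition, wald_summaries)
from .errors import SpecificationError
from .quadrature import LOG2PI

__all__ = ["MELS"]


class MELS(BaseLocationScaleModel):
    """Mixed-effects location-scale model.

    Parameters
    ----------
    data : LongitudinalData
    outcome : str
        Level-1 (time-varying) outcome variable.
    mean, bs_var, ws_var : sequences of str
        Regressor names for the mean, the log BS variance, and the log WS
        variance; an intercept is implied in each.
    ncov : {0, 1, 2}
        Association of the random location effect with the WS variance:
        none, linear, or linear + quadratic.
    random_scale : bool
        Include the random scale effect (default True).  When False the fit
        stops after the second submodel.
    quad_points : int
        Gauss–Hermite points per dimension (default 11).
    adaptive : bool
        Recenter/rescale the grid at each subject's posterior mode
        (default True).
    """

    def __init__(self, data, outcome, mean=(), bs_var=(), ws_var=(),
                 ncov=1, random_scale=True, quad_points=11, adaptive=True,
                 tol=1e-5, ll_tol=1e-6, max_iter=100, ridge=0.0):
        super().__init__(data, outcome, ws_var=ws_var,
                         quad_points=quad_points, adaptive=adaptive, tol=tol,
                         ll_tol=ll_tol, max_iter=max_iter, ridge=ridge,
                         random_scale=random_scale)
        if ncov not in (0, 1, 2):
            raise SpecificationError("ncov must be 0, 1 or 2 for MELS")
        self.ncov = int(ncov)
        self.mean_names = list(mean)
        self.bs_var_names = list(bs_var)
        self.X = data.design(self.mean_names)
        self.U = data.design(self.bs_var_names)
        self._check_design(self.X, self.mean_names, "mean")
        self._check_design(self.U, self.bs_var_names, "BS-variance")
        self._check_design(self.W, self.ws_var, "WS-variance")
        if outcome in data.level2_names:
            raise SpecificationError(
                f"outcome {outcome!r} is time-invariant; the stage-1 outcome "
                "must vary within subjects")

    # ------------------------------------------------------------------ stages
    def _stages(self):
        px, pu, pw = self.X.shape[1], self.U.shape[1], self.W.shape[1]
        beta_names = ["Intercept"] + self.mean_names
        alpha_names = ["Intercept"] + self.bs_var_names
        tau_names = ["Intercept"] + self.ws_var

        def stage(label, n_tau, ncov, scale):
            n = px + pu + n_tau + (1 if ncov >= 1 else 0) \
                + (1 if ncov == 2 else 0) + (1 if scale else 0)
            names = ([f"beta.{s}" for s in beta_names]
                     + [f"alpha.{s}" for s in alpha_names]
                     + [f"tau.{s}" for s in tau_names[:n_tau]])
            if ncov >= 1:
                names.append("tau_l")
            if ncov == 2:
                names.append("tau_q")
            if scale:
                names.append("sigma_omega")
            lower = None
            if scale:
                lower = np.full(n, -np.inf)
                lower[-1] = SD_FLOOR
            return {
                "label": label, "n_params": n, "names": names,
                "px": px, "pu": pu, "n_tau": n_tau, "ncov": ncov,
                "scale": scale, "dim": 2 if scale else 1, "lower": lower,
                "effect_names": ["Locat_1", "Scale"] if scale else ["Locat_1"],
            }

        stages = [
            stage("submodel 1 (standard multilevel model)", 1, 0, False),
            stage("submodel 2 (+ WS-variance covariates / association)",
                  pw, self.ncov, False),
        ]
        if self.random_scale:
            stages.append(stage("submodel 3 (+ random scale)",
                                pw, self.ncov, True))
        return stages

    def _unpack(self, params, stage):
        px, pu, nt = stage["px"], stage["pu"], stage["n_tau"]
        k = 0
        beta = params[k:k + px]; k += px
        alpha = params[k:k + pu]; k += pu
        tau = params[k:k + nt]; k += nt
        tau_l = tau_q = 0.0
        if stage["ncov"] >= 1:
            tau_l = params[k]; k += 1
        if stage["ncov"] == 2:
            tau_q = params[k]; k += 1
        sw = params[k] if stage["scale"] else 0.0
        return beta, alpha, tau, tau_l, tau_q, sw

    def _start_params(self, stage_index, previous):
        stages = self._stages()
        stage = stages[stage_index]
        if stage_index == 0:
            beta = ols_start(self.X, self.y)
            resid = self.y - self.X @ beta
            vb, vw = variance_decomposition(resid, self._starts, self._ni)
            alpha = np.zeros(stage["pu"])
            alpha[0] = np.log(vb)
            return np.concatenate([beta, alpha, [np.log(vw)]])
        prev = previous.params
        px, pu = stage["px"], stage["pu"]
        beta = prev[:px]
        alpha = prev[px:px + pu]
        prev_stage = stages[stage_index - 1]
        tau_prev = prev[px + pu:px + pu + prev_stage["n_tau"]]
        tau = np.zeros(stage["n_tau"])
        tau[:len(tau_prev)] = tau_prev
        out = [beta, alpha, tau]
        k = px + pu + prev_stage["n_tau"]
        if stage["ncov"] >= 1:
            out.append([prev[k]] if prev_stage["ncov"] >= 1 else [0.0])
            if prev_stage["ncov"] >= 1:
                k += 1
        if stage["ncov"] == 2:
            out.append([prev[k]] if prev_stage["ncov"] == 2 else [0.0])
        if stage["scale"]:
            out.append([0.1])
        return np.concatenate(out)

    # --------------------------------------------------------------- likelihood
    def _pieces(self, params, stage, theta_rows):
        beta, alpha, tau, tau_l, tau_q, sw = self._unpack(params, stage)
        th1 = theta_rows[..., 0]
        c = np.exp(0.5 * (self.U @ alpha))
        ups = c[:, None] * th1
        mu = (self.X @ beta)[:, None] + ups
        ls2 = (self.W[:, :stage["n_tau"]] @ tau)[:, None] + np.zeros_like(ups)
        if stage["ncov"] >= 1:
            ls2 += tau_l * ups
        if stage["ncov"] == 2:
            ls2 += tau_q * ups * ups
        if stage["scale"]:
            ls2 = ls2 + sw * theta_rows[..., 1]
        r = self.y[:, None] - mu
        # overflow guard: nodes this far out carry no posterior weight
        ls2 = np.clip(ls2, -650.0, 650.0)
        inv_s2 = np.exp(-ls2)
        e = np.minimum(r * r * inv_s2, 1e12)
        logf = -0.5 * (LOG2PI + ls2 + e)
        return dict(beta=beta, alpha=alpha, tau=tau, tau_l=tau_l, tau_q=tau_q,
                    sw=sw, c=c, ups=ups, r=r, inv_s2=inv_s2, e=e, logf=logf)

    def _cond_loglik_rows(self, params, stage, theta_rows):
        return self._pieces(params, stage, theta_rows)["logf"]

    def _eval(self, params, stage, cache, want_grad):
        pz = self._pieces(params, stage, cache.theta_rows)
        l_iq = np.add.reduceat(pz["logf"], self._starts, axis=0)
        a = cache.logw + l_iq
        m = a.max(axis=1, keepdims=True)
        expa = np.exp(a - m)
        s = expa.sum(axis=1)
        ll = float((m[:, 0] + np.log(s)).sum())
        if not want_grad:
            return ll, None
        p_iq = expa / s[:, None]
        P = self._repeat_rows(p_iq)
        d_mu = pz["r"] * pz["inv_s2"]
        d_ls = 0.5 * (pz["e"] - 1.0)
        PF = P * d_mu
        PD = P * d_ls
        ups = pz["ups"]
        g = [self.X.T @ PF.sum(axis=1)]
        if stage["ncov"] >= 1:
            dl_dups = d_mu + d_ls * (pz["tau_l"] + 2.0 * pz["tau_q"] * ups)
        else:
            dl_dups = d_mu
        g.append(self.U.T @ (0.5 * (P * dl_dups * ups).sum(axis=1)))
        g.append(self.W[:, :stage["n_tau"]].T @ PD.sum(axis=1))
        if stage["ncov"] >= 1:
            g.append([float((PD * ups).sum())])
        if stage["ncov"] == 2:
            g.append([float((PD * ups * ups).sum())])
        if stage["scale"]:
            g.append([float((PD * cache.theta_rows[..., 1]).sum())])
        return ll, np.concatenate(g)

    # ------------------------------------------------------------------ report
    def _param_table(self, stage, params, cov):
        se, z, p = wald_summaries(params, cov)
        px, pu, nt = stage["px"], stage["pu"], stage["n_tau"]
        sections, names = [], []
        sections += ["BETA (regression coefficients)"] * px
        names += ["Intercept"] + self.mean_names
        sections += ["ALPHA (BS variance parameters: log-linear model)"] * pu
        names += ["Intercept"] + self.bs_var_names
        sections += ["TAU (WS variance parameters: log-linear model)"] * nt
        names += (["Intercept"] + self.ws_var)[:nt]
        if stage["scale"]:
            # keep printed ordering: Std Dev before the association rows
            pass
        rows = pd.DataFrame({
            "section": sections, "name": names,
            "estimate": params[:px + pu + nt],
            "se": se[:px + pu + nt], "z": z[:px + pu + nt],
            "p": p[:px + pu + nt]})
        extra = []
        k = px + pu + nt
        if stage["scale"]:
            ks = stage["n_params"] - 1
            extra.append(("Random scale standard deviation", "Std Dev", ks))
        if stage["ncov"] >= 1:
            extra.append(("Random location (mean) effect on WS variance",
                          "Loc Eff", k))
            k += 1
        if stage["ncov"] == 2:
            extra.append(("Random location (mean) effect on WS variance",
                          "Loc Eff^2", k))
        more = pd.DataFrame(
            [{"section": s, "name": n, "estimate": params[i], "se": se[i],
              "z": z[i], "p": p[i]} for s, n, i in extra])
        return pd.concat([rows, more], ignore_index=True)
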