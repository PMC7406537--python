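"""Gauss–Hermite quadrature over standardized normal random effects.

The stage-1 marginal likelihood integrates the conditional likelihood over
standardized effects theta ~ N(0, I_d).  A *frozen grid* holds node locations
and log-weights such that

    L_i = sum_q exp(logw_iq + l_cond_i(theta_iq))

where l_cond is the conditional (given theta) log-likelihood of subject i's
data.  Because the effects are standardized the prior density is absorbed
into the weights, so a frozen grid makes L_i an exact, smooth function of
the model parameters — gradients taken with the grid fixed are exact.

Adaptive grids recenter and rescale the prior grid at each subject's
posterior mean/covariance with the usual change-of-variables weight
correction; this is the moment-based adaption scheme of classic
mixed-model quadrature fitters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import roots_hermitenorm

LOG2PI = np.log(2.0 * np.pi)

__all__ = ["gh_rule", "prior_grid", "adapt_grid", "FrozenGrid", "LOG2PI"]


def gh_rule(n_points):
    """1-D Gauss–Hermite nodes/weights for expectations under N(0,1)."""
    z, w = roots_hermitenorm(int(n_points))
    return z, w / np.sqrt(2.0 * np.pi)


@dataclass
class FrozenGrid:
    """Quadrature nodes (n_groups_or_1, Q, d) and log-weights (same leading
    shape, Q).  A leading axis of 1 means the grid is shared by all subjects
    (non-adaptive)."""

    nodes: np.ndarray
    logw: np.ndarray

    @property
    def n_points(self):
        return self.nodes.shape[1]

    @property
    def dim(self):
        return self.nodes.shape[2]

    def per_subject(self):
        return self.nodes.shape[0] > 1


def prior_grid(n_points, dim):
    """Tensor-product grid for theta ~ N(0, I_dim)."""
    z, w = gh_rule(n_points)
    logw1 = np.log(w)
    nodes = np.array(list(itertools.product(z, repeat=dim)))  # (Q, d)
    logw = np.zeros(len(nodes))
    for k, combo in enumerate(itertools.product(range(len(z)), repeat=dim)):
        logw[k] = logw1[list(combo)].sum()
    return FrozenGrid(nodes[None, :, :], logw[None, :])


def adapt_grid(base, centers, covs, jitter=1e-8):
    """Recenter/rescale a prior grid at per-subject posterior locations.

    Parameters
    ----------
    base : FrozenGrid
        Prior grid from :func:`prior_grid` (shared, leading axis 1).
    centers : (N, d) array
        Posterior means (or modes) of the standardized effects.
    covs : (N, d, d) array
        Posterior covariance approximations; clipped to be SPD.

    Returns
    -------
    FrozenGrid with per-subject nodes theta_iq = m_i + A_i z_q and
    log-weights  logw_q + log|A_i| - (|theta_iq|^2 - |z_q|^2)/2,
    which leaves  sum_q exp(logw) * exp(l_cond)  an approximation of
    E_{theta~N(0,I)}[exp(l_cond(theta))].
    """
    z = base.nodes[0]            # (Q, d)
    logw = base.logw[0]          # (Q,)
    n, d = centers.shape
    covs = np.asarray(covs, float).copy()
    # symmetrize + eigenvalue floor so Cholesky always exists
    covs = 0.5 * (covs + np.transpose(covs, (0, 2, 1)))
    evals, evecs = np.linalg.eigh(covs)
    evals = np.clip(evals, jitter, None)
    covs = np.einsum("nij,nj,nkj->nik", evecs, evals, evecs)
    A = np.linalg.cholesky(covs)                     # (N, d, d)
    nodes = centers[:, None, :] + np.einsum("nij,qj->nqi", A, z)
    logdetA = np.log(np.diagonal(A, axis1=1, axis2=2)).sum(axis=1)  # (N,)
    sq = (nodes ** 2).sum(axis=2)                    # (N, Q)
    sqz = (z ** 2).sum(axis=1)                       # (Q,)
    logW = logw[None, :] + logdetA[:, None] - 0.5 * (sq - sqz[None, :])
    return FrozenGrid(nodes, logW)
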