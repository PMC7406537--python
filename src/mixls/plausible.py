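"""Plausible-value resampling of subject random effects.

Point estimates of subject random effects (EB posterior means) understate
their uncertainty; using them as fixed stage-2 regressors makes stage-2
standard errors too small.  Instead, M sets of "plausible values" are drawn
from each subject's multivariate-normal EB posterior and the stage-2 model
is fitted once per imputed set, with Rubin's rules pooling the results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SpecificationError

__all__ = ["PlausibleDraws", "draw_plausible_values", "SEED_MIN", "SEED_MAX"]

SEED_MIN, SEED_MAX = 1, 65000


@dataclass
class PlausibleDraws:
    """M multivariate-normal draws of each subject's random effects.

    ``draws`` has shape (M, N, d) — imputation x subject x effect, effects
    ordered as in the source EB estimates (locations, then scale).
    """

    draws: np.ndarray
    ids: np.ndarray
    names: list
    seed: int

    @property
    def n_imputations(self):
        return self.draws.shape[0]

    def to_frame(self):
        """Long-format table: imputation, ID, effect columns."""
        m, n, d = self.draws.shape
        out = {"imputation": np.repeat(np.arange(1, m + 1), n),
               "id": np.tile(self.ids, m)}
        flat = self.draws.reshape(m * n, d)
        for k, name in enumerate(self.names):
            out[name] = flat[:, k]
        return pd.DataFrame(out)

    def save(self, path):
        self.to_frame().to_csv(path, index=False)


def _psd_cholesky(covs):
    """Batched Cholesky with eigenvalue clipping for indefinite inputs."""
    covs = 0.5 * (covs + np.transpose(covs, (0, 2, 1)))
    try:
        return np.linalg.cholesky(covs)
    except np.linalg.LinAlgError:
        warnings.warn(
            "posterior covariance not positive semi-definite for at least "
            "one subject; repaired by clipping eigenvalues at zero",
            UserWarning, stacklevel=3)
        evals, evecs = np.linalg.eigh(covs)
        evals = np.clip(evals, 0.0, None)
        repaired = np.einsum("nij,nj,nkj->nik", evecs, evals, evecs)
        # reconstruction error leaves ~1e-16-scale negative eigenvalues and
        # exact zeros break cholesky: add a relative jitter
        scale = np.maximum(np.abs(evals).max(axis=1), 1.0)
        repaired += (1e-12 * scale)[:, None, None] * np.eye(covs.shape[1])
        return np.linalg.cholesky(repaired)


def draw_plausible_values(eb, n_imputations=500, seed=1):
    """Draw M plausible values per subject from the EB posteriors.

    Parameters
    ----------
    eb : EBEstimates
    n_imputations : int
        M >= 2; 500 is recommended for stable pooled results.
    seed : int
        Master seed in [1, 65000].  One sub-stream per imputation is
        spawned deterministically, so draws do not depend on subject
        iteration order and identical seeds give identical draws.
    """
    if n_imputations < 2:
        raise SpecificationError("need at least 2 imputations")
    if not (SEED_MIN <= int(seed) <= SEED_MAX):
        raise SpecificationError(
            f"seed must lie in [{SEED_MIN}, {SEED_MAX}]")
    n, d = eb.means.shape
    covs = np.asarray(eb.covs, float)
    zero = np.all(covs == 0.0, axis=(1, 2))
    L = np.zeros_like(covs)
    if not zero.all():
        L[~zero] = _psd_cholesky(covs[~zero])
    children = np.random.SeedSequence(int(seed)).spawn(int(n_imputations))
    draws = np.empty((int(n_imputations), n, d))
    for m, ss in enumerate(children):
        z = np.random.default_rng(ss).standard_normal((n, d))
        draws[m] = eb.means + np.einsum("nij,nj->ni", L, z)
    return PlausibleDraws(draws=draws, ids=np.asarray(eb.ids),
                          names=list(eb.names), seed=int(seed))
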