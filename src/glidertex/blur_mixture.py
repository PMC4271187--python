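"""Blur rejection: two-component Gaussian mixture over the 9-D statistics.

Photographic ensembles mix in-focus patches with patches blurred by camera
motion or defocus.  Blur saturates the second- and fourth-order glider
coordinates, so the two populations separate cleanly in the 9-D coordinate
space and can be recovered by a two-component Gaussian mixture fitted with
EM.  The in-focus component is identified as the one whose mean is closer
to the origin in the (beta, alpha) sub-coordinates, and patches are
hard-assigned by maximum posterior responsibility.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import multivariate_normal
from sklearn.mixture import GaussianMixture

__all__ = ["MixtureModel", "fit_mixture", "classify_patches"]

# indices of the beta and alpha coordinates within the 9-D (gamma-free) vector
_BETA_ALPHA = np.array([0, 1, 2, 3, 8])


@dataclass
class MixtureModel:
    weights: np.ndarray  # (2,)
    means: np.ndarray  # (2, 9)
    covariances: np.ndarray  # (2, 9, 9)
    in_focus_index: int
    log_likelihood: float = float("nan")
    converged: bool = True

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "means": self.means.tolist(),
                "covariances": self.covariances.tolist(),
                "in_focus_index": self.in_focus_index,
                "log_likelihood": self.log_likelihood,
            }
        )


def fit_mixture(
    vectors: np.ndarray,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_init: int = 10,
) -> MixtureModel:
    """Maximum-likelihood 2-component Gaussian mixture (EM, multi-start).

    The best of ``n_init`` seeded restarts by log-likelihood is kept.
    Near-singular component covariances are ridge-regularized by
    1e-6 x trace(cov)/9 (with a warning).  The in-focus component is the
    one whose mean has the smaller Euclidean norm restricted to the
    (beta, alpha) sub-coordinates; blur inflates exactly those coordinates.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2:
        raise ValueError("vectors must be (n, d)")
    n, d = vectors.shape
    if n < 20:
        raise ValueError(f"need at least 20 vectors to fit a mixture, got {n}")

    data_cov_trace = np.trace(np.cov(vectors.T, ddof=0)) if d > 1 else vectors.var()
    reg = 1e-6 * data_cov_trace / d
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        tol=tol,
        max_iter=max_iter,
        n_init=n_init,
        reg_covar=max(reg, 1e-12),
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(vectors)
    if not gm.converged_:
        raise RuntimeError(
            f"EM did not converge in {max_iter} iterations "
            f"(lower bound {gm.lower_bound_:.6g}); increase max_iter or tol"
        )
    min_eig = min(np.linalg.eigvalsh(c).min() for c in gm.covariances_)
    if min_eig < 10 * reg:
        warnings.warn("near-singular component covariance; ridge regularization active")

    ba = gm.means_[:, _BETA_ALPHA] if d == 9 else gm.means_
    in_focus = int(np.argmin(np.linalg.norm(ba, axis=1)))
    return MixtureModel(
        weights=gm.weights_.copy(),
        means=gm.means_.copy(),
        covariances=gm.covariances_.copy(),
        in_focus_index=in_focus,
        log_likelihood=float(gm.lower_bound_ * n),
        converged=bool(gm.converged_),
    )


def responsibilities(model: MixtureModel, vectors: np.ndarray) -> np.ndarray:
    """Posterior component probabilities, shape (n, 2)."""
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    logp = np.stack(
        [
            np.log(model.weights[k])
            + np.atleast_1d(
                multivariate_normal.logpdf(
                    vectors, mean=model.means[k], cov=model.covariances[k],
                    allow_singular=True,
                )
            )
            for k in range(2)
        ],
        axis=1,
    )
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    return p / p.sum(axis=1, keepdims=True)


def classify_patches(
    model: MixtureModel, vectors: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hard-assign patches; return (in_focus_mask, in_focus_subset).

    Ties in posterior responsibility (probability exactly 0.5) go to the
    in-focus component.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    resp = responsibilities(model, vectors)
    in_focus = resp[:, model.in_focus_index] >= 0.5
    return in_focus, vectors[in_focus]
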