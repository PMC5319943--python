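"""Multivariate-Gaussian heartbeat synthesis.

A subject's genuine beats X (n x k) are modelled as draws from N(mu, Sigma)
with mu the column means and Sigma the sample covariance; synthetic beats
are drawn from that distribution to enlarge the genuine class.  With the
baseline of n = 20 real beats and k = 200 dimensions the sample covariance
is rank-deficient (rank <= n - 1); sampling goes through the
eigendecomposition x = mu + V sqrt(L) z, which needs no inversion and keeps
every draw inside the affine span of the data.  An optional ridge
(shrinkage) term restores full-rank spread when wanted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import HeartbeatMatrix

_EIG_TOL = 1e-10  # relative eigenvalue cutoff for the recorded rank


@dataclass
class GaussianHeartbeatModel:
    mu: np.ndarray  # (k,) mV
    Sigma: np.ndarray  # (k, k) symmetric PSD
    rank: int
    shrinkage: float
    # cached eigendecomposition (V, sqrt(L)) for sampling
    _eigvecs: np.ndarray | None = None
    _sqrt_eigvals: np.ndarray | None = None

    @property
    def k(self) -> int:
        return len(self.mu)


def fit_gaussian(X, shrinkage: float = 0.0) -> GaussianHeartbeatModel:
    """mu = column means; Sigma = sample covariance + shrinkage ridge.

    The ridge is `shrinkage * mean(diag(S)) * I`, so shrinkage is a
    dimensionless fraction of the average per-sample variance.
    """
    beats = getattr(X, "beats", X)
    beats = np.atleast_2d(np.asarray(beats, dtype=float))
    n, k = beats.shape
    if n < 2:
        raise ValueError("fit_gaussian needs at least 2 observations")
    if shrinkage < 0:
        raise ValueError("shrinkage must be >= 0")
    mu = beats.mean(axis=0)
    dev = beats - mu
    Sigma = dev.T @ dev / (n - 1)
    if shrinkage > 0:
        Sigma = Sigma + shrinkage * float(np.mean(np.diag(Sigma))) * np.eye(k)
    Sigma = 0.5 * (Sigma + Sigma.T)
    eigvals, eigvecs = np.linalg.eigh(Sigma)
    eigvals = np.clip(eigvals, 0.0, None)
    top = float(eigvals.max(initial=0.0))
    # eigenvalues at numerical-noise level are treated as exact zeros so
    # rank-deficient models sample strictly inside their affine span
    eigvals[eigvals <= _EIG_TOL * max(top, 1e-300)] = 0.0
    rank = int(np.sum(eigvals > 0.0))
    return GaussianHeartbeatModel(
        mu=mu, Sigma=Sigma, rank=rank, shrinkage=float(shrinkage),
        _eigvecs=eigvecs, _sqrt_eigvals=np.sqrt(eigvals))


def sample_heartbeats(model: GaussianHeartbeatModel, count: int,
                      seed) -> HeartbeatMatrix:
    """Draw `count` beats x = mu + V sqrt(L) z with z iid standard normal.

    `seed` may be an integer or a numpy Generator; passing a Generator lets
    successive calls continue one RNG stream, so splitting a total draw
    into consecutive calls yields the same beats as one big call.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if model._eigvecs is None or model._sqrt_eigvals is None:
        eigvals, eigvecs = np.linalg.eigh(model.Sigma)
        eigvals = np.clip(eigvals, 0.0, None)
        top = float(eigvals.max(initial=0.0))
        eigvals[eigvals <= _EIG_TOL * max(top, 1e-300)] = 0.0
        model._sqrt_eigvals = np.sqrt(eigvals)
        model._eigvecs = eigvecs
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    k = model.k
    z = rng.standard_normal((count, k))
    beats = model.mu + (z * model._sqrt_eigvals) @ model._eigvecs.T
    return HeartbeatMatrix(beats.reshape(count, k))
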