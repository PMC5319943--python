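"""One-class Gaussian-mixture model of normal heartbeats.

A GMM with M components (M=2 by default) is fitted by EM to a pool of
normal beats; any beat whose negative log-likelihood under the mixture
exceeds a threshold calibrated on the training pool is classified abnormal
and removed.  Each decision depends only on the trained model and the beat
itself, so the rule is online and subject-invariant.

Covariances are diagonal by default: with k = 200 sample dimensions and a
few hundred beats, full covariances are singular; a full-covariance mode
with ridge regularisation is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class GaussianComponent:
    """One weighted k-dimensional Gaussian density."""

    weight: float
    mean: np.ndarray  # (k,) mV
    cov: np.ndarray  # (k, k) symmetric PSD (diagonal matrix in "diag" mode)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("component weight must lie in [0, 1]")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")


@dataclass
class GMMModel:
    components: list
    M: int
    k: int
    train_loglik_trace: np.ndarray = field(
        default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        w = sum(c.weight for c in self.components)
        if abs(w - 1.0) > 1e-8:
            raise ValueError("component weights must sum to 1")


@dataclass(frozen=True)
class OutlierDecisionRule:
    threshold: float  # negative log-likelihood cutoff
    calibration_percentile: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


def _log_density(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log of the k-dimensional Gaussian density, via Cholesky."""
    X = np.atleast_2d(X)
    k = mean.shape[0]
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "covariance is singular after regularisation; "
            "increase the ridge or use diagonal covariances") from exc
    dev = X - mean
    sol = np.linalg.solve(L, dev.T)  # (k, n); L is triangular

    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (k * _LOG2PI + logdet + maha)


def component_density(x: np.ndarray, comp: GaussianComponent) -> float:
    """Gaussian density p(x, mu, C) evaluated in log space internally."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != comp.mean.shape[0]:
        raise ValueError("dimension mismatch between x and component")
    return float(np.exp(_log_density(x, comp.mean, comp.cov)[0]))


def _diag_loglik(X, means, vars_, log_w):
    """(n, M) matrix of log w_m + log N(x | mu_m, diag var_m)."""
    n, k = X.shape
    out = np.empty((n, len(log_w)))
    for m in range(len(log_w)):
        dev = X - means[m]
        out[:, m] = (log_w[m]
                     - 0.5 * (k * _LOG2PI + np.sum(np.log(vars_[m]))
                              + np.sum(dev**2 / vars_[m], axis=1)))
    return out


def em_fit(X, M: int = 2, seed: int = 0, tol: float = 1e-6,
           max_iter: int = 200, covariance: str = "diag",
           ridge: float = 1e-6) -> GMMModel:
    """Fit an M-component GMM by EM (responsibility-weighted updates).

    Initialisation: kmeans++-seeded means, uniform weights, pooled
    variances.  Iterates until the relative training log-likelihood gain
    falls below `tol` or `max_iter` is reached; the per-iteration mean
    log-likelihood trace is recorded on the model.
    """
    beats = getattr(X, "beats", X)
    beats = np.atleast_2d(np.asarray(beats, dtype=float))
    n, k = beats.shape
    if not np.all(np.isfinite(beats)):
        raise ValueError("training beats must be finite")
    if n < M:
        raise ValueError(f"need at least M={M} observations, got {n}")
    if covariance not in ("diag", "full"):
        raise ValueError("covariance must be 'diag' or 'full'")

    rng = np.random.default_rng(seed)
    if M == 1:
        means = beats.mean(axis=0, keepdims=True)
    else:
        means, _ = kmeans_plusplus(
            beats, n_clusters=M,
            random_state=int(rng.integers(0, 2**31 - 1)))
    pooled = beats.var(axis=0) + 1e-12
    var_floor = 1e-6 * float(pooled.mean())
    vars_ = np.tile(np.maximum(pooled, var_floor), (M, 1))
    weights = np.full(M, 1.0 / M)

    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        # E-step: responsibilities from the previous iteration's parameters
        log_joint = _diag_loglik(beats, means, vars_, np.log(weights))
        log_norm = logsumexp(log_joint, axis=1)
        resp = np.exp(log_joint - log_norm[:, None])  # (n, M)
        ll = float(np.mean(log_norm))
        trace.append(ll)

        # M-step: responsibility-weighted weight/mean/variance updates
        nk = resp.sum(axis=0) + 1e-300
        weights = nk / n
        means = (resp.T @ beats) / nk[:, None]
        for m in range(M):
            dev = beats - means[m]
            vars_[m] = np.maximum(
                (resp[:, m] @ dev**2) / nk[m], var_floor)

        if ll - prev < tol * max(1.0, abs(ll)) and len(trace) > 1:
            break
        prev = ll

    if covariance == "full":
        comps = []
        for m in range(M):
            dev = beats - means[m]
            nkm = resp[:, m].sum() + 1e-300
            cov = (resp[:, m][:, None] * dev).T @ dev / nkm
            lam = ridge * float(np.mean(np.diag(cov)) + 1e-12)
            comps.append(GaussianComponent(
                float(weights[m]), means[m], cov + lam * np.eye(k)))
    else:
        comps = [GaussianComponent(float(weights[m]), means[m],
                                   np.diag(vars_[m])) for m in range(M)]
    return GMMModel(comps, M=M, k=k, train_loglik_trace=np.asarray(trace))


def model_log_likelihood(model: GMMModel, x) -> float | np.ndarray:
    """log P(x) of the mixture (log-sum-exp over weighted components)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.k:
        raise ValueError(f"x has dimension {X.shape[1]}, model expects {model.k}")
    per_comp = np.column_stack([
        np.log(c.weight + 1e-300) + _log_density(X, c.mean, c.cov)
        for c in model.components])
    out = logsumexp(per_comp, axis=1)
    return float(out[0]) if single else out


def calibrate_rule(model: GMMModel, X_train,
                   percentile: float = 0.95) -> OutlierDecisionRule:
    """Threshold at the given percentile of training negative log-likelihoods."""
    beats = getattr(X_train, "beats", X_train)
    beats = np.atleast_2d(np.asarray(beats, dtype=float))
    if beats.size == 0:
        raise ValueError("X_train must be nonempty")
    if not 0.0 <= percentile <= 1.0:
        raise ValueError("percentile must be in [0, 1]")
    nll = -model_log_likelihood(model, beats)
    return OutlierDecisionRule(float(np.quantile(nll, percentile)), percentile)


def classify_beats(model: GMMModel, rule: OutlierDecisionRule, X) -> np.ndarray:
    """True where a beat is abnormal: -log P(x) above the calibrated cutoff."""
    beats = getattr(X, "beats", X)
    beats = np.atleast_2d(np.asarray(beats, dtype=float))
    nll = -model_log_likelihood(model, beats)
    return nll > rule.threshold
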