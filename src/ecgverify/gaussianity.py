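"""Univariate and multivariate normality testing, and greedy subset search.

The univariate test is Shapiro-Wilk with Royston's AS R94 coefficient and
p-value approximations.  The multivariate test is Royston's H: each
variable's W statistic is mapped through a normalising transformation to an
approximately chi-square-distributed quantity R_j, and the R_j are averaged
and rescaled by an equivalent degrees of freedom e that discounts the
average inter-variable correlation.  Under multivariate normality H is
approximately chi-square with e degrees of freedom.

Sequential Forward Selection (SFS) looks for a maximal subset of variables
that jointly passes the multivariate test: variables failing the univariate
test at the chosen level are excluded outright, then variables are added
greedily, each step keeping the candidate that maximises the Royston
p-value of the enlarged subset, until no candidate keeps the subset at or
above the significance level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ShapiroWilkResult:
    W: float
    p_value: float
    n: int


@dataclass(frozen=True)
class RoystonResult:
    R_values: np.ndarray  # per-variable transformed statistics
    H: float
    e: float  # equivalent degrees of freedom
    C: float  # average correlation quantity
    p_value: float


@dataclass(frozen=True)
class SFSTrace:
    steps: list  # ordered (variable index, subset p-value) pairs
    selected: tuple
    alpha: float


# ---------------------------------------------------------------------------
# Shapiro-Wilk (AS R94)
# ---------------------------------------------------------------------------

def _sw_weights(n: int) -> np.ndarray:
    """AS R94 approximation to the optimal order-statistic weights."""
    m = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    mm = float(m @ m)
    c = m / np.sqrt(mm)
    u = 1.0 / np.sqrt(n)
    a = np.empty(n)
    if n == 3:
        a[:] = [-np.sqrt(0.5), 0.0, np.sqrt(0.5)]
        return a
    an = (-2.706056 * u**5 + 4.434685 * u**4 - 2.071190 * u**3
          - 0.147981 * u**2 + 0.221157 * u + c[-1])
    if n <= 5:
        phi = (mm - 2.0 * m[-1] ** 2) / (1.0 - 2.0 * an**2)
        a[1:-1] = m[1:-1] / np.sqrt(phi)
        a[-1] = an
        a[0] = -an
    else:
        an1 = (-3.582633 * u**5 + 5.682633 * u**4 - 1.752461 * u**3
               - 0.293762 * u**2 + 0.042981 * u + c[-2])
        phi = ((mm - 2.0 * m[-1] ** 2 - 2.0 * m[-2] ** 2)
               / (1.0 - 2.0 * an**2 - 2.0 * an1**2))
        a[2:-2] = m[2:-2] / np.sqrt(phi)
        a[-1], a[-2] = an, an1
        a[0], a[1] = -an, -an1
    return a


def _sw_p_value(W: float, n: int) -> float:
    """Normalising-transformation p-value of AS R94."""
    if n == 3:
        p = 6.0 / np.pi * (np.arcsin(np.sqrt(W)) - np.arcsin(np.sqrt(0.75)))
        return float(min(max(p, 0.0), 1.0))
    if n <= 11:
        gamma = -2.273 + 0.459 * n
        w = -np.log(gamma - np.log1p(-W))
        mu = 0.5440 - 0.39978 * n + 0.025054 * n**2 - 0.0006714 * n**3
        sigma = np.exp(1.3822 - 0.77857 * n + 0.062767 * n**2
                       - 0.0020322 * n**3)
    else:
        x = np.log(n)
        w = np.log1p(-W)
        mu = -1.5861 - 0.31082 * x - 0.083751 * x**2 + 0.0038915 * x**3
        sigma = np.exp(-0.4803 - 0.082676 * x + 0.0030302 * x**2)
    return float(stats.norm.sf((w - mu) / sigma))


def shapiro_wilk(x) -> ShapiroWilkResult:
    """Shapiro-Wilk W and p-value via the AS R94 approximations."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if not 3 <= n <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    rng_ = x[-1] - x[0]
    if rng_ == 0.0:
        raise ValueError("sample is constant; W is undefined")
    a = _sw_weights(n)
    dev = x - x.mean()
    W = float((a @ x) ** 2 / (dev @ dev))
    W = min(W, 1.0)
    return ShapiroWilkResult(W=W, p_value=_sw_p_value(W, n), n=n)


# ---------------------------------------------------------------------------
# Royston's multivariate test
# ---------------------------------------------------------------------------

def _royston_ms(n: int) -> tuple[float, float]:
    """Normalising-transform location/scale polynomials in log n."""
    x = np.log(n)
    m = -1.5861 - 0.31082 * x - 0.083751 * x**2 + 0.0038915 * x**3
    s = np.exp(-0.4803 - 0.082676 * x + 0.0030302 * x**2)
    return m, s


def royston_transform(W_j: float, n: int) -> float:
    """Map a Shapiro-Wilk statistic to R_j = [phi^-1(0.5 phi(-z))]^2.

    z is the normalised (1 - W) transform; for the supported sample sizes
    (12 <= n <= 2000) the power exponent of the published approximation is
    zero, i.e. the transform is taken on log(1 - W).
    """
    if not 0.0 < W_j <= 1.0:
        raise ValueError("W must lie in (0, 1]")
    if not 12 <= n <= 2000:
        raise ValueError("royston_transform supports 12 <= n <= 2000")
    m, s = _royston_ms(n)
    z = (np.log1p(-W_j) - m) / s
    return float(stats.norm.ppf(0.5 * stats.norm.sf(z)) ** 2)


def royston_test(X) -> RoystonResult:
    """Royston's H test of multivariate normality on an (n, p) matrix.

    H = e * mean(R_j) with e = p / (1 + (p-1) C); C is the average of the
    pairwise correlation-derived terms of Royston's published formula, and
    the p-value comes from chi-square with e degrees of freedom.
    """
    beats = getattr(X, "beats", X)
    Xa = np.atleast_2d(np.asarray(beats, dtype=float))
    n, p = Xa.shape
    if n < 12:
        raise ValueError("Royston's test requires n >= 12")
    if np.any(Xa.max(axis=0) == Xa.min(axis=0)):
        raise ValueError("constant column: normality is undefined")

    R = np.array([royston_transform(shapiro_wilk(Xa[:, j]).W, n)
                  for j in range(p)])
    if p == 1:
        e = 1.0
        C = 0.0
    else:
        x = np.log(n)
        u = 0.715
        v = 0.21364 + 0.015124 * x**2 - 0.0018034 * x**3
        lam = 5.0
        rho = np.corrcoef(Xa, rowvar=False)
        cmat = rho**lam * (1.0 - (u * (1.0 - rho) ** u) / v)
        total = float(cmat.sum() - np.trace(cmat))
        C = total / (p**2 - p)
        e = p / (1.0 + (p - 1) * C)
    H = float(e * R.sum() / p)
    return RoystonResult(R_values=R, H=H, e=float(e), C=float(C),
                         p_value=float(stats.chi2.sf(H, e)))


# ---------------------------------------------------------------------------
# Sequential Forward Selection of a multivariate-normal subset
# ---------------------------------------------------------------------------

def _subset_p(R: np.ndarray, cmat: np.ndarray, subset: list, n: int) -> float:
    """Royston p-value for a subset from precomputed R_j and pair terms."""
    p = len(subset)
    if p == 1:
        return float(stats.chi2.sf(R[subset[0]], 1.0))
    sub = np.ix_(subset, subset)
    block = cmat[sub]
    C = float(block.sum() - np.trace(block)) / (p**2 - p)
    e = p / (1.0 + (p - 1) * C)
    H = e * R[subset].sum() / p
    return float(stats.chi2.sf(H, e))


def sfs_multinormal(X, alpha: float = 0.05, max_vars: int | None = None) -> SFSTrace:
    """Greedy forward search for a maximal multivariate-normal variable set.

    Stage 1 keeps only variables individually passing Shapiro-Wilk at
    `alpha`; Stage 2 repeatedly adds the candidate maximising the Royston
    p-value of the enlarged subset (ties to the lowest index) while that
    p-value stays >= alpha and the subset is below `max_vars`.
    """
    beats = getattr(X, "beats", X)
    Xa = np.atleast_2d(np.asarray(beats, dtype=float))
    n, k = Xa.shape
    if n < 12:
        raise ValueError("SFS with Royston's test requires n >= 12")
    max_vars = k if max_vars is None else int(max_vars)

    sw = []
    for j in range(k):
        col = Xa[:, j]
        if col.max() == col.min():
            sw.append(None)
            continue
        sw.append(shapiro_wilk(col))
    survivors = [j for j, r in enumerate(sw)
                 if r is not None and r.p_value >= alpha]
    if not survivors:
        return SFSTrace(steps=[], selected=(), alpha=alpha)

    R = np.full(k, np.nan)
    for j in survivors:
        R[j] = royston_transform(sw[j].W, n)
    x = np.log(n)
    u = 0.715
    v = 0.21364 + 0.015124 * x**2 - 0.0018034 * x**3
    rho = np.corrcoef(Xa, rowvar=False) if k > 1 else np.ones((1, 1))
    cmat = rho**5 * (1.0 - (u * (1.0 - rho) ** u) / v)

    selected: list[int] = []
    steps: list[tuple[int, float]] = []
    remaining = list(survivors)
    while remaining and len(selected) < max_vars:
        best_j, best_p = -1, -1.0
        for j in remaining:
            pv = _subset_p(R, cmat, selected + [j], n)
            if pv > best_p:
                best_j, best_p = j, pv
        if best_p < alpha:
            break
        selected.append(best_j)
        remaining.remove(best_j)
        steps.append((best_j, best_p))
    return SFSTrace(steps=steps, selected=tuple(selected), alpha=alpha)
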