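"""Bagged best-split Gini decision trees on presorted features.

Bootstrap resampling with replacement is expressed as integer sample
weights, so every tree of a bagging ensemble reuses one feature-wise
argsort of the training matrix instead of re-sorting at every node.  The
split rule is exact weighted CART: at each node the (feature, midpoint
threshold) pair maximising the Gini impurity decrease over weighted
samples is chosen, ties resolved toward the lowest feature index and then
the lowest threshold, so fits are fully deterministic in the seed.

Trees are stored as flat arrays (feature, threshold, left, right, leaf
class) concatenated across the ensemble; `left == -1` marks a leaf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit


@njit(cache=True)
def _compact(work, w, out):
    """Drop zero-weight (out-of-bag) samples from each presorted row."""
    d, n = work.shape
    m = 0
    for f in range(d):
        m = 0
        for ii in range(n):
            i = work[f, ii]
            if w[i] > 0.0:
                out[f, m] = i
                m += 1
    return m


@njit(cache=True)
def _grow_tree(XT, y, w, work, n, tmp, mask, feature, threshold, left, right,
               value, stack_lo, stack_hi, stack_id):
    """Grow one weighted CART into the preallocated flat arrays.

    XT: (d, n_total) feature-major training matrix; work: presorted sample
    indices restricted to in-bag samples, first `n` entries of each row
    (consumed; partitioned in place); w: per-sample weights.  Returns the
    number of nodes used.
    """
    d = XT.shape[0]
    node_count = 1
    top = 0
    stack_lo[0] = 0
    stack_hi[0] = n
    stack_id[0] = 0
    while top >= 0:
        lo = stack_lo[top]
        hi = stack_hi[top]
        nid = stack_id[top]
        top -= 1

        pos = 0.0
        neg = 0.0
        for ii in range(lo, hi):
            i = work[0, ii]
            if y[i] == 1:
                pos += w[i]
            else:
                neg += w[i]
        total = pos + neg

        if pos == 0.0 or neg == 0.0 or total < 2.0:
            feature[nid] = -1
            left[nid] = -1
            right[nid] = -1
            value[nid] = 1 if pos > neg else 0
            continue

        best_proxy = -1.0e308
        best_f = -1
        best_thr = 0.0
        for f in range(d):
            lp = 0.0
            ln_ = 0.0
            prev_val = 0.0
            seen = False
            for ii in range(lo, hi):
                i = work[f, ii]
                v = XT[f, i]
                if seen and v > prev_val:
                    rp = pos - lp
                    rn = neg - ln_
                    wl = lp + ln_
                    wr = rp + rn
                    proxy = (lp * lp + ln_ * ln_) / wl + (rp * rp + rn * rn) / wr
                    if proxy > best_proxy:
                        best_proxy = proxy
                        best_f = f
                        best_thr = 0.5 * (prev_val + v)
                if y[i] == 1:
                    lp += w[i]
                else:
                    ln_ += w[i]
                prev_val = v
                seen = True

        if best_f < 0:
            feature[nid] = -1
            left[nid] = -1
            right[nid] = -1
            value[nid] = 1 if pos > neg else 0
            continue

        # stable partition of every feature's sorted segment
        for ii in range(lo, hi):
            i = work[best_f, ii]
            mask[i] = XT[best_f, i] <= best_thr
        mid = lo
        for f in range(d):
            p = lo
            r = 0
            for ii in range(lo, hi):
                i = work[f, ii]
                if mask[i]:
                    work[f, p] = i
                    p += 1
                else:
                    tmp[r] = i
                    r += 1
            for j in range(r):
                work[f, p + j] = tmp[j]
            mid = p

        lid = node_count
        rid = node_count + 1
        node_count += 2
        feature[nid] = best_f
        threshold[nid] = best_thr
        left[nid] = lid
        right[nid] = rid
        top += 1
        stack_lo[top] = lo
        stack_hi[top] = mid
        stack_id[top] = lid
        top += 1
        stack_lo[top] = mid
        stack_hi[top] = hi
        stack_id[top] = rid
    return node_count


@njit(cache=True)
def _vote_fractions(P, feature, threshold, left, right, value, offsets):
    """Fraction of trees classifying each probe row of P as class 1."""
    m = P.shape[0]
    n_trees = offsets.shape[0] - 1
    votes = np.zeros(m)
    for t in range(n_trees):
        base = offsets[t]
        for j in range(m):
            nid = base
            while left[nid] >= 0:
                if P[j, feature[nid]] <= threshold[nid]:
                    nid = left[nid]
                else:
                    nid = right[nid]
            votes[j] += value[nid]
    return votes / n_trees


@dataclass
class TreeEnsemble:
    """Flat-array forest; `offsets[t]` is the root node of tree t."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    offsets: np.ndarray
    n_features: int

    @property
    def n_trees(self) -> int:
        return len(self.offsets) - 1

    def vote_fractions(self, P: np.ndarray) -> np.ndarray:
        P = np.ascontiguousarray(np.atleast_2d(np.asarray(P, dtype=np.float64)))
        if P.shape[1] != self.n_features:
            raise ValueError(
                f"probe dimension {P.shape[1]} != training dimension {self.n_features}")
        return _vote_fractions(P, self.feature, self.threshold, self.left,
                               self.right, self.value, self.offsets)


def fit_tree(X, y, sample_weight=None) -> TreeEnsemble:
    """Single weighted CART (an ensemble of one); used directly in tests."""
    return fit_bagged_trees(X, y, n_trees=1, seed=0, _bootstrap=False,
                            sample_weight=sample_weight)


def fit_bagged_trees(X, y, n_trees: int, seed, _bootstrap: bool = True,
                     sample_weight=None) -> TreeEnsemble:
    """Fit `n_trees` CARTs, each on an n-with-replacement bootstrap of (X, y)."""
    X = np.ascontiguousarray(np.atleast_2d(np.asarray(X, dtype=np.float64)))
    y = np.asarray(y).astype(np.int8)
    n, d = X.shape
    if n == 0 or n_trees < 1:
        raise ValueError("need at least one sample and one tree")
    if y.shape[0] != n:
        raise ValueError("X and y length mismatch")
    XT = np.ascontiguousarray(X.T)
    sorted_idx = np.ascontiguousarray(np.argsort(X, axis=0, kind="stable").T
                                      ).astype(np.int32)
    rng = np.random.default_rng(seed)

    max_nodes = 2 * n + 1
    feats, thrs, lefts, rights, vals, sizes = [], [], [], [], [], []
    tmp = np.empty(n, dtype=np.int32)
    mask = np.empty(n, dtype=np.bool_)
    work = np.empty_like(sorted_idx)
    stack_lo = np.empty(max_nodes, dtype=np.int64)
    stack_hi = np.empty(max_nodes, dtype=np.int64)
    stack_id = np.empty(max_nodes, dtype=np.int64)
    for _ in range(n_trees):
        if _bootstrap:
            w = np.bincount(rng.integers(0, n, size=n), minlength=n
                            ).astype(np.float64)
        elif sample_weight is not None:
            w = np.asarray(sample_weight, dtype=np.float64)
        else:
            w = np.ones(n)
        feature = np.empty(max_nodes, dtype=np.int32)
        threshold = np.zeros(max_nodes)
        left = np.empty(max_nodes, dtype=np.int32)
        right = np.empty(max_nodes, dtype=np.int32)
        value = np.zeros(max_nodes, dtype=np.int8)
        n_inbag = _compact(sorted_idx, w, work)
        used = _grow_tree(XT, y, w, work, n_inbag, tmp, mask, feature,
                          threshold, left, right, value,
                          stack_lo, stack_hi, stack_id)
        feats.append(feature[:used].copy())
        thrs.append(threshold[:used].copy())
        lefts.append(left[:used].copy())
        rights.append(right[:used].copy())
        vals.append(value[:used].copy())
        sizes.append(used)

    offsets = np.zeros(n_trees + 1, dtype=np.int64)
    offsets[1:] = np.cumsum(sizes)
    shift = np.concatenate([
        np.where(lf >= 0, lf + off, -1)
        for lf, off in zip(lefts, offsets[:-1])])
    shift_r = np.concatenate([
        np.where(rt >= 0, rt + off, -1)
        for rt, off in zip(rights, offsets[:-1])])
    return TreeEnsemble(
        feature=np.concatenate(feats),
        threshold=np.concatenate(thrs),
        left=shift.astype(np.int32),
        right=shift_r.astype(np.int32),
        value=np.concatenate(vals),
        offsets=offsets,
        n_features=d,
    )
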