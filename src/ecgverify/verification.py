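"""Genuine/imposter verification: bagging, the parallel ensemble, and metrics.

The base verifier is a bagging ensemble of B full-depth Gini decision trees
(each fit on an n-with-replacement bootstrap); its genuine-confidence for a
probe is the fraction of trees voting genuine.  The parallel ensemble
trains L such baggers on the same genuine data but independently drawn
imposter subsets, and fuses them by the arithmetic mean of member
confidences — the redundancy between the two levels is deliberate: bagging
resamples one pool, the parallel scheme changes the imposter pool itself.

Metrics follow the standard verification identities: FAR = nFP / I,
FRR = 1 - nTP / G, TRR = 1 - FAR, TAR = 1 - FRR; the EER is the error at
the operating threshold where FAR and FRR cross.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import HeartbeatMatrix
from .trees import TreeEnsemble, fit_bagged_trees


@dataclass
class TrainingSet:
    genuine_real: HeartbeatMatrix
    genuine_synth: HeartbeatMatrix | None = None
    imposter: HeartbeatMatrix | None = None

    def genuine_beats(self) -> np.ndarray:
        parts = [self.genuine_real.beats]
        if self.genuine_synth is not None and self.genuine_synth.n > 0:
            parts.append(self.genuine_synth.beats)
        return np.vstack(parts)


@dataclass
class BaggingModel:
    trees: TreeEnsemble
    B: int
    bootstrap_seed: int


@dataclass
class ParallelEnsemble:
    members: list  # L BaggingModel
    imposter_subsets: list  # per-member index arrays into the imposter pool
    L: int


def train_bagging(train: TrainingSet, B: int = 50, seed: int = 0) -> BaggingModel:
    """Fit B trees, each on a bootstrap of the pooled labelled data."""
    if B < 1:
        raise ValueError("B must be >= 1")
    genuine = train.genuine_beats()
    if train.imposter is None or train.imposter.n == 0 or len(genuine) == 0:
        raise ValueError("training needs both genuine and imposter beats")
    X = np.vstack([genuine, train.imposter.beats])
    y = np.concatenate([np.ones(len(genuine), dtype=np.int8),
                        np.zeros(train.imposter.n, dtype=np.int8)])
    ens = fit_bagged_trees(X, y, n_trees=B, seed=seed)
    return BaggingModel(trees=ens, B=B, bootstrap_seed=int(seed))


def bagging_confidence(model: BaggingModel, x) -> float | np.ndarray:
    """Fraction of trees voting genuine, in [0, 1]."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    out = model.trees.vote_fractions(np.atleast_2d(x))
    return float(out[0]) if single else out


def train_parallel(genuine_real: HeartbeatMatrix,
                   genuine_synth: HeartbeatMatrix | None,
                   imposter_pool: HeartbeatMatrix,
                   L: int = 1,
                   imposters_per_member: int | None = None,
                   B: int = 50,
                   seed: int = 0) -> ParallelEnsemble:
    """L bagging members sharing genuine data, each with its own imposter draw.

    Member i trains on (genuine_real + genuine_synth) against an
    independently seeded uniform without-replacement draw of
    `imposters_per_member` beats from `imposter_pool`.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    m = imposter_pool.n if imposters_per_member is None else int(imposters_per_member)
    if imposter_pool.n < m:
        raise ValueError(
            f"imposter pool of {imposter_pool.n} < {m} beats per member")
    rng = np.random.default_rng(seed)
    members, subsets = [], []
    for _ in range(L):
        idx = rng.choice(imposter_pool.n, size=m, replace=False)
        member_seed = int(rng.integers(0, 2**31 - 1))
        train = TrainingSet(genuine_real, genuine_synth,
                            imposter_pool.subset(idx))
        members.append(train_bagging(train, B=B, seed=member_seed))
        subsets.append(idx)
    return ParallelEnsemble(members=members, imposter_subsets=subsets, L=L)


def parallel_confidence(ens: ParallelEnsemble, x) -> float | np.ndarray:
    """Arithmetic mean of member bagging confidences."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    out = np.mean([m.trees.vote_fractions(X) for m in ens.members], axis=0)
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class VerificationReport:
    thresholds: np.ndarray
    far_curve: np.ndarray
    frr_curve: np.ndarray
    eer: float
    eer_threshold: float
    tar_at_half: float
    trr_at_half: float
    per_subject_tar: np.ndarray | None = None
    per_subject_trr: np.ndarray | None = None

    @property
    def tar_curve(self) -> np.ndarray:
        return 1.0 - self.frr_curve

    @property
    def trr_curve(self) -> np.ndarray:
        return 1.0 - self.far_curve


def _rates_at(thresholds, sg, si):
    """FAR/FRR step curves: accept iff score >= threshold."""
    far = np.array([np.mean(si >= t) for t in thresholds])
    frr = np.array([np.mean(sg < t) for t in thresholds])
    return far, frr


def evaluate(scores_genuine, scores_imposter) -> VerificationReport:
    """FAR/FRR at every distinct operating threshold, EER at the crossing.

    Candidate thresholds are all distinct scores plus one point beyond each
    extreme, so every attainable (FAR, FRR) pair is visited.  With the
    accept-iff-score>=threshold rule, FAR - FRR is non-increasing in the
    threshold, so its zero crossing is unique: the EER is the common value
    of FAR and FRR linearly interpolated between the two operating points
    bracketing the sign change (exactly the point where the interpolated
    curves meet); when the difference hits zero on a plateau, the lowest
    such threshold is reported.
    """
    sg = np.asarray(scores_genuine, dtype=float)
    si = np.asarray(scores_imposter, dtype=float)
    if sg.size == 0 or si.size == 0:
        raise ValueError("both score lists must be nonempty")
    allsc = np.unique(np.concatenate([sg, si]))
    thresholds = np.concatenate([[allsc[0] - 1.0], allsc, [allsc[-1] + 1.0]])
    far, frr = _rates_at(thresholds, sg, si)
    d = far - frr  # monotone non-increasing, from +1 to -1
    i = int(np.argmax(d <= 0.0))  # first threshold at/past the crossing
    if d[i] == 0.0 or i == 0:
        eer = float(far[i])
        eer_threshold = float(thresholds[i])
    else:
        alpha = d[i - 1] / (d[i - 1] - d[i])
        eer = float(far[i - 1] + alpha * (far[i] - far[i - 1]))
        eer_threshold = float(thresholds[i - 1]
                              + alpha * (thresholds[i] - thresholds[i - 1]))
    return VerificationReport(
        thresholds=thresholds,
        far_curve=far,
        frr_curve=frr,
        eer=eer,
        eer_threshold=eer_threshold,
        tar_at_half=float(np.mean(sg >= 0.5)),
        trr_at_half=float(np.mean(si < 0.5)),
    )
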