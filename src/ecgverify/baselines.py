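"""Dimensionality-reduction comparator systems for the same verifier.

The alternative to enlarging the genuine class by synthesis is shrinking
the feature space; this module plugs a PCA embedding (fit on the pooled
genuine + imposter training beats) in front of the identical bagging
verifier so the two remedies for the small-sample-size problem can be
compared on identical seeded splits.  Other embeddings can be supplied via
the same transform interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .experiments import (ExperimentConfig, build_benchmark, derive_seed,
                          run_cell)
from .preprocess import HeartbeatMatrix
from .verification import evaluate, parallel_confidence, train_parallel


@dataclass(frozen=True)
class EmbeddingSpec:
    method: str = "pca"  # "pca" or "none"
    n_dims: int = 40

    def __post_init__(self) -> None:
        if self.method not in ("pca", "none"):
            raise ValueError("method must be 'pca' or 'none'")
        if self.n_dims < 1:
            raise ValueError("n_dims must be >= 1")


class IdentityTransform:
    def transform(self, X):
        return np.asarray(X, dtype=float)


def fit_embedding(X, spec: EmbeddingSpec):
    """Fit the embedding on pooled training beats; returns a transform object."""
    beats = getattr(X, "beats", X)
    beats = np.atleast_2d(np.asarray(beats, dtype=float))
    n, k = beats.shape
    if spec.method == "none":
        return IdentityTransform()
    if n < 2:
        raise ValueError("need at least 2 beats to fit PCA")
    if spec.n_dims > min(n, k):
        raise ValueError(f"n_dims={spec.n_dims} exceeds min(n, k)={min(n, k)}")
    return PCA(n_components=spec.n_dims, svd_solver="full").fit(beats)


def _run_embedded_cell(subjects, spec: EmbeddingSpec, imposter_count: int,
                       config: ExperimentConfig, cell_seed: int,
                       split_seed: int):
    """Pooled EER of the PCA-fronted verifier (no synthesis) for one cell."""
    from .experiments import _imposter_split

    pooled_g, pooled_i = [], []
    for s_idx, subj in enumerate(subjects):
        split_rng = np.random.default_rng(derive_seed(split_seed, s_idx))
        train_subj, test_subj = _imposter_split(subjects, s_idx, split_rng)
        pool = np.vstack([np.vstack([subjects[j].train, subjects[j].test])
                          for j in train_subj])
        if len(pool) < imposter_count:
            raise ValueError("imposter pool too small")
        test_pool = np.vstack([subjects[j].test for j in test_subj])
        ti = split_rng.choice(
            len(test_pool),
            size=min(config.test_imposter_count, len(test_pool)),
            replace=False)
        test_imposters = test_pool[ti]

        draw_rng = np.random.default_rng(derive_seed(cell_seed, s_idx, 3))
        imp_idx = draw_rng.choice(len(pool), size=imposter_count,
                                  replace=False)
        emb = fit_embedding(np.vstack([subj.train, pool[imp_idx]]), spec)
        ens = train_parallel(
            HeartbeatMatrix(emb.transform(subj.train)), None,
            HeartbeatMatrix(emb.transform(pool[imp_idx])),
            L=1, B=config.B, seed=derive_seed(cell_seed, s_idx, 2))
        pooled_g.append(parallel_confidence(ens, emb.transform(subj.test)))
        pooled_i.append(parallel_confidence(ens, emb.transform(test_imposters)))
    return evaluate(np.concatenate(pooled_g), np.concatenate(pooled_i))


def compare_systems(config: ExperimentConfig,
                    systems: dict | None = None,
                    synth_count: int = 200,
                    imposter_count: int = 200) -> pd.DataFrame:
    """Synthesis system vs embedding systems on identical seeded splits.

    `systems` maps a system name to an EmbeddingSpec; the synthesis system
    (raw k-dimensional beats + synthetic genuine data) is always included.
    Returns one row per system and master seed with the pooled EER in %.
    """
    if systems is None:
        systems = {"pca": EmbeddingSpec("pca", 40)}
    rows = []
    for master_seed in config.master_seeds:
        subjects = build_benchmark(config, master_seed)
        split_seed = derive_seed(master_seed, 11)
        cell_seed = derive_seed(master_seed, 40)
        rep = run_cell(subjects, synth_count, imposter_count, config,
                       cell_seed, split_seed=split_seed)
        rows.append(dict(master_seed=master_seed, system="data_synthesis",
                         n_dims=subjects[0].train.shape[1],
                         eer_pct=100 * rep.eer))
        for name, spec in systems.items():
            rep = _run_embedded_cell(subjects, spec, imposter_count, config,
                                     cell_seed, split_seed)
            rows.append(dict(master_seed=master_seed, system=name,
                             n_dims=spec.n_dims, eer_pct=100 * rep.eer))
    return pd.DataFrame(rows)
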