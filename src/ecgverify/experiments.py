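"""End-to-end experiment runner on the synthetic multi-subject benchmark.

Builds a cohort of synthetic subjects, runs the full pipeline (simulate ->
band-pass -> Pan-Tompkins -> segment -> GMM outlier removal), then trains
and evaluates per-subject verifiers under three designs:

* a (synthesis count x imposter count) grid of pooled EER / TAR / TRR —
  the class-imbalance and data-synthesis experiments;
* a stability run measuring the per-subject standard deviation of TAR/TRR
  across independent imposter re-draws as the parallel width L grows;
* a redundancy run contrasting (L=50 members, 1 tree) with
  (1 member, 50-tree bagging) on identical data.

Every quantity is deterministic in the experiment's master seed: one root
seed fans out per-subject, per-cell and per-member seeds through hash
chains (numpy SeedSequence), so any cell can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .outliers import calibrate_rule, classify_beats, em_fit
from .preprocess import (HeartbeatMatrix, bandpass_filter, detect_r_peaks,
                         label_beats_from_truth, segment_heartbeats)
from .synthesis import fit_gaussian, sample_heartbeats
from .synthetic import NoiseSpec, make_subject, synthesize_record
from .verification import evaluate, parallel_confidence, train_parallel

log = logging.getLogger(__name__)


def derive_seed(*keys) -> int:
    """Deterministic hash-chain fan-out of integer seed material (< 2^31)."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0]
               & 0x7FFFFFFF)


@dataclass
class ExperimentConfig:
    n_subjects: int = 30
    duration_s: float = 60.0
    fs: float = 200.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    abnormal_fraction: float = 0.10
    outlier_M: int = 2
    outlier_percentile: float = 0.95
    genuine_train_count: int = 20
    synth_counts: tuple = (0, 50, 100, 200, 400)
    imposter_counts: tuple = (20, 40, 60, 80, 100, 150, 200, 250)
    L: int = 1
    L_grid: tuple = (1, 5, 10, 20)
    B: int = 50
    n_redraws: int = 3
    stability_synth: int = 200
    stability_imposters: int = 100
    shrinkage: float = 0.0
    test_genuine_max: int = 40
    test_imposter_count: int = 100
    master_seeds: tuple = tuple(range(10))
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.genuine_train_count, self.B,
               self.n_redraws) < 1:
            raise ValueError("all counts must be positive")
        if not self.synth_counts or not self.imposter_counts or not self.L_grid:
            raise ValueError("grids must be nonempty")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["noise"] = {
            "baseline_wander": list(self.noise.baseline_wander),
            "powerline": list(self.noise.powerline),
            "electrode_movement": [list(self.noise.electrode_movement[0]),
                                   self.noise.electrode_movement[1]],
            "broadband_sd": self.noise.broadband_sd,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "noise" in d and isinstance(d["noise"], dict):
            nd = d["noise"]
            d["noise"] = NoiseSpec(
                tuple(nd["baseline_wander"]),
                tuple(nd["powerline"]),
                (tuple(nd["electrode_movement"][0]),
                 nd["electrode_movement"][1]),
                nd["broadband_sd"])
        for key in ("synth_counts", "imposter_counts", "L_grid",
                    "master_seeds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SubjectData:
    """Post-outlier-removal beats of one benchmark subject."""

    subject_id: str
    train: np.ndarray  # (genuine_train_count, k)
    test: np.ndarray  # held-out genuine beats


def build_benchmark(config: ExperimentConfig, master_seed: int) -> list:
    """Simulate, preprocess and outlier-filter a cohort; returns SubjectData.

    The GMM normal-beat model is trained once on generator-truth normal
    beats pooled across subjects (the rule is subject-invariant), then
    applied to every subject's detected beats.
    """
    log.info("benchmark: simulating %d subjects (seed %d)",
             config.n_subjects, master_seed)
    per_subject = []
    normal_pool = []
    for i in range(config.n_subjects):
        tseed = derive_seed(master_seed, 1, i)
        template = make_subject(tseed, subject_id=f"S{i:03d}")
        record = synthesize_record(
            template, config.duration_s, config.fs, config.noise,
            config.abnormal_fraction, seed=derive_seed(master_seed, 2, i))
        filt = bandpass_filter(record)
        peaks = detect_r_peaks(filt)
        beats = segment_heartbeats(filt, peaks)
        is_abn, matched = label_beats_from_truth(filt, beats.r_indices)
        per_subject.append((template.subject_id, beats, is_abn, matched))
        normal_pool.append(beats.beats[matched & ~is_abn])

    log.info("benchmark: fitting GMM outlier model")
    pool = np.vstack(normal_pool)
    gmm = em_fit(pool, M=config.outlier_M,
                 seed=derive_seed(master_seed, 3))
    rule = calibrate_rule(gmm, pool, config.outlier_percentile)

    subjects = []
    for subject_id, beats, _, _ in per_subject:
        abnormal = classify_beats(gmm, rule, beats)
        kept = beats.beats[~abnormal]
        need = config.genuine_train_count + 2
        if len(kept) < need:
            log.warning("benchmark: subject %s has %d clean beats (<%d), "
                        "skipping", subject_id, len(kept), need)
            continue
        train = kept[: config.genuine_train_count]
        test = kept[config.genuine_train_count:
                    config.genuine_train_count + config.test_genuine_max]
        subjects.append(SubjectData(subject_id, train, test))
    log.info("benchmark: %d usable subjects", len(subjects))
    return subjects


def _imposter_split(subjects, s_idx, rng):
    """Disjoint train/test imposter subject sets for one target subject."""
    others = [j for j in range(len(subjects)) if j != s_idx]
    perm = rng.permutation(len(others))
    half = len(others) // 2
    train_subj = [others[j] for j in perm[:half]]
    test_subj = [others[j] for j in perm[half:]]
    return train_subj, test_subj


def run_cell(subjects, synth_count: int, imposter_count: int,
             config: ExperimentConfig, cell_seed: int,
             L: int | None = None, B: int | None = None,
             split_seed: int | None = None):
    """Train/evaluate every subject's verifier for one grid cell.

    Returns a pooled VerificationReport with per-subject TAR/TRR attached.
    The imposter subject split and the test-imposter draw are seeded by
    `split_seed` (default: the cell seed), so cells sharing a split_seed
    are evaluated on identical probe sets; training draws and bootstraps
    are seeded by `cell_seed`.  Raises ValueError when a subject's
    imposter training pool is smaller than `imposter_count`.
    """
    L = config.L if L is None else L
    B = config.B if B is None else B
    split_seed = cell_seed if split_seed is None else split_seed
    pooled_g, pooled_i = [], []
    tars, trrs = [], []
    for s_idx, subj in enumerate(subjects):
        split_rng = np.random.default_rng(derive_seed(split_seed, s_idx))
        train_subj, test_subj = _imposter_split(subjects, s_idx, split_rng)
        pool = np.vstack([np.vstack([subjects[j].train, subjects[j].test])
                          for j in train_subj])
        if len(pool) < imposter_count:
            raise ValueError(
                f"imposter pool ({len(pool)}) < imposter count "
                f"({imposter_count})")
        test_pool = np.vstack([subjects[j].test for j in test_subj])
        ti = split_rng.choice(
            len(test_pool),
            size=min(config.test_imposter_count, len(test_pool)),
            replace=False)
        test_imposters = test_pool[ti]

        synth = None
        if synth_count > 0:
            model = fit_gaussian(subj.train, shrinkage=config.shrinkage)
            synth = sample_heartbeats(
                model, synth_count,
                seed=np.random.default_rng(derive_seed(cell_seed, s_idx, 1)))
        ens = train_parallel(
            HeartbeatMatrix(subj.train), synth, HeartbeatMatrix(pool),
            L=L, imposters_per_member=imposter_count, B=B,
            seed=derive_seed(cell_seed, s_idx, 2))
        sg = parallel_confidence(ens, subj.test)
        si = parallel_confidence(ens, test_imposters)
        pooled_g.append(sg)
        pooled_i.append(si)
        tars.append(float(np.mean(sg >= 0.5)))
        trrs.append(float(np.mean(si < 0.5)))
    report = evaluate(np.concatenate(pooled_g), np.concatenate(pooled_i))
    report.per_subject_tar = np.asarray(tars)
    report.per_subject_trr = np.asarray(trrs)
    return report


def run_grid(config: ExperimentConfig) -> pd.DataFrame:
    """The (synthesis x imposter) grid over all master seeds; rates in %."""
    rows = []
    for master_seed in config.master_seeds:
        subjects = build_benchmark(config, master_seed)
        split_seed = derive_seed(master_seed, 11)
        for synth_count in config.synth_counts:
            for imposter_count in config.imposter_counts:
                cell_seed = derive_seed(master_seed, 10, synth_count,
                                        imposter_count)
                try:
                    rep = run_cell(subjects, synth_count, imposter_count,
                                   config, cell_seed,
                                   split_seed=split_seed)
                except ValueError as exc:
                    log.warning("cell (synth=%d, imp=%d) skipped: %s",
                                synth_count, imposter_count, exc)
                    rows.append(dict(master_seed=master_seed,
                                     synth_count=synth_count,
                                     imposter_count=imposter_count,
                                     skipped=True, cell_seed=cell_seed,
                                     eer_pct=np.nan, tar_pct=np.nan,
                                     trr_pct=np.nan))
                    continue
                rows.append(dict(
                    master_seed=master_seed, synth_count=synth_count,
                    imposter_count=imposter_count, skipped=False,
                    cell_seed=cell_seed,
                    eer_pct=100 * rep.eer,
                    tar_pct=100 * rep.tar_at_half,
                    trr_pct=100 * rep.trr_at_half))
                log.info("grid seed=%d synth=%d imp=%d: EER %.2f%%",
                         master_seed, synth_count, imposter_count,
                         100 * rep.eer)
    return pd.DataFrame(rows)


def run_stability(config: ExperimentConfig,
                  master_seed: int | None = None) -> pd.DataFrame:
    """Per-subject TAR/TRR standard deviation across imposter re-draws.

    For each subject and re-draw, max(L_grid) members are trained (each
    with its own imposter draw); an L-member ensemble is scored as the mean
    confidence of the first L members, so every L in the grid is evaluated
    on nested member sets from identical seeds.
    """
    master_seed = (config.master_seeds[0] if master_seed is None
                   else master_seed)
    subjects = build_benchmark(config, master_seed)
    L_max = max(config.L_grid)
    # tar_runs[L][subject] -> list over redraws
    tar_runs = {L: [[] for _ in subjects] for L in config.L_grid}
    trr_runs = {L: [[] for _ in subjects] for L in config.L_grid}
    for s_idx, subj in enumerate(subjects):
        rng = np.random.default_rng(derive_seed(master_seed, 20, s_idx))
        train_subj, test_subj = _imposter_split(subjects, s_idx, rng)
        pool = HeartbeatMatrix(np.vstack(
            [np.vstack([subjects[j].train, subjects[j].test])
             for j in train_subj]))
        test_pool = np.vstack([subjects[j].test for j in test_subj])
        ti = rng.choice(len(test_pool),
                        size=min(config.test_imposter_count, len(test_pool)),
                        replace=False)
        test_imposters = test_pool[ti]
        synth = None
        if config.stability_synth > 0:
            model = fit_gaussian(subj.train, shrinkage=config.shrinkage)
            synth = sample_heartbeats(
                model, config.stability_synth,
                seed=np.random.default_rng(derive_seed(master_seed, 21, s_idx)))
        for r in range(config.n_redraws):
            ens = train_parallel(
                HeartbeatMatrix(subj.train), synth, pool, L=L_max,
                imposters_per_member=config.stability_imposters, B=config.B,
                seed=derive_seed(master_seed, 22, s_idx, r))
            conf_g = np.vstack([m.trees.vote_fractions(subj.test)
                                for m in ens.members])
            conf_i = np.vstack([m.trees.vote_fractions(test_imposters)
                                for m in ens.members])
            for L in config.L_grid:
                sg = conf_g[:L].mean(axis=0)
                si = conf_i[:L].mean(axis=0)
                tar_runs[L][s_idx].append(float(np.mean(sg >= 0.5)))
                trr_runs[L][s_idx].append(float(np.mean(si < 0.5)))
    rows = []
    for L in config.L_grid:
        tar_std = np.mean([np.std(v, ddof=1) if len(v) > 1 else 0.0
                           for v in tar_runs[L]])
        trr_std = np.mean([np.std(v, ddof=1) if len(v) > 1 else 0.0
                           for v in trr_runs[L]])
        rows.append(dict(master_seed=master_seed, L=L,
                         n_redraws=config.n_redraws,
                         tar_std_pct=100 * tar_std,
                         trr_std_pct=100 * trr_std))
        log.info("stability L=%d: TAR std %.2f%%", L, 100 * tar_std)
    return pd.DataFrame(rows)


def run_redundancy(config: ExperimentConfig) -> pd.DataFrame:
    """(L=50, B=1) vs (L=1, B=50) on identical data and seeds, per seed."""
    rows = []
    for master_seed in config.master_seeds:
        subjects = build_benchmark(config, master_seed)
        for L, B in ((50, 1), (1, 50)):
            cell_seed = derive_seed(master_seed, 30)
            rep = run_cell(subjects, synth_count=200, imposter_count=200,
                           config=config, cell_seed=cell_seed, L=L, B=B)
            rows.append(dict(master_seed=master_seed, L=L, B=B,
                             eer_pct=100 * rep.eer,
                             tar_pct=100 * rep.tar_at_half,
                             trr_pct=100 * rep.trr_at_half))
            log.info("redundancy seed=%d L=%d B=%d: EER %.2f%%",
                     master_seed, L, B, 100 * rep.eer)
    return pd.DataFrame(rows)


def save_results(df: pd.DataFrame, config: ExperimentConfig, path) -> None:
    """CSV table + JSON sidecar of the resolved configuration."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    with open(path.with_suffix(".config.json"), "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
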