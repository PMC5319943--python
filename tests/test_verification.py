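"""Bagging verifier, parallel ensemble, and FAR/FRR/EER evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgverify import (HeartbeatMatrix, TrainingSet, bagging_confidence,
                       evaluate, parallel_confidence, train_bagging,
                       train_parallel)


def brute_force_eer(sg, si):
    """Exact-rational sweep: the FAR/FRR crossing by counting loops."""
    from fractions import Fraction

    scores = sorted(set(list(sg) + list(si)))
    cands = [scores[0] - 1] + scores + [scores[-1] + 1]
    pts = []
    for t in cands:
        far = Fraction(sum(1 for s in si if s >= t), len(si))
        frr = Fraction(sum(1 for s in sg if s < t), len(sg))
        pts.append((far, frr))
    for (f1, r1), (f2, r2) in zip(pts, pts[1:]):
        d1, d2 = f1 - r1, f2 - r2
        if d2 <= 0:
            if d2 == 0 or d1 == d2:
                return float(f2) if d2 == 0 else float((f1 + r1) / 2)
            alpha = d1 / (d1 - d2)
            return float(f1 + alpha * (f2 - f1))
    raise AssertionError("no FAR/FRR crossing found")


def _toy_training(seed=0, n_g=30, n_i=40, sep=10.0):
    rng = np.random.default_rng(seed)
    g = rng.normal(size=(n_g, 2))
    i = rng.normal(size=(n_i, 2)) + sep
    return TrainingSet(HeartbeatMatrix(g), None, HeartbeatMatrix(i)), g, i


class TestTrainBagging:
    def test_single_tree_degenerate_ensemble(self):
        train, g, i = _toy_training()
        m = train_bagging(train, B=1, seed=0)
        assert m.trees.n_trees == 1

    def test_separable_data_perfect_training_accuracy(self):
        train, g, i = _toy_training(sep=20.0)
        m = train_bagging(train, B=50, seed=1)
        assert np.all(bagging_confidence(m, g) == 1.0)
        assert np.all(bagging_confidence(m, i) == 0.0)

    def test_single_class_rejected(self):
        g = HeartbeatMatrix(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError):
            train_bagging(TrainingSet(g, None, HeartbeatMatrix(
                np.empty((0, 2)))), B=5)

    def test_synthetic_beats_join_genuine_class(self):
        rng = np.random.default_rng(2)
        real = HeartbeatMatrix(rng.normal(size=(5, 2)))
        synth = HeartbeatMatrix(rng.normal(size=(20, 2)))
        imp = HeartbeatMatrix(rng.normal(size=(10, 2)) + 8.0)
        m = train_bagging(TrainingSet(real, synth, imp), B=10, seed=0)
        assert np.mean(bagging_confidence(m, synth.beats)) > 0.8


class TestBaggingConfidence:
    def test_confidence_is_vote_fraction(self):
        train, g, i = _toy_training(sep=3.0)
        m = train_bagging(train, B=20, seed=3)
        probes = np.random.default_rng(4).normal(size=(30, 2)) + 1.5
        conf = bagging_confidence(m, probes)
        assert np.all((conf >= 0) & (conf <= 1))
        # vote granularity: multiples of 1/B
        np.testing.assert_allclose(conf * 20, np.round(conf * 20), atol=1e-9)

    def test_dimension_mismatch_rejected(self):
        train, _, _ = _toy_training()
        m = train_bagging(train, B=3, seed=0)
        with pytest.raises(ValueError):
            bagging_confidence(m, np.zeros(5))


class TestTrainParallel:
    def test_pool_too_small_rejected(self):
        rng = np.random.default_rng(5)
        g = HeartbeatMatrix(rng.normal(size=(5, 2)))
        pool = HeartbeatMatrix(rng.normal(size=(8, 2)))
        with pytest.raises(ValueError):
            train_parallel(g, None, pool, L=2, imposters_per_member=10)

    def test_members_share_genuine_but_differ_on_imposters(self):
        """Two imposter clusters: members drawing different clusters diverge."""
        rng = np.random.default_rng(6)
        g = HeartbeatMatrix(rng.normal(size=(20, 2)))
        cluster_a = rng.normal(size=(30, 2)) + [15.0, 0.0]
        cluster_b = rng.normal(size=(30, 2)) + [0.0, 15.0]
        pool = HeartbeatMatrix(np.vstack([cluster_a, cluster_b]))
        ens = train_parallel(g, None, pool, L=8, imposters_per_member=12,
                             B=10, seed=7)
        subs = [set(s.tolist()) for s in ens.imposter_subsets]
        assert any(sa != sb for sa in subs for sb in subs)
        probe = np.array([[15.0, 0.0]])
        member_conf = [bagging_confidence(m, probe)[0] for m in ens.members]
        assert max(member_conf) - min(member_conf) > 0.0

    def test_L1_equivalent_to_single_bagging_with_same_draws(self):
        rng = np.random.default_rng(8)
        g = HeartbeatMatrix(rng.normal(size=(10, 2)))
        pool = HeartbeatMatrix(rng.normal(size=(30, 2)) + 6.0)
        ens = train_parallel(g, None, pool, L=1, imposters_per_member=20,
                             B=10, seed=9)
        inner = np.random.default_rng(9)
        idx = inner.choice(30, size=20, replace=False)
        seed = int(inner.integers(0, 2**31 - 1))
        direct = train_bagging(
            TrainingSet(g, None, pool.subset(idx)), B=10, seed=seed)
        P = rng.normal(size=(40, 2)) + 3.0
        np.testing.assert_array_equal(parallel_confidence(ens, P),
                                      bagging_confidence(direct, P))


class TestParallelConfidence:
    def test_mean_of_member_confidences(self):
        rng = np.random.default_rng(10)
        g = HeartbeatMatrix(rng.normal(size=(15, 2)))
        pool = HeartbeatMatrix(rng.normal(size=(60, 2)) + 5.0)
        ens = train_parallel(g, None, pool, L=5, imposters_per_member=20,
                             B=8, seed=11)
        P = rng.normal(size=(25, 2)) + 2.0
        expected = np.mean([bagging_confidence(m, P) for m in ens.members],
                           axis=0)
        np.testing.assert_allclose(parallel_confidence(ens, P), expected,
                                   atol=1e-12)


class TestEvaluate:
    def test_perfect_separation_gives_zero_eer(self):
        rep = evaluate([1.0] * 10, [0.0] * 12)
        assert rep.eer == 0.0

    def test_identical_distributions_give_half(self):
        rng = np.random.default_rng(12)
        s = rng.uniform(size=400)
        rep = evaluate(s, s)
        assert rep.eer == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_sweep(self, seed):
        rng = np.random.default_rng(seed)
        sg = rng.uniform(size=200)
        si = rng.uniform(size=200) * 0.8
        rep = evaluate(sg, si)
        assert rep.eer == pytest.approx(brute_force_eer(sg, si), abs=1e-9)

    def test_trr_tar_identities_along_curve(self):
        rng = np.random.default_rng(13)
        rep = evaluate(rng.uniform(size=50), rng.uniform(size=60))
        np.testing.assert_allclose(rep.trr_curve, 1 - rep.far_curve)
        np.testing.assert_allclose(rep.tar_curve, 1 - rep.frr_curve)

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [0.5])
        with pytest.raises(ValueError):
            evaluate([0.5], [])

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.floats(0.1, 5.0), st.floats(-2.0, 2.0))
    def test_eer_invariant_under_monotone_transform(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        sg = rng.normal(1.0, 1.0, size=60)
        si = rng.normal(0.0, 1.0, size=80)
        base = evaluate(sg, si).eer
        trans = evaluate(scale * sg + shift, scale * si + shift).eer
        assert trans == pytest.approx(base, abs=1e-12)

    def test_operating_point_at_half(self):
        sg = np.array([0.9, 0.8, 0.4, 0.6])
        si = np.array([0.1, 0.55, 0.3, 0.2, 0.7])
        rep = evaluate(sg, si)
        assert rep.tar_at_half == pytest.approx(3 / 4)
        assert rep.trr_at_half == pytest.approx(3 / 5)
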