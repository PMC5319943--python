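"""One-class GMM: densities, EM fitting, calibration and classification."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from ecgverify import (GaussianComponent, calibrate_rule, classify_beats,
                       component_density, em_fit, model_log_likelihood)


def brute_force_density(x, mu, C):
    """Direct evaluation with explicit determinant and inverse."""
    k = len(mu)
    dev = x - mu
    return (1.0 / ((2 * np.pi) ** (k / 2) * np.linalg.det(C) ** 0.5)
            * np.exp(-0.5 * dev @ np.linalg.inv(C) @ dev))


class TestComponentDensity:
    def test_standard_normal_at_mode(self):
        c = GaussianComponent(1.0, np.zeros(1), np.eye(1))
        assert component_density(np.zeros(1), c) == pytest.approx(
            1 / np.sqrt(2 * np.pi), rel=1e-12)

    def test_bivariate_identity_at_mean(self):
        c = GaussianComponent(1.0, np.array([3.0, -2.0]), np.eye(2))
        assert component_density(np.array([3.0, -2.0]), c) == pytest.approx(
            1 / (2 * np.pi), rel=1e-12)

    def test_matches_brute_force_k3(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            A = rng.normal(size=(3, 3))
            C = A @ A.T + 0.5 * np.eye(3)
            mu = rng.normal(size=3)
            x = rng.normal(size=3)
            c = GaussianComponent(1.0, mu, C)
            assert component_density(x, c) == pytest.approx(
                brute_force_density(x, mu, C), rel=1e-10)

    def test_dimension_mismatch_rejected(self):
        c = GaussianComponent(1.0, np.zeros(3), np.eye(3))
        with pytest.raises(ValueError):
            component_density(np.zeros(2), c)


class TestEMFit:
    def test_single_component_closed_form(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 4)) * [1.0, 2.0, 0.5, 3.0] + [0, 1, -1, 5]
        m = em_fit(X, M=1, seed=0)
        np.testing.assert_allclose(m.components[0].mean, X.mean(axis=0),
                                   atol=1e-10)
        np.testing.assert_allclose(np.diag(m.components[0].cov),
                                   X.var(axis=0), rtol=1e-8)
        assert m.components[0].weight == pytest.approx(1.0)

    def test_two_separated_clusters_recovered(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(240, 3)) + [0.0, 0.0, 0.0]
        b = rng.normal(size=(160, 3)) + [20.0, 20.0, 20.0]
        X = np.vstack([a, b])
        m = em_fit(X, M=2, seed=0)
        means = sorted([c.mean for c in m.components], key=lambda v: v[0])
        np.testing.assert_allclose(means[0], a.mean(axis=0), atol=0.1)
        np.testing.assert_allclose(means[1], b.mean(axis=0), atol=0.1)
        weights = sorted(c.weight for c in m.components)
        assert weights[0] == pytest.approx(0.4, abs=0.02)
        assert weights[1] == pytest.approx(0.6, abs=0.02)

    @pytest.mark.parametrize("seed", range(10))
    def test_loglik_trace_nondecreasing(self, seed):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(size=(30, 5)),
                       rng.normal(size=(30, 5)) + 2.0])
        m = em_fit(X, M=2, seed=seed)
        assert np.all(np.diff(m.train_loglik_trace) >= -1e-8)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(3)
        m = em_fit(rng.normal(size=(50, 4)), M=3, seed=1)
        assert sum(c.weight for c in m.components) == pytest.approx(1.0)

    def test_high_dimension_small_n_stays_finite(self):
        """k=200, n=60: regularised diagonal covariances keep densities finite."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 200))
        m = em_fit(X, M=2, seed=0)
        ll = model_log_likelihood(m, X)
        assert np.all(np.isfinite(ll))

    def test_errors(self):
        with pytest.raises(ValueError):
            em_fit(np.zeros((1, 3)), M=2)
        with pytest.raises(ValueError):
            em_fit(np.full((10, 3), np.nan), M=2)


class TestModelLogLikelihood:
    def test_single_component_equals_density(self):
        rng = np.random.default_rng(5)
        m = em_fit(rng.normal(size=(30, 3)), M=1, seed=0)
        x = rng.normal(size=3)
        assert model_log_likelihood(m, x) == pytest.approx(
            np.log(component_density(x, m.components[0])), rel=1e-10)

    def test_matches_brute_force_mixture_sum(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(size=(40, 4)),
                       rng.normal(size=(40, 4)) + 3.0])
        m = em_fit(X, M=2, seed=0)
        for _ in range(10):
            x = rng.normal(size=4)
            direct = np.log(sum(c.weight * brute_force_density(x, c.mean, c.cov)
                                for c in m.components))
            assert model_log_likelihood(m, x) == pytest.approx(direct, abs=1e-8)

    def test_nll_ranking_equals_likelihood_ranking(self):
        rng = np.random.default_rng(7)
        m = em_fit(rng.normal(size=(50, 3)), M=2, seed=0)
        P = rng.normal(size=(20, 3))
        ll = model_log_likelihood(m, P)
        assert np.array_equal(np.argsort(-ll), np.argsort(ll)[::-1])


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(200, 5))
    model = em_fit(X, M=2, seed=0)
    return model, X


class TestCalibrationAndClassification:

    def test_percentile_one_keeps_all_training_beats(self, fitted):
        model, X = fitted
        rule = calibrate_rule(model, X, percentile=1.0)
        assert not classify_beats(model, rule, X).any()

    def test_percentile_095_flags_about_5pct(self, fitted):
        model, X = fitted
        rule = calibrate_rule(model, X, percentile=0.95)
        frac = classify_beats(model, rule, X).mean()
        assert frac == pytest.approx(0.05, abs=0.015)

    def test_mode_of_heaviest_component_is_normal(self, fitted):
        model, X = fitted
        heaviest = max(model.components, key=lambda c: c.weight)
        rule = calibrate_rule(model, X, percentile=0.0)
        # the component mode is at least as likely as any training beat
        nll_mode = -model_log_likelihood(model, heaviest.mean)
        assert nll_mode <= rule.threshold + 1e-9

    def test_empty_training_rejected(self, fitted):
        model, _ = fitted
        with pytest.raises(ValueError):
            calibrate_rule(model, np.empty((0, 5)))

    def test_injected_abnormal_beats_scored_auc_above_09(self):
        """20% morphologically abnormal beats; score = -log-likelihood."""
        from ecgverify import (NoiseSpec, bandpass_filter, make_subject,
                               label_beats_from_truth, segment_heartbeats,
                               synthesize_record)

        train_parts, test_parts, labels = [], [], []
        for s in range(5):
            t = make_subject(s)
            clean = synthesize_record(t, 60.0, 200.0, NoiseSpec(), 0.0,
                                      seed=200 + s)
            mixed = synthesize_record(t, 60.0, 200.0, NoiseSpec(), 0.2,
                                      seed=300 + s)
            for rec, bucket in ((clean, "train"), (mixed, "test")):
                filt = bandpass_filter(rec)
                half = int(rec.fs) // 2
                peaks = rec.truth_r[(rec.truth_r >= half)
                                    & (rec.truth_r <= len(rec.samples) - half)]
                mat = segment_heartbeats(filt, peaks)
                if bucket == "train":
                    train_parts.append(mat.beats)
                else:
                    abn, _ = label_beats_from_truth(filt, mat.r_indices)
                    test_parts.append(mat.beats)
                    labels.append(abn)
        model = em_fit(np.vstack(train_parts), M=2, seed=0)
        scores = -model_log_likelihood(model, np.vstack(test_parts))
        auc = roc_auc_score(np.concatenate(labels), scores)
        assert auc > 0.9
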