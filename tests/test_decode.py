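"""Shrinkage LDA, ROC/AUC and cross-validation against independent oracles."""

import numpy as np
import pytest

from hipponav.decode import (
    crossval_auc,
    decision_scores,
    fit_shrinkage_lda,
    ledoit_wolf_shrinkage,
    roc_auc,
)
from hipponav.labeling import LabeledDataset


def brute_force_shrinkage(z):
    """Loop re-implementation of the analytic shrinkage intensity.

    For centered rows z_i: S = (1/n) sum z_i z_i', nu = tr(S)/p,
    d^2 = ||S - nu I||_F^2, b^2 = min(d^2, (1/n^2) sum ||z_i z_i' - S||_F^2),
    lambda = b^2 / d^2.
    """
    n, p = z.shape
    S = np.zeros((p, p))
    for i in range(n):
        S += np.outer(z[i], z[i])
    S /= n
    nu = np.trace(S) / p
    d2 = np.sum((S - nu * np.eye(p)) ** 2)
    if d2 == 0:
        return 0.0
    acc = 0.0
    for i in range(n):
        acc += np.sum((np.outer(z[i], z[i]) - S) ** 2)
    b2 = min(acc / n**2, d2)
    return b2 / d2


def brute_force_auc(scores, labels):
    """All-pairs concordance count, ties worth one half."""
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    total = 0.0
    for i in pos:
        for j in neg:
            if scores[i] > scores[j]:
                total += 1.0
            elif scores[i] == scores[j]:
                total += 0.5
    return total / (len(pos) * len(neg))


def _dataset(X, y, scheme="decile"):
    return LabeledDataset(features=X, labels=y,
                          window_index=np.arange(len(y)), scheme=scheme)


class TestShrinkage:
    @pytest.mark.parametrize("n,p", [(10, 50), (100, 5), (30, 30), (8, 3)])
    def test_matches_brute_force(self, n, p, rng):
        z = rng.standard_normal((n, p)) @ rng.standard_normal((p, p))
        z -= z.mean(axis=0)
        lam, _, _ = ledoit_wolf_shrinkage(z)
        assert lam == pytest.approx(brute_force_shrinkage(z), abs=1e-12)
        assert 0.0 <= lam <= 1.0

    def test_matches_sklearn(self, rng):
        from sklearn.covariance import ledoit_wolf_shrinkage as sk_shrinkage

        for _ in range(10):
            n, p = rng.integers(5, 60), rng.integers(2, 40)
            z = rng.standard_normal((int(n), int(p)))
            z -= z.mean(axis=0)
            lam, _, _ = ledoit_wolf_shrinkage(z)
            assert lam == pytest.approx(
                sk_shrinkage(z, assume_centered=True), abs=1e-10
            )

    def test_lambda_vanishes_with_many_samples(self):
        # anisotropic covariance: the identity target is misspecified, so
        # with plentiful samples the optimal blend weight goes to zero
        scale = np.array([1.0, 2.0, 3.0, 4.0])
        lams = []
        for seed in range(11):
            r = np.random.default_rng(seed)
            z = r.standard_normal((2000, 4)) * scale
            z -= z.mean(axis=0)
            lams.append(ledoit_wolf_shrinkage(z)[0])
        assert np.median(lams) < 0.05


class TestFitLda:
    def test_1d_discriminant_direction(self, rng):
        x0 = rng.normal(0.0, 1.0, (50, 1))
        x1 = rng.normal(2.0, 1.0, (50, 1))
        X = np.vstack([x0, x1])
        y = np.repeat([0, 1], 50)
        model = fit_shrinkage_lda(X, y)
        assert model.w[0] > 0
        assert decision_scores(model, model.mu1[None, :])[0] > 0
        assert decision_scores(model, model.mu0[None, :])[0] < 0

    def test_rank_deficient_features_still_fit(self, rng):
        base = rng.standard_normal((40, 3))
        X = np.hstack([base, base])  # duplicated features, singular S
        y = np.repeat([0, 1], 20)
        X[y == 1] += 1.0
        model = fit_shrinkage_lda(X, y)
        assert model.lam > 0
        assert np.all(np.isfinite(model.w))

    def test_midpoint_scores_zero(self, rng):
        X = rng.standard_normal((60, 4))
        y = np.repeat([0, 1], 30)
        X[y == 1] += 0.5
        model = fit_shrinkage_lda(X, y)
        mid = (model.mu0 + model.mu1) / 2.0
        assert decision_scores(model, mid[None, :])[0] == pytest.approx(0.0,
                                                                        abs=1e-12)

    def test_affine_shift_invariance(self, rng):
        X = rng.standard_normal((80, 5))
        y = np.repeat([0, 1], 40)
        X[y == 1] += 0.7
        shift = rng.standard_normal(5) * 10
        m1 = fit_shrinkage_lda(X, y)
        m2 = fit_shrinkage_lda(X + shift, y)
        Xt = rng.standard_normal((7, 5))
        np.testing.assert_allclose(
            decision_scores(m1, Xt), decision_scores(m2, Xt + shift),
            rtol=1e-8, atol=1e-8,
        )

    def test_small_class_rejected(self, rng):
        X = rng.standard_normal((5, 2))
        with pytest.raises(ValueError, match="at least 2"):
            fit_shrinkage_lda(X, np.array([0, 0, 0, 0, 1]))

    def test_dimension_mismatch_rejected(self, rng):
        X = rng.standard_normal((20, 3))
        y = np.repeat([0, 1], 10)
        model = fit_shrinkage_lda(X, y)
        with pytest.raises(ValueError, match="dimension"):
            decision_scores(model, rng.standard_normal((4, 5)))

    def test_bayes_direction_recovered_with_more_samples(self):
        """The LDA weights align with Sigma^-1 (mu1-mu0) as n grows."""
        p = 6
        r = np.random.default_rng(0)
        A = r.standard_normal((p, p))
        sigma = A @ A.T / p + np.eye(p)
        delta = r.standard_normal(p)
        bayes = np.linalg.solve(sigma, delta)
        bayes /= np.linalg.norm(bayes)

        def mean_angle(n, reps=10):
            angles = []
            for seed in range(reps):
                rr = np.random.default_rng(100 + seed)
                L = np.linalg.cholesky(sigma)
                x0 = rr.standard_normal((n, p)) @ L.T
                x1 = rr.standard_normal((n, p)) @ L.T + delta
                model = fit_shrinkage_lda(
                    np.vstack([x0, x1]), np.repeat([0, 1], n)
                )
                w = model.w / np.linalg.norm(model.w)
                angles.append(np.arccos(np.clip(abs(w @ bayes), -1, 1)))
            return np.mean(angles)

        assert mean_angle(500) < mean_angle(50)


class TestRocAuc:
    def test_hand_example(self):
        auc, _ = roc_auc(np.array([0.1, 0.4, 0.35, 0.8]),
                         np.array([0, 0, 1, 1]))
        assert auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        auc, pts = roc_auc(np.array([1.0, 2.0, 10.0, 11.0]),
                           np.array([0, 0, 1, 1]))
        assert auc == 1.0
        assert pts[0].tolist() == [0.0, 0.0]
        assert pts[-1].tolist() == [1.0, 1.0]

    def test_all_tied_scores_give_half(self):
        auc, _ = roc_auc(np.zeros(10), np.repeat([0, 1], 5))
        assert auc == pytest.approx(0.5)

    def test_matches_brute_force_with_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 120))
            scores = rng.integers(0, 8, n).astype(float)  # many ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            auc, pts = roc_auc(scores, labels)
            assert auc == pytest.approx(brute_force_auc(scores, labels),
                                        abs=1e-12)
            # curve area equals the Mann-Whitney statistic exactly
            assert np.trapezoid(pts[:, 1], pts[:, 0]) == pytest.approx(
                auc, abs=1e-12
            )

    def test_negation_flips_auc_without_ties(self, rng):
        scores = rng.standard_normal(80)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(-scores, labels)
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.arange(4.0), np.zeros(4, dtype=int))

    def test_roc_points_monotone(self, rng):
        scores = rng.integers(0, 5, 60).astype(float)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        _, pts = roc_auc(scores, labels)
        assert np.all(np.diff(pts[:, 0]) >= 0)
        assert np.all(np.diff(pts[:, 1]) >= 0)


class TestCrossval:
    def test_separable_features_give_high_auc(self, rng):
        y = np.repeat([0, 1], 50)
        X = np.column_stack([y + rng.normal(0, 1e-3, 100),
                             rng.standard_normal(100)])
        res = crossval_auc(_dataset(X, y), k=10, seed=1)
        assert res.auc >= 0.99

    def test_each_sample_tested_exactly_once(self, rng):
        y = np.repeat([0, 1], 30)
        X = rng.standard_normal((60, 4))
        res = crossval_auc(_dataset(X, y), k=10, seed=2)
        assert len(res.fold_assignment) == 60
        assert set(res.fold_assignment) == set(range(10))
        # every sample belongs to exactly one test fold by construction;
        # fold sizes are balanced within each class
        for cls in (0, 1):
            counts = np.bincount(res.fold_assignment[y == cls], minlength=10)
            assert counts.max() - counts.min() <= 1

    def test_null_features_give_chance_auc(self):
        aucs = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            X = r.standard_normal((200, 10))
            y = r.permutation(np.repeat([0, 1], 100))
            aucs.append(crossval_auc(_dataset(X, y), k=10, seed=seed).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_deterministic_given_seed(self, rng):
        y = np.repeat([0, 1], 25)
        X = rng.standard_normal((50, 3))
        r1 = crossval_auc(_dataset(X, y), k=5, seed=9)
        r2 = crossval_auc(_dataset(X, y), k=5, seed=9)
        assert r1.auc == r2.auc
        np.testing.assert_array_equal(r1.fold_assignment, r2.fold_assignment)
        np.testing.assert_array_equal(r1.scores, r2.scores)

    def test_k_reduced_for_small_class(self, rng, caplog):
        y = np.array([0] * 5 + [1] * 40)
        X = rng.standard_normal((45, 3))
        with caplog.at_level("WARNING"):
            res = crossval_auc(_dataset(X, y), k=10, seed=0)
        assert res.k == 5
        assert "reducing folds" in caplog.text

    def test_tiny_class_rejected(self, rng):
        y = np.array([0, 1, 1, 1])
        X = rng.standard_normal((4, 2))
        with pytest.raises(ValueError):
            crossval_auc(_dataset(X, y))
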