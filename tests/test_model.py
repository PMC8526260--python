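"""The boosted-tree classifier: gradients, splits, leaves, training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mi_ecgkit.model import (GradientBoostedTreeClassifier, best_split,
                             leaf_weight, softmax_grad_hess)


class TestSoftmaxGradHess:
    def test_uniform_scores_closed_form(self):
        scores = np.zeros((1, 10))
        g, h = softmax_grad_hess(scores, np.array([3]))
        assert g[0, 3] == pytest.approx(-0.9)
        assert np.allclose(np.delete(g[0], 3), 0.1)
        assert h[0, 3] == pytest.approx(0.09)

    def test_confident_prediction_has_vanishing_gradient(self):
        scores = np.array([[50.0, 0.0, 0.0]])
        g, _ = softmax_grad_hess(scores, np.array([0]))
        assert abs(g[0, 0]) < 1e-12

    def test_hessian_nonnegative(self, rng):
        scores = rng.normal(size=(30, 5))
        _, h = softmax_grad_hess(scores, rng.integers(0, 5, 30))
        assert np.all(h >= 0)

    def test_matches_numerical_derivatives(self, rng):
        """g and h agree with central finite differences of the
        cross-entropy loss on random scores."""
        scores = rng.normal(size=(6, 4))
        y = rng.integers(0, 4, 6)
        g, h = softmax_grad_hess(scores, y)
        eps = 1e-5

        def loss(s, i):
            z = s - s.max()
            return -(z[y[i]] - np.log(np.exp(z).sum()))

        for i in range(6):
            for k in range(4):
                sp, sm = scores[i].copy(), scores[i].copy()
                sp[k] += eps
                sm[k] -= eps
                g_num = (loss(sp, i) - loss(sm, i)) / (2 * eps)
                h_num = (loss(sp, i) - 2 * loss(scores[i], i)
                         + loss(sm, i)) / eps ** 2
                assert g[i, k] == pytest.approx(g_num, abs=1e-5)
                assert h[i, k] == pytest.approx(h_num, abs=1e-4)

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError):
            softmax_grad_hess(np.array([[np.inf, 0.0]]), np.array([0]))


def brute_force_best_split(X, g, h, lam, gamma):
    """Exhaustive enumeration over every (feature, midpoint threshold)."""
    n, d = X.shape
    G, H = g.sum(), h.sum()
    parent = G * G / (H + lam)
    best = None
    for j in range(d):
        vals = np.unique(X[:, j])
        for a, b in zip(vals[:-1], vals[1:]):
            thr = 0.5 * (a + b)
            left = X[:, j] <= thr
            GL, HL = g[left].sum(), h[left].sum()
            GR, HR = G - GL, H - HL
            gain = 0.5 * (GL * GL / (HL + lam) + GR * GR / (HR + lam)
                          - parent) - gamma
            if gain > 1e-12 and (best is None or gain > best[2] + 1e-12):
                best = (j, thr, gain)
    return best


class TestBestSplit:
    def test_hand_worked_example(self):
        """x=[1,2,3,4], g=[-1,-1,1,1], h=1, lambda=1: the optimal split is
        between 2 and 3 with gain 1/2 [4/3 + 4/3 - 0/5] = 4/3."""
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        g = np.array([-1.0, -1.0, 1.0, 1.0])
        h = np.ones(4)
        feat, thr, gain = best_split(X, g, h, reg_lambda=1.0, gamma=0.0)
        assert feat == 0
        assert 2.0 < thr < 3.0
        assert gain == pytest.approx(4.0 / 3.0)

    def test_homogeneous_gradients_make_leaf(self):
        X = np.arange(8, dtype=float)[:, None]
        g = np.full(8, 0.5)
        h = np.full(8, 1.0)
        assert best_split(X, g, h, 1.0, gamma=0.1) is None

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.data())
    def test_matches_exhaustive_enumeration(self, data):
        """Property: on any small table the returned split equals the
        brute-force optimum over all (feature, threshold) pairs."""
        n = data.draw(st.integers(2, 8))
        d = data.draw(st.integers(1, 3))
        vals = st.integers(-3, 3)
        X = np.array(data.draw(st.lists(
            st.lists(vals, min_size=d, max_size=d),
            min_size=n, max_size=n)), dtype=float)
        g = np.array(data.draw(st.lists(vals, min_size=n, max_size=n)),
                     dtype=float)
        h = np.array(data.draw(st.lists(st.integers(0, 3),
                                        min_size=n, max_size=n)), dtype=float)
        lam, gamma = 1.0, 0.0
        mine = best_split(X, g, h, lam, gamma)
        oracle = brute_force_best_split(X, g, h, lam, gamma)
        if oracle is None:
            assert mine is None
        else:
            assert mine is not None
            assert mine[2] == pytest.approx(oracle[2], abs=1e-9)


class TestLeafWeight:
    def test_formula(self):
        assert leaf_weight(2.0, 3.0, 1.0) == pytest.approx(-0.5)
        assert leaf_weight(0.0, 5.0, 1.0) == 0.0

    def test_minimizes_leaf_quadratic_on_grid(self):
        """w* minimizes Gw + 1/2 (H+lambda) w^2 over a dense grid."""
        G, H, lam = 1.7, 2.3, 0.9
        w_star = leaf_weight(G, H, lam)
        grid = np.linspace(-3, 3, 20001)
        obj = G * grid + 0.5 * (H + lam) * grid ** 2
        assert abs(grid[np.argmin(obj)] - w_star) < 1e-3

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            leaf_weight(1.0, -2.0, 1.0)


@pytest.fixture(scope="module")
def toy_separable(rng=None):
    r = np.random.default_rng(17)
    X = np.vstack([r.normal(0, 0.5, (10, 2)), r.normal(4, 0.5, (10, 2))])
    y = np.array(["a"] * 10 + ["b"] * 10)
    return X, y


class TestBoosting:
    def test_separable_data_reaches_full_training_accuracy(self, toy_separable):
        X, y = toy_separable
        m = GradientBoostedTreeClassifier(n_estimators=20, max_depth=3,
                                          learning_rate=0.3, colsample=1.0,
                                          random_state=0).fit(X, y)
        assert (m.predict(X) == y).mean() == 1.0

    def test_zero_rounds_predict_uniform(self, toy_separable):
        X, y = toy_separable
        m = GradientBoostedTreeClassifier(n_estimators=0).fit(X, y)
        p = m.predict_proba(X)
        assert np.allclose(p, 0.5)

    def test_training_loss_non_increasing(self, toy_separable):
        X, y = toy_separable
        m = GradientBoostedTreeClassifier(n_estimators=30, max_depth=3,
                                          learning_rate=0.2, colsample=1.0,
                                          random_state=0).fit(X, y)
        assert np.all(np.diff(m.train_loss_) <= 1e-12)

    def test_probabilities_sum_to_one(self, rng, toy_separable):
        X, y = toy_separable
        m = GradientBoostedTreeClassifier(n_estimators=5,
                                          random_state=0).fit(X, y)
        p = m.predict_proba(rng.normal(size=(40, 2)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_increasing_gamma_never_increases_leaf_count(self, rng):
        X = rng.normal(size=(100, 5))
        y = (X[:, 0] + 0.3 * rng.normal(size=100) > 0).astype(str)
        leaves = []
        for gamma in (0.0, 0.5, 2.0, 8.0):
            m = GradientBoostedTreeClassifier(
                n_estimators=5, max_depth=4, gamma=gamma, colsample=1.0,
                random_state=0).fit(X, y)
            leaves.append(m.total_leaves())
        assert all(a >= b for a, b in zip(leaves, leaves[1:]))

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(60, 8))
        y = (X[:, 0] > 0).astype(str)
        a = GradientBoostedTreeClassifier(n_estimators=5, colsample=0.5,
                                          random_state=3).fit(X, y)
        b = GradientBoostedTreeClassifier(n_estimators=5, colsample=0.5,
                                          random_state=3).fit(X, y)
        assert a.to_json() == b.to_json()

    def test_feature_count_mismatch_rejected(self, toy_separable):
        X, y = toy_separable
        m = GradientBoostedTreeClassifier(n_estimators=2).fit(X, y)
        with pytest.raises(ValueError, match="features"):
            m.predict(np.zeros((3, 5)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            GradientBoostedTreeClassifier().fit(np.zeros((5, 2)),
                                                np.array(["a"] * 5))

    def test_json_roundtrip_preserves_predictions(self, toy_separable):
        X, y = toy_separable
        m = GradientBoostedTreeClassifier(n_estimators=10, random_state=0
                                          ).fit(X, y)
        m2 = GradientBoostedTreeClassifier.from_json(m.to_json())
        assert np.array_equal(m.predict_proba(X), m2.predict_proba(X))

    def test_agrees_with_reference_library(self):
        """On matched hyperparameters and easy data, predictions agree
        with xgboost on >=95% of held-out points."""
        xgb = pytest.importorskip("xgboost")
        r = np.random.default_rng(5)
        X = np.vstack([r.normal(0, 1, (100, 4)), r.normal(3, 1, (100, 4))])
        y = np.array([0] * 100 + [1] * 100)
        Xt = np.vstack([r.normal(0, 1, (50, 4)), r.normal(3, 1, (50, 4))])
        yt = np.array([0] * 50 + [1] * 50)
        mine = GradientBoostedTreeClassifier(
            n_estimators=30, max_depth=4, learning_rate=0.2, reg_lambda=1.0,
            gamma=0.0, colsample=1.0, random_state=0).fit(X, y)
        ref = xgb.XGBClassifier(
            n_estimators=30, max_depth=4, learning_rate=0.2, reg_lambda=1.0,
            gamma=0.0, tree_method="exact", n_jobs=1).fit(X, y)
        agree = np.mean(mine.predict(Xt) == ref.predict(Xt))
        assert agree >= 0.95
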