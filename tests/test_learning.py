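"""Feature selection, SMOTE balancing and the classical classifiers."""

import numpy as np
import pytest

from physiomap.learning import (ModelSpec, make_classical_estimator, predict,
                                relieff_rank, smote_balance, top_fraction,
                                train_classical, wrapper_select)


def _brute_force_relieff(Xs, y, k):
    """Literal per-instance ReliefF on a scaled matrix (binary labels)."""
    n, f = Xs.shape
    W = np.zeros(f)
    priors = {c: np.mean(y == c) for c in np.unique(y)}
    for i in range(n):
        d = np.abs(Xs - Xs[i]).sum(axis=1)
        for c in np.unique(y):
            same = [j for j in range(n) if j != i and y[j] == c]
            same.sort(key=lambda j: d[j])
            near = same[:k]
            diff = np.abs(Xs[near] - Xs[i]).mean(axis=0)
            if c == y[i]:
                W -= diff / n
            else:
                W += priors[c] / (1 - priors[y[i]]) * diff / n
    return W


class TestRelieff:
    def _toy(self, rng):
        # 20 x 2: one perfectly class-separating feature, one pure noise
        y = np.array(["IDHwt"] * 10 + ["IDHmut"] * 10)
        sep = np.r_[rng.uniform(0, 0.4, 10), rng.uniform(0.6, 1.0, 10)]
        noise = rng.random(20)
        return np.c_[noise, sep], y

    def test_separating_feature_ranked_first(self, rng):
        X, y = self._toy(rng)
        _, order = relieff_rank(X, y, k_neighbors=3)
        assert order[0] == 1

    def test_matches_brute_force_on_toy_matrix(self, rng):
        X, y = self._toy(rng)
        W, _ = relieff_rank(X, y, k_neighbors=3)
        span = X.max(axis=0) - X.min(axis=0)
        Xs = (X - X.min(axis=0)) / span
        expected = _brute_force_relieff(Xs, y, k=3)
        assert np.allclose(W, expected, atol=1e-12)

    def test_constant_feature_weight_zero(self, rng):
        X, y = self._toy(rng)
        X = np.c_[X, np.full(20, 3.7)]
        W, _ = relieff_rank(X, y, k_neighbors=3)
        assert W[2] == 0.0

    def test_label_permutation_shrinks_weights(self, rng):
        X, y = self._toy(rng)
        W_true, _ = relieff_rank(X, y, k_neighbors=3)
        perm_w = []
        for _ in range(100):
            W_p, _ = relieff_rank(X, y[rng.permutation(20)], k_neighbors=3)
            perm_w.append(W_p[1])
        assert np.mean(perm_w) < W_true[1]

    def test_single_class_rejected(self, rng):
        X = rng.random((10, 3))
        with pytest.raises(ValueError):
            relieff_rank(X, np.repeat("IDHwt", 10))

    def test_shortlist_size_is_ceil_quarter(self):
        ranking = np.arange(428)
        assert top_fraction(ranking, 428).size == int(np.ceil(0.25 * 428)) == 107


class TestWrapper:
    def _classifier(self, seed=0):
        from sklearn.tree import DecisionTreeClassifier
        return DecisionTreeClassifier(criterion="entropy", random_state=seed)

    def test_single_separating_feature_selected_quickly(self, rng):
        y = np.array(["IDHwt"] * 20 + ["IDHmut"] * 20)
        X = rng.random((40, 6))
        X[:, 3] = np.r_[np.zeros(20), np.ones(20)] + 0.01 * rng.random(40)
        selected, history = wrapper_select([3, 0, 1, 2, 4, 5], X, y, self._classifier(),
                                           folds=5, seed=1)
        assert selected[0] == 3
        assert history[0] == pytest.approx(1.0)
        assert len(selected) <= 2

    def test_all_noise_shortlist_stays_small_with_chance_accuracy(self, rng):
        # large-enough folds keep the best-of-pool selection bias inside the
        # chance band; many repetitions select nothing at all
        sizes, accs = [], []
        for rep in range(10):
            y = np.array(["IDHwt"] * 50 + ["IDHmut"] * 50)
            X = rng.random((100, 8))
            selected, history = wrapper_select(list(range(8)), X, y, self._classifier(),
                                               folds=10, seed=rep)
            sizes.append(len(selected))
            accs.append(history[-1] if history else 0.5)
        # best-of-pool selection bias admits a few noise features but the
        # search stops far short of the pool and stays in the chance band
        assert np.median(sizes) <= 3
        assert max(sizes) <= 4
        assert abs(np.mean(accs) - 0.5) < 0.15

    def test_fixed_seed_reproducible(self, rng):
        y = np.array(["IDHwt"] * 20 + ["IDHmut"] * 20)
        X = rng.random((40, 10))
        a = wrapper_select(list(range(10)), X, y, self._classifier(), folds=5, seed=3)
        b = wrapper_select(list(range(10)), X, y, self._classifier(), folds=5, seed=3)
        assert a == b

    def test_empty_shortlist_rejected(self, rng):
        with pytest.raises(ValueError):
            wrapper_select([], rng.random((10, 2)),
                           np.repeat(["IDHwt", "IDHmut"], 5), self._classifier())


class TestSmote:
    def test_imbalanced_cohort_counts_equalised(self, rng):
        # the study cohort imbalance: 43 minority vs 123 majority
        X = rng.random((166, 5))
        y = np.array(["IDHwt"] * 123 + ["IDHmut"] * 43)
        Xb, yb = smote_balance(X, y)
        assert (yb == "IDHwt").sum() == (yb == "IDHmut").sum() == 123

    def test_balanced_input_only_shuffled(self, rng):
        X = rng.random((20, 3))
        y = np.repeat(["IDHwt", "IDHmut"], 10)
        Xb, yb = smote_balance(X, y)
        assert Xb.shape == X.shape
        assert sorted(map(tuple, Xb)) == sorted(map(tuple, X))

    def test_synthetic_points_lie_on_parent_segments(self, rng):
        X = rng.random((40, 4))
        y = np.array(["IDHwt"] * 30 + ["IDHmut"] * 10)
        Xb, yb = smote_balance(X, y, k=5, seed=2)
        originals = {tuple(r) for r in X}
        minority = X[y == "IDHmut"]
        synth = [r for r, lab in zip(Xb, yb) if lab == "IDHmut" and tuple(r) not in originals]
        assert len(synth) == 20
        for s in synth:
            # collinear with some minority pair and between them
            ok = False
            for i in range(len(minority)):
                for j in range(len(minority)):
                    if i == j:
                        continue
                    v1, v2 = s - minority[i], minority[j] - minority[i]
                    denom = np.dot(v2, v2)
                    lam = np.dot(v1, v2) / denom
                    if 0 <= lam <= 1 and np.linalg.norm(v1 - lam * v2) < 1e-9:
                        ok = True
                        break
                if ok:
                    break
            assert ok

    def test_tiny_minority_rejected(self, rng):
        X = rng.random((10, 2))
        y = np.array(["IDHwt"] * 7 + ["IDHmut"] * 3)
        with pytest.raises(ValueError):
            smote_balance(X, y, k=5)


class TestClassical:
    def _separable(self, rng, n=40):
        y = np.array(["IDHwt"] * (n // 2) + ["IDHmut"] * (n // 2))
        X = np.clip(rng.standard_normal((n, 2)), -2.5, 2.5)
        X[y == "IDHmut"] += 6.0  # margin wide enough for exact separation
        return X, y

    @pytest.mark.parametrize("kind", ["MLP", "ABoost", "RF"])
    def test_separable_toy_perfect_cv(self, kind, rng):
        X, y = self._separable(rng)
        model = train_classical(X, y, ModelSpec(kind, seed=0))
        assert model.history["cv_accuracy"] == pytest.approx(1.0)

    def test_permuted_labels_give_chance_cv(self, rng):
        accs = []
        for rep in range(10):
            X, y = self._separable(rng)
            yp = y[rng.permutation(len(y))]
            model = train_classical(X, yp, ModelSpec("RF", seed=rep))
            accs.append(model.history["cv_accuracy"])
        assert abs(np.mean(accs) - 0.5) < 0.12

    def test_mlp_hidden_width_is_features_plus_classes(self):
        est = make_classical_estimator("MLP", 428, seed=0, hyper={})
        assert est.named_steps["mlpclassifier"].hidden_layer_sizes == (430,)

    def test_predict_contracts(self, rng):
        X, y = self._separable(rng)
        names = ["f0", "f1"]
        model = train_classical(X, y, ModelSpec("RF", seed=0), feature_names=names)
        p = predict(model, X, feature_names=names)
        assert np.all((p >= 0) & (p <= 1))
        # training data through its own model: accuracy >= CV estimate - 0.1
        acc = np.mean(np.where(p >= 0.5, "IDHmut", "IDHwt") == y)
        assert acc >= model.history["cv_accuracy"] - 0.1

    def test_feature_mismatch_names_discrepancy(self, rng):
        X, y = self._separable(rng)
        model = train_classical(X, y, ModelSpec("RF", seed=0), feature_names=["a", "b"])
        with pytest.raises(ValueError, match="manifest"):
            predict(model, X, feature_names=["a", "zzz"])
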