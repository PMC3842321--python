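import numpy as np
import pytest

from pgl_metabotyper.chemometrics import (
    ConfusionMatrix,
    MCCVConfig,
    Performance,
    PLSDAModel,
    PreprocessParams,
    apply_preprocess,
    mccv,
    pca,
    performance,
    plsda_fit,
    plsda_predict,
    preprocess,
    round_half_away,
    select_components_q2,
)


def separable_data(rng, n_per_class=10, gap=8.0):
    """Two classes with disjoint ranges in the first feature."""
    X = rng.normal(size=(2 * n_per_class, 4))
    X[:n_per_class, 0] = rng.uniform(gap, gap + 1.0, size=n_per_class)
    X[n_per_class:, 0] = rng.uniform(0.0, 1.0, size=n_per_class)
    y = np.array(["a"] * n_per_class + ["b"] * n_per_class)
    return X, y


class TestPreprocess:
    def test_constant_column_centered_to_zero(self):
        X = np.column_stack([np.full(5, 3.0), np.arange(5.0)])
        Xt, _ = preprocess(X, mode="none")
        assert np.allclose(Xt[:, 0], 0.0)

    def test_unit_variance_column_sd(self, rng):
        X = rng.normal(size=(20, 4)) * np.array([1, 10, 100, 1000])
        Xt, _ = preprocess(X, mode="unit_variance")
        assert np.allclose(Xt.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_pareto_scaling(self, rng):
        X = rng.normal(size=(20, 3))
        Xt, params = preprocess(X, mode="pareto")
        sd = X.std(axis=0, ddof=1)
        assert np.allclose(Xt, (X - X.mean(axis=0)) / np.sqrt(sd))

    def test_transform_idempotence(self, rng):
        X = rng.normal(size=(12, 4))
        Xt, params = preprocess(X, mode="unit_variance")
        assert np.allclose(apply_preprocess(X, params), Xt)

    def test_zero_variance_dropped_with_warning(self, rng):
        X = np.column_stack([np.full(8, 2.0), rng.normal(size=8)])
        with pytest.warns(UserWarning, match="zero-variance"):
            Xt, params = preprocess(X, mode="unit_variance")
        assert Xt.shape == (8, 1)
        assert params.kept.tolist() == [False, True]


class TestPCA:
    def test_collinear_data_pc1_explains_all(self):
        t = np.linspace(-1, 1, 10)
        X = np.outer(t, [1.0, 2.0, -0.5])
        res = pca(X, 1)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_full_rank_reconstruction(self, rng):
        X = rng.normal(size=(8, 3))
        Xc = X - X.mean(axis=0)
        res = pca(Xc, 3)
        assert np.allclose(res.scores @ res.loadings.T, Xc, atol=1e-10)

    def test_explained_variance_vs_eigendecomposition(self, rng):
        # brute-force oracle: eigenvalues of the sample covariance matrix
        X = rng.normal(size=(6, 4))
        Xc = X - X.mean(axis=0)
        res = pca(Xc, 3)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(Xc, rowvar=False)))[::-1]
        assert np.allclose(res.explained_variance, eigvals[:3], atol=1e-10)

    def test_loadings_orthonormal(self, rng):
        X = rng.normal(size=(10, 4))
        res = pca(X - X.mean(axis=0), 3)
        assert np.allclose(res.loadings.T @ res.loadings, np.eye(3), atol=1e-12)

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError):
            pca(np.zeros((5, 3)), 1)

    def test_hotelling_outlier_flagged(self, rng):
        X = rng.normal(size=(30, 3))
        X[0] += 50.0
        Xc = X - X.mean(axis=0)
        res = pca(Xc, 2)
        assert res.outlier_flags[0]


class TestPLSDAFit:
    def test_first_weight_closed_form(self, rng):
        # oracle: with one component and two classes, w is proportional to
        # X-transposed times the centered dummy column
        X, y = separable_data(rng, gap=1.0)
        model = plsda_fit(X, y, n_components=1, scaling="none")
        Xc = X - X.mean(axis=0)
        dummy = (y == "a").astype(float)
        w_oracle = Xc.T @ (dummy - dummy.mean())
        w_oracle /= np.linalg.norm(w_oracle)
        w = model.weights[:, 0]
        assert np.allclose(w, np.sign(w @ w_oracle) * w_oracle, atol=1e-8)

    def test_training_accuracy_separable(self, rng):
        X, y = separable_data(rng)
        model = plsda_fit(X, y, n_components=2)
        pred, _ = plsda_predict(model, X)
        assert np.all(pred == y)

    def test_score_orthogonality(self, rng):
        X = rng.normal(size=(15, 4))
        y = np.array(["a", "b", "c"] * 5)
        model = plsda_fit(X, y, n_components=2)
        T = model.scores
        dot = abs(T[:, 0] @ T[:, 1])
        assert dot < 1e-8 * np.linalg.norm(T[:, 0]) * np.linalg.norm(T[:, 1])

    def test_coefficients_reproduce_training_fit(self, rng):
        X = rng.normal(size=(12, 4))
        y = np.array(["a", "b"] * 6)
        model = plsda_fit(X, y, n_components=2, scaling="unit_variance")
        Xt = apply_preprocess(X, model.params)
        fitted = model.scores @ model.y_loadings.T
        assert np.allclose(Xt @ model.coefficients, fitted, atol=1e-10)

    def test_duplicated_feature_equivalence(self, rng):
        # duplicating a column is algebraically identical to scaling that
        # single column by sqrt(2) under centering-only preprocessing
        X = rng.normal(size=(10, 2))
        y = np.array(["a", "b"] * 5)
        X_dup = np.column_stack([X[:, 0], X[:, 0], X[:, 1]])
        X_scaled = np.column_stack([np.sqrt(2) * X[:, 0], X[:, 1]])
        m_dup = plsda_fit(X_dup, y, n_components=2, scaling="none")
        m_scaled = plsda_fit(X_scaled, y, n_components=2, scaling="none")
        # duplicated columns carry identical coefficients
        assert np.allclose(m_dup.coefficients[0], m_dup.coefficients[1], atol=1e-10)
        X_new = rng.normal(size=(5, 2))
        _, s_dup = plsda_predict(m_dup, np.column_stack([X_new[:, 0], X_new[:, 0], X_new[:, 1]]))
        _, s_scaled = plsda_predict(
            m_scaled, np.column_stack([np.sqrt(2) * X_new[:, 0], X_new[:, 1]])
        )
        assert np.allclose(s_dup, s_scaled, atol=1e-8)

    def test_rank_truncation_warns(self):
        t = np.linspace(-1, 1, 8)
        X = np.column_stack([t, 2 * t, -t, 0.5 * t])  # rank 1
        y = np.array(["a", "b"] * 4)
        with pytest.warns(UserWarning, match="truncat"):
            model = plsda_fit(X, y, n_components=3, scaling="none")
        assert model.n_components < 3


class TestPLSDAPredict:
    def test_training_rows_predicted_correctly(self, rng):
        X, y = separable_data(rng)
        model = plsda_fit(X, y)
        pred, _ = plsda_predict(model, X)
        assert np.all(pred == y)

    def test_exact_tie_breaks_alphabetically(self):
        params = PreprocessParams(
            mean=np.zeros(2), scale=np.ones(2), kept=np.ones(2, dtype=bool), mode="none"
        )
        model = PLSDAModel(
            classes=["alpha", "beta"],
            params=params,
            n_components=1,
            weights=np.zeros((2, 1)),
            x_loadings=np.zeros((2, 1)),
            y_loadings=np.zeros((2, 1)),
            coefficients=np.zeros((2, 2)),
            scores=np.zeros((4, 1)),
            y_mean=np.array([0.5, 0.5]),
        )
        pred, scores = plsda_predict(model, np.array([[1.0, 2.0]]))
        assert scores[0, 0] == scores[0, 1]
        assert pred[0] == "alpha"

    def test_feature_mismatch_rejected(self, rng):
        X, y = separable_data(rng)
        model = plsda_fit(X, y)
        with pytest.raises(ValueError, match="feature mismatch"):
            plsda_predict(model, rng.normal(size=(3, 5)))

    def test_prediction_matches_deflation_oracle(self, rng):
        # independent route: accumulate t q' per component while deflating
        # X_new by t p', instead of using the collapsed coefficient matrix
        X = rng.normal(size=(14, 4))
        y = np.array(["a", "b"] * 7)
        model = plsda_fit(X, y, n_components=2, scaling="unit_variance")
        X_new = rng.normal(size=(6, 4))
        _, scores = plsda_predict(model, X_new)
        Xd = apply_preprocess(X_new, model.params)
        oracle = np.tile(model.y_mean, (6, 1))
        W, P, Q = model.weights, model.x_loadings, model.y_loadings
        for a in range(model.n_components):
            t = Xd @ W[:, a]
            oracle += np.outer(t, Q[:, a])
            Xd = Xd - np.outer(t, P[:, a])
        assert np.allclose(scores, oracle, atol=1e-8)


class TestMCCV:
    def test_separable_data_perfect_pooled_accuracy(self, rng):
        # centering-only scaling: UV scaling would inflate the pure-noise
        # features to the same scale as the (hugely) separating one
        X, y = separable_data(rng, n_per_class=9)
        res = mccv(X, y, MCCVConfig(n_iterations=100, seed=0, scaling="none"))
        assert res.pooled_accuracy == 1.0

    def test_permutation_null_near_chance(self, rng):
        X = rng.normal(size=(24, 4))
        y = np.array(["a", "b"] * 12)
        rng.shuffle(y)
        res = mccv(X, y, MCCVConfig(n_iterations=500, seed=1))
        assert abs(res.pooled_accuracy - 0.5) <= 0.1

    def test_determinism(self, rng):
        X, y = separable_data(rng)
        r1 = mccv(X, y, MCCVConfig(n_iterations=50, seed=3))
        r2 = mccv(X, y, MCCVConfig(n_iterations=50, seed=3))
        assert np.array_equal(r1.confusion.counts, r2.confusion.counts)

    def test_counts_sum_to_iterations_times_test_size(self, rng):
        X, y = separable_data(rng, n_per_class=10)
        cfg = MCCVConfig(n_iterations=40, seed=2)
        res = mccv(X, y, cfg)
        expected_per_iter = sum(res.test_counts.values())
        assert res.confusion.total == cfg.n_iterations * expected_per_iter
        # row sums match per-class allocations
        for i, c in enumerate(res.confusion.classes):
            assert res.confusion.counts[i].sum() == cfg.n_iterations * res.test_counts[c]

    def test_class_too_small_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        y = np.array(["a", "a", "a", "a", "b"])
        with pytest.raises(ValueError, match="too small.*b"):
            mccv(X, y, MCCVConfig(n_iterations=5))


class TestPerformance:
    def test_two_class_printed_counts(self):
        cm = ConfusionMatrix(["SDHx", "sporadic"], np.array([[11, 1], [1, 9]]))
        p = performance(cm, "SDHx").as_percent()
        assert p == {
            "sensitivity": 92,
            "specificity": 90,
            "ppv": 92,
            "npv": 90,
            "accuracy": 91,
        }

    def test_carrier_collapse_counts(self):
        cm = ConfusionMatrix(["positive", "negative"], np.array([[17, 1], [2, 8]]))
        p = performance(cm, "positive").as_percent()
        assert p["sensitivity"] == 94
        assert p["specificity"] == 80
        assert p["ppv"] == 89
        assert p["npv"] == 89
        assert p["accuracy"] == 89

    def test_all_correct(self):
        cm = ConfusionMatrix(["a", "b"], np.array([[5, 0], [0, 7]]))
        p = performance(cm, "a").as_percent()
        assert all(v == 100 for v in p.values())

    def test_zero_denominator_is_none_not_zero(self):
        cm = ConfusionMatrix(["a", "b"], np.array([[0, 0], [1, 5]]))
        p = performance(cm, "a")
        assert p.sensitivity is None
        assert p.as_percent()["sensitivity"] is None

    def test_class_set_positive(self):
        cm = ConfusionMatrix(
            ["SDHx", "VHL", "sporadic"],
            np.array([[12, 0, 0], [0, 5, 1], [1, 1, 8]]),
        )
        p = performance(cm, {"SDHx", "VHL"})
        assert p.sensitivity == pytest.approx(17 / 18)
        assert p.specificity == pytest.approx(8 / 10)

    def test_permutation_invariance(self, rng):
        classes = ["a", "b", "c"]
        counts = rng.integers(0, 20, size=(3, 3))
        counts[np.diag_indices(3)] += 5
        cm = ConfusionMatrix(classes, counts)
        perm = [2, 0, 1]
        cm_perm = ConfusionMatrix(
            [classes[i] for i in perm], counts[np.ix_(perm, perm)]
        )
        for positive in ("a", {"a", "b"}):
            p1 = performance(cm, positive)
            p2 = performance(cm_perm, positive)
            assert p1 == p2

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(91.5) == 92
        assert round_half_away(90.4999) == 90
        assert round_half_away(-2.5) == -3


class TestComponentSelection:
    def test_q2_selector_reasonable(self, rng):
        X, y = separable_data(rng, n_per_class=8)
        k = select_components_q2(X, y, max_components=3)
        assert 1 <= k <= 3
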