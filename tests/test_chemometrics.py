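"""PCA/OPLS-DA model behavior, cross-validation, VIP, ROC, classification."""
import numpy as np
import pandas as pd
import pytest

from lipidscreen.chemometrics import (
    auto_select_orthogonal,
    classification_metrics,
    classify,
    crossvalidate_q2,
    fit_opls_da,
    fit_pca,
    predict,
    roc_auc,
    splot,
    vip,
)


def _scaled(X):
    return (X - X.mean(0)) / X.std(0, ddof=1)


@pytest.fixture
def separable(rng):
    n = 60
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 8))
    X[:, 0] += 6 * y  # pure separating direction
    return _scaled(X), y


class TestPca:
    def test_collinear_data_first_component_explains_all(self):
        t = np.linspace(-1, 1, 20)
        X = np.outer(t, [1.0, 2.0, -0.5])
        scores, loadings, evr = fit_pca(X)
        assert evr[0] == pytest.approx(1.0)

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(20, 10))
        X = X - X.mean(0)
        scores, loadings, _ = fit_pca(X)
        assert np.allclose(scores @ loadings.T, X, atol=1e-8)

    def test_sign_convention_deterministic(self, rng):
        X = rng.normal(size=(15, 6))
        _, l1, _ = fit_pca(X)
        _, l2, _ = fit_pca(X.copy())
        assert np.allclose(l1, l2)
        for j in range(l1.shape[1]):
            assert l1[np.argmax(np.abs(l1[:, j])), j] > 0


class TestOplsDa:
    def test_zero_orthogonal_equals_pls1(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = _scaled(rng.normal(size=(40, 12)))
        y = (rng.random(40) > 0.5).astype(int)
        model = fit_opls_da(X, y, n_orthogonal=0)
        pls = PLSRegression(n_components=1, scale=False).fit(X, y.astype(float))
        assert np.allclose(predict(model, X), pls.predict(X).ravel(), atol=1e-8)

    def test_orthogonal_component_captures_nuisance(self, rng):
        # class signal along e1, strong class-unrelated nuisance along e2
        n = 80
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 6)) * 0.2
        X[:, 0] += 1.5 * y
        X[:, 1] += 4.0 * rng.normal(size=n)
        Xs = _scaled(X)
        opls = fit_opls_da(Xs, y, n_orthogonal=1)
        pls = fit_opls_da(Xs, y, n_orthogonal=0)
        assert abs(opls.p_ortho[0, 1]) > abs(opls.p_ortho[0, 0])
        r_opls = np.corrcoef(opls.t, y)[0, 1]
        r_pls = np.corrcoef(pls.t, y)[0, 1]
        assert r_opls > r_pls

    def test_separable_clusters_perfect_training_accuracy(self, separable):
        X, y = separable
        model = fit_opls_da(X, y, 0)
        rep = classification_metrics(y, classify(predict(model, X)))
        assert rep.accuracy == 100.0

    def test_predictive_score_orthogonal_to_orthogonal_scores(self, rng):
        X = _scaled(rng.normal(size=(50, 10)))
        y = (rng.random(50) > 0.5).astype(int)
        model = fit_opls_da(X, y, n_orthogonal=3)
        for to in model.t_ortho:
            assert abs(model.t @ to) < 1e-8 * np.linalg.norm(model.t) * np.linalg.norm(to)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="single class"):
            fit_opls_da(X, np.ones(10), 0)

    def test_sample_permutation_equivariance(self, separable, rng):
        X, y = separable
        model = fit_opls_da(X, y, 1)
        perm = rng.permutation(len(y))
        model_p = fit_opls_da(X[perm], y[perm], 1)
        assert np.allclose(model_p.w, model.w, atol=1e-10)
        assert np.allclose(predict(model, X)[perm], predict(model_p, X[perm]), atol=1e-10)


class TestPredict:
    def test_training_set_reproduces_fitted_values(self, separable):
        X, y = separable
        model = fit_opls_da(X, y, 1)
        fitted = model.t * model.q + model.y_mean
        assert np.allclose(predict(model, X), fitted, atol=1e-10)

    def test_duplicated_sample_same_prediction(self, separable):
        X, y = separable
        model = fit_opls_da(X, y, 1)
        y_hat = predict(model, X)
        dup = predict(model, X[[3]])
        assert dup[0] == pytest.approx(y_hat[3], abs=1e-12)

    def test_species_mismatch_listed(self, separable):
        X, y = separable
        model = fit_opls_da(X, y, 0, species=[f"L{i}" for i in range(X.shape[1])])
        with pytest.raises(ValueError, match="L7"):
            predict(model, X[:, :7], species=[f"L{i}" for i in range(7)])


class TestCrossvalidation:
    def test_null_data_q2_nonpositive_in_median(self, rng):
        q2s = []
        for i in range(50):
            X = rng.normal(size=(35, 10))
            y = (rng.random(35) > 0.5).astype(int)
            if y.sum() in (0, len(y)):
                continue
            q2s.append(crossvalidate_q2(_scaled(X), y, 0, seed=i))
        assert np.median(q2s) < 0.05

    def test_noiseless_linear_relation_q2_near_one(self, rng):
        n = 70
        y = np.repeat([0.0, 1.0], n // 2)
        X = np.column_stack([y, y, y]) + 0.0
        X = X + rng.normal(size=X.shape) * 1e-6
        assert crossvalidate_q2(_scaled(X), y, 0, seed=0) > 0.99

    def test_q2_never_exceeds_r2y(self, rng):
        for i in range(10):
            X = rng.normal(size=(40, 8))
            y = (X[:, 0] + rng.normal(size=40) > 0).astype(int)
            if y.sum() in (0, len(y)):
                continue
            Xs = _scaled(X)
            model = fit_opls_da(Xs, y, 0)
            q2 = crossvalidate_q2(Xs, y, 0, seed=i)
            assert q2 <= model.R2Y + 1e-9


class TestAutoSelectOrthogonal:
    def test_pure_signal_returns_zero(self, rng):
        # every variable is the class signal plus tiny noise: nothing
        # orthogonal to remove, Q2 is already at its ceiling
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = np.column_stack([y + rng.normal(size=n) * 1e-3 for _ in range(5)])
        assert auto_select_orthogonal(_scaled(X), y, max_k=3, seed=0) == 0

    def test_nuisance_direction_adds_component(self, rng):
        n = 120
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 5)) * 0.1
        X[:, 0] += 0.8 * y
        nuisance = rng.normal(size=n) * 5
        X[:, 1] += nuisance
        X[:, 2] += 0.5 * nuisance
        assert auto_select_orthogonal(_scaled(X), y, max_k=3, seed=0) >= 1

    def test_bounded_by_max_k(self, rng):
        X = _scaled(rng.normal(size=(30, 6)))
        y = (rng.random(30) > 0.5).astype(int)
        assert auto_select_orthogonal(X, y, max_k=2, seed=0) <= 2


class TestClassifyAndMetrics:
    @pytest.mark.parametrize(
        "y_hat,expected",
        [(0.5, 0), (0.51, 1), (-0.2, 0), (1.4, 1)],
    )
    def test_y_cutoff_boundary(self, y_hat, expected):
        assert classify([y_hat])[0] == expected

    def test_perfect_prediction(self):
        rep = classification_metrics([1, 0, 1], [1, 0, 1])
        assert (rep.sensitivity, rep.specificity, rep.accuracy) == (100.0, 100.0, 100.0)

    def test_forced_confusion_arithmetic(self):
        truth = [1] * 10 + [0] * 10
        pred = [1] * 9 + [0] + [0] * 8 + [1] * 2
        rep = classification_metrics(truth, pred)
        assert rep.sensitivity == pytest.approx(90.0)
        assert rep.specificity == pytest.approx(80.0)
        assert rep.accuracy == pytest.approx(85.0)

    def test_all_predicted_positive_zero_specificity(self):
        rep = classification_metrics([1, 0, 0], [1, 1, 1])
        assert rep.specificity == 0.0

    def test_no_positives_sensitivity_missing(self):
        rep = classification_metrics([0, 0], [0, 1])
        assert np.isnan(rep.sensitivity)


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == pytest.approx(1.0)

    def test_all_tied_scores(self):
        _, auc = roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_matches_exhaustive_pair_counting(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 13))
            scores = rng.integers(0, 5, n).astype(float)  # force ties
            truth = rng.integers(0, 2, n)
            if truth.sum() in (0, n):
                continue
            _, auc = roc_auc(scores, truth)
            pos = scores[truth == 1]
            neg = scores[truth == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])


class TestVip:
    def test_single_variable_vip_is_one(self, rng):
        y = np.repeat([0, 1], 10)
        X = (y + rng.normal(size=20) * 0.1).reshape(-1, 1)
        model = fit_opls_da(_scaled(X), y, 0)
        assert vip(model)[0] == pytest.approx(1.0)

    def test_mean_squared_vip_is_one(self, rng):
        for k in (0, 2):
            X = _scaled(rng.normal(size=(40, 9)))
            y = (rng.random(40) > 0.5).astype(int)
            model = fit_opls_da(X, y, k)
            assert np.mean(vip(model) ** 2) == pytest.approx(1.0, abs=1e-10)

    def test_informative_markers_rank_on_top(self):
        # 7 configured markers among nulls: top-7 VIP should contain them
        from lipidscreen.preprocess import transform_scale
        from lipidscreen.synthetic import CohortConfig, generate_cohort
        from lipidscreen.lipids import MARKER_SPECIES

        hits = 0
        reps = 10
        for i in range(reps):
            cfg = CohortConfig(n_cases=200, n_controls=200, n_lipids=60, seed=300 + i)
            matrix, samples = generate_cohort(cfg)
            X, _ = transform_scale(matrix, log=True, scaling="pareto")
            y = (samples["group"] == "T").astype(int).to_numpy()
            model = fit_opls_da(X.to_numpy(), y, 0, species=list(X.columns))
            v = pd.Series(vip(model), index=X.columns)
            top7 = set(v.nlargest(7).index)
            hits += top7 == set(MARKER_SPECIES)
        assert hits / reps >= 0.9


class TestSplot:
    def test_species_equal_to_score_has_unit_correlation(self, separable):
        X, y = separable
        model = fit_opls_da(X, y, 0)
        X_aug = np.column_stack([X, model.t])
        coords = splot(model, X_aug)
        assert coords["pcorr1"].iloc[-1] == pytest.approx(1.0)

    def test_marker_correlation_signs_match_directions(self):
        from lipidscreen.preprocess import transform_scale
        from lipidscreen.synthetic import CohortConfig, generate_cohort
        from lipidscreen.lipids import MARKER_SPECIES

        cfg = CohortConfig(n_cases=200, n_controls=200, n_lipids=40, seed=5)
        matrix, samples = generate_cohort(cfg)
        X, _ = transform_scale(matrix, log=True, scaling="pareto")
        y = (samples["group"] == "T").astype(int).to_numpy()
        model = fit_opls_da(X.to_numpy(), y, 0, species=list(X.columns))
        coords = splot(model, X.to_numpy())
        # downregulated markers anticorrelate with the case-positive score
        for name in MARKER_SPECIES:
            assert coords.loc[name, "pcorr1"] < 0

    def test_correlation_bounded(self, rng):
        X = _scaled(rng.normal(size=(30, 6)))
        y = (rng.random(30) > 0.5).astype(int)
        model = fit_opls_da(X, y, 1)
        coords = splot(model, X)
        assert (coords["pcorr1"].abs() <= 1 + 1e-12).all()
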