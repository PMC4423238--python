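"""Fisher discriminant, LOOCV, confusion metrics and PCA-LDA."""

import numpy as np
import pytest

import sersband as sb
from sersband.lda import _masks


def random_two_class(rng, n_per_class=8, p=2, sep=2.0):
    mu = rng.normal(0, 1, size=p)
    delta = rng.normal(0, 1, size=p)
    delta *= sep / np.linalg.norm(delta)
    A = rng.normal(0, 1, size=(p, p))
    cov = A @ A.T / p + 0.5 * np.eye(p)
    L = np.linalg.cholesky(cov)
    Xn = mu + rng.normal(size=(n_per_class, p)) @ L.T
    Xc = mu + delta + rng.normal(size=(n_per_class, p)) @ L.T
    X = np.vstack([Xn, Xc])
    y = np.array(["normal"] * n_per_class + ["cancer"] * n_per_class, dtype=object)
    return X, y


def fisher_criterion(X, y, w):
    pos, neg = _masks(y)
    mu_p, mu_n = X[pos].mean(0), X[neg].mean(0)
    Dp, Dn = X[pos] - mu_p, X[neg] - mu_n
    Sw = Dp.T @ Dp + Dn.T @ Dn
    between = float(w @ (mu_p - mu_n)) ** 2
    within = float(w @ Sw @ w)
    return between / within


def naive_loocv(X, y, ridge=0.0):
    """Independent fold-by-fold reimplementation (oracle)."""
    preds, scores = [], []
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        model = sb.fit_lda(X[mask], y[mask], ridge=ridge)
        s, lab = sb.predict(model, X[i][None, :])
        preds.append(lab[0])
        scores.append(float(s[0]) - model.threshold)
    return np.array(preds, dtype=object), np.array(scores)


class TestFitLDA:
    def test_identity_scatter_closed_form(self):
        # class means (0,0) and (2,0), pooled within-class scatter = c*I
        Xn = np.array([[1.0, 0], [-1, 0], [0, 1], [0, -1]])
        Xc = Xn + np.array([2.0, 0])
        X = np.vstack([Xn, Xc])
        y = np.array(["normal"] * 4 + ["cancer"] * 4, dtype=object)
        model = sb.fit_lda(X, y, ridge=0.0)
        w = model.weights / np.linalg.norm(model.weights)
        assert np.allclose(np.abs(w), [1.0, 0.0], atol=1e-12)
        # threshold sits at the projection of the midpoint (1, 0)
        assert model.threshold == pytest.approx(float(model.weights @ [1.0, 0.0]))

    def test_direction_matches_brute_force_fisher_maximizer(self):
        rng = np.random.default_rng(0)
        angles = np.radians(np.arange(0.0, 180.0, 0.05))
        directions = np.stack([np.cos(angles), np.sin(angles)], axis=1)
        for _ in range(100):
            X, y = random_two_class(rng, n_per_class=8, p=2)
            model = sb.fit_lda(X, y, ridge=0.0)
            crits = [fisher_criterion(X, y, d) for d in directions]
            best = directions[int(np.argmax(crits))]
            w = model.weights / np.linalg.norm(model.weights)
            angle = np.degrees(np.arccos(np.clip(abs(w @ best), -1, 1)))
            assert angle < 1.0

    def test_duplicate_feature_column_with_ridge_matches_single_copy(self):
        rng = np.random.default_rng(1)
        X, y = random_two_class(rng, n_per_class=10, p=3)
        Xdup = np.hstack([X, X[:, [0]]])
        cv_one = sb.loocv(X, y, ridge="auto")
        cv_dup = sb.loocv(Xdup, y, ridge="auto")
        assert np.all(np.isfinite(sb.fit_lda(Xdup, y, ridge="auto").weights))
        assert list(cv_one.y_pred) == list(cv_dup.y_pred)

    def test_one_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        with pytest.raises(ValueError, match="normal"):
            sb.fit_lda(X, np.array(["cancer"] * 6, dtype=object))


class TestPredict:
    @pytest.fixture()
    def model(self):
        rng = np.random.default_rng(2)
        X, y = random_two_class(rng, n_per_class=10, p=3)
        return sb.fit_lda(X, y)

    def test_cancer_mean_is_called_cancer(self, model):
        _, lab = sb.predict(model, model.mean_cancer[None, :])
        assert lab[0] == "cancer"

    def test_exact_threshold_ties_to_normal(self, model):
        w = model.weights
        x = model.threshold * w / float(w @ w)  # w @ x == threshold exactly?
        score, lab = sb.predict(model, x[None, :])
        if score[0] == model.threshold:  # exact-tie construction succeeded
            assert lab[0] == "normal"
        else:  # float round-off: nudge strictly below
            eps = np.spacing(model.threshold)
            score2, lab2 = sb.predict(model, (x * (1 - 1e-12))[None, :])
            assert lab2[0] == "normal" or score2[0] > model.threshold

    def test_score_monotone_along_weight_direction(self, model):
        base = model.mean_normal
        steps = np.linspace(0, 3, 7)
        scores = [sb.predict(model, (base + t * model.weights)[None, :])[0][0]
                  for t in steps]
        assert np.all(np.diff(scores) > 0)

    def test_dimension_mismatch_rejected(self, model):
        with pytest.raises(ValueError, match="dimension"):
            sb.predict(model, np.ones((1, model.weights.size + 1)))


class TestLOOCV:
    def test_separated_data_classifies_perfectly(self):
        X = np.concatenate([np.linspace(0, 1, 8), np.linspace(10, 11, 8)])[:, None]
        y = np.array(["normal"] * 8 + ["cancer"] * 8, dtype=object)
        cv = sb.loocv(X, y)
        assert cv.accuracy == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_naive_fold_by_fold_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X, y = random_two_class(rng, n_per_class=6, p=3, sep=1.5)
        cv = sb.loocv(X, y, ridge=1e-10)
        preds, scores = naive_loocv(X, y, ridge=1e-10)
        assert list(cv.y_pred) == list(preds)
        assert np.allclose(cv.scores, scores, rtol=1e-6, atol=1e-9)

    def test_duplicated_samples_predict_like_their_twins(self):
        rng = np.random.default_rng(3)
        X, y = random_two_class(rng, n_per_class=6, p=2, sep=2.5)
        Xd = np.vstack([X, X])
        yd = np.concatenate([y, y])
        cv = sb.loocv(Xd, yd)
        n = len(y)
        assert list(cv.y_pred[:n]) == list(cv.y_pred[n:])

    def test_variable_reordering_is_irrelevant(self):
        rng = np.random.default_rng(4)
        X, y = random_two_class(rng, n_per_class=7, p=4)
        perm = np.array([2, 0, 3, 1])
        cv_a = sb.loocv(X, y, ridge=0.0)
        cv_b = sb.loocv(X[:, perm], y, ridge=0.0)
        assert list(cv_a.y_pred) == list(cv_b.y_pred)
        assert np.allclose(cv_a.scores, cv_b.scores, rtol=1e-8)

    def test_rescaling_one_variable_is_irrelevant_without_ridge(self):
        rng = np.random.default_rng(5)
        X, y = random_two_class(rng, n_per_class=7, p=3)
        X2 = X.copy()
        X2[:, 1] *= 250.0
        cv_a = sb.loocv(X, y, ridge=0.0)
        cv_b = sb.loocv(X2, y, ridge=0.0)
        assert list(cv_a.y_pred) == list(cv_b.y_pred)
        assert np.allclose(cv_a.scores, cv_b.scores, rtol=1e-6)

    def test_too_small_class_names_the_limit(self):
        X = np.random.default_rng(0).normal(size=(5, 2))
        y = np.array(["cancer", "cancer", "normal", "normal", "cancer"], dtype=object)
        with pytest.raises(ValueError, match="normal"):
            sb.loocv(X, y)


class TestMetrics:
    def test_headline_confusion_arithmetic(self):
        # 55 cancer / 36 normal cohort: 50 TP, 5 FN, 36 TN, 0 FP
        m = sb.Metrics(tp=50, fn=5, tn=36, fp=0)
        assert round(100 * m.sensitivity, 1) == 90.9
        assert round(100 * m.specificity, 1) == 100.0
        assert round(100 * m.accuracy, 1) == 94.5

    def test_comparator_confusion_arithmetic(self):
        m = sb.Metrics(tp=41, fn=14, tn=35, fp=1)
        assert round(100 * m.accuracy, 1) == 83.5
        assert round(100 * m.specificity, 1) == 97.2

    def test_all_correct_is_all_hundreds(self):
        y = np.array(["cancer"] * 3 + ["normal"] * 3, dtype=object)
        cv = sb.CVResult(ids=np.arange(6).astype(object), y_true=y,
                         scores=np.where(y == "cancer", 1.0, -1.0), y_pred=y.copy())
        m = sb.compute_metrics(cv)
        assert (m.sensitivity, m.specificity, m.accuracy) == (1.0, 1.0, 1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_identities_on_random_confusion_tables(self, seed):
        rng = np.random.default_rng(seed)
        y_true = np.array(rng.choice(["cancer", "normal"], size=30), dtype=object)
        while len(set(y_true)) < 2:
            y_true = np.array(rng.choice(["cancer", "normal"], size=30), dtype=object)
        y_pred = np.array(rng.choice(["cancer", "normal"], size=30), dtype=object)
        cv = sb.CVResult(ids=np.arange(30).astype(object), y_true=y_true,
                         scores=np.zeros(30), y_pred=y_pred)
        m = sb.compute_metrics(cv)
        assert m.tp + m.fn == int(np.sum(y_true == "cancer"))
        assert m.tn + m.fp == int(np.sum(y_true == "normal"))
        assert m.accuracy == pytest.approx(np.mean(y_true == y_pred))
        assert m.sensitivity == pytest.approx(m.tp / (m.tp + m.fn))
        assert m.specificity == pytest.approx(m.tn / (m.tn + m.fp))


class TestPCA:
    def test_collinear_points_have_one_component(self):
        t = np.linspace(0, 1, 10)[:, None]
        X = t @ np.array([[1.0, 2.0, -1.0]])
        scores, evr = sb.pca_scores(X, 2)
        assert evr[0] == pytest.approx(1.0, abs=1e-12)

    def test_full_rank_explains_everything(self):
        X = np.random.default_rng(6).normal(size=(12, 5))
        _, evr = sb.pca_scores(X, 5)
        assert np.sum(evr) == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(evr) <= 1e-12)

    def test_reconstruction_error_decreases_with_components(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(15, 6))
        Xc = X - X.mean(0)
        # eigen-decomposition oracle for the residual energy
        errs = []
        for k in range(1, 7):
            scores, evr = sb.pca_scores(X, k)
            errs.append(np.sum(Xc**2) * (1 - np.sum(evr)))
        assert np.all(np.diff(errs) < 1e-9)

    def test_component_count_bounds(self):
        X = np.random.default_rng(8).normal(size=(6, 4))
        with pytest.raises(ValueError, match="n_components"):
            sb.pca_scores(X, 6)


class TestPCALDA:
    def test_full_component_space_equals_plain_loocv(self):
        rng = np.random.default_rng(9)
        X, y = random_two_class(rng, n_per_class=8, p=4)
        cv_plain = sb.loocv(X, y, ridge=0.0)
        cv_pca = sb.pca_lda_loocv(X, y, n_components=4, ridge=0.0)
        assert list(cv_plain.y_pred) == list(cv_pca.y_pred)

    def test_single_component_misses_orthogonal_class_signal(self):
        rng = np.random.default_rng(10)
        n = 20
        loud = rng.normal(0, 10, size=2 * n)  # dominant variance, no signal
        quiet = np.concatenate([rng.normal(0, 0.3, n), rng.normal(2.5, 0.3, n)])
        X = np.stack([loud, quiet], axis=1)
        y = np.array(["normal"] * n + ["cancer"] * n, dtype=object)
        acc1 = sb.pca_lda_loocv(X, y, n_components=1).accuracy
        acc2 = sb.pca_lda_loocv(X, y, n_components=2).accuracy
        assert acc1 < 0.7 < acc2

    def test_deterministic_across_calls(self):
        rng = np.random.default_rng(11)
        X, y = random_two_class(rng, n_per_class=9, p=5)
        a = sb.pca_lda_loocv(X, y, n_components=3)
        b = sb.pca_lda_loocv(X, y, n_components=3)
        assert np.array_equal(a.scores, b.scores)
        assert list(a.y_pred) == list(b.y_pred)

    def test_per_fold_refit_runs_and_agrees_on_easy_data(self):
        X = np.concatenate([np.linspace(0, 1, 6), np.linspace(8, 9, 6)])[:, None]
        X = np.hstack([X, np.random.default_rng(12).normal(size=(12, 2))])
        y = np.array(["normal"] * 6 + ["cancer"] * 6, dtype=object)
        cv = sb.pca_lda_loocv(X, y, n_components=2, refit_per_fold=True)
        assert cv.accuracy == 1.0
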