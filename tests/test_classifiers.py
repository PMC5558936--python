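"""Classifier contracts: NB oracle equivalence, SVM behaviour, metrics."""

import itertools

import numpy as np
import pytest
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB as SklearnNB

import imitkin as ik
from imitkin.classifiers import (
    DEFAULT_C_GRID,
    GaussianNB,
    SVMSpec,
    compute_metrics,
    grid_search_svm,
    nb_loocv,
    round_half_up,
    svm_train,
    tree_fit,
    forest_fit,
)


def brute_force_log_joint(Xtr, ytr, Xte):
    """Posterior evidence by direct per-feature Gaussian density products."""
    eps = max(1e-9 * Xtr.var(axis=0).max(), 1e-12)
    out = np.zeros((len(Xte), 2))
    for c in (0, 1):
        members = Xtr[ytr == c]
        prior = len(members) / len(ytr)
        for i, x in enumerate(Xte):
            ll = np.log(prior)
            for j in range(Xtr.shape[1]):
                ll += stats.norm.logpdf(
                    x[j], members[:, j].mean(), np.sqrt(members[:, j].var() + eps)
                )
            out[i, c] = ll
    return out


class TestGaussianNB:
    def test_symmetric_1d_boundary(self):
        X = np.array([[-1.5], [-0.5], [0.5], [1.5]])
        y = np.array([0, 0, 1, 1])  # class means -1 and +1, equal variance
        model = GaussianNB().fit(X, y)
        assert model.predict(np.array([[0.2]]))[0] == 1
        assert model.predict(np.array([[-0.2]]))[0] == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_posterior_equals_brute_force_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        d = int(rng.integers(1, 4))
        X = rng.normal(size=(n, d))
        y = np.array([0, 1] * (n // 2) + [0] * (n % 2))
        model = GaussianNB().fit(X, y)
        Xte = rng.normal(size=(4, d))
        assert np.allclose(model.log_joint(Xte), brute_force_log_joint(X, y, Xte), atol=1e-10)

    def test_matches_sklearn_predictions(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 6))
        y = (rng.random(30) < 0.5).astype(int)
        y[:2], y[-2:] = 0, 1  # both classes guaranteed
        X[y == 1] += 0.7
        ours = GaussianNB().fit(X, y).predict(X)
        theirs = SklearnNB().fit(X, y).predict(X)
        assert np.array_equal(ours, theirs)

    def test_duplicated_feature_preserves_sample_ranking(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 1))
        y = np.array([0] * 6 + [1] * 6)
        X[y == 1] += 1.0
        base = GaussianNB().fit(X, y)
        dup = GaussianNB().fit(np.hstack([X, X]), y)
        lo_base = base.log_joint(X)[:, 1] - base.log_joint(X)[:, 0]
        Xd = np.hstack([X, X])
        lo_dup = dup.log_joint(Xd)[:, 1] - dup.log_joint(Xd)[:, 0]
        assert np.array_equal(np.argsort(lo_base), np.argsort(lo_dup))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            GaussianNB().fit(np.zeros((4, 2)), np.zeros(4, dtype=int))

    def test_loocv_fast_path_equals_per_fold_refits(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(16, 4))
        y = np.array([0, 1] * 8)
        preds_fast, _ = nb_loocv(X, y)
        for i in range(16):
            mask = np.ones(16, bool)
            mask[i] = False
            model = GaussianNB().fit(X[mask], y[mask])
            assert model.predict(X[i : i + 1])[0] == preds_fast[i]


class TestSVM:
    def _clusters(self, seed=0, sep=5.0, n=20, d=3):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, d))
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        X[y == 1, 0] += sep
        X[y == 0, 0] -= sep
        return X, y

    def test_separable_clusters_fit_perfectly(self):
        X, y = self._clusters()
        model = svm_train(X, y, SVMSpec("linear", C=100.0))
        assert (model.predict(X) == y).all()

    def test_label_flip_negates_decision_function(self):
        X, y = self._clusters(seed=4, sep=2.0)
        a = svm_train(X, y, SVMSpec("linear", C=1.0))
        b = svm_train(X, 1 - y, SVMSpec("linear", C=1.0))
        # agreement limited by the solver's convergence tolerance (1e-3)
        assert np.allclose(a.decision_function(X), -b.decision_function(X), atol=5e-3)

    def test_informative_feature_outweighs_noise(self):
        wins = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 2))
            y = np.array([0] * 15 + [1] * 15)
            X[y == 1, 0] += 3.0  # feature 0 separates, feature 1 is noise
            model = svm_train(X, y, SVMSpec("linear", C=1.0))
            w = np.abs(model.coef_[0])
            wins += w[0] > w[1]
        assert wins >= 48

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SVMSpec("linear", C=-1.0)
        with pytest.raises(ValueError):
            SVMSpec("rbf", C=1.0, gamma=None)
        with pytest.raises(ValueError):
            SVMSpec("poly", C=1.0)


class TestGridSearch:
    def test_single_point_grid_returned(self):
        X, y = np.random.default_rng(0).normal(size=(12, 2)), np.array([0, 1] * 6)
        spec, _ = grid_search_svm(X, y, C_grid=np.array([4.0]))
        assert spec.C == 4.0 and spec.kernel == "linear"

    def test_separable_data_reaches_perfect_inner_accuracy(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 2))
        y = np.array([0] * 10 + [1] * 10)
        X[y == 1, 0] += 8.0
        _, acc = grid_search_svm(X, y, seed=0)
        assert acc == 1.0

    def test_exhaustive_against_manual_sweep(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        y = np.array([0] * 10 + [1] * 10)
        X[y == 1] += 0.8
        grid = np.array([0.1, 1.0, 10.0])
        spec, acc = grid_search_svm(X, y, C_grid=grid, inner_folds=3, seed=9)
        # independent sweep with the identical fold plan
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=9)
        folds = list(skf.split(X, y))
        sweep = {}
        for C in grid:
            correct = 0
            for tr, te in folds:
                m = svm_train(X[tr], y[tr], SVMSpec("linear", C=float(C)))
                correct += int((m.predict(X[te]) == y[te]).sum())
            sweep[float(C)] = correct / len(y)
        assert acc == max(sweep.values())
        assert spec.C == min(C for C, a in sweep.items() if a == acc)  # tie to smaller C


class TestTreesAndForest:
    def test_single_separating_feature_depth_one(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array([0, 0, 1, 1])
        model = tree_fit(X, y)
        assert model.get_depth() == 1
        assert (model.predict(X) == y).all()

    def test_forest_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 5))
        y = np.array([0, 1] * 10)
        a = forest_fit(X, y, seed=3, n_trees=50).predict(X)
        b = forest_fit(X, y, seed=3, n_trees=50).predict(X)
        assert np.array_equal(a, b)


class TestMetrics:
    @pytest.mark.parametrize(
        "tp,tn,expected",
        [
            (11, 13, (78.6, 81.3, 80.0)),  # Naive Bayes row
            (11, 14, (78.6, 87.5, 83.3)),  # RBF SVM row
            (12, 14, (85.7, 87.5, 86.7)),  # linear SVM row
            (8, 12, (57.1, 75.0, 66.7)),  # decision tree row
            (10, 11, (71.4, 68.8, 70.0)),  # random forest row
        ],
    )
    def test_diagnostic_triples_from_counts(self, tp, tn, expected):
        res = ik.EvalResult(tp=tp, fp=16 - tn, tn=tn, fn=14 - tp)
        assert res.rounded() == expected

    def test_full_enumeration_against_direct_formula(self):
        for tp, tn in itertools.product(range(15), range(17)):
            res = ik.EvalResult(tp=tp, fp=16 - tn, tn=tn, fn=14 - tp)
            assert res.sensitivity == pytest.approx(100 * tp / 14)
            assert res.specificity == pytest.approx(100 * tn / 16)
            assert res.accuracy == pytest.approx(100 * (tp + tn) / 30)
            # accuracy is the positives/negatives-weighted mean of sens/spec
            assert res.accuracy == pytest.approx(
                (14 * res.sensitivity + 16 * res.specificity) / 30
            )

    def test_counts_from_predictions(self):
        labels = np.array([1] * 14 + [0] * 16)
        preds = labels.copy()
        res = compute_metrics(preds, labels)
        assert (res.tp, res.tn, res.fp, res.fn) == (14, 16, 0, 0)
        assert res.rounded() == (100.0, 100.0, 100.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([1, 0]), np.array([1, 0, 1]))

    def test_half_up_rounding_convention(self):
        assert round_half_up(81.25) == 81.3
        assert round_half_up(68.75) == 68.8
        assert round_half_up(-81.25) == -81.3
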