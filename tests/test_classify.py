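import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

from ehgkit import classify as clf
from ehgkit._qda import FastQDA
from ehgkit.classify import ConfusionCounts
from ehgkit.features import FeatureMatrix

from conftest import make_toy_matrix


def _gaussian_matrix(n_a, n_b, d=4, shift=0.0, seed=0, positive="a"):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n_a, d)),
                   rng.normal(shift, 1, (n_b, d))])
    y = pd.Series(["a"] * n_a + ["b"] * n_b, dtype=object)
    meta = pd.DataFrame({"record_id": ["r"] * (n_a + n_b),
                         "interval_label": ["d"] * (n_a + n_b),
                         "synthetic": [False] * (n_a + n_b)})
    return FeatureMatrix(pd.DataFrame(X, columns=[f"f{i}" for i in range(d)]),
                         y, meta, positive_label=positive)


class TestSmote:
    def test_47_vs_53_becomes_53_53(self):
        fm = _gaussian_matrix(47, 53, shift=1.0, seed=1)
        out = clf.balance_smote(fm, seed=2)
        assert out.class_counts() == {"a": 53, "b": 53}

    def test_balanced_input_unchanged(self):
        fm = _gaussian_matrix(30, 30, seed=3)
        assert clf.balance_smote(fm, seed=0) is fm

    def test_synthetic_rows_are_convex_combinations(self):
        fm = _gaussian_matrix(20, 40, shift=2.0, seed=4)
        out = clf.balance_smote(fm, seed=5)
        Xmin = fm.X.values[fm.y.values == "a"]
        synth = out.X.values[out.meta["synthetic"].values]
        assert len(synth) == 20
        for s in synth:
            on_segment = False
            for i, j in itertools.combinations(range(len(Xmin)), 2):
                a, b = Xmin[i], Xmin[j]
                denom = b - a
                with np.errstate(divide="ignore", invalid="ignore"):
                    u = (s - a) / denom
                u = u[np.isfinite(u)]
                if u.size and np.allclose(u, u[0], atol=1e-8) \
                        and -1e-9 <= u[0] <= 1 + 1e-9:
                    on_segment = True
                    break
            assert on_segment

    def test_majority_rows_untouched(self):
        fm = _gaussian_matrix(10, 25, seed=6)
        out = clf.balance_smote(fm, k_neighbors=3, seed=7)
        maj_before = fm.X.values[fm.y.values == "b"]
        maj_after = out.X.values[out.y.values == "b"]
        np.testing.assert_array_equal(np.sort(maj_before, axis=0),
                                      np.sort(maj_after, axis=0))

    def test_minority_too_small_for_k(self):
        fm = _gaussian_matrix(3, 20, seed=8)
        with pytest.raises(ValueError, match="smaller k"):
            clf.balance_smote(fm, k_neighbors=5)


class TestAdasyn:
    def test_19_vs_143_lands_near_parity(self):
        fm = _gaussian_matrix(19, 143, shift=1.5, seed=9)
        out = clf.balance_adasyn(fm, seed=10)
        n_min = out.class_counts()["a"]
        assert 129 <= n_min <= 143

    def test_balanced_input_unchanged(self):
        fm = _gaussian_matrix(25, 25, seed=11)
        assert clf.balance_adasyn(fm, seed=0) is fm

    def test_isolated_minority_degenerates_to_uniform(self):
        # minority cluster far from majority: every minority neighborhood is
        # pure minority, so the density rule falls back to uniform weights
        rng = np.random.default_rng(12)
        Xa = rng.normal(0, 0.1, (10, 3)) + 100.0
        Xb = rng.normal(0, 1, (40, 3))
        fm = FeatureMatrix(
            pd.DataFrame(np.vstack([Xa, Xb]), columns=list("xyz")),
            pd.Series(["a"] * 10 + ["b"] * 40, dtype=object),
            pd.DataFrame({"record_id": ["r"] * 50,
                          "interval_label": ["d"] * 50,
                          "synthetic": [False] * 50}))
        out = clf.balance_adasyn(fm, seed=13)
        assert 36 <= out.class_counts()["a"] <= 44


class TestQda:
    def test_separated_clouds_perfect_training_accuracy(self):
        rng = np.random.default_rng(14)
        X = np.vstack([rng.normal(0, 1, (100, 2)),
                       rng.normal(6, 1, (100, 2))])
        y = np.array(["n"] * 100 + ["p"] * 100)
        model = clf.qda_fit(X, y)
        labels, scores = clf.qda_predict(model, X, positive="p")
        assert (labels == y).mean() == 1.0
        assert scores[y == "p"].min() > scores[y == "n"].max()

    def test_identical_distributions_score_at_chance(self):
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(0, 1, (200, 3))
            y = np.array(["n", "p"] * 100)
            model = clf.qda_fit(X[:150], y[:150])
            labels, _ = clf.qda_predict(model, X[150:])
            accs.append((labels == y[150:]).mean())
        assert 0.40 <= np.mean(accs) <= 0.60

    def test_constant_feature_column_survives(self):
        rng = np.random.default_rng(15)
        X = np.c_[rng.normal(0, 1, 40), np.ones(40)]
        y = np.array(["n"] * 20 + ["p"] * 20)
        model = clf.qda_fit(X, y)
        labels, scores = clf.qda_predict(model, X)
        assert np.all(np.isfinite(scores))

    def test_fast_qda_agrees_with_sklearn(self):
        rng = np.random.default_rng(16)
        X = np.vstack([rng.normal(0, 1, (150, 3)),
                       rng.normal(1.2, 1.8, (150, 3))])
        y = np.array([0] * 150 + [1] * 150)
        ours = FastQDA().fit(X, y)
        ref = QuadraticDiscriminantAnalysis().fit(X, y)
        Xt = rng.normal(0.5, 1.5, (500, 3))
        agree = (ours.predict(Xt) == ref.predict(Xt)).mean()
        assert agree > 0.995
        np.testing.assert_allclose(ours.predict_proba_of(Xt, 1),
                                   ref.predict_proba(Xt)[:, 1], atol=1e-6)


class TestConfusion:
    def test_printed_formulas(self):
        c = ConfusionCounts(TP=9, FN=1, TN=8, FP=2)
        assert c.se == pytest.approx(90.0)
        assert c.sp == pytest.approx(80.0)
        assert c.ca == pytest.approx(85.0)


class TestCrossValidation:
    def test_oracle_labels_give_perfect_metrics(self):
        rng = np.random.default_rng(17)
        y = np.array(["n", "p"] * 40)
        X = (y == "p").astype(float)[:, None] + rng.normal(0, 0.01, (80, 1))
        fm = FeatureMatrix(pd.DataFrame(X, columns=["f"]),
                           pd.Series(y, dtype=object),
                           pd.DataFrame({"record_id": ["r"] * 80,
                                         "interval_label": ["d"] * 80,
                                         "synthetic": [False] * 80}),
                           positive_label="p")
        rep = clf.cross_validated_metrics(fm, folds=10, repetitions=3, seed=1)
        assert rep.se == rep.sp == rep.ca == rep.auc == 100.0

    def test_test_rows_never_synthetic_and_fully_covered(self):
        fm = _gaussian_matrix(23, 37, shift=2.0, seed=18)
        rep = clf.cross_validated_metrics(fm, folds=5, repetitions=2,
                                          balance="smote", seed=3)
        for fold_counts in rep.fold_counts:
            assert sum(c.total for c in fold_counts) == fm.n_rows

    def test_bit_reproducible(self):
        fm = _gaussian_matrix(20, 30, shift=1.0, seed=19)
        a = clf.cross_validated_metrics(fm, folds=5, repetitions=3,
                                        balance="smote", seed=5)
        b = clf.cross_validated_metrics(fm, folds=5, repetitions=3,
                                        balance="smote", seed=5)
        pd.testing.assert_frame_equal(a.per_repetition, b.per_repetition)

    def test_balance_upfront_mode(self):
        fm = _gaussian_matrix(15, 45, shift=2.0, seed=20)
        rep = clf.cross_validated_metrics(fm, folds=5, repetitions=2,
                                          balance="smote", seed=4,
                                          balance_upfront=True)
        assert 0 <= rep.ca <= 100

    def test_auc_invariant_to_monotone_score_transform(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(21)
        truth = rng.integers(0, 2, 200).astype(bool)
        scores = rng.uniform(0, 1, 200) + truth * 0.3
        a = roc_auc_score(truth, scores)
        b = roc_auc_score(truth, np.exp(3 * scores))
        assert a == pytest.approx(b)

    def test_fold_count_exceeding_class_size_rejected(self):
        fm = _gaussian_matrix(4, 40, seed=22)
        with pytest.raises(ValueError, match="folds"):
            clf.cross_validated_metrics(fm, folds=5, repetitions=1, seed=0)

    def test_sklearn_and_fast_paths_agree_on_metrics(self):
        fm = _gaussian_matrix(30, 30, shift=1.5, seed=23)
        a = clf.cross_validated_metrics(fm, folds=5, repetitions=2, seed=6,
                                        use_fast_qda=True)
        b = clf.cross_validated_metrics(fm, folds=5, repetitions=2, seed=6,
                                        use_fast_qda=False)
        assert a.ca == pytest.approx(b.ca, abs=1.0)
        assert a.auc == pytest.approx(b.auc, abs=1.0)
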