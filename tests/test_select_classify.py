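import numpy as np
import pytest

from cardiocouple.select_classify import (
    ConfusionCounts,
    GridSpec,
    compute_metrics,
    make_folds,
    rfe_rank,
    run_cv,
    select_k,
    svm_grid_fit,
)


class TestMakeFolds:
    def test_balanced_20_subjects(self):
        subjects = [(f"s{i}", i % 2) for i in range(20)]
        assignment = make_folds(subjects, k=5, seed=0)
        for fold in range(5):
            members = [s for s, f in assignment.items() if f == fold]
            labels = [int(s[1:]) % 2 for s in members]
            assert sorted(labels) == [0, 0, 1, 1]

    def test_same_seed_identical(self):
        subjects = [(f"s{i}", i % 2) for i in range(14)]
        assert make_folds(subjects, 5, 3) == make_folds(subjects, 5, 3)

    def test_small_class_rejected(self):
        subjects = [("a", 0), ("b", 0), ("c", 0), ("d", 0), ("e", 0), ("f", 1)]
        with pytest.raises(ValueError, match="fewer than"):
            make_folds(subjects, k=5, seed=0)


def _informative_features(n=200, d=10, n_signal=1, seed=0, sep=3.0):
    r = np.random.default_rng(seed)
    y = np.tile([0, 1], n // 2)
    X = r.standard_normal((n, d))
    for j in range(n_signal):
        X[:, j] += sep * y
    return X, y


class TestRFE:
    def test_single_informative_feature_ranked_first(self):
        X, y = _informative_features()
        ranking = rfe_rank(X, y)
        assert ranking[0] == 1

    def test_duplicated_informative_feature_tops_ranking(self):
        X, y = _informative_features(d=8)
        X = np.column_stack([X, X[:, 0]])  # exact duplicate of the signal column
        ranking = rfe_rank(X, y)
        assert {ranking[0], ranking[-1]} == {1, 2}

    def test_two_features_full_ranking(self):
        X, y = _informative_features(d=2)
        assert sorted(rfe_rank(X, y, step=1)) == [1, 2]

    def test_single_class_rejected(self):
        X, _ = _informative_features()
        with pytest.raises(ValueError, match="single-class"):
            rfe_rank(X, np.zeros(len(X), dtype=int))


class TestSelectK:
    def test_three_signal_features_selected_early(self):
        X, y = _informative_features(n=200, d=20, n_signal=3, sep=3.0)
        ranking = rfe_rank(X, y)
        best_k, curve = select_k(X, y, ranking, seed=0)
        assert best_k <= 5
        assert curve[best_k] >= curve[20] - 1e-9

    def test_single_feature_trivial(self):
        X, y = _informative_features(d=3)
        best_k, curve = select_k(X[:, :1], y, np.array([1]), k_schedule=[1], seed=0)
        assert best_k == 1

    def test_all_noise_near_chance(self):
        r = np.random.default_rng(4)
        X = r.standard_normal((120, 10))
        y = np.tile([0, 1], 60)
        best_k, curve = select_k(X, y, np.arange(1, 11), seed=0)
        assert curve[best_k] <= 0.68  # no feature count rescues pure noise


class TestGridSVM:
    def test_grid_enumerates_270_configurations(self):
        assert len(GridSpec().configurations()) == 270  # 18 linear + 18*14 rbf

    def test_separable_blobs_fit_perfectly(self):
        r = np.random.default_rng(0)
        X = np.vstack([r.normal(-3, 0.3, (40, 2)), r.normal(3, 0.3, (40, 2))])
        y = np.repeat([0, 1], 40)
        clf, cfg = svm_grid_fit(X, y, seed=0)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_choice_deterministic(self):
        X, y = _informative_features(n=80, d=4)
        _, cfg1 = svm_grid_fit(X, y, seed=2)
        _, cfg2 = svm_grid_fit(X, y, seed=2)
        assert cfg1 == cfg2

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            svm_grid_fit(np.zeros((10, 2)), np.zeros(10, dtype=int))

    def test_column_order_does_not_change_predictions(self):
        # selecting "all features" must reproduce the no-selection classifier
        X, y = _informative_features(n=80, d=6)
        perm = np.random.default_rng(0).permutation(6)
        clf_a, _ = svm_grid_fit(X, y, seed=1)
        clf_b, _ = svm_grid_fit(X[:, perm], y, seed=1)
        Xt, _ = _informative_features(n=40, d=6, seed=9)
        np.testing.assert_array_equal(clf_a.predict(Xt), clf_b.predict(Xt[:, perm]))


class TestMetrics:
    def test_worked_example(self):
        m = compute_metrics(ConfusionCounts(tp=50, tn=30, fp=10, fn=10))
        assert round(m["ACC"], 2) == 80.00
        assert round(m["SEN"], 2) == 83.33
        assert round(m["SPE"], 2) == 75.00
        assert round(m["F1"], 2) == 83.33

    def test_degenerate_all_true_positive(self):
        m = compute_metrics(ConfusionCounts(tp=7))
        assert m["ACC"] == 100.0 and m["SEN"] == 100.0 and m["F1"] == 100.0
        assert m["SPE"] is None  # undefined, not zero

    def test_matches_bruteforce_counting(self, rng):
        for _ in range(100):
            y = rng.integers(0, 2, 30)
            p = rng.integers(0, 2, 30)
            c = ConfusionCounts.from_predictions(y, p)
            tp = sum(1 for a, b in zip(y, p) if a == 1 and b == 1)
            tn = sum(1 for a, b in zip(y, p) if a == 0 and b == 0)
            fp = sum(1 for a, b in zip(y, p) if a == 0 and b == 1)
            fn = sum(1 for a, b in zip(y, p) if a == 1 and b == 0)
            assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)
            m = compute_metrics(c)
            if m["ACC"] is not None:
                assert m["ACC"] == 100.0 * (tp + tn) / 30


def _subject_features(n_subjects=20, segs=6, d=30, n_signal=4, sep=2.0, seed=0):
    r = np.random.default_rng(seed)
    sids, labels, rows = [], [], []
    for i in range(n_subjects):
        lab = i % 2
        for _ in range(segs):
            x = r.standard_normal(d)
            x[:n_signal] += sep * lab
            rows.append(x)
            sids.append(f"s{i}")
            labels.append(lab)
    return np.array(rows), np.array(labels), sids


class TestRunCV:
    def test_separable_dataset_high_accuracy(self):
        X, y, sids = _subject_features()
        report = run_cv(X, y, sids, k=5, seed=0, rfe_step=2)
        assert report.mean["ACC"] >= 85.0

    def test_fold_subjects_disjoint_and_covering(self):
        X, y, sids = _subject_features()
        report = run_cv(X, y, sids, k=5, seed=0, rfe_step=5)
        all_subjects = set()
        for fs in report.fold_subjects:
            assert not (set(fs) & all_subjects)
            all_subjects |= set(fs)
        assert all_subjects == set(sids)

    def test_permuted_labels_near_chance(self):
        X, y, sids = _subject_features(seed=1)
        r = np.random.default_rng(5)
        subj = sorted(set(sids))
        lab_of = {s: y[sids.index(s)] for s in subj}
        perm = dict(zip(subj, r.permutation([lab_of[s] for s in subj])))
        yp = np.array([perm[s] for s in sids])
        report = run_cv(X, yp, sids, k=5, seed=0, rfe_step=5)
        assert 35.0 <= report.mean["ACC"] <= 65.0

    def test_inconsistent_subject_labels_rejected(self):
        X, y, sids = _subject_features(n_subjects=10)
        y = y.copy()
        y[0] = 1 - y[0]
        with pytest.raises(ValueError, match="inconsistent"):
            run_cv(X, y, sids, k=5, seed=0)
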