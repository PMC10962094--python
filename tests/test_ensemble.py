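"""The balanced SVM ensemble: training protocol, prediction, CV, ranking."""

import numpy as np
import pandas as pd
import pytest

from m6aconserve.ensemble import (
    cross_validate,
    feature_selection_curve,
    fit_ensemble,
    fit_member,
    load_model,
    predict,
    rank_features,
    save_model,
)
from m6aconserve.features import genomic_feature_names


def blobs(n_pos=40, n_neg=40, n_feat=6, shift=3.0, seed=0, prefix=""):
    """Two Gaussian clouds, positives shifted by `shift` in every axis."""
    rng = np.random.default_rng(seed)
    pos = rng.normal(shift, 1.0, size=(n_pos, n_feat))
    neg = rng.normal(0.0, 1.0, size=(n_neg, n_feat))
    cols = [f"{prefix}f{i}" for i in range(n_feat)]
    pos_df = pd.DataFrame(pos, columns=cols,
                          index=[f"p{i}" for i in range(n_pos)])
    neg_df = pd.DataFrame(neg, columns=cols,
                          index=[f"n{i}" for i in range(n_neg)])
    return pos_df, neg_df


class TestFitMember:
    def test_separable_blobs_reach_perfect_training_accuracy(self):
        pos, neg = blobs(shift=6.0)
        X = pd.concat([pos, neg])
        y = np.r_[np.ones(len(pos), int), np.zeros(len(neg), int)]
        clf = fit_member(X, y, seed=0)
        assert (clf.predict(X.to_numpy()) == y).mean() == 1.0

    def test_single_class_rejected(self):
        pos, _ = blobs()
        with pytest.raises(ValueError, match="both classes"):
            fit_member(pos, np.ones(len(pos), int))

    def test_identical_features_random_labels_score_at_chance(self):
        """Constant feature rows carry no information: over 20 seeded
        label draws the CV AUROC is 0.5 by the tie convention."""
        row = np.ones((40, 4))
        X = pd.DataFrame(row, columns=list("abcd"),
                         index=[f"s{i}" for i in range(40)])
        aurocs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            labels = rng.permutation([1] * 20 + [0] * 20)
            pos, neg = X[labels == 1], X[labels == 0]
            _, mean = cross_validate(pos, neg, folds=5, k=2, seed=seed)
            aurocs.append(mean.auroc)
        assert np.mean(aurocs) == pytest.approx(0.5, abs=0.1)

    def test_deterministic_given_seed(self):
        pos, neg = blobs(shift=1.0)
        X = pd.concat([pos, neg])
        y = np.r_[np.ones(len(pos), int), np.zeros(len(neg), int)]
        a = fit_member(X, y, seed=3).decision_function(X.to_numpy())
        b = fit_member(X, y, seed=3).decision_function(X.to_numpy())
        assert np.array_equal(a, b)


class TestFitEnsemble:
    def test_ten_members(self):
        pos, neg = blobs(n_pos=20, n_neg=60)
        model = fit_ensemble(pos, neg, k=10, seed=0)
        assert model.k == 10

    def test_single_member_ensemble_equals_its_member(self):
        pos, neg = blobs(n_pos=25, n_neg=25, shift=2.0)
        model = fit_ensemble(pos, neg, k=1, seed=0)
        X = pd.concat([pos, neg])
        assert np.array_equal(predict(model, X),
                              model.members[0].predict_proba(X))

    def test_k_exceeding_negative_capacity_rejected(self):
        pos, neg = blobs(n_pos=5, n_neg=5)
        with pytest.raises(ValueError, match="non-empty"):
            fit_ensemble(pos, neg, k=7, seed=0)

    def test_schema_mismatch_between_classes_rejected(self):
        pos, _ = blobs()
        _, neg = blobs(prefix="x_")
        with pytest.raises(ValueError, match="schema"):
            fit_ensemble(pos, neg, k=2, seed=0)


class TestPredict:
    def test_mean_of_member_probabilities(self, rng):
        pos, neg = blobs(n_pos=30, n_neg=60, shift=1.5)
        model = fit_ensemble(pos, neg, k=3, seed=1)
        X = pd.DataFrame(rng.normal(size=(100, 6)), columns=pos.columns)
        expected = np.mean(
            [m.predict_proba(X) for m in model.members], axis=0
        )
        assert predict(model, X) == pytest.approx(expected)

    def test_probabilities_in_unit_interval(self):
        pos, neg = blobs(n_pos=30, n_neg=30)
        model = fit_ensemble(pos, neg, k=2, seed=1)
        scores = predict(model, pd.concat([pos, neg]))
        assert np.all((scores >= 0) & (scores <= 1))

    def test_member_permutation_invariance(self):
        pos, neg = blobs(n_pos=30, n_neg=30, shift=1.0)
        model = fit_ensemble(pos, neg, k=3, seed=1)
        X = pd.concat([pos, neg])
        before = predict(model, X)
        model.members = list(reversed(model.members))
        assert predict(model, X) == pytest.approx(before)

    def test_schema_mismatch_rejected(self):
        pos, neg = blobs()
        model = fit_ensemble(pos, neg, k=2, seed=0)
        bad = pos.rename(columns={"f0": "zzz"})
        with pytest.raises(ValueError, match="schema"):
            predict(model, bad)

    def test_constant_feature_changes_no_prediction_after_scaling(self):
        """A feature constant in training normalizes to 0 everywhere and
        cannot move predictions (linear backend keeps the kernel width
        out of the comparison)."""
        pos, neg = blobs(n_pos=30, n_neg=30, shift=1.5)
        X_eval = pd.concat([pos, neg])
        base = fit_ensemble(pos, neg, k=2, seed=0, backend="glm")
        pos2 = pos.assign(const=5.0)
        neg2 = neg.assign(const=5.0)
        aug = fit_ensemble(pos2, neg2, k=2, seed=0, backend="glm")
        assert predict(aug, X_eval.assign(const=99.0)) == pytest.approx(
            predict(base, X_eval), abs=1e-9
        )


class TestCrossValidate:
    def test_folds_partition_the_data(self):
        from sklearn.model_selection import StratifiedKFold

        pos, neg = blobs(n_pos=25, n_neg=50)
        X = pd.concat([pos, neg])
        y = np.r_[np.ones(25, int), np.zeros(50, int)]
        seen = []
        for _, test_idx in StratifiedKFold(5, shuffle=True,
                                           random_state=0).split(X, y):
            seen.extend(test_idx)
        assert sorted(seen) == list(range(len(X)))
        reports, mean = cross_validate(pos, neg, folds=5, k=2, seed=0)
        assert len(reports) == 5
        assert mean.auroc == pytest.approx(
            np.mean([r.auroc for r in reports])
        )

    def test_too_many_folds_rejected(self):
        pos, neg = blobs(n_pos=3, n_neg=30)
        with pytest.raises(ValueError, match="folds"):
            cross_validate(pos, neg, folds=5, k=2, seed=0)


class TestRankFeatures:
    @pytest.fixture()
    def labeled_data(self):
        rng = np.random.default_rng(7)
        n = 120
        labels = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        X = pd.DataFrame({
            "label_copy": labels.astype(float),
            "noise_a": rng.normal(size=n),
            "noise_b": rng.normal(size=n),
        }, index=[f"s{i}" for i in range(n)])
        return X, labels

    def test_label_copy_ranks_first_and_noise_is_null(self, labeled_data):
        X, y = labeled_data
        model = fit_ensemble(X[y == 1], X[y == 0], k=2, seed=0)
        report = rank_features(model, X, y, n_repeats=20, seed=1)
        assert report.iloc[0]["feature"] == "label_copy"
        noise = report.set_index("feature").loc[["noise_a", "noise_b"]]
        assert (noise["importance"].abs() < 0.02).all()
        assert sorted(report["rank"]) == [1, 2, 3]

    def test_deterministic_given_seed(self, labeled_data):
        X, y = labeled_data
        model = fit_ensemble(X[y == 1], X[y == 0], k=2, seed=0)
        a = rank_features(model, X, y, n_repeats=3, seed=9)
        b = rank_features(model, X, y, n_repeats=3, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestFeatureSelectionCurve:
    def test_full_slot_count_reproduces_full_model(self, small_dataset):
        pos = small_dataset.pos_train.iloc[:40]
        neg = small_dataset.neg_train.iloc[:60]
        ranked = genomic_feature_names()
        curve = feature_selection_curve(ranked, pos, neg, ks=[54], seed=0,
                                        k_members=2)
        again = feature_selection_curve(ranked, pos, neg, ks=[54], seed=0,
                                        k_members=2)
        assert curve == again
        assert len(curve) == 1 and curve[0][0] == 54

    def test_k_zero_keeps_sequence_block_only(self, small_dataset):
        pos = small_dataset.pos_train.iloc[:40]
        neg = small_dataset.neg_train.iloc[:60]
        curve = feature_selection_curve(genomic_feature_names(), pos, neg,
                                        ks=[0], seed=0, k_members=2)
        assert 0.0 <= curve[0][1] <= 1.0

    def test_k_above_54_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="54"):
            feature_selection_curve(
                genomic_feature_names(),
                small_dataset.pos_train, small_dataset.neg_train,
                ks=[55], seed=0,
            )


def test_model_archive_roundtrip(tmp_path):
    pos, neg = blobs(n_pos=20, n_neg=20, shift=2.0)
    model = fit_ensemble(pos, neg, k=2, seed=4)
    path = tmp_path / "model.joblib"
    save_model(model, path)
    loaded = load_model(path)
    X = pd.concat([pos, neg])
    assert predict(loaded, X) == pytest.approx(predict(model, X))
    assert loaded.feature_schema == model.feature_schema
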