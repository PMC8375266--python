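import numpy as np
import pytest
from scipy import stats

from smrwalk.classifier import (build_labeled_features, compare_baselines,
                                cross_validate, cross_validate_resampled,
                                fit_final_model, predict_novel, roc_metrics,
                                sample_negatives, train_svm,
                                zscore_fit_transform)
from smrwalk.rw_encoder import rwr_encode


def brute_force_auc(y, scores):
    """Pair-counting oracle: fraction of positive-negative pairs ranked
    correctly, ties worth 1/2 (the Mann-Whitney U / (n+ n-) statistic)."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestZscore:
    def test_hand_computed_column(self):
        X = np.array([[1.0], [2.0], [3.0]])
        Xn, _ = zscore_fit_transform(X, [0, 1, 2])
        # population sd = sqrt(2/3)
        assert Xn[:, 0] == pytest.approx([-1.22474487, 0.0, 1.22474487])

    def test_constant_column_guarded_to_zero(self):
        X = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        Xn, scaler = zscore_fit_transform(X, [0, 1, 2])
        assert np.all(Xn[:, 0] == 0.0) and scaler.scale_[0] == 1.0

    def test_fit_rows_have_zero_mean(self):
        rng = np.random.default_rng(0)
        X = rng.normal(2.0, 3.0, size=(20, 4))
        fit = np.arange(12)
        Xn, _ = zscore_fit_transform(X, fit)
        assert Xn[fit].mean(axis=0) == pytest.approx(np.zeros(4), abs=1e-8)
        assert Xn[fit].std(axis=0) == pytest.approx(np.ones(4), abs=1e-8)

    def test_all_nan_column_is_an_error(self):
        X = np.full((3, 1), np.nan)
        with pytest.raises(ValueError, match="NaN"):
            zscore_fit_transform(X, [0, 1, 2])


class TestSampleNegatives:
    def test_disjoint_from_seeds_and_reproducible(self, small_dataset):
        _, _, net, _ = small_dataset
        neg = sample_negatives(net, 8, seed=1)
        assert len(neg) == 8 and not (neg & net.seed_genes)
        assert neg == sample_negatives(net, 8, seed=1)
        assert neg != sample_negatives(net, 8, seed=2)

    def test_full_pool(self, small_dataset):
        _, _, net, _ = small_dataset
        pool = set(net.unlabeled())
        assert sample_negatives(net, len(pool), seed=0) == pool

    def test_oversampling_is_an_error(self, small_dataset):
        _, _, net, _ = small_dataset
        with pytest.raises(ValueError):
            sample_negatives(net, net.n_nodes + 1, seed=0)


class TestTrainSvm:
    def test_linearly_separable_toy(self):
        X = np.array([[0, 0], [0, 1], [3, 3], [3, 4.0]])
        y = np.array([0, 0, 1, 1])
        model = train_svm(X, y, kernel="linear")
        assert np.array_equal(model.predict(X), y)

    def test_xor_with_rbf_kernel(self):
        X = np.array([[0, 0], [1, 1], [0, 1], [1, 0.0]])
        y = np.array([0, 0, 1, 1])
        model = train_svm(X, y, kernel="rbf", C=100.0, gamma=1.0)
        assert np.array_equal(model.predict(X), y)

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError, match="classes"):
            train_svm(np.zeros((4, 2)), np.ones(4))


class TestRocMetrics:
    def test_perfect_and_reversed_scores(self):
        y = np.array([1, 1, 0, 0])
        assert roc_metrics(y, [0.9, 0.8, 0.2, 0.1]) == (1.0, 1.0)
        assert roc_metrics(y, [0.1, 0.2, 0.8, 0.9])[0] == 0.0

    def test_six_gene_worked_example(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        scores = np.array([0.9, 0.8, 0.4, 0.7, 0.3, 0.2])
        a, _ = roc_metrics(y, scores)
        assert a == pytest.approx(8 / 9)
        assert a == pytest.approx(brute_force_auc(y, scores))

    def test_equals_mann_whitney_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n_pos, n_neg = rng.integers(2, 15, size=2)
            y = np.concatenate([np.ones(n_pos), np.zeros(n_neg)]).astype(int)
            # discrete scores force ties so tie handling is exercised too
            scores = rng.integers(0, 6, size=n_pos + n_neg).astype(float)
            a, _ = roc_metrics(y, scores)
            assert a == pytest.approx(brute_force_auc(y, scores))


@pytest.fixture(scope="module")
def encoded(small_dataset):
    _, _, net, truth = small_dataset
    return rwr_encode(net, restart_prob=0.3), net, truth


class TestCrossValidate:
    def test_planted_module_is_learnable(self, encoded):
        emb, net, _ = encoded
        rep = cross_validate_resampled(emb, net, k=4, n_resamplings=5, seed=0)
        assert 0.5 < rep.mean_auc <= 1.0
        assert rep.mean_auc > 0.7

    def test_label_permutation_gives_chance_auc(self, encoded):
        emb, net, _ = encoded
        rng = np.random.default_rng(1)
        aucs = []
        for r in range(10):
            pos = list(rng.choice(emb.gene_ids, size=8, replace=False))
            rest = [g for g in emb.gene_ids if g not in pos]
            neg = list(rng.choice(rest, size=8, replace=False))
            data = build_labeled_features(emb, pos, neg)
            aucs.append(cross_validate(data, k=4, seed=r).mean_auc)
        assert abs(np.mean(aucs) - 0.5) < 0.15

    def test_fold_partition_and_bounds(self, encoded):
        emb, net, _ = encoded
        neg = sample_negatives(net, len(net.seed_genes), seed=5)
        data = build_labeled_features(emb, sorted(net.seed_genes), sorted(neg))
        rep = cross_validate(data, k=4, seed=0)
        assert sorted(np.unique(rep.fold_assignments)) == [0, 1, 2, 3]
        assert all(0 <= a <= 1 for a in rep.fold_auc)
        assert all(0 <= a <= 1 for a in rep.fold_aupr)

    def test_k_larger_than_class_is_an_error(self, encoded):
        emb, net, _ = encoded
        neg = sample_negatives(net, 3, seed=5)
        data = build_labeled_features(emb, sorted(net.seed_genes)[:3],
                                      sorted(neg))
        with pytest.raises(ValueError, match="class size"):
            cross_validate(data, k=4, seed=0)

    def test_scaler_leakage_changes_metrics(self):
        # guard: fitting the scaler on all rows (leak) must change AUC on
        # data whose fold means differ strongly from the global mean
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 1, (12, 3)), rng.normal(1, 5, (12, 3))])
        y = np.array([1] * 12 + [0] * 12)
        data_ids = [f"g{i}" for i in range(24)]
        from smrwalk.classifier import LabeledFeatures
        from sklearn.model_selection import StratifiedKFold
        from smrwalk.classifier import train_svm, _score
        data = LabeledFeatures(gene_ids=data_ids, X=X, y=y)
        clean = cross_validate(data, k=3, seed=0)
        # leaky variant, coded here on identical folds
        Xg, _ = zscore_fit_transform(X, np.arange(len(y)))
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=0)
        leaky_auc = []
        for tr, te in skf.split(X, y):
            model = train_svm(Xg[tr], y[tr], kernel="rbf", C=1.0, gamma="auto")
            a, _ = roc_metrics(y[te], _score(model, Xg[te]))
            leaky_auc.append(a)
        assert np.mean(leaky_auc) != pytest.approx(clean.mean_auc, abs=1e-6)

    def test_duplicated_features_leave_svm_metrics_unchanged(self, encoded):
        # z-scoring + gamma = 1/n_features makes the RBF kernel invariant
        # to duplicating every feature column
        emb, net, _ = encoded
        neg = sample_negatives(net, len(net.seed_genes), seed=5)
        from smrwalk.classifier import LabeledFeatures
        data = build_labeled_features(emb, sorted(net.seed_genes), sorted(neg))
        doubled = LabeledFeatures(gene_ids=data.gene_ids,
                                  X=np.hstack([data.X, data.X]), y=data.y)
        a = cross_validate(data, k=4, seed=0)
        b = cross_validate(doubled, k=4, seed=0)
        assert a.fold_auc == pytest.approx(b.fold_auc)
        assert a.fold_aupr == pytest.approx(b.fold_aupr)


class TestPredictNovel:
    def test_threshold_extremes(self, encoded):
        emb, net, _ = encoded
        neg = sample_negatives(net, len(net.seed_genes), seed=3)
        data = build_labeled_features(emb, sorted(net.seed_genes), sorted(neg))
        model, scaler = fit_final_model(data)
        hi = predict_novel(model, scaler, data.unlabeled_ids,
                           data.X_unlabeled, threshold=np.inf)
        lo = predict_novel(model, scaler, data.unlabeled_ids,
                           data.X_unlabeled, threshold=-np.inf)
        assert hi.predicted_positive == set()
        assert lo.predicted_positive == set(data.unlabeled_ids)

    def test_empty_pool_warns(self, encoded):
        emb, net, _ = encoded
        neg = sample_negatives(net, len(net.seed_genes), seed=3)
        data = build_labeled_features(emb, sorted(net.seed_genes), sorted(neg))
        model, scaler = fit_final_model(data)
        with pytest.warns(UserWarning, match="empty"):
            preds = predict_novel(model, scaler, [], np.empty((0, emb.dim)))
        assert preds.predicted_positive == set()

    def test_predictions_enriched_for_module_genes(self, default_dataset,
                                                   default_embedding):
        _, _, net, truth = default_dataset
        emb = default_embedding
        neg = sample_negatives(net, len(net.seed_genes), seed=3)
        data = build_labeled_features(emb, sorted(net.seed_genes), sorted(neg))
        model, scaler = fit_final_model(data)
        preds = predict_novel(model, scaler, data.unlabeled_ids,
                              data.X_unlabeled)
        pool = set(data.unlabeled_ids)
        module_in_pool = truth.module_genes & pool
        k = len(preds.predicted_positive & module_in_pool)
        # hypergeometric upper tail: P(X >= k) drawing |pred| from the pool
        p = stats.hypergeom.sf(k - 1, len(pool), len(module_in_pool),
                               len(preds.predicted_positive))
        assert preds.predicted_positive.isdisjoint(net.seed_genes)
        assert p < 0.01


class TestCompareBaselines:
    def test_all_learners_beat_chance_on_planted_module(self, encoded):
        emb, net, _ = encoded
        neg = sample_negatives(net, len(net.seed_genes), seed=9)
        data = build_labeled_features(emb, sorted(net.seed_genes), sorted(neg))
        table = compare_baselines(data, k=4, seed=0)
        assert set(table["algorithm"]) == {
            "svm", "random_forest", "naive_bayes", "bp_ann",
            "logistic_regression"}
        assert (table["auc"] > 0.5).all()

    def test_svm_row_matches_direct_cross_validate(self, encoded):
        emb, net, _ = encoded
        neg = sample_negatives(net, len(net.seed_genes), seed=9)
        data = build_labeled_features(emb, sorted(net.seed_genes), sorted(neg))
        table = compare_baselines(data, k=4, seed=0)
        direct = cross_validate(data, k=4, seed=0)
        svm_row = table.set_index("algorithm").loc["svm"]
        assert svm_row["auc"] == pytest.approx(direct.mean_auc)
        assert svm_row["aupr"] == pytest.approx(direct.mean_aupr)
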