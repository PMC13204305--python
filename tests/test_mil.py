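import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from lrpathomics import mil


class TestSplitPatients:
    def _labels(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(
            rng.integers(0, 2, n), index=[f"P{i:03d}" for i in range(n)]
        )

    def test_hundred_patients_75_25_no_overlap(self):
        labels = self._labels(100)
        train, test = mil.split_patients(labels)
        assert abs(len(train) - 75) <= 1
        assert len(train) + len(test) == 100
        assert not set(train) & set(test)

    def test_split_is_stratified(self):
        labels = pd.Series([0] * 40 + [1] * 60,
                           index=[f"P{i}" for i in range(100)])
        train, _ = mil.split_patients(labels)
        assert abs(labels.loc[train].mean() - 0.6) <= 0.02

    def test_same_seed_identical(self):
        labels = self._labels(30, seed=1)
        assert mil.split_patients(labels, seed=42) == mil.split_patients(
            labels, seed=42
        )

    def test_five_patients_within_one_rule(self):
        labels = pd.Series([0, 0, 1, 1, 1], index=list("abcde"))
        train, test = mil.split_patients(labels)
        assert len(test) >= 1 and len(train) >= 3
        assert abs(len(train) - 0.75 * 5) <= 1

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            mil.split_patients(pd.Series([0, 1, 1, 1], index=list("abcd")))
        with pytest.raises(ValueError):
            mil.split_patients(pd.Series([1, 1, 1, 1], index=list("abcd")))


def separable_data(n, seed=0, gap=6.0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.standard_normal((n, 10))
    X[:, 0] += gap * y
    return X, y


class TestTrainPatchClassifier:
    def test_separable_classes_high_accuracy(self):
        X, y = separable_data(400, seed=0)
        clf = mil.train_patch_classifier(X, y, seed=0)
        acc = ((clf.predict_proba(X) > 0.5) == y).mean()
        assert acc >= 0.95

    def test_shuffled_labels_chance_auc(self):
        # permutation control: labels decoupled from features everywhere,
        # so held-out AUC against the shuffled labels sits at chance
        X, y = separable_data(2000, seed=1)
        rng = np.random.default_rng(2)
        y_shuf = rng.permutation(y)
        clf = mil.train_patch_classifier(X[:1000], y_shuf[:1000], seed=0)
        auc = roc_auc_score(y_shuf[1000:], clf.predict_proba(X[1000:]))
        assert abs(auc - 0.5) <= 0.1

    def test_probabilities_bounded(self):
        X, y = separable_data(100, seed=3)
        clf = mil.train_patch_classifier(X, y, seed=0)
        p = clf.predict_proba(X)
        assert (p >= 0).all() and (p <= 1).all()

    def test_single_class_rejected(self):
        X, _ = separable_data(50, seed=4)
        with pytest.raises(ValueError, match="single class"):
            mil.train_patch_classifier(X, np.zeros(50), seed=0)


class TestEvaluatePerCluster:
    def test_noise_and_aligned_clusters(self):
        rng = np.random.default_rng(5)
        n = 500
        y = rng.integers(0, 2, n)
        # cluster 0: probabilities independent of label (noise)
        # cluster 1: probabilities equal to label +- small jitter (aligned)
        clusters = rng.integers(0, 2, n)
        p = np.where(
            clusters == 0,
            rng.random(n),
            np.clip(y + rng.normal(0, 0.1, n), 0, 1),
        )
        table = mil.evaluate_per_cluster(p, y, clusters)
        assert abs(table.loc[0, "auc"] - 0.5) <= 0.1
        assert table.loc[1, "auc"] >= 0.95
        assert table.loc[0, "reliable"] and table.loc[1, "reliable"]

    def test_single_class_cluster_nan_auc(self):
        y = np.array([1, 1, 1, 0, 1])
        p = np.array([0.9, 0.8, 0.7, 0.2, 0.6])
        clusters = np.array([0, 0, 0, 1, 1])
        table = mil.evaluate_per_cluster(p, y, clusters)
        assert math.isnan(table.loc[0, "auc"])
        assert not table.loc[0, "reliable"]  # n = 3 < 20

    def test_empty_cluster_omitted_with_warning(self):
        y = np.array([0, 1])
        p = np.array([0.1, 0.9])
        clusters = np.array([0, 0])
        with pytest.warns(UserWarning, match="cluster 1"):
            table = mil.evaluate_per_cluster(
                p, y, clusters, all_clusters=[0, 1]
            )
        assert list(table.index) == [0]


class TestSelectClusters:
    def _metrics(self, aucs, n=30, reliable=None):
        reliable = [True] * len(aucs) if reliable is None else reliable
        return pd.DataFrame(
            {
                "auc": aucs,
                "accuracy": [0.5] * len(aucs),
                "n": [n] * len(aucs),
                "reliable": reliable,
            },
            index=pd.Index(range(len(aucs)), name="cluster"),
        )

    def test_threshold_rule_retains_high_clusters(self):
        m = self._metrics([0.8, 0.5, 0.75, 0.52, 0.7, 0.72])
        assert mil.select_clusters(m, auc_threshold=0.55) == [0, 2, 4, 5]

    def test_threshold_zero_retains_all(self):
        m = self._metrics([0.8, 0.5, 0.75])
        assert mil.select_clusters(m, auc_threshold=0.0) == [0, 1, 2]

    def test_nan_and_unreliable_excluded(self):
        m = self._metrics([0.9, np.nan, 0.9], reliable=[True, True, False])
        assert mil.select_clusters(m, auc_threshold=0.55) == [0]

    def test_top_m_rule(self):
        m = self._metrics([0.6, 0.9, 0.7, 0.8])
        assert mil.select_clusters(m, top_m=2) == [1, 3]

    def test_all_excluded_raises(self):
        m = self._metrics([0.4, 0.3])
        with pytest.raises(ValueError, match="threshold"):
            mil.select_clusters(m, auc_threshold=0.55)
        with pytest.raises(ValueError):
            mil.select_clusters(m.iloc[:0])


class TestMajorityVote:
    def _preds(self, probs, cluster=0, slide="s"):
        return pd.DataFrame(
            {
                "slide": [slide] * len(probs),
                "cluster": [cluster] * len(probs),
                "probability": probs,
            }
        )

    def test_seven_three_majority_high(self):
        preds = self._preds([0.9] * 7 + [0.1] * 3)
        out = mil.majority_vote(preds, [0])
        assert out.loc["s", "vote_label"] == "high"
        assert out.loc["s", "n_high"] == 7 and out.loc["s", "n_low"] == 3

    def test_exact_tie_goes_high(self):
        preds = self._preds([0.9] * 5 + [0.1] * 5)
        assert mil.majority_vote(preds, [0]).loc["s", "vote_label"] == "high"

    def test_cutoff_is_strict(self):
        preds = self._preds([0.5] * 10)
        assert mil.majority_vote(preds, [0]).loc["s", "vote_label"] == "low"

    def test_invariant_to_patch_order(self):
        rng = np.random.default_rng(6)
        preds = self._preds(rng.random(21).tolist())
        shuffled = preds.sample(frac=1, random_state=1).reset_index(drop=True)
        a = mil.majority_vote(preds, [0])
        b = mil.majority_vote(shuffled, [0])
        assert a.equals(b)

    def test_no_retained_patches_warns_na(self):
        preds = self._preds([0.9, 0.8], cluster=3)
        with pytest.warns(UserWarning, match="s"):
            out = mil.majority_vote(preds, [0])
        assert out.loc["s", "vote_label"] is None


class TestPLHFeatures:
    def test_delta_distribution_one_hot(self):
        v = mil.plh_features(np.full(20, 0.93), n_bins=15)
        assert v[13] == 1.0 and v.sum() == 1.0

    def test_two_point_distribution(self):
        v = mil.plh_features(np.array([0.1, 0.9]), n_bins=15)
        assert v[1] == 0.5 and v[13] == 0.5

    def test_probability_one_lands_in_last_bin(self):
        v = mil.plh_features(np.array([1.0]), n_bins=15)
        assert v[14] == 1.0

    def test_uniform_law_of_large_numbers(self):
        rng = np.random.default_rng(7)
        v = mil.plh_features(rng.random(10_000), n_bins=15)
        assert np.abs(v - 1 / 15).max() <= 0.01
        assert v.sum() == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mil.plh_features(np.array([]))


def bow_oracle(slide_probs, n_words):
    """Brute-force TF-IDF: plain loops, no shared code with the library."""
    slides = sorted(slide_probs, key=str)
    N = len(slides)
    counts = {}
    for s in slides:
        c = [0] * n_words
        for p in slide_probs[s]:
            b = min(int(p * n_words), n_words - 1)
            c[b] += 1
        counts[s] = c
    out = {}
    for s in slides:
        total = sum(counts[s])
        vec = []
        for w in range(n_words):
            tf = counts[s][w] / total
            df = sum(1 for t in slides if counts[t][w] > 0)
            idf = math.log((1 + N) / (1 + df)) + 1.0
            vec.append(tf * idf)
        norm = math.sqrt(sum(x * x for x in vec))
        out[s] = [x / norm if norm else x for x in vec]
    return out


class TestBowTFIDF:
    def test_three_slide_toy_matches_oracle(self):
        corpus = {
            "a": np.array([0.05, 0.05, 0.55]),
            "b": np.array([0.05, 0.95]),
            "c": np.array([0.55, 0.55, 0.95, 0.95]),
        }
        out = mil.bow_tfidf_features(corpus, n_words=10)
        oracle = bow_oracle(corpus, 10)
        for s in corpus:
            assert np.allclose(out.loc[s].to_numpy(), oracle[s], atol=1e-12)

    def test_random_corpora_match_oracle(self):
        rng = np.random.default_rng(8)
        for trial in range(5):
            n_slides = int(rng.integers(2, 6))
            corpus = {
                f"s{i}": rng.random(int(rng.integers(1, 30)))
                for i in range(n_slides)
            }
            out = mil.bow_tfidf_features(corpus, n_words=10)
            oracle = bow_oracle(corpus, 10)
            for s in corpus:
                assert np.allclose(out.loc[s].to_numpy(), oracle[s], atol=1e-12)

    def test_ubiquitous_word_idf_one(self):
        # every slide has all its mass in word 0 -> tf = 1, idf = ln(1)+1 = 1
        corpus = {"a": np.array([0.01]), "b": np.array([0.02])}
        out = mil.bow_tfidf_features(corpus, n_words=10)
        assert out.loc["a", "bow_00"] == pytest.approx(1.0)

    def test_single_word_slides_unit_one_hot(self):
        corpus = {"a": np.full(5, 0.95), "b": np.full(3, 0.05)}
        out = mil.bow_tfidf_features(corpus, n_words=10)
        for s in corpus:
            v = out.loc[s].to_numpy()
            assert np.linalg.norm(v) == pytest.approx(1.0)
            assert (v > 0).sum() == 1

    def test_corpus_and_slide_preconditions(self):
        with pytest.raises(ValueError, match="2 slides"):
            mil.bow_tfidf_features({"a": np.array([0.5])})
        with pytest.raises(ValueError, match="b"):
            mil.bow_tfidf_features({"a": np.array([0.5]), "b": np.array([])})


class TestAssembleFeatures:
    def _tables(self, n_plh=15, n_bow=30):
        rng = np.random.default_rng(9)
        idx = pd.Index(["s1", "s2"], name="slide")
        plh = pd.DataFrame(rng.random((2, n_plh)), index=idx)
        plh = plh.div(plh.sum(axis=1), axis=0)
        bow = pd.DataFrame(
            rng.random((2, n_bow)),
            index=idx,
            columns=[f"bow_{j:02d}" for j in range(n_bow)],
        )
        return plh, bow

    def test_default_config_45_named_columns(self):
        plh, bow = self._tables()
        out = mil.assemble_features(plh, bow)
        assert out.shape[1] == 45
        assert list(out.columns[:2]) == ["plh_00", "plh_01"]
        assert list(out.columns[-1:]) == ["bow_29"]

    def test_custom_config_dims(self):
        plh, bow = self._tables(10, 10)
        assert mil.assemble_features(plh, bow).shape[1] == 20

    def test_sub_invariants_preserved(self):
        plh, bow = self._tables()
        out = mil.assemble_features(plh, bow)
        assert np.allclose(out[[f"plh_{j:02d}" for j in range(15)]].sum(axis=1), 1)

    def test_slide_mismatch_rejected(self):
        plh, bow = self._tables()
        with pytest.raises(ValueError, match="slide"):
            mil.assemble_features(plh.iloc[:1], bow)


class TestPearsonFilter:
    def test_duplicate_column_dropped(self):
        rng = np.random.default_rng(10)
        x = rng.random(20)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.random(20)})
        assert mil.pearson_filter(df) == ["a", "c"]

    def test_orthogonal_columns_all_retained(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.standard_normal((500, 8)))
        df.columns = [f"f{j}" for j in range(8)]
        assert mil.pearson_filter(df) == list(df.columns)

    def test_threshold_one_keeps_near_duplicates(self):
        rng = np.random.default_rng(12)
        x = rng.random(50)
        df = pd.DataFrame({"a": x, "near": x + rng.normal(0, 1e-3, 50),
                           "dup": x})
        kept = mil.pearson_filter(df, r_threshold=1.0)
        assert "near" in kept  # |r| < 1 exactly

    def test_constant_column_warned_and_dropped(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame({"k": np.ones(10), "a": rng.random(10)})
        with pytest.warns(UserWarning, match="k"):
            assert mil.pearson_filter(df) == ["a"]

    def test_needs_two_slides(self):
        df = pd.DataFrame({"a": [1.0]})
        with pytest.raises(ValueError):
            mil.pearson_filter(df)


class TestTrainWSIClassifiers:
    def _features(self, n, seed):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.standard_normal((n, 10)),
            index=pd.Index([f"s{i}" for i in range(n)], name="slide"),
            columns=[f"f{j}" for j in range(10)],
        )
        return X, rng

    def test_independent_labels_chance_level(self):
        X, rng = self._features(120, seed=14)
        y = pd.Series(rng.integers(0, 2, 120), index=X.index)
        out = mil.train_wsi_classifiers(X, y, seed=0)
        for fam in ("rf", "lr"):
            assert abs(out[fam]["mean_auc"] - 0.5) <= 0.1

    def test_informative_features_high_auc(self):
        X, rng = self._features(60, seed=15)
        y = pd.Series(rng.integers(0, 2, 60), index=X.index)
        X["f0"] += 4.0 * y
        out = mil.train_wsi_classifiers(X, y, seed=0)
        assert out["rf"]["mean_auc"] >= 0.9
        assert out["lr"]["mean_auc"] >= 0.9

    def test_same_seed_identical_fold_aucs(self):
        X, rng = self._features(30, seed=16)
        y = pd.Series(rng.integers(0, 2, 30), index=X.index)
        a = mil.train_wsi_classifiers(X, y, seed=3)
        b = mil.train_wsi_classifiers(X, y, seed=3)
        assert a["rf"]["fold_aucs"] == b["rf"]["fold_aucs"]
        assert a["lr"]["fold_aucs"] == b["lr"]["fold_aucs"]

    def test_tiny_class_rejected(self):
        X, _ = self._features(10, seed=17)
        y = pd.Series([0] * 8 + [1] * 2, index=X.index)
        with pytest.raises(ValueError, match="n_folds"):
            mil.train_wsi_classifiers(X, y, n_folds=3)
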