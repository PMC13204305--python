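"""Weakly-supervised slide-level risk classification.

Patients are split 0.75:0.25 at the patient level (stratified, seed 42 by
default). A patch-level classifier is trained under weak supervision (each
patch inherits its slide's label), evaluated separately within each
morphological cluster, and low-performing clusters are excluded. Retained
patch predictions are aggregated to slide level two ways:

* majority voting over thresholded patch probabilities, and
* slide feature vectors — a patch likelihood histogram (PLH, 15 bins) and
  a bag-of-words TF-IDF over probability bins (30 words), 45 features
  total — filtered for collinearity and fed to random-forest and
  logistic-regression classifiers under stratified 3-fold CV.

The default patch classifier is a penalized logistic model on the
handcrafted patch features; a CNN backend can be supplied through the same
fit/predict-proba contract.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler


def split_patients(patient_labels: pd.Series, ratio: float = 0.75,
                   seed: int = 42):
    """Stratified patient-level train/test split (no patient in both sets).

    The train fraction is within one patient of ``ratio``.
    """
    labels = pd.Series(patient_labels)
    if len(labels) < 4:
        raise ValueError("need at least 4 patients")
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 patients")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in sorted(counts.index, key=str):
        ids = labels.index[labels == cls].to_numpy()
        ids = ids[rng.permutation(len(ids))]
        n_tr = int(round(len(ids) * ratio))
        n_tr = min(max(n_tr, 1), len(ids) - 1)
        train.extend(ids[:n_tr])
        test.extend(ids[n_tr:])
    return sorted(train, key=str), sorted(test, key=str)


@dataclass
class PatchClassifier:
    """Probability scorer over patch feature vectors."""

    model: object
    source_slides: tuple = ()  # provenance: slides whose patches trained it

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(high risk) per patch, in [0, 1]."""
        return self.model.predict_proba(X)[:, 1]


def train_patch_classifier(
    X: np.ndarray,
    y,
    classifier_spec: str = "logistic",
    seed: int | None = None,
    source_slides: tuple = (),
) -> PatchClassifier:
    """Fit the weakly-supervised patch classifier (default: penalized
    logistic regression on patch features)."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    if classifier_spec == "logistic":
        model = make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=2000, C=1.0, random_state=seed),
        )
    else:
        raise ValueError(f"unknown classifier spec: {classifier_spec!r}")
    model.fit(X, y)
    return PatchClassifier(model=model, source_slides=tuple(source_slides))


def evaluate_per_cluster(
    probabilities: np.ndarray,
    y: np.ndarray,
    clusters: np.ndarray,
    min_reliable: int = 20,
    all_clusters=None,
) -> pd.DataFrame:
    """Patch-level AUC/accuracy within each cluster of the test set.

    Clusters with fewer than ``min_reliable`` patches are flagged
    unreliable; single-class clusters get AUC = NaN. ``all_clusters``
    optionally names the full cluster set so that clusters with no test
    patches are reported as omitted (with a warning) rather than silently
    absent.
    """
    rows = []
    ids = (
        sorted(set(int(v) for v in clusters))
        if all_clusters is None
        else sorted(int(v) for v in all_clusters)
    )
    for c in ids:
        sel = clusters == c
        n = int(sel.sum())
        if n == 0:
            warnings.warn(f"cluster {c} has no test patches; omitted")
            continue
        yc, pc = y[sel], probabilities[sel]
        acc = accuracy_score(yc, pc > 0.5)
        auc = roc_auc_score(yc, pc) if np.unique(yc).size == 2 else np.nan
        rows.append((c, auc, acc, n, n >= min_reliable))
    return pd.DataFrame(
        rows, columns=["cluster", "auc", "accuracy", "n", "reliable"]
    ).set_index("cluster")


def select_clusters(
    metrics: pd.DataFrame,
    auc_threshold: float = 0.55,
    top_m: int | None = None,
) -> list:
    """Retain clusters by AUC threshold (default) or keep the top m.

    NaN-AUC and unreliable clusters are excluded. Raises if nothing
    survives.
    """
    if metrics.empty:
        raise ValueError("metrics table is empty")
    ok = metrics.dropna(subset=["auc"])
    ok = ok[ok["reliable"]]
    if top_m is not None:
        kept = ok.sort_values("auc", ascending=False).head(top_m).index
    else:
        kept = ok.index[ok["auc"] >= auc_threshold]
    kept = sorted(int(c) for c in kept)
    if not kept:
        raise ValueError(
            "all clusters excluded; lower auc_threshold or use top_m"
        )
    return kept


def majority_vote(
    predictions: pd.DataFrame,
    retained_clusters,
    prob_cutoff: float = 0.5,
) -> pd.DataFrame:
    """Slide labels by majority vote over retained-cluster patches.

    A patch votes high iff its probability strictly exceeds ``prob_cutoff``;
    exact vote ties go to high. ``predictions`` has columns
    (slide, cluster, probability). Slides with no retained-cluster patch
    are labeled NA with a warning. Invariant to patch ordering.
    """
    retained = set(int(c) for c in retained_clusters)
    rows = []
    for slide, sub in predictions.groupby("slide", sort=True):
        sub = sub[sub["cluster"].isin(retained)]
        if sub.empty:
            warnings.warn(f"slide {slide} has no retained-cluster patches")
            rows.append((slide, None, 0, 0))
            continue
        n_high = int((sub["probability"] > prob_cutoff).sum())
        n_low = len(sub) - n_high
        label = "high" if n_high >= n_low else "low"
        rows.append((slide, label, n_high, n_low))
    return pd.DataFrame(
        rows, columns=["slide", "vote_label", "n_high", "n_low"]
    ).set_index("slide")


def _bin_index(p: np.ndarray, n_bins: int) -> np.ndarray:
    # equal-width bins on [0, 1]; the last bin is right-closed
    return np.minimum((p * n_bins).astype(int), n_bins - 1)


def plh_features(probabilities: np.ndarray, n_bins: int = 15) -> np.ndarray:
    """Patch likelihood histogram: binned probabilities, normalized to sum 1."""
    p = np.asarray(probabilities, float)
    if p.size == 0:
        raise ValueError("no patch probabilities")
    counts = np.bincount(_bin_index(p, n_bins), minlength=n_bins)
    return counts / counts.sum()


def bow_tfidf_features(slide_probs: dict, n_words: int = 30) -> pd.DataFrame:
    """Bag-of-words TF-IDF over probability bins, one vector per slide.

    Vocabulary = ``n_words`` equal-width probability bins; tf = word count
    over slide patch count; idf = ln((1 + N) / (1 + df)) + 1 with N slides
    and df the number of slides containing the word; vectors are tf*idf,
    L2-normalized.
    """
    if len(slide_probs) < 2:
        raise ValueError("corpus must contain at least 2 slides")
    slides = sorted(slide_probs, key=str)
    counts = np.zeros((len(slides), n_words))
    for i, s in enumerate(slides):
        p = np.asarray(slide_probs[s], float)
        if p.size == 0:
            raise ValueError(f"slide {s} has no patches")
        counts[i] = np.bincount(_bin_index(p, n_words), minlength=n_words)
    tf = counts / counts.sum(axis=1, keepdims=True)
    df_count = (counts > 0).sum(axis=0)
    idf = np.log((1 + len(slides)) / (1 + df_count)) + 1.0
    v = tf * idf
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    v = v / np.where(norms == 0, 1.0, norms)
    return pd.DataFrame(
        v, index=pd.Index(slides, name="slide"),
        columns=[f"bow_{j:02d}" for j in range(n_words)],
    )


def assemble_features(plh: pd.DataFrame, bow: pd.DataFrame) -> pd.DataFrame:
    """Concatenate PLH and BoW blocks into slide feature vectors (default
    15 + 30 = 45 columns, named plh_00.. and bow_00..)."""
    if set(plh.index) != set(bow.index):
        raise ValueError("PLH and BoW cover different slide sets")
    plh = plh.sort_index().copy()
    plh.columns = [f"plh_{j:02d}" for j in range(plh.shape[1])]
    return pd.concat([plh, bow.sort_index()], axis=1)


def plh_table(slide_probs: dict, n_bins: int = 15) -> pd.DataFrame:
    """PLH vectors for a corpus of slides, as a DataFrame."""
    slides = sorted(slide_probs, key=str)
    mat = np.stack([plh_features(slide_probs[s], n_bins) for s in slides])
    return pd.DataFrame(
        mat, index=pd.Index(slides, name="slide"),
        columns=[f"plh_{j:02d}" for j in range(n_bins)],
    )


def pearson_filter(features: pd.DataFrame, r_threshold: float = 0.9) -> list:
    """Greedy collinearity filter in column order.

    A feature is dropped if its |Pearson r| with an already-retained
    feature exceeds ``r_threshold``; constant columns are dropped with a
    warning. Returns retained column names.
    """
    if len(features) < 2:
        raise ValueError("need at least 2 slides")
    retained = []
    X = features.to_numpy(float)
    for j, col in enumerate(features.columns):
        x = X[:, j]
        if x.std() == 0:
            warnings.warn(f"constant feature {col} dropped")
            continue
        collinear = False
        for k in retained:
            r = np.corrcoef(x, X[:, features.columns.get_loc(k)])[0, 1]
            if abs(r) > r_threshold:
                collinear = True
                break
        if not collinear:
            retained.append(col)
    return retained


def train_wsi_classifiers(
    features: pd.DataFrame,
    labels: pd.Series,
    n_folds: int = 3,
    seed: int | None = None,
):
    """Random-forest and logistic-regression slide classifiers with
    stratified k-fold CV.

    Returns a dict per model family with per-fold AUCs, their mean, pooled
    ROC points, and the model refit on all slides.
    """
    y = labels.loc[features.index].to_numpy()
    if min(np.bincount(pd.factorize(y)[0])) < n_folds:
        raise ValueError("each class needs at least n_folds slides")
    X = features.to_numpy(float)
    y01 = (y == np.unique(y)[-1]).astype(int) if y.dtype != int else y

    models = {
        "rf": lambda: RandomForestClassifier(
            n_estimators=200, random_state=seed, n_jobs=1
        ),
        "lr": lambda: make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed)
        ),
    }
    results = {}
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for name, factory in models.items():
        fold_aucs = []
        pooled_p, pooled_y = [], []
        for tr, te in skf.split(X, y01):
            m = factory()
            m.fit(X[tr], y01[tr])
            p = m.predict_proba(X[te])[:, 1]
            fold_aucs.append(roc_auc_score(y01[te], p))
            pooled_p.append(p)
            pooled_y.append(y01[te])
        fpr, tpr, _ = roc_curve(np.concatenate(pooled_y), np.concatenate(pooled_p))
        final = factory()
        final.fit(X, y01)
        results[name] = {
            "fold_aucs": fold_aucs,
            "mean_auc": float(np.mean(fold_aucs)),
            "roc": (fpr, tpr),
            "model": final,
        }
    return results
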