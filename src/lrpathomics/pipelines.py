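"""End-to-end drivers chaining the pipeline stages.

``run_signature_pipeline`` takes a cohort (expression, survival, catalog)
to a fitted risk model: normalization, pair support filter, activity
scoring, univariate Cox screen, LASSO-Cox and RSF selection, intersection,
multivariate Cox, median stratification, and Kaplan-Meier/log-rank.

``run_wsi_pipeline`` takes labeled slides to slide-level risk calls:
tiling, Macenko normalization to a training-slide reference, z-scoring,
featurization, PCA, K-means, weakly-supervised patch classification,
per-cluster evaluation, cluster selection, majority voting, and PLH +
BoW/TF-IDF slide classifiers — with every fitted artifact carrying the
slide ids it was trained on so the no-leakage contract is checkable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import clustering, lr, mil, survival, wsi
from .synthetic import SlideTruth, simulate_slide


def run_signature_pipeline(
    expr: pd.DataFrame,
    surv: pd.DataFrame,
    catalog: pd.DataFrame,
    seed: int | None = None,
    alpha: float = 0.05,
    n_folds: int = 10,
    n_trees: int = 5000,
    top_k: int = 10,
    min_detect_frac: float = 0.1,
    min_pairs: int = 80,
) -> dict:
    """Full prognostic-signature workflow on a bulk cohort."""
    norm = lr.tc_normalize(expr)
    supported = lr.filter_supported_pairs(
        norm, catalog, min_detect_frac=min_detect_frac, min_pairs=min_pairs
    )
    activity = lr.activity_matrix(norm, supported)
    activity = activity[activity.std(axis=1) > 0]

    screen = survival.univariate_cox_screen(activity, surv, alpha=alpha)
    screened = screen.index[screen["flagged"]].tolist()
    out = {"screen": screen, "screened_pairs": screened}
    if len(screened) < 2:
        warnings.warn("fewer than 2 pairs pass the univariate screen")
        out["selected_pairs"] = screened
        return out

    act_screened = activity.loc[screened]
    lasso_set, lasso_meta = survival.lasso_cox_select(
        act_screened, surv, n_folds=n_folds, seed=seed
    )
    rsf_table = survival.rsf_importance(
        act_screened, surv, n_trees=n_trees, top_k=top_k, seed=seed
    )
    selected = survival.intersect_features(lasso_set, list(rsf_table.index))
    out.update(
        lasso_pairs=lasso_set,
        lasso_meta=lasso_meta,
        rsf_table=rsf_table,
        selected_pairs=selected,
    )
    if not selected:
        return out

    model = survival.fit_risk_model(activity.loc[selected], surv)
    groups = survival.stratify_by_median(model)
    curves, chi2, p = survival.km_logrank(groups, surv)
    uni, multi = survival.covariate_adjusted_cox(model.risk_score, surv)
    out.update(
        model=model,
        groups=groups,
        km_curves=curves,
        logrank_chi2=chi2,
        logrank_p=p,
        cox_univariate=uni,
        cox_multivariate=multi,
    )
    return out


def simulate_slide_cohort(
    n_slides: int,
    seed: int = 0,
    k_classes: int = 6,
    grid: tuple = (4, 4),
    background_frac: float = 0.25,
    tumor_frac: float = 0.4,
    label_shift: float = 0.08,
    noise_class_jitter: float = 0.15,
    texture_noise: float = 1.0,
) -> list:
    """Simulate a balanced labeled slide set for the MIL study.

    Half the slides are high-risk (label 1). The two tumor classes are
    rendered with a label-dependent concentration shift, emulating
    label-informative morphology; the remaining classes carry slide-level
    staining jitter uncorrelated with the label, so they are noise with
    respect to risk.
    """
    rng = np.random.default_rng(seed)
    slides = []
    for i in range(n_slides):
        label = i % 2
        truth = SlideTruth(seed=int(rng.integers(0, 2**31 - 1)))
        img, t = simulate_slide(
            k_classes=k_classes,
            grid=grid,
            background_frac=background_frac,
            truth=truth,
            tumor_frac=tumor_frac,
            label=label,
            label_shift=label_shift,
            noise_class_jitter=noise_class_jitter,
            texture_noise=texture_noise,
        )
        slides.append({"slide_id": f"WSI{i:03d}", "image": img, "truth": t,
                       "label": label})
    return slides


def assert_no_leakage(provenance: dict):
    """Verify that no test slide contributed to any fitted artifact."""
    test = set(provenance["test_slides"])
    train = set(provenance["train_slides"])
    if train & test:
        raise AssertionError("train/test slide sets overlap")
    for name in ("reference_stain", "channel_stats", "pca", "kmeans",
                 "patch_classifier"):
        sources = set(provenance[name])
        if sources & test:
            raise AssertionError(f"{name} was fitted on test slides")
        if not sources <= train:
            raise AssertionError(f"{name} used slides outside the train split")


def run_wsi_pipeline(
    slides: list,
    seed: int = 0,
    split_seed: int = 42,
    k: int = 6,
    plh_bins: int = 15,
    bow_bins: int = 30,
    auc_threshold: float = 0.55,
    r_threshold: float = 0.9,
    n_folds: int = 3,
    min_tissue_frac: float = 0.5,
    normalize_stain: bool = True,
) -> dict:
    """Full pathomics workflow on labeled slides.

    ``slides`` is a list of dicts with keys slide_id, image, label.
    Returns per-cluster metrics, the retained cluster set, majority-vote
    calls on test slides, MIL feature tables and CV results with and
    without cluster selection, and a provenance record for the leakage
    check.
    """
    labels = pd.Series(
        {s["slide_id"]: s["label"] for s in slides}, name="label"
    )
    train_ids, test_ids = mil.split_patients(labels, seed=split_seed)
    train_set = set(train_ids)

    # tile all slides
    patch_pixels, rows = [], []
    for s in slides:
        mask = wsi.detect_tissue(s["image"])
        for p in wsi.tile_slide(s["image"], mask, slide_id=s["slide_id"],
                                min_tissue_frac=min_tissue_frac):
            patch_pixels.append(p.pixels)
            rows.append((p.slide_id, p.x, p.y, p.tissue_frac))
    manifest = pd.DataFrame(rows, columns=["slide", "x", "y", "tissue_frac"])
    is_train = manifest["slide"].isin(train_set).to_numpy()

    if normalize_stain:
        ref_pixels = np.concatenate(
            [p.reshape(-1, 3) for p, tr in zip(patch_pixels, is_train) if tr]
        )
        reference = wsi.macenko_fit(ref_pixels)
        norm_pixels = []
        for sid, sub in manifest.groupby("slide", sort=False):
            idx = sub.index.to_numpy()
            src = wsi.macenko_fit(
                np.concatenate([patch_pixels[i].reshape(-1, 3) for i in idx])
            )
            for i in idx:
                norm_pixels.append(
                    (i, wsi.macenko_normalize(patch_pixels[i], src, reference))
                )
        norm_pixels.sort(key=lambda t: t[0])
        patch_pixels = [p for _, p in norm_pixels]
        ref_sources = tuple(sorted(train_set))
    else:
        reference = None
        ref_sources = ()

    patch_arr = np.stack(patch_pixels)
    _, stats = wsi.zscore_rgb(patch_arr[is_train], source_slides=train_ids)
    z_all, _ = wsi.zscore_rgb(patch_arr, stats=stats)

    feats = clustering.extract_features(z_all)
    reduced_train, pca = clustering.reduce_pca(feats[is_train], seed=seed)
    reduced_all = pca.transform(feats)

    cmodel = clustering.cluster_patches(
        reduced_train, k=k, seed=seed, source_slides=train_ids
    )
    assign_all = cmodel.assign(reduced_all)

    patch_labels = labels.loc[manifest["slide"]].to_numpy()
    clf = mil.train_patch_classifier(
        feats[is_train], patch_labels[is_train], seed=seed,
        source_slides=train_ids,
    )
    probs = clf.predict_proba(feats)

    metrics = mil.evaluate_per_cluster(
        probs[~is_train], patch_labels[~is_train], assign_all[~is_train]
    )
    retained = mil.select_clusters(metrics, auc_threshold=auc_threshold)

    predictions = manifest.assign(cluster=assign_all, probability=probs)
    votes = mil.majority_vote(
        predictions[~is_train], retained_clusters=retained
    )

    def mil_cv(cluster_filter):
        sub = (
            predictions[predictions["cluster"].isin(cluster_filter)]
            if cluster_filter is not None
            else predictions
        )
        slide_probs = {
            sid: g["probability"].to_numpy() for sid, g in sub.groupby("slide")
        }
        missing = set(labels.index) - set(slide_probs)
        for m in missing:
            warnings.warn(f"slide {m} has no patches in the retained clusters")
        plh = mil.plh_table(slide_probs, n_bins=plh_bins)
        bow = mil.bow_tfidf_features(slide_probs, n_words=bow_bins)
        features = mil.assemble_features(plh, bow)
        kept_cols = mil.pearson_filter(features, r_threshold=r_threshold)
        cv = mil.train_wsi_classifiers(
            features[kept_cols], labels.loc[features.index],
            n_folds=n_folds, seed=seed,
        )
        return features, kept_cols, cv

    feat_sel, cols_sel, cv_sel = mil_cv(set(retained))
    feat_all, cols_all, cv_all = mil_cv(None)

    provenance = {
        "train_slides": tuple(train_ids),
        "test_slides": tuple(test_ids),
        "reference_stain": ref_sources,
        "channel_stats": stats.source_slides,
        "pca": tuple(train_ids),
        "kmeans": cmodel.source_slides,
        "patch_classifier": clf.source_slides,
    }
    return {
        "manifest": manifest,
        "labels": labels,
        "train_slides": train_ids,
        "test_slides": test_ids,
        "assignments": assign_all,
        "probabilities": probs,
        "cluster_model": cmodel,
        "per_cluster_metrics": metrics,
        "retained_clusters": retained,
        "votes": votes,
        "mil_features_selected": feat_sel,
        "mil_features_all": feat_all,
        "cv_with_selection": cv_sel,
        "cv_without_selection": cv_all,
        "provenance": provenance,
    }
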