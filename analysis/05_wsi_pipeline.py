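#!/usr/bin/env python
"""Run the pathomics pipeline on a slide directory written by
04_simulate_slides.py: tiling, optional Macenko normalization, z-scoring,
featurization, PCA, K-means, weakly-supervised patch classification,
per-cluster evaluation and selection, majority voting, and PLH+BoW slide
classifiers with 3-fold CV."""

import argparse
from pathlib import Path

import pandas as pd

from lrpathomics import io
from lrpathomics.pipelines import assert_no_leakage, run_wsi_pipeline


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--slide-dir", type=Path, default=Path("results/slides"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--split-seed", type=int, default=42)
    ap.add_argument("--k", type=int, default=6)
    ap.add_argument("--auc-threshold", type=float, default=0.55)
    ap.add_argument("--normalize-stain", action="store_true",
                    help="enable Macenko normalization (off by default for "
                         "the controlled synthetic study; see methods note)")
    ap.add_argument("--out-dir", type=Path, default=Path("results/wsi"))
    args = ap.parse_args()

    labels = pd.read_csv(args.slide_dir / "labels.csv")
    slides = [
        {
            "slide_id": row["slide"],
            "image": io.read_png(args.slide_dir / f"{row['slide']}.png"),
            "label": int(row["label"]),
        }
        for _, row in labels.iterrows()
    ]

    out = run_wsi_pipeline(
        slides, seed=args.seed, split_seed=args.split_seed, k=args.k,
        auc_threshold=args.auc_threshold,
        normalize_stain=args.normalize_stain,
    )
    assert_no_leakage(out["provenance"])

    args.out_dir.mkdir(parents=True, exist_ok=True)
    out["manifest"].assign(
        cluster=out["assignments"], probability=out["probabilities"]
    ).to_csv(args.out_dir / "patch_predictions.csv", index=False)
    out["per_cluster_metrics"].to_csv(args.out_dir / "cluster_metrics.csv")
    out["votes"].to_csv(args.out_dir / "votes.csv")
    out["mil_features_selected"].to_csv(args.out_dir / "mil_features.csv")
    io.write_json(
        {
            "retained_clusters": out["retained_clusters"],
            "train_slides": out["train_slides"],
            "test_slides": out["test_slides"],
            "cv_with_selection": {
                fam: {
                    "fold_aucs": out["cv_with_selection"][fam]["fold_aucs"],
                    "mean_auc": out["cv_with_selection"][fam]["mean_auc"],
                }
                for fam in ("rf", "lr")
            },
            "cv_without_selection": {
                fam: {
                    "fold_aucs": out["cv_without_selection"][fam]["fold_aucs"],
                    "mean_auc": out["cv_without_selection"][fam]["mean_auc"],
                }
                for fam in ("rf", "lr")
            },
        },
        args.out_dir / "cv_results.json",
    )
    print(f"retained clusters: {out['retained_clusters']}")
    for fam in ("rf", "lr"):
        print(
            f"{fam}: mean CV AUC with selection "
            f"{out['cv_with_selection'][fam]['mean_auc']:.3f}, "
            f"without {out['cv_without_selection'][fam]['mean_auc']:.3f}"
        )


if __name__ == "__main__":
    main()
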