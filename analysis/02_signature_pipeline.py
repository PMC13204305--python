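#!/usr/bin/env python
"""Run the prognostic-signature pipeline on a cohort directory written by
01_simulate_cohort.py: TC normalization, pair support filter, activity
scoring, univariate Cox screen, LASSO-Cox and RSF selection, intersection,
multivariate Cox risk model, median stratification, KM/log-rank, and
covariate-adjusted Cox. Also writes spot co-enrichment fractions for the
selected pairs."""

import argparse
from pathlib import Path

from lrpathomics import io, lr
from lrpathomics.pipelines import run_signature_pipeline


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort-dir", type=Path,
                    default=Path("results/cohort"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-trees", type=int, default=300,
                    help="RSF forest size (desk-scale default)")
    ap.add_argument("--out-dir", type=Path, default=Path("results/signature"))
    args = ap.parse_args()

    expr = io.read_expression_tsv(args.cohort_dir / "expression.tsv")
    surv = io.read_survival_csv(args.cohort_dir / "survival.csv")
    catalog = io.read_catalog_tsv(args.cohort_dir / "catalog.tsv")

    out = run_signature_pipeline(
        expr, surv, catalog, seed=args.seed, n_trees=args.n_trees
    )

    args.out_dir.mkdir(parents=True, exist_ok=True)
    out["screen"].to_csv(args.out_dir / "univariate_screen.csv")
    io.write_json(
        {
            "screened_pairs": out["screened_pairs"],
            "lasso_pairs": out.get("lasso_pairs", []),
            "selected_pairs": out.get("selected_pairs", []),
        },
        args.out_dir / "selected_pairs.json",
    )
    if "rsf_table" in out:
        out["rsf_table"].to_csv(args.out_dir / "rsf_importance.csv")
    if "model" in out:
        model = out["model"]
        io.write_json(
            {
                "pairs": model.pairs,
                "coefficients": dict(model.coefficients),
                "cutoff": model.cutoff,
                "logrank_chi2": out["logrank_chi2"],
                "logrank_p": out["logrank_p"],
            },
            args.out_dir / "risk_model.json",
        )
        out["groups"].to_frame("group").to_csv(args.out_dir / "groups.csv")
        for name, curve in out["km_curves"].items():
            curve.to_csv(args.out_dir / f"km_{name}.csv")
        out["cox_univariate"].to_csv(args.out_dir / "cox_univariate.csv")
        out["cox_multivariate"].to_csv(args.out_dir / "cox_multivariate.csv")

        norm = lr.tc_normalize(expr)
        rows = {}
        for pair in model.pairs:
            lig = catalog.loc[pair, "ligand"]
            rec = catalog.loc[pair, "receptor"]
            enriched = lr.spot_coenrichment(norm, lig, rec)
            rows[pair] = float(enriched.mean())
        io.write_json(rows, args.out_dir / "coenrichment_fractions.json")

        print(f"selected pairs: {out['selected_pairs']}")
        print(f"log-rank chi2 = {out['logrank_chi2']:.3f}, "
              f"p = {out['logrank_p']:.3e}")
    else:
        print("pipeline stopped early: "
              f"{len(out['screened_pairs'])} pairs passed the screen")


if __name__ == "__main__":
    main()
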