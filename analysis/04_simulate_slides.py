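#!/usr/bin/env python
"""Simulate a labeled slide cohort (Beer-Lambert stain-mixed tiles, two
label-informative tumor classes, label-independent staining jitter on the
rest) and write PNGs plus a labels CSV and truth JSONs."""

import argparse
from pathlib import Path

import pandas as pd

from lrpathomics import io
from lrpathomics.pipelines import simulate_slide_cohort


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-slides", type=int, default=48)
    ap.add_argument("--grid", type=int, nargs=2, default=(4, 4))
    ap.add_argument("--background-frac", type=float, default=0.125)
    ap.add_argument("--out-dir", type=Path, default=Path("results/slides"))
    args = ap.parse_args()

    slides = simulate_slide_cohort(
        args.n_slides, seed=args.seed, grid=tuple(args.grid),
        background_frac=args.background_frac,
    )

    args.out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in slides:
        io.write_png(s["image"], args.out_dir / f"{s['slide_id']}.png")
        io.write_json(
            {
                "class_of_patch": s["truth"].class_of_patch,
                "slide_label": s["truth"].slide_label,
            },
            args.out_dir / f"{s['slide_id']}.truth.json",
        )
        rows.append((s["slide_id"], s["label"]))
    pd.DataFrame(rows, columns=["slide", "label"]).to_csv(
        args.out_dir / "labels.csv", index=False
    )
    print(f"wrote {len(slides)} slides to {args.out_dir}")


if __name__ == "__main__":
    main()
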