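"""Ligand-receptor pair identification and activity scoring from bulk expression.

The stage takes a normalized genes x samples matrix and an L-R catalog
(ligand, receptor, pathway), scores each pair's co-expression by Spearman
correlation with BH false-discovery control, removes pathway redundancy by
keeping each (ligand, receptor) under its most significant pathway, and
summarizes each pair per sample as the geometric mean of log1p ligand and
receptor expression. A spot-level co-enrichment rule supports spatial data
(spots as samples).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

logger_warn = warnings.warn


def tc_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Total-count normalization: scale each sample to the mean library size.

    Preserves within-sample gene proportions exactly.
    """
    if expr.attrs.get("normalized", False):
        raise ValueError("matrix is already normalized")
    totals = expr.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample: {zero.index[0]}")
    target = totals.mean()
    out = expr * (target / totals)
    out.attrs["normalized"] = True
    return out


def filter_supported_pairs(
    expr: pd.DataFrame,
    catalog: pd.DataFrame,
    min_detect_frac: float = 0.1,
    min_pairs: int = 80,
) -> pd.DataFrame:
    """Keep pairs whose ligand AND receptor are detected in enough samples.

    A gene is detected in a sample if its value is > 0; it must be detected
    in at least ``min_detect_frac`` of samples. Raises if fewer than
    ``min_pairs`` pairs survive (dataset-level support requirement).
    """
    detect = (expr > 0).mean(axis=1)

    def supported(g):
        return g in detect.index and detect[g] >= min_detect_frac

    keep = [
        supported(row.ligand) and supported(row.receptor)
        for row in catalog.itertuples()
    ]
    out = catalog[keep]
    if len(out) < min_pairs:
        raise ValueError(
            f"only {len(out)} supported ligand-receptor pairs "
            f"(minimum {min_pairs} required)"
        )
    return out


def score_pair_significance(
    expr: pd.DataFrame,
    catalog: pd.DataFrame,
    method: str = "analytic",
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Spearman correlation and BH-adjusted significance per L-R pair.

    ``analytic`` uses the t-approximation for the Spearman null;
    ``permutation`` permutes sample labels of the receptor vector. Pairs
    with a constant ligand or receptor get rho = NaN and are excluded from
    the BH family.
    """
    if not expr.attrs.get("normalized", False):
        raise ValueError("expression must be normalized first")
    if expr.shape[1] < 5:
        raise ValueError("need at least 5 samples")
    if method not in ("analytic", "permutation"):
        raise ValueError(f"unknown method: {method}")
    rng = np.random.default_rng(seed)

    rows = []
    for pair in catalog.itertuples():
        lig = expr.loc[pair.ligand].to_numpy(float)
        rec = expr.loc[pair.receptor].to_numpy(float)
        if np.ptp(lig) == 0 or np.ptp(rec) == 0:
            logger_warn(f"constant expression for pair {pair.Index}; excluded")
            rows.append((pair.Index, pair.ligand, pair.receptor, pair.pathway,
                         np.nan, np.nan))
            continue
        rho, p = sps.spearmanr(lig, rec)
        if method == "permutation":
            rl = sps.rankdata(lig)
            rr = sps.rankdata(rec)
            rl = (rl - rl.mean()) / rl.std()
            rr = (rr - rr.mean()) / rr.std()
            n = rl.size
            perms = np.array([rng.permutation(rr) for _ in range(n_perm)])
            rho_perm = perms @ rl / n
            p = (1 + np.sum(np.abs(rho_perm) >= abs(rho) - 1e-12)) / (n_perm + 1)
        rows.append((pair.Index, pair.ligand, pair.receptor, pair.pathway, rho, p))

    out = pd.DataFrame(
        rows, columns=["pair", "ligand", "receptor", "pathway", "rho", "p"]
    ).set_index("pair")
    out["q"] = bh_adjust(out["p"])
    return out.sort_values("q", kind="mergesort")


def reduce_to_best_pathway(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Keep one record per (ligand, receptor): minimal q, ties to the
    lexicographically smallest pathway id. Idempotent."""
    if stats_df.empty:
        return stats_df.copy()
    ordered = stats_df.sort_values(["q", "pathway"], kind="mergesort")
    return ordered[~ordered.duplicated(subset=["ligand", "receptor"])]


def lr_activity(expr: pd.DataFrame, ligand: str, receptor: str) -> pd.Series:
    """Per-sample activity: geometric mean of log1p ligand and receptor values.

    Symmetric in ligand/receptor, monotone in each, zero iff either gene is
    zero in that sample.
    """
    for g in (ligand, receptor):
        if g not in expr.index:
            raise KeyError(f"gene not in expression matrix: {g}")
    return np.sqrt(np.log1p(expr.loc[ligand]) * np.log1p(expr.loc[receptor]))


def activity_matrix(expr: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Pairs x samples activity scores for every catalog pair."""
    rows = {
        pair.Index: lr_activity(expr, pair.ligand, pair.receptor)
        for pair in catalog.itertuples()
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "pair"
    return out.loc[catalog.index]


def spot_coenrichment(
    spot_expr: pd.DataFrame,
    ligand: str,
    receptor: str,
    quantile: float = 0.75,
    annotations: pd.Series | None = None,
):
    """Flag spots where ligand AND receptor both exceed their own quantile.

    Returns a boolean per-spot Series, plus per-annotation enriched
    fractions when a spot -> annotation map is given.
    """
    if spot_expr.shape[1] < 10:
        raise ValueError("need at least 10 spots")
    lig = spot_expr.loc[ligand]
    rec = spot_expr.loc[receptor]
    thr_l = lig.quantile(quantile)
    thr_r = rec.quantile(quantile)
    enriched = (lig > thr_l) & (rec > thr_r)
    if not enriched.any():
        logger_warn("no spot exceeds both thresholds")
    if annotations is None:
        return enriched
    fractions = enriched.groupby(annotations).mean()
    return enriched, fractions
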