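"""Shared statistical utilities: BH correction and Cox partial likelihood."""

from __future__ import annotations

import numpy as np
import pandas as pd


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values).

    NaN entries are passed through as NaN and excluded from the family.
    The largest p in the family maps to itself; q is monotone in p-rank.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    q[ok] = out
    return q


def cox_partial_loglik(linear_predictor, time, event) -> float:
    """Breslow partial log-likelihood of a fixed linear predictor.

    Used to score held-out folds when tuning the LASSO-Cox penalty.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    order = np.argsort(-t, kind="mergesort")  # decreasing time
    lp, t, d = lp[order], t[order], d[order]
    # risk set at time t_i = samples with time >= t_i = prefix in this order;
    # ties share the same risk set under Breslow
    elp = np.exp(lp - lp.max())
    cum = np.cumsum(elp)
    # for tied times, every tied sample uses the full tied risk set
    risk = np.empty_like(cum)
    i = 0
    n = t.size
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        risk[i : j + 1] = cum[j]
        i = j + 1
    ll = np.sum(d * (lp - lp.max() - np.log(risk)))
    return float(ll)


def standardize_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Standardize each row to mean 0, sd 1 (population sd)."""
    mu = df.mean(axis=1)
    sd = df.std(axis=1, ddof=0)
    if (sd == 0).any():
        bad = df.index[sd == 0].tolist()
        raise ValueError(f"zero-variance rows cannot be standardized: {bad[:5]}")
    return df.sub(mu, axis=0).div(sd, axis=0)
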