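"""Prognostic signature construction and evaluation.

Stages: univariate Cox screen over L-R activities, LASSO-Cox selection
(penalty tuned by cross-validated partial-likelihood deviance), random
survival forest permutation importance, intersection of the two feature
sets, a multivariate Cox risk score, median stratification, Kaplan-Meier /
log-rank comparison, covariate-adjusted Cox fits, and a risk-group
mutation-frequency comparison (Fisher exact per gene with BH correction).

All Cox fits use per-pair standardized activities, so hazard ratios are
per standard deviation of activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy.stats import fisher_exact
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold
from sksurv.ensemble import RandomSurvivalForest
from sksurv.linear_model import CoxnetSurvivalAnalysis

from .stats import bh_adjust, cox_partial_loglik, standardize_rows


def _check_events(surv: pd.DataFrame, minimum: int = 10):
    n_events = int(surv["OS"].sum())
    if n_events < minimum:
        raise ValueError(f"need at least {minimum} events, got {n_events}")


def _sksurv_y(surv: pd.DataFrame):
    return np.array(
        list(zip(surv["OS"].astype(bool), surv["OS.time"].astype(float))),
        dtype=[("event", "?"), ("time", "<f8")],
    )


def univariate_cox_screen(
    activity: pd.DataFrame, surv: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """One Cox proportional-hazards fit per pair on standardized activity.

    Returns a table of Wald hazard ratios and p-values with BH q-values;
    pairs with p < alpha are flagged. Zero-variance or non-converging
    pairs are skipped with a warning.
    """
    _check_events(surv)
    surv = surv.loc[activity.columns]
    rows = []
    for pair, vals in activity.iterrows():
        v = vals.to_numpy(float)
        sd = v.std()
        if sd == 0:
            warnings.warn(f"zero-variance activity for {pair}; skipped")
            continue
        df = pd.DataFrame(
            {
                "x": (v - v.mean()) / sd,
                "T": surv["OS.time"].to_numpy(),
                "E": surv["OS"].to_numpy(),
            }
        )
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="T", event_col="E")
        except (ConvergenceError, np.linalg.LinAlgError):
            warnings.warn(f"Cox fit did not converge for {pair}; excluded")
            continue
        s = cph.summary.loc["x"]
        rows.append((pair, float(s["exp(coef)"]), float(s["coef"]), float(s["p"])))
    out = pd.DataFrame(rows, columns=["pair", "HR", "coef", "p"]).set_index("pair")
    out["q"] = bh_adjust(out["p"])
    out["flagged"] = out["p"] < alpha
    return out


def lasso_cox_select(
    activity: pd.DataFrame,
    surv: pd.DataFrame,
    n_folds: int = 10,
    seed: int | None = None,
    n_alphas: int = 50,
    alphas=None,
):
    """LASSO-Cox feature selection with CV-tuned penalty.

    The penalty path comes from an elastic-net Cox fit with l1_ratio = 1;
    lambda is chosen at the minimum of the cross-validated partial-likelihood
    deviance (not the 1-SE rule). An explicit ``alphas`` grid overrides the
    automatic path (a single huge value forces full shrinkage). Returns
    ``(selected pair list, metadata)`` where metadata holds the path,
    per-lambda CV deviance, and coefficients at the chosen lambda.
    """
    surv = surv.loc[activity.columns]
    if int(surv["OS"].sum()) < n_folds:
        raise ValueError("need at least as many events as folds")
    X = standardize_rows(activity).T.to_numpy()
    y = _sksurv_y(surv)

    if alphas is None:
        base = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas,
                                      alpha_min_ratio=0.01)
    else:
        base = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(alphas))
    base.fit(X, y)
    alphas = np.asarray(base.alphas_)

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    dev = np.zeros(alphas.size)
    n_eval = np.zeros(alphas.size, dtype=int)
    for tr, te in kf.split(X):
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.fit(X[tr], y[tr])
        coefs = m.coef_  # p x (alphas the fold kept; the path may stop early)
        kept = np.asarray(m.alphas_)
        for jj, a in enumerate(kept):
            j = int(np.argmin(np.abs(alphas - a)))
            lp = X[te] @ coefs[:, jj]
            dev[j] += -2.0 * cox_partial_loglik(
                lp, surv["OS.time"].to_numpy()[te], surv["OS"].to_numpy()[te]
            )
            n_eval[j] += 1
    valid = n_eval == n_folds  # compare only alphas scored in every fold
    if not valid.any():
        raise RuntimeError("no penalty value survived all CV folds")
    dev_mean = np.where(valid, dev / np.maximum(n_eval, 1), np.inf)
    best = int(np.argmin(dev_mean))
    coef_best = base.coef_[:, best]
    selected = [p for p, c in zip(activity.index, coef_best) if c != 0]
    if not selected:
        warnings.warn("all LASSO coefficients zero at the chosen penalty")
    meta = {
        "alphas": alphas,
        "cv_deviance": dev_mean,
        "alpha_best": float(alphas[best]),
        "coefficients": pd.Series(coef_best, index=activity.index),
    }
    return selected, meta


def rsf_importance(
    activity: pd.DataFrame,
    surv: pd.DataFrame,
    n_trees: int = 5000,
    top_k: int = 10,
    seed: int | None = None,
    n_repeats: int = 5,
) -> pd.DataFrame:
    """Random-survival-forest permutation variable importance, top-k pairs.

    Importance is the drop in concordance when a feature is permuted.
    Ties are broken by pair id.
    """
    if n_trees < 50:
        raise ValueError("n_trees < 50 gives unstable importances")
    if activity.shape[0] == 0:
        raise ValueError("no candidate pairs")
    if activity.shape[0] == 1:
        # a single candidate is returned regardless of importance
        return pd.DataFrame(
            {"importance": [np.nan]}, index=activity.index.rename("pair")
        )
    surv = surv.loc[activity.columns]
    X = standardize_rows(activity).T.to_numpy()
    y = _sksurv_y(surv)
    rsf = RandomSurvivalForest(
        n_estimators=n_trees,
        min_samples_leaf=15,
        max_features="sqrt",
        n_jobs=1,
        random_state=seed,
    )
    rsf.fit(X, y)
    imp = permutation_importance(
        rsf, X, y, n_repeats=n_repeats, random_state=seed
    )
    out = pd.DataFrame(
        {"pair": activity.index, "importance": imp.importances_mean}
    ).set_index("pair")
    out["_id"] = out.index
    out = out.sort_values(["importance", "_id"], ascending=[False, True],
                          kind="mergesort").drop(columns="_id")
    return out.head(min(top_k, len(out)))


def intersect_features(lasso_set, rsf_set) -> list:
    """Intersection of the LASSO and RSF feature sets, sorted by pair id."""
    out = sorted(set(lasso_set) & set(rsf_set))
    if not out:
        warnings.warn("LASSO and RSF feature sets are disjoint")
    return out


@dataclass
class SignatureModel:
    """Multivariate Cox risk model over selected L-R pair activities."""

    pairs: list
    coefficients: pd.Series  # log-hazard per SD of activity
    means: pd.Series
    sds: pd.Series
    risk_score: pd.Series  # linear predictor per sample
    cutoff: float | None = None
    groups: pd.Series | None = None

    def score(self, activity: pd.DataFrame) -> pd.Series:
        z = activity.loc[self.pairs].sub(self.means, axis=0).div(self.sds, axis=0)
        return z.mul(self.coefficients, axis=0).sum(axis=0)


def fit_risk_model(activity: pd.DataFrame, surv: pd.DataFrame) -> SignatureModel:
    """Multivariate Cox fit on standardized activities of the final pair set.

    The risk score is the linear predictor. Raises on non-convergence
    (typically collinear features), suggesting a Pearson pre-filter.
    """
    if activity.shape[0] == 0:
        raise ValueError("final pair set is empty")
    _check_events(surv)
    surv = surv.loc[activity.columns]
    means = activity.mean(axis=1)
    sds = activity.std(axis=1, ddof=0)
    z = standardize_rows(activity)
    df = z.T.copy()
    df["T"] = surv["OS.time"].to_numpy()
    df["E"] = surv["OS"].to_numpy()
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="T", event_col="E")
    except (ConvergenceError, np.linalg.LinAlgError) as err:
        raise RuntimeError(
            "multivariate Cox did not converge; consider removing collinear "
            "features with a Pearson pre-filter"
        ) from err
    coefs = cph.params_.reindex(activity.index)
    score = z.mul(coefs, axis=0).sum(axis=0)
    return SignatureModel(
        pairs=list(activity.index),
        coefficients=coefs,
        means=means,
        sds=sds,
        risk_score=score,
    )


def stratify_by_median(model: SignatureModel) -> pd.Series:
    """Split samples at the median risk score; ties go to the low-risk group."""
    score = model.risk_score
    if len(score) < 2:
        raise ValueError("need at least 2 samples")
    if score.nunique() == 1:
        raise ValueError("all risk scores identical; stratification degenerate")
    cutoff = float(score.median())
    groups = pd.Series(
        np.where(score > cutoff, "high", "low"), index=score.index, name="group"
    )
    model.cutoff = cutoff
    model.groups = groups
    return groups


def km_logrank(groups: pd.Series, surv: pd.DataFrame):
    """Kaplan-Meier curves per group plus the two-sample log-rank test.

    Returns ``(curves dict of DataFrames, chi2, p)``.
    """
    surv = surv.loc[groups.index]
    labels = groups.unique()
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    curves = {}
    for lab in labels:
        sub = surv[groups == lab]
        if sub.empty:
            raise ValueError(f"group {lab} is empty")
        if sub["OS"].sum() == 0:
            warnings.warn(f"group {lab} has zero events")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["OS.time"], sub["OS"], label=str(lab))
        curves[lab] = kmf.survival_function_
    a, b = labels
    res = logrank_test(
        surv.loc[groups == a, "OS.time"],
        surv.loc[groups == b, "OS.time"],
        event_observed_A=surv.loc[groups == a, "OS"],
        event_observed_B=surv.loc[groups == b, "OS"],
    )
    return curves, float(res.test_statistic), float(res.p_value)


def _cox_table(cph: CoxPHFitter) -> pd.DataFrame:
    s = cph.summary
    return pd.DataFrame(
        {
            "HR": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )


def covariate_adjusted_cox(
    risk_score: pd.Series,
    surv: pd.DataFrame,
    per_sd: bool = True,
):
    """Uni- and multivariate Cox fits of the risk score with age and gender.

    With ``per_sd`` (default) the risk score is standardized so its hazard
    ratio is per standard deviation. Returns ``(univariate, multivariate)``
    tables of HR, 95% CI, and p per term.
    """
    surv = surv.loc[risk_score.index]
    rs = risk_score.astype(float)
    if per_sd:
        rs = (rs - rs.mean()) / rs.std(ddof=0)
    base = pd.DataFrame(
        {"risk_score": rs, "T": surv["OS.time"], "E": surv["OS"]}
    )
    cph_u = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph_u.fit(base, duration_col="T", event_col="E")
    uni = _cox_table(cph_u)

    multi_df = base.copy()
    multi_df["age"] = surv["age"].astype(float)
    gender = surv["gender"]
    if gender.nunique() > 1:
        multi_df["gender_male"] = (gender == "male").astype(float)
    else:
        warnings.warn("gender has a single level; dropped from the model")
    cph_m = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph_m.fit(multi_df, duration_col="T", event_col="E")
    return uni, _cox_table(cph_m)


def compare_mutation_frequency(
    mutations: pd.DataFrame,
    groups: pd.Series,
    min_mutated: int = 3,
) -> pd.DataFrame:
    """Per-gene Fisher exact test of mutation frequency between risk groups.

    Genes mutated in fewer than ``min_mutated`` samples are excluded.
    Returns odds ratio (high vs low), p, and BH q per gene.
    """
    if mutations.empty:
        return pd.DataFrame(columns=["odds_ratio", "p", "q"])
    unknown = set(mutations["sample"]) - set(groups.index)
    if unknown:
        raise ValueError(f"mutated sample without group label: {sorted(unknown)[0]}")
    n_high = int((groups == "high").sum())
    n_low = int((groups == "low").sum())
    rows = []
    for gene, sub in mutations.groupby("gene"):
        carriers = set(sub["sample"])
        if len(carriers) < min_mutated:
            continue
        mut_high = sum(groups[s] == "high" for s in carriers)
        mut_low = len(carriers) - mut_high
        table = [[mut_high, n_high - mut_high], [mut_low, n_low - mut_low]]
        odds, p = fisher_exact(table)
        rows.append((gene, odds, p))
    out = pd.DataFrame(rows, columns=["gene", "odds_ratio", "p"]).set_index("gene")
    out["q"] = bh_adjust(out["p"])
    return out
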