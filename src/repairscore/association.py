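"""Score-disease association: adjusted odds ratios and ANCOVA-adjusted means.

Two logistic model forms quantify the association of the repair score with
case status, both adjusted for age, sex, and smoking:

* ``per_sd_decrease`` — the score standardized by the CONTROL-group SD and
  negated, so the reported OR is the odds multiplier per 1-SD DECREASE in
  repair capacity (the direction of increased risk);
* ``tertile`` — indicator terms for the middle and lowest control-derived
  tertiles, with the highest tertile as the referent.

Adjusted group means come from an analysis of covariance: an OLS fit of the
score on the grouping factor plus the adjusters, summarized as
population-averaged least-squares means (predictions averaged over the
whole sample's covariate distribution). Confidence intervals are Wald
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._design import adjuster_design, case_indicator
from ._logistic import LogisticResult, logistic_fit
from .scoring import ScoreStrata, stratify_scores

__all__ = ["LogisticFit", "AdjustedMeans", "fit_adjusted_logistic", "adjusted_group_means"]


@dataclass
class LogisticFit:
    """Adjusted logistic fit with an odds-ratio table.

    ``table`` columns: term, coef, se, or_, ci_low, ci_high, p. ORs are
    ``exp(coef)`` with Wald 95% CIs.
    """

    form: str
    table: pd.DataFrame
    result: LogisticResult
    control_sd: float | None = None

    def odds_ratio(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "or_"])

    def linear_predictor(self, X: np.ndarray | None = None) -> np.ndarray:
        if X is None:
            X = self._X
        return self.result.linear_predictor(X)


@dataclass
class AdjustedMeans:
    """Population-averaged least-squares means per group level."""

    grouping: str
    table: pd.DataFrame  # level, n, mean, se, ci_low, ci_high
    comparisons: pd.DataFrame  # level_a, level_b, estimate, se, p
    trend_p: float | None = None


def _or_table(res: LogisticResult) -> pd.DataFrame:
    se = res.bse
    z = res.params / se
    p = 2 * stats.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):  # quasi-separated dummies overflow to inf
        lo = np.exp(res.params - 1.959963984540054 * se)
        hi = np.exp(res.params + 1.959963984540054 * se)
    return pd.DataFrame(
        {
            "term": res.names,
            "coef": res.params,
            "se": se,
            "or_": np.exp(res.params),
            "ci_low": lo,
            "ci_high": hi,
            "p": p,
        }
    )


def fit_adjusted_logistic(
    cohort: pd.DataFrame,
    scores: pd.Series,
    strata: ScoreStrata | None = None,
    form: str = "per_sd_decrease",
    *,
    adjusted: bool = True,
    exclude_never_smokers: bool = False,
) -> LogisticFit:
    """Fit case status on the score (continuous or tertile), adjusted.

    ``adjusted=False`` drops the age/sex/smoking terms (crude model);
    ``exclude_never_smokers=True`` reproduces the ever-smoker sensitivity
    analysis (the smoking design then keeps only the current-vs-past
    indicator).
    """
    if form not in ("per_sd_decrease", "tertile"):
        raise ValueError(f"unknown form {form!r}")
    df = cohort.reset_index(drop=True)
    s = np.asarray(scores, dtype=float)
    if s.shape[0] != len(df):
        raise ValueError("scores are not aligned to the cohort")
    if strata is None:
        strata = stratify_scores(pd.Series(s, index=df.index), df)
    if exclude_never_smokers:
        keep = (df["smoking"] != "never").to_numpy()
        df = df.loc[keep].reset_index(drop=True)
        s = s[keep]
        labels = np.asarray(strata.labels)[keep]
    else:
        labels = np.asarray(strata.labels)

    y = case_indicator(df)
    if form == "per_sd_decrease":
        cols = [-(s / strata.control_sd)]
        names = ["score_per_sd_decrease"]
    else:
        for lab in ("lowest", "middle", "highest"):
            if not np.any(labels == lab):
                raise ValueError(f"empty tertile cell: no subjects in '{lab}' tertile")
        cols = [
            (labels == "middle").astype(float),
            (labels == "lowest").astype(float),
        ]
        names = ["tertile_middle", "tertile_lowest"]
    if adjusted:
        adj, adj_names = adjuster_design(df)
        if exclude_never_smokers:
            # past-smoker column is redundant with the intercept restricted
            # to ever-smokers; keep current-vs-past only
            keep_cols = [i for i, n in enumerate(adj_names) if n != "smoking_past"]
            adj = adj[:, keep_cols]
            adj_names = [adj_names[i] for i in keep_cols]
        cols.append(adj)
        names += adj_names
    X = np.column_stack(cols)
    res = logistic_fit(X, y, names=names)
    fit = LogisticFit(form=form, table=_or_table(res), result=res, control_sd=strata.control_sd)
    fit._X = X
    return fit


def _level_design(df, scores, grouping, adjusters, subset):
    if subset is not None:
        df = df.loc[subset].reset_index(drop=True)
        scores = np.asarray(scores)[np.asarray(subset)]
    s = np.asarray(scores, dtype=float)
    levels = [lv for lv in pd.unique(df[grouping]) if not pd.isna(lv)]
    if df[grouping].isna().any():
        keep = df[grouping].notna().to_numpy()
        df = df.loc[keep].reset_index(drop=True)
        s = s[keep]
    return df, s, levels


def adjusted_group_means(
    scores,
    cohort: pd.DataFrame,
    grouping: str,
    adjusters: tuple[str, ...] = ("age", "sex", "smoking"),
    *,
    subset=None,
    level_order: list | None = None,
) -> AdjustedMeans:
    """ANCOVA-adjusted mean score per level of ``grouping``.

    Fits ``score ~ C(grouping) + adjusters`` by OLS and reports, per level,
    the average model prediction over the WHOLE sample with the grouping set
    to that level (population-averaged least-squares means), with Wald CIs
    using the residual t distribution. ``comparisons`` holds all pairwise
    level contrasts; ``trend_p`` a linear contrast over ``level_order``
    (or the observed level order) for ordered factors such as stage.
    """
    import statsmodels.api as sm

    df, s, levels = _level_design(cohort, scores, grouping, adjusters, subset)
    if level_order is not None:
        levels = [lv for lv in level_order if lv in levels]
    if len(levels) < 1:
        raise ValueError("grouping has no non-missing levels")

    # grouping dummies (first level reference) + adjuster columns
    g = df[grouping].to_numpy()
    gd = np.column_stack([(g == lv).astype(float) for lv in levels[1:]]) if len(levels) > 1 else np.empty((len(df), 0))
    g_names = [f"{grouping}[{lv}]" for lv in levels[1:]]
    acols, anames = [], []
    for a in adjusters:
        if a == "sex":
            acols.append((df["sex"] == "male").to_numpy(dtype=float)[:, None])
            anames += ["sex_male"]
        elif a == "smoking":
            acols.append(
                np.column_stack(
                    [
                        (df["smoking"] == "past").to_numpy(dtype=float),
                        (df["smoking"] == "current").to_numpy(dtype=float),
                    ]
                )
            )
            anames += ["smoking_past", "smoking_current"]
        elif a == "case_status":
            acols.append((df["case_status"] == "case").to_numpy(dtype=float)[:, None])
            anames += ["case"]
        else:
            acols.append(df[a].to_numpy(dtype=float)[:, None])
            anames += [a]
    A = np.hstack(acols) if acols else np.empty((len(df), 0))
    core = np.column_stack([np.ones(len(df)), gd]) if gd.size else np.ones((len(df), 1))
    core_rank = np.linalg.matrix_rank(core)
    if core_rank < core.shape[1]:
        raise ValueError(
            f"rank-deficient ANCOVA design: grouping '{grouping}' dummies "
            f"{g_names} are collinear"
        )
    # adjusters confounded with the grouping (or redundant within a subset,
    # e.g. smoking dummies among all-ever-smoker cases) are dropped; an
    # adjuster that absorbs the grouping itself is an error
    X = core
    names = ["intercept"] + g_names
    kept_rank = core_rank
    dropped = []
    for j, aname in enumerate(anames):
        cand = np.column_stack([X, A[:, j]])
        r = np.linalg.matrix_rank(cand)
        if r > kept_rank:
            X, kept_rank, names = cand, r, names + [aname]
        else:
            dropped.append(aname)
    if dropped:
        span_check = np.column_stack([np.ones(len(df)), A])
        if gd.size and np.linalg.matrix_rank(span_check) >= np.linalg.matrix_rank(
            np.column_stack([span_check, gd])
        ):
            raise ValueError(
                f"rank-deficient ANCOVA design: grouping '{grouping}' is "
                f"confounded with adjuster column(s) {dropped}"
            )
    ols = sm.OLS(s, X).fit()
    V = np.asarray(ols.cov_params())
    dfree = ols.df_resid
    tcrit = stats.t.ppf(0.975, dfree)

    # population-averaged design vector for each level: grouping dummies set
    # to the level, adjusters averaged over the whole analysis sample
    gvecs = {}
    for lv in levels:
        Xl = X.copy()
        for j, other in enumerate(levels[1:], start=1):
            Xl[:, j] = 1.0 if other == lv else 0.0
        gvecs[lv] = Xl.mean(axis=0)

    rows = []
    for lv in levels:
        gv = gvecs[lv]
        m = float(gv @ ols.params)
        se = float(np.sqrt(gv @ V @ gv))
        rows.append(
            {
                "level": lv,
                "n": int((g == lv).sum()),
                "mean": m,
                "se": se,
                "ci_low": m - tcrit * se,
                "ci_high": m + tcrit * se,
            }
        )
    table = pd.DataFrame(rows)

    comps = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            c = gvecs[levels[i]] - gvecs[levels[j]]
            est = float(c @ ols.params)
            se = float(np.sqrt(c @ V @ c))
            t = est / se if se > 0 else 0.0
            comps.append(
                {
                    "level_a": levels[i],
                    "level_b": levels[j],
                    "estimate": est,
                    "se": se,
                    "p": float(2 * stats.t.sf(abs(t), dfree)),
                }
            )
    comparisons = pd.DataFrame(comps)

    trend_p = None
    if len(levels) > 2:
        w = np.arange(len(levels), dtype=float)
        w -= w.mean()
        c = np.sum([wi * gvecs[lv] for wi, lv in zip(w, levels)], axis=0)
        est = float(c @ ols.params)
        se = float(np.sqrt(c @ V @ c))
        if se > 0:
            trend_p = float(2 * stats.t.sf(abs(est / se), dfree))
    return AdjustedMeans(grouping=grouping, table=table, comparisons=comparisons, trend_p=trend_p)
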