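"""Optimism-corrected evaluation: LOOCV scores, ROC/AUC, BCa bootstrap.

Deriving the score weights and judging their discrimination on the same
subjects overstates performance. Leave-one-out cross-validation removes
that optimism: each subject's score (or combined linear predictor) is
computed from a model fit that excluded the subject. AUC is the
tie-corrected Mann-Whitney concordance probability — identical to the
trapezoidal area under the empirical ROC curve — and its confidence
interval comes from a stratified nonparametric bootstrap with
bias-correction and acceleration (BCa). Marker convention everywhere:
HIGHER marker value = more case-like (pass the negated repair score).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from ._design import adjuster_design, case_indicator
from ._logistic import SeparationError, logistic_fit
from .scoring import ENZYMES, compute_scores, fit_score_model, stratify_scores

__all__ = [
    "CVScoreSet",
    "RocCurve",
    "AucInference",
    "auc_mann_whitney",
    "roc_analysis",
    "loocv_scores",
    "loocv_linear_predictors",
    "bootstrap_auc_inference",
]


def auc_mann_whitney(marker, labels) -> float:
    """Tie-corrected concordance AUC: P(case > control) + 0.5*P(tie)."""
    marker = np.asarray(marker, dtype=float)
    y = np.asarray(labels, dtype=float)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required to compute AUC")
    r = stats.rankdata(marker)
    u = r[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class RocCurve:
    """Empirical ROC curve over all observed thresholds.

    ``points`` columns: threshold, sensitivity, specificity (threshold rule:
    predict case when marker >= threshold). ``auc`` is the concordance AUC;
    ``auc_trapezoid`` the trapezoidal integral of the curve — the two are
    computed independently and verified to agree to 1e-12.
    """

    points: pd.DataFrame
    auc: float
    auc_trapezoid: float
    marker_kind: str = "marker"
    cv: bool = False
    sensitivity_at: dict = field(default_factory=dict)

    def sensitivity_at_specificity(self, s: float) -> float:
        """Max sensitivity among thresholds achieving specificity >= s."""
        ok = self.points["specificity"] >= s
        if not ok.any():
            return 0.0
        return float(self.points.loc[ok, "sensitivity"].max())


def roc_analysis(
    marker,
    labels,
    target_specificities: tuple[float, ...] = (0.90, 0.95),
    *,
    marker_kind: str = "marker",
    cv: bool = False,
) -> RocCurve:
    """Build the empirical ROC curve and its AUC for a case-positive marker."""
    marker = np.asarray(marker, dtype=float)
    y = np.asarray(labels, dtype=float)
    auc = auc_mann_whitney(marker, y)
    case = marker[y == 1]
    ctrl = marker[y == 0]
    thresholds = np.unique(marker)[::-1]  # descending: strictest first
    sens = [0.0]
    spec = [1.0]
    rows = []
    for t in thresholds:
        se = float(np.mean(case >= t))
        sp = float(np.mean(ctrl < t))
        rows.append({"threshold": t, "sensitivity": se, "specificity": sp})
        sens.append(se)
        spec.append(sp)
    points = pd.DataFrame(rows)
    fpr = 1.0 - np.asarray(spec)
    tpr = np.asarray(sens)
    auc_trap = float(np.trapezoid(tpr, fpr))
    if abs(auc_trap - auc) > 1e-12:
        raise AssertionError(
            f"internal ROC inconsistency: concordance {auc} vs trapezoid {auc_trap}"
        )
    curve = RocCurve(points=points, auc=auc, auc_trapezoid=auc_trap,
                     marker_kind=marker_kind, cv=cv)
    curve.sensitivity_at = {s: curve.sensitivity_at_specificity(s) for s in target_specificities}
    return curve


@dataclass
class CVScoreSet:
    """Leave-one-out cross-validated scores and control-derived summaries."""

    scores: pd.Series
    converged: pd.Series
    control_sd: float
    lower_cut: float
    upper_cut: float


def loocv_scores(cohort: pd.DataFrame, *, warm_start: bool = True) -> CVScoreSet:
    """Re-derive each subject's score from a fit excluding that subject.

    For subject i the enzyme weights are re-estimated on the cohort minus i
    and i's score computed from those weights, so no subject's outcome
    informs their own score. CV tertile cutpoints and the CV control SD are
    recomputed from the CV control scores. Refits that hit separation are
    flagged non-converged, given a NaN score, and excluded from summaries.
    """
    df = cohort.reset_index(drop=True)
    full = fit_score_model(df)
    start = full.fit.params if warm_start else None
    n = len(df)
    out = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    y = case_indicator(df)
    adj, adj_names = adjuster_design(df)
    E = df[list(ENZYMES)].to_numpy(dtype=float)
    X = np.column_stack([E, adj])
    names = list(ENZYMES) + adj_names
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        try:
            res = logistic_fit(X[keep], y[keep], names=names, start=start)
        except SeparationError as exc:
            warnings.warn(f"LOOCV refit for subject {df['id'].iloc[i] if 'id' in df else i} "
                          f"separated and was excluded: {exc}")
            continue
        # same control-high orientation as fit_score_model: negated coefficients
        w = -np.array([res.coef(e) for e in ENZYMES])
        out[i] = float(E[i] @ w)
        ok[i] = True
    ids = df["id"] if "id" in df.columns else df.index
    scores = pd.Series(out, index=pd.Index(ids, name="id"), name="cv_score")
    conv = pd.Series(ok, index=scores.index, name="converged")
    ctrl = scores[( df["case_status"] == "control").to_numpy() & ok]
    if len(ctrl) < 3:
        raise ValueError("fewer than 3 converged control refits; CV summaries undefined")
    lower, upper = np.quantile(ctrl, [1 / 3, 2 / 3])
    return CVScoreSet(
        scores=scores,
        converged=conv,
        control_sd=float(np.std(ctrl, ddof=1)),
        lower_cut=float(lower),
        upper_cut=float(upper),
    )


def loocv_linear_predictors(cohort: pd.DataFrame, scores=None, *, warm_start: bool = True) -> np.ndarray:
    """Leave-one-out linear predictor of the adjusted score+covariates model.

    The combined-marker analogue of :func:`loocv_scores`: for each subject,
    the logistic model case ~ score + age + sex + smoking is refit without
    that subject and the subject's linear predictor evaluated under that
    refit. ``scores`` defaults to the reference-weight scores of the cohort.
    """
    df = cohort.reset_index(drop=True)
    if scores is None:
        scores = compute_scores(df)
    s = np.asarray(scores, dtype=float)
    y = case_indicator(df)
    adj, adj_names = adjuster_design(df)
    X = np.column_stack([s, adj])
    names = ["score"] + adj_names
    full = logistic_fit(X, y, names=names)
    start = full.params if warm_start else None
    n = len(df)
    lp = np.full(n, np.nan)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        try:
            res = logistic_fit(X[keep], y[keep], names=names, start=start)
        except SeparationError:
            continue
        lp[i] = float(res.params[0] + X[i] @ res.params[1:])
    return lp


@dataclass
class AucInference:
    """BCa bootstrap inference for an AUC (optionally a paired comparison)."""

    auc: float
    ci_low: float
    ci_high: float
    B: int
    seed: int
    n_redraws: int = 0
    delta_auc: float | None = None
    p_percentile: float | None = None
    p_normal: float | None = None


def _stratified_indices(rng, case_idx, ctrl_idx):
    return np.concatenate(
        [
            rng.choice(ctrl_idx, size=ctrl_idx.size, replace=True),
            rng.choice(case_idx, size=case_idx.size, replace=True),
        ]
    )


def _bca_interval(theta_hat, boots, jack, alpha=0.05):
    boots = np.asarray(boots, dtype=float)
    if np.allclose(boots, theta_hat, atol=1e-15) or boots.std() == 0:
        return float(theta_hat), float(theta_hat)
    prop = np.mean(boots < theta_hat) + 0.5 * np.mean(boots == theta_hat)
    prop = min(max(prop, 1.0 / (boots.size + 1)), 1 - 1.0 / (boots.size + 1))
    z0 = ndtri(prop)
    jm = jack.mean()
    d = jm - jack
    denom = np.sum(d**2) ** 1.5
    a = float(np.sum(d**3) / (6.0 * denom)) if denom > 0 else 0.0
    zlo, zhi = ndtri(alpha / 2), ndtri(1 - alpha / 2)
    alo = stats.norm.cdf(z0 + (z0 + zlo) / (1 - a * (z0 + zlo)))
    ahi = stats.norm.cdf(z0 + (z0 + zhi) / (1 - a * (z0 + zhi)))
    lo, hi = np.quantile(boots, [alo, ahi])
    return float(lo), float(hi)


def bootstrap_auc_inference(
    marker_builder,
    cohort: pd.DataFrame,
    B: int = 2000,
    seed: int = 0,
    second_marker_builder=None,
) -> AucInference:
    """Stratified nonparametric bootstrap BCa CI for an AUC.

    ``marker_builder(cohort) -> (marker, labels)`` must be a deterministic
    procedure; any model fitting it performs therefore happens inside every
    bootstrap replicate. Resampling is with replacement within cases and
    within controls (preserving the case:control ratio). With a second
    builder, the SAME resamples feed both markers and the paired AUC
    difference is returned with a doubled-percentile p-value (capped at 1)
    plus a normal-approximation p for comparison.
    """
    if B < 200:
        raise ValueError("B must be >= 200")
    df = cohort.reset_index(drop=True)
    m1, y = marker_builder(df)
    theta = auc_mann_whitney(m1, y)
    theta2 = d_hat = None
    if second_marker_builder is not None:
        m2, y2 = second_marker_builder(df)
        if not np.array_equal(np.asarray(y), np.asarray(y2)):
            raise ValueError("both markers must be built on the same subjects")
        theta2 = auc_mann_whitney(m2, y)
        d_hat = theta - theta2

    y = np.asarray(y, dtype=float)
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    rng = np.random.default_rng(seed)
    boots = np.empty(B)
    boots_d = np.empty(B) if second_marker_builder is not None else None
    redraws = 0
    for b in range(B):
        for _ in range(11):
            ind = _stratified_indices(rng, case_idx, ctrl_idx)
            rb = df.iloc[ind].reset_index(drop=True)
            mb, yb = marker_builder(rb)
            yb = np.asarray(yb, dtype=float)
            if 0 < yb.sum() < yb.size:
                break
            redraws += 1
            if redraws > 10 * B:
                raise RuntimeError("too many single-class bootstrap redraws")
        boots[b] = auc_mann_whitney(mb, yb)
        if boots_d is not None:
            m2b, _ = second_marker_builder(rb)
            boots_d[b] = boots[b] - auc_mann_whitney(m2b, yb)

    # jackknife (leave one subject out) for the acceleration constant
    n = len(df)
    jack = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        sub = df.iloc[idx != i].reset_index(drop=True)
        mj, yj = marker_builder(sub)
        jack[i] = auc_mann_whitney(mj, yj)
    lo, hi = _bca_interval(theta, boots, jack)
    lo = float(np.clip(lo, 0.0, 1.0))
    hi = float(np.clip(hi, 0.0, 1.0))

    out = AucInference(auc=theta, ci_low=lo, ci_high=hi, B=B, seed=seed, n_redraws=redraws)
    if boots_d is not None:
        out.delta_auc = d_hat
        p_lo = float(np.mean(boots_d <= 0.0))
        p_hi = float(np.mean(boots_d >= 0.0))
        out.p_percentile = float(min(1.0, 2.0 * min(p_lo, p_hi)))
        sd = boots_d.std(ddof=1)
        out.p_normal = float(2 * stats.norm.sf(abs(d_hat) / sd)) if sd > 0 else 1.0
    return out
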