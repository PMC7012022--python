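"""Deriving and applying the composite DNA-repair score.

The score is the linear combination of three base-excision-repair enzyme
activities whose weights are the enzyme coefficients of an unconditional
logistic regression of case status on the activities, adjusted for age, sex,
and smoking status. The published reference weights are

    score = 0.00621*APE1 - 0.047*OGG1 - 0.0223*MPG

with higher score meaning more repair capacity. Subjects are stratified into
tertiles of the CONTROL score distribution; a score exactly at a cutpoint is
assigned to the lower category, matching the published "<= lower cut" /
">= upper cut" tertile boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._design import adjuster_design, case_indicator
from ._logistic import LogisticResult, SeparationError, logistic_fit
from .cohort import REFERENCE_WEIGHTS

__all__ = [
    "ScoreModel",
    "ScoreStrata",
    "MissingActivityError",
    "fit_score_model",
    "compute_scores",
    "stratify_scores",
    "REFERENCE_WEIGHTS",
]

ENZYMES = ("ape1", "ogg1", "mpg")
TERTILE_LABELS = ("lowest", "middle", "highest")


class MissingActivityError(ValueError):
    """One or more subjects lack an enzyme activity needed for the score."""

    def __init__(self, records):
        self.records = records  # list of (id, missing columns)
        super().__init__(
            f"{len(records)} subject(s) with missing enzyme activities: "
            + "; ".join(f"{sid}: {cols}" for sid, cols in records[:10])
        )


@dataclass
class ScoreModel:
    """Enzyme score weights plus the adjusting coefficients of the derivation fit."""

    w_ape1: float
    w_ogg1: float
    w_mpg: float
    intercept: float
    adjust_coefs: dict
    converged: bool
    llf: float
    fit: LogisticResult | None = None

    @property
    def weights(self) -> dict:
        return {"ape1": self.w_ape1, "ogg1": self.w_ogg1, "mpg": self.w_mpg}


@dataclass
class ScoreStrata:
    """Control-derived tertile cutpoints, control SD, and per-subject labels."""

    lower_cut: float
    upper_cut: float
    control_sd: float
    labels: pd.Series  # categorical, aligned to subject ids


def fit_score_model(cohort: pd.DataFrame) -> ScoreModel:
    """Derive score weights by logistic regression of case status.

    Covariates are the three enzyme activities plus age, sex, and two
    smoking indicators. The score weights are the enzyme coefficients
    oriented so that a HIGHER score means LOWER disease odds (more repair),
    matching the published score's direction — i.e. the negated
    case-logistic coefficients; the raw fit is kept in ``.fit``. The fit is
    deterministic given the data. Raises
    :class:`repairscore.SeparationError` when the activities separate the
    outcome perfectly (the MLE then diverges).
    """
    _check_activities(cohort)
    y = case_indicator(cohort)
    if y.min() == y.max():
        raise ValueError("cohort must contain both cases and controls")
    adj, adj_names = adjuster_design(cohort)
    X = np.column_stack([cohort[list(ENZYMES)].to_numpy(dtype=float), adj])
    res = logistic_fit(X, y, names=list(ENZYMES) + adj_names)
    return ScoreModel(
        w_ape1=-res.coef("ape1"),
        w_ogg1=-res.coef("ogg1"),
        w_mpg=-res.coef("mpg"),
        intercept=res.coef("intercept"),
        adjust_coefs={n: res.coef(n) for n in adj_names},
        converged=res.converged,
        llf=res.llf,
        fit=res,
    )


def _check_activities(cohort: pd.DataFrame) -> None:
    missing = []
    sub = cohort[list(ENZYMES)]
    bad = sub.isna().any(axis=1)
    if bad.any():
        for idx in cohort.index[bad]:
            cols = [c for c in ENZYMES if pd.isna(cohort.at[idx, c])]
            sid = cohort.at[idx, "id"] if "id" in cohort.columns else str(idx)
            missing.append((sid, cols))
        raise MissingActivityError(missing)


def compute_scores(cohort: pd.DataFrame, model_or_weights=None) -> pd.Series:
    """Compute per-subject scores ``w_ape1*APE1 + w_ogg1*OGG1 + w_mpg*MPG``.

    ``model_or_weights`` may be a :class:`ScoreModel`, a mapping with keys
    ``ape1/ogg1/mpg``, or None for the published reference weights. The
    adjusting covariates and intercept of the derivation fit are NOT part
    of the score. Subjects with missing activities raise
    :class:`MissingActivityError` carrying per-subject records.
    """
    if model_or_weights is None:
        w = REFERENCE_WEIGHTS
    elif isinstance(model_or_weights, ScoreModel):
        w = model_or_weights.weights
    else:
        w = dict(model_or_weights)
    for k in ENZYMES:
        if k not in w or not np.isfinite(w[k]):
            raise ValueError(f"weight for '{k}' missing or non-finite")
    _check_activities(cohort)
    vals = (
        w["ape1"] * cohort["ape1"].to_numpy(dtype=float)
        + w["ogg1"] * cohort["ogg1"].to_numpy(dtype=float)
        + w["mpg"] * cohort["mpg"].to_numpy(dtype=float)
    )
    index = cohort["id"] if "id" in cohort.columns else cohort.index
    return pd.Series(vals, index=pd.Index(index, name="id"), name="score")


def stratify_scores(scores: pd.Series, cohort: pd.DataFrame) -> ScoreStrata:
    """Label every subject by tertiles of the control score distribution.

    Cutpoints are the 1/3 and 2/3 empirical quantiles of the CONTROL scores
    (linear order-statistic interpolation, numpy's default); ``control_sd``
    is the n-1 sample SD of control scores. Scores at or below the lower
    cut are "lowest", at or above the upper cut "highest", otherwise
    "middle" — boundary values go to the lower category.
    """
    is_control = (cohort["case_status"] == "control").to_numpy()
    ctrl = np.asarray(scores)[is_control]
    if ctrl.size < 3:
        raise ValueError(f"need >=3 controls to form tertiles, got {ctrl.size}")
    sd = float(np.std(ctrl, ddof=1))
    if sd == 0.0:
        raise ValueError("control scores have zero variance; tertiles undefined")
    lower, upper = np.quantile(ctrl, [1 / 3, 2 / 3])
    vals = np.asarray(scores, dtype=float)
    labels = np.where(vals <= lower, "lowest", np.where(vals >= upper, "highest", "middle"))
    lab = pd.Series(
        pd.Categorical(labels, categories=list(TERTILE_LABELS)),
        index=scores.index,
        name="tertile",
    )
    return ScoreStrata(lower_cut=float(lower), upper_cut=float(upper), control_sd=sd, labels=lab)
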