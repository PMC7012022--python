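"""Absolute-risk updating with a score likelihood ratio.

An externally supplied baseline absolute risk (for example a Liverpool Lung
Project 5-year risk) is updated with the likelihood ratio of the subject's
score falling in a control-percentile region:

    LR = P(score in region | case) / P(score in region | control)
    posterior odds = prior odds * LR

The score distributions come either from a binormal model (group means and
SDs) or from empirical score vectors. This is the naive MARGINAL likelihood
ratio: it conditions on nothing besides case status. A covariate-conditional
variant is obtained by passing residual scores (score minus its
covariate-model prediction) in empirical mode. The baseline risk model
itself is an input and is never reimplemented here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["ScoreDistributionPair", "Region", "likelihood_ratio_for_region", "update_risk", "RiskUpdateResult"]


@dataclass
class ScoreDistributionPair:
    """Control/case score distributions: binormal parameters or raw vectors."""

    control_mean: float | None = None
    control_sd: float | None = None
    case_mean: float | None = None
    case_sd: float | None = None
    control_scores: np.ndarray | None = None
    case_scores: np.ndarray | None = None

    @property
    def mode(self) -> str:
        return "empirical" if self.control_scores is not None else "binormal"

    def validate(self) -> None:
        if self.mode == "binormal":
            if None in (self.control_mean, self.control_sd, self.case_mean, self.case_sd):
                raise ValueError("binormal mode needs means and SDs for both groups")
            if self.control_sd <= 0 or self.case_sd <= 0:
                raise ValueError("SDs must be positive")
        else:
            if self.case_scores is None:
                raise ValueError("empirical mode needs both score vectors")
            if len(self.control_scores) < 20 or len(self.case_scores) < 20:
                raise ValueError("empirical mode needs >=20 scores per group")


@dataclass
class Region:
    """Control-percentile score region: at-or-below / at-or-above a percentile."""

    kind: str  # "le" or "ge"
    percentile: float  # of the CONTROL distribution, in [0, 100]

    @classmethod
    def parse(cls, text: str) -> "Region":
        m = re.fullmatch(r"(le|ge):(\d+(?:\.\d+)?)", text.strip())
        if not m:
            raise ValueError(f"cannot parse region {text!r}; expected 'le:5' or 'ge:75'")
        return cls(kind=m.group(1), percentile=float(m.group(2)))

    def validate(self) -> None:
        if self.kind not in ("le", "ge"):
            raise ValueError(f"unknown region kind {self.kind!r}")
        if not 0.0 <= self.percentile <= 100.0:
            raise ValueError("percentile must be in [0, 100]")


@dataclass
class RiskUpdateResult:
    prior: float
    region: str
    lr: float
    posterior: float
    mode: str = "binormal"


def likelihood_ratio_for_region(distributions: ScoreDistributionPair, region: Region | str) -> float:
    """Tail-probability likelihood ratio for a control-percentile region."""
    if isinstance(region, str):
        region = Region.parse(region)
    region.validate()
    distributions.validate()
    q = region.percentile / 100.0
    if distributions.mode == "binormal":
        thr = norm.ppf(q, loc=distributions.control_mean, scale=distributions.control_sd)
        if region.kind == "le":
            p_ctrl = q
            p_case = norm.cdf(thr, loc=distributions.case_mean, scale=distributions.case_sd)
        else:
            p_ctrl = 1.0 - q
            p_case = norm.sf(thr, loc=distributions.case_mean, scale=distributions.case_sd)
    else:
        ctrl = np.asarray(distributions.control_scores, dtype=float)
        case = np.asarray(distributions.case_scores, dtype=float)
        thr = np.quantile(ctrl, q)
        if region.kind == "le":
            p_ctrl = float(np.mean(ctrl <= thr))
            p_case = float(np.mean(case <= thr))
        else:
            p_ctrl = float(np.mean(ctrl >= thr))
            p_case = float(np.mean(case >= thr))
    if p_ctrl <= 0.0:
        raise ValueError(f"region has zero control probability (percentile {region.percentile})")
    return float(p_case / p_ctrl)


def update_risk(prior_risk: float, lr: float, *, region: str = "", mode: str = "binormal") -> RiskUpdateResult:
    """Bayes odds update: posterior = prior*LR / (1 - prior + prior*LR)."""
    if not 0.0 < prior_risk < 1.0:
        raise ValueError("prior risk must be strictly between 0 and 1")
    if lr <= 0.0:
        raise ValueError("likelihood ratio must be positive")
    post = prior_risk * lr / (1.0 - prior_risk + prior_risk * lr)
    return RiskUpdateResult(prior=prior_risk, region=region, lr=lr, posterior=float(post), mode=mode)
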