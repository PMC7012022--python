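"""Shared covariate-coding conventions.

Sex is coded with a single male indicator (female reference); smoking with
two indicators, past-vs-never and current-vs-never; case status as a 0/1
case indicator. Every model in the package uses these codings so that
coefficients are comparable across modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SEX_LEVELS = ("female", "male")
SMOKING_LEVELS = ("never", "past", "current")
CASE_LEVELS = ("control", "case")
STAGE_LEVELS = ("IA", "IB", "II", "III", "IV")


def case_indicator(df: pd.DataFrame) -> np.ndarray:
    bad = set(df["case_status"].unique()) - set(CASE_LEVELS)
    if bad:
        raise ValueError(f"unknown case_status levels: {sorted(bad)}")
    return (df["case_status"] == "case").to_numpy(dtype=float)


def adjuster_design(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Design columns for the standard adjusters: age, sex, smoking."""
    bad = set(df["sex"].unique()) - set(SEX_LEVELS)
    if bad:
        raise ValueError(f"unknown sex levels: {sorted(bad)}")
    bad = set(df["smoking"].unique()) - set(SMOKING_LEVELS)
    if bad:
        raise ValueError(f"unknown smoking levels: {sorted(bad)}")
    cols = [
        df["age"].to_numpy(dtype=float),
        (df["sex"] == "male").to_numpy(dtype=float),
        (df["smoking"] == "past").to_numpy(dtype=float),
        (df["smoking"] == "current").to_numpy(dtype=float),
    ]
    return np.column_stack(cols), ["age", "sex_male", "smoking_past", "smoking_current"]
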