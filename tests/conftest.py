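import numpy as np
import pandas as pd
import pytest

from repairscore import CohortParams, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Study-calibrated cohort: 140 controls / 149 cases, fixed seed."""
    return generate_cohort(CohortParams(), seed=42)


@pytest.fixture(scope="session")
def balanced_cohort_60():
    """Small cohort without the extreme never-smoker imbalance.

    Used where two optimizers are compared at tight tolerance: balanced
    smoking avoids quasi-separated nuisance coefficients that stop at
    optimizer-dependent magnitudes.
    """
    params = CohortParams(
        n_controls=30, n_cases=30, smoking_p_case=(0.25, 0.45, 0.30)
    )
    return generate_cohort(params, seed=7)


def make_logistic_cohort(rng, n, coefs, intercept):
    """Cohort whose case status is Bernoulli from a known logistic law.

    ``coefs`` maps column -> true coefficient over (ape1, ogg1, mpg, age,
    sex_male, smoking_past, smoking_current). Independent covariates, so
    the fitted logistic model is correctly specified.
    """
    from scipy.special import expit

    ogg1 = rng.normal(7, 1.5, n).clip(0.1)
    mpg = rng.normal(15, 3, n).clip(0.1)
    ape1 = rng.normal(800, 100, n).clip(1.0)
    age = rng.normal(60, 10, n)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    smoking = rng.choice(["never", "past", "current"], size=n, p=[1 / 3, 1 / 3, 1 / 3])
    eta = (
        intercept
        + coefs["ape1"] * ape1
        + coefs["ogg1"] * ogg1
        + coefs["mpg"] * mpg
        + coefs.get("age", 0.0) * age
        + coefs.get("sex_male", 0.0) * (sex == "male")
        + coefs.get("smoking_past", 0.0) * (smoking == "past")
        + coefs.get("smoking_current", 0.0) * (smoking == "current")
    )
    y = rng.random(n) < expit(eta)
    return pd.DataFrame(
        {
            "id": [f"S{i}" for i in range(n)],
            "case_status": np.where(y, "case", "control"),
            "ogg1": ogg1,
            "mpg": mpg,
            "ape1": ape1,
            "age": age,
            "sex": sex,
            "smoking": smoking,
        }
    )
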