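import numpy as np
import pandas as pd
import pytest

from trialpower import synth


def balanced_lme_table(
    n_subjects: int,
    visits_months,
    beta0: float = 0.0,
    beta1: float = -0.20,
    sigma_b0: float = 0.9,
    sigma_b1: float = 0.10,
    rho: float = 0.3,
    sigma_w: float = 0.30,
    seed: int = 0,
    value_col: str = "value",
) -> pd.DataFrame:
    """Complete-data random-slope cohort used across the model tests."""
    rng = np.random.default_rng(seed)
    t = np.asarray(visits_months, dtype=float) / 12.0
    cov = np.array(
        [
            [sigma_b0**2, rho * sigma_b0 * sigma_b1],
            [rho * sigma_b0 * sigma_b1, sigma_b1**2],
        ]
    )
    b = rng.multivariate_normal([0, 0], cov, size=n_subjects)
    y = (
        beta0
        + b[:, [0]]
        + (beta1 + b[:, [1]]) * t[None, :]
        + rng.normal(0, sigma_w, (n_subjects, t.size))
    )
    return pd.DataFrame(
        {
            "subject_id": np.repeat([f"S{i:04d}" for i in range(n_subjects)], t.size),
            "visit_month": np.tile(np.asarray(visits_months, dtype=float), n_subjects),
            value_col: y.ravel(),
        }
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Mid-sized synthetic cohort shared by cohort/pipeline tests."""
    return synth.generate_cohort(
        {"control": 150, "preclinical_ad": 150, "mild_ad": 200}, seed=20
    )


@pytest.fixture(scope="session")
def lme_table():
    return balanced_lme_table(300, (0, 6, 12, 24, 36, 48), seed=7)
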