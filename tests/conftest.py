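import dataclasses

import numpy as np
import pandas as pd
import pytest

from gipm import mets, synthetic_cohort as sc
from gipm.config import ScenarioConfig


@pytest.fixture(scope="session")
def smoke_scenario() -> ScenarioConfig:
    """A small, event-rich scenario for fast end-to-end checks.

    The baseline hazard is raised tenfold so that a few-thousand-participant
    cohort carries enough events for every model to be estimable.
    """
    return ScenarioConfig(
        n_participants=6_000,
        baseline_hazard=9.950301e-3,
        seed=421,
    )


@pytest.fixture(scope="session")
def smoke_cohort(smoke_scenario) -> sc.Cohort:
    return sc.simulate_cohort(smoke_scenario)


@pytest.fixture(scope="session")
def smoke_analysis_frame(smoke_cohort) -> pd.DataFrame:
    """Eligibility-filtered, imputed, classified smoke cohort."""
    df, _ = mets.apply_eligibility(smoke_cohort.phenotypes)
    df = mets.impute_covariates(df)
    return mets.classify_cohort(df)


@pytest.fixture()
def null_scenario() -> ScenarioConfig:
    """No planted effects; used for calibration checks."""
    return ScenarioConfig(
        n_participants=2_500,
        baseline_hazard=2.0e-2,
        planted_loghr={},
        seed=7,
    )


def make_survival_frame(n: int, loghr: float, seed: int,
                        censor: float = 2.0,
                        rate0: float = 0.5) -> pd.DataFrame:
    """Minimal two-arm exponential survival data (no covariates beyond the arm)."""
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n)
    t = rng.exponential(1.0 / (rate0 * np.exp(loghr * x)))
    event = t <= censor
    return pd.DataFrame(
        {
            "arm": x.astype(float),
            "time_years": np.where(event, t, censor),
            "event": event.astype(int),
            "site": np.where(event, "CRC", ""),
        }
    )
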