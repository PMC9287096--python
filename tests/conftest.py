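import numpy as np
import pandas as pd
import pytest

import deprisk as d


@pytest.fixture(scope="session")
def assign_spec():
    return d.load_packaged_spec("assign")


@pytest.fixture(scope="session")
def score2_spec():
    return d.load_packaged_spec("score2")


@pytest.fixture(scope="session")
def pce_spec():
    return d.load_packaged_spec("pce")


@pytest.fixture(scope="session")
def endpoint_specs():
    return d.load_endpoint_specs()


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n=15,000, seed 1) shared across tests."""
    return d.simulate_cohort(d.default_config())


@pytest.fixture(scope="session")
def clean_config():
    """Default generative model without missingness or extra censoring,
    for self-consistency checks needing fully scorable cohorts."""
    return d.default_config().replace(
        missingness={}, dropout_hazard=0.0, noncvd_death_rate=1e-9
    )


def random_profile(rng: np.random.Generator) -> d.CovariateProfile:
    smoker = bool(rng.random() < 0.3)
    tchol = float(rng.uniform(3.5, 8.0))
    return d.CovariateProfile(
        age=float(rng.uniform(35, 75)),
        sex="F" if rng.random() < 0.5 else "M",
        systolic_bp=float(rng.uniform(100, 180)),
        total_chol=tchol,
        hdl_chol=float(rng.uniform(0.7, min(2.5, tchol - 0.6))),
        smoker=smoker,
        cigarettes_per_day=float(rng.integers(1, 40)) if smoker else 0.0,
        diabetes=bool(rng.random() < 0.08),
        family_history_cvd=bool(rng.random() < 0.4),
        bp_treated=bool(rng.random() < 0.15),
        simd=float(rng.uniform(0.94, 89.89)),
    )
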