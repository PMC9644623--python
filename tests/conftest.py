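import numpy as np
import pandas as pd
import pytest

from lexhaz import (
    Covariate,
    ModelSpec,
    TimeScale,
    expand_tvc_rows,
    fit_fpm,
    simulate_matched_cohort,
    simulate_tvc_cohort,
)


@pytest.fixture(scope="session")
def tvc_spec():
    """Illness-death specification: log-time reference scale, gated second
    scale, linear age and treatment covariates."""
    return ModelSpec(
        scales=(
            TimeScale("t1", log=True, n_knots=4),
            TimeScale("t2", offset="r", gate="I_RM", n_knots=4),
        ),
        covariates=(Covariate("age"), Covariate("hormon")),
    )


@pytest.fixture(scope="session")
def tvc_subjects():
    return simulate_tvc_cohort(n=400, seed=7)


@pytest.fixture(scope="session")
def tvc_episodes(tvc_subjects):
    return expand_tvc_rows(tvc_subjects)


@pytest.fixture(scope="session")
def tvc_fit(tvc_episodes, tvc_spec):
    return fit_fpm(tvc_episodes, tvc_spec)


@pytest.fixture(scope="session")
def matched_spec():
    """Matched-cohort specification: attained-age reference, gated
    time-since-diagnosis, sex covariate (all scales on the natural axis,
    delayed entry)."""
    return ModelSpec(
        scales=(
            TimeScale("t1", n_knots=5),
            TimeScale("t2", offset="a0", gate="I_MPN", n_knots=5),
        ),
        covariates=(Covariate("I_sex"),),
    )


@pytest.fixture(scope="session")
def matched_episodes():
    return simulate_matched_cohort(n_cases=400, seed=19)


@pytest.fixture(scope="session")
def exp_episodes():
    """A tiny cohort with varying entry/exit for closed-form checks."""
    rng = np.random.default_rng(3)
    n = 60
    entry = rng.uniform(0.0, 0.5, n)
    exit_ = entry + rng.uniform(0.2, 4.0, n)
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "entry": entry,
            "exit": exit_,
            "event": rng.integers(0, 2, n),
        }
    )


@pytest.fixture(scope="session")
def intercept_only_spec():
    # zero knots on the reference scale: constant (exponential) hazard
    return ModelSpec(scales=(TimeScale("t", n_knots=0),))
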