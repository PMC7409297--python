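import numpy as np
import pytest

import cachexsim as cx


@pytest.fixture(scope="session")
def hp():
    """Fitted healthy feedback parameters."""
    return cx.table1_healthy_params()


@pytest.fixture(scope="session")
def bundle():
    """Fitted tumor/cachexia/treatment parameters and cohort ICs."""
    return cx.table2_bundle()


@pytest.fixture(scope="session")
def conv():
    return cx.ConversionConvention()


@pytest.fixture(scope="session")
def growth_traj(hp):
    """Healthy growth solve from the 3-week lean-deconstruction ICs."""
    return cx.healthy_growth_solve(hp, t_stop=300.0, t_step=1.0)


@pytest.fixture(scope="session")
def psi49(hp):
    return cx.day49_stem_ratio(hp)


@pytest.fixture(scope="session")
def cachexia_spec(hp, bundle):
    """Group A cachexia run spec over the 30-day observation window."""
    return cx.ExperimentSpec(
        model="cachexia",
        healthy=hp,
        cachexia=bundle["cachexia"],
        tumor=bundle["tumor"],
        initial_state=bundle["group_a_ics"],
        t_stop=30.0,
        t_step=0.5,
    )


def random_valid_healthy(rng: np.random.Generator) -> cx.HealthyParams:
    """A random parameter set satisfying p0 < 1/2 < p0+p1 <= 1."""
    p0 = rng.uniform(0.05, 0.49)
    p1 = rng.uniform(0.51 - p0 + 0.01, min(1.0 - p0, 0.9))
    return cx.HealthyParams(
        p0=p0,
        p1=p1,
        nu0=rng.uniform(0.01, 1.0),
        nu1=rng.uniform(0.1, 8.0),
        d0=rng.uniform(0.005, 0.3),
        m=rng.uniform(50.0, 5000.0),
    )
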