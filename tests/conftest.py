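import numpy as np
import pytest

from mliswd import (
    ContrastSpec,
    CorrelationSpec,
    MeanModelSpec,
    VarianceSpec,
    load_example,
    make_standard_swd,
)


@pytest.fixture(scope="session")
def example_bundle():
    """The packaged multilevel diabetes-prevention worked example."""
    return load_example("diabetes_example")


@pytest.fixture
def small_layout():
    """Tiny complete wedge: T=4, S=3, one cluster per sequence, N=2."""
    return make_standard_swd(4, 3, 1, cohort_size=2, il_split=0.5)


def random_instance(rng: np.random.Generator):
    """Random small problem over all links, for oracle comparisons."""
    # S >= 2: a single-sequence wedge cannot separate an incremental CL
    # effect from a linear time trend
    T = int(rng.integers(3, 5))
    S = int(rng.integers(2, T))
    m = [int(rng.integers(1, 3)) for _ in range(S)]
    N = int(rng.integers(2, 4))
    link = rng.choice(["identity", "log", "logit"])
    effect_model = rng.choice(["average", "incremental"])
    layout = make_standard_swd(T, S, m, cohort_size=N, il_split=0.5)
    # keep coefficients small so log/logit means stay in a safe range
    theta = tuple(np.round(rng.normal(0, 0.15, 5), 3))
    if link == "logit":
        theta = (-0.2,) + theta[1:]
    mspec = MeanModelSpec(
        effect_model=effect_model,
        time_trend="linear",
        link=link,
        theta=theta,
        scaling=(2.0, 2.0, 2.0),
        n_periods=T,
    )
    cspec = CorrelationSpec("block_exchangeable", alpha=(0.06, 0.02, 0.35))
    family = {"identity": "gaussian", "log": "poisson", "logit": "binomial"}[link]
    vspec = VarianceSpec(family, dispersion=1.0 if family != "gaussian" else 1.3)
    return layout, mspec, cspec, vspec


@pytest.fixture
def worked_example_contrasts(example_bundle):
    return example_bundle.contrasts
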