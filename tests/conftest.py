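import numpy as np
import pytest

import lipusopt as lo
from lipusopt import synthetic_data as sd


@pytest.fixture(scope="session")
def study_grid():
    return lo.load_study_grid()


@pytest.fixture(scope="session")
def printed_intervals():
    return lo.dataset.load_printed_intervals()


@pytest.fixture(scope="session")
def noiseless_grid():
    """Deterministic noiseless factorial grid from the default planted surface."""
    spec = sd.SurfaceSpec(noise_sd=0.0)
    grid, _ = sd.simulate_grid(spec, rng_seed=0)
    return grid


def linear_grid(slopes=(1.0, 10.0, 0.5), intercept=100.0):
    """A noiseless grid whose viability is affine in the condition."""
    summaries = []
    for v in (5.0, 6.0, 7.0, 8.0):
        for f in (0.6, 0.8, 1.0, 1.2):
            for d in (3.0, 6.0, 9.0):
                y = intercept + slopes[0] * v + slopes[1] * f + slopes[2] * d
                summaries.append(
                    lo.GroupSummary(lo.StimulationCondition(v, f, d), y, 0.0, 20)
                )
    return lo.ResponseGrid(summaries)


@pytest.fixture()
def affine_grid():
    return linear_grid()
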