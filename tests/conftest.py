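"""Shared fixtures: the ground-truth preset and data derived from it.

Expensive artifacts (ODE solves, sampled datasets, fitted transforms) are
session-scoped; tests must not mutate them.
"""

import numpy as np
import pytest

import bloomdyn as bd
from bloomdyn.drivers import fit_driver_set
from bloomdyn.preprocessing import TransformSpec
from bloomdyn.synthetic import sample_monitoring, simulate_truth, with_noise


@pytest.fixture(scope="session")
def preset():
    return bd.make_two_bloom_preset(0)


@pytest.fixture(scope="session")
def day_grid():
    return np.arange(1.0, 366.0)


@pytest.fixture(scope="session")
def truth_trajectory(preset, day_grid):
    return simulate_truth(preset, day_grid)


@pytest.fixture(scope="session")
def analytic_sample(preset):
    return bd.analytic_derivative_sample(preset)


@pytest.fixture(scope="session")
def clean_dataset(preset):
    """Noiseless, complete monitoring records from the preset."""
    return sample_monitoring(with_noise(preset, 0.0, 0.0))


@pytest.fixture(scope="session")
def noisy_dataset(preset):
    """Records at the default observation noise and missingness."""
    return sample_monitoring(preset)


@pytest.fixture(scope="session")
def standardized_clean(clean_dataset):
    """(spec, standardized training series, drivers) from clean records."""
    complete = bd.drop_incomplete(clean_dataset.records)
    train, _ = bd.split_by_year(complete)
    spec = TransformSpec.fit(train, "two_bloom")
    std = bd.log_zscore(train, spec)
    drivers = fit_driver_set(std)
    return spec, std, drivers
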