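"""Shared fixtures: the study protocol, frame grids and small phantoms."""

import numpy as np
import pytest

from fpetbold.phantom import PhantomSpec, make_atlas, simulate_cohort
from fpetbold.protocol import FrameTiming, StimulationProtocol


@pytest.fixture(scope="session")
def protocol():
    return StimulationProtocol()


@pytest.fixture(scope="session")
def pet_timing():
    return FrameTiming.uniform(95, 60.0)


@pytest.fixture(scope="session")
def small_spec():
    """Small grid, full temporal structure — fast per-test simulation."""
    return PhantomSpec(grid_shape=(16, 16, 8), n_chr2=4, n_gfp=4,
                       bold_frame_duration=15.0, seed=11)


@pytest.fixture(scope="session")
def small_atlas(small_spec):
    return make_atlas(small_spec)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return simulate_cohort(small_spec, include_bold=True)


@pytest.fixture(scope="session")
def noiseless_spec():
    return PhantomSpec(grid_shape=(16, 16, 8), noise_sd_pet=0.0,
                       noise_sd_bold=0.0, drift_amplitude=0.0,
                       n_chr2=1, n_gfp=1, bold_frame_duration=15.0, seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
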