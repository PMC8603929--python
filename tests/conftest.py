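"""Shared fixtures: small phantoms and precomputed forward solves."""

import warnings

import numpy as np
import pytest

from mrept.grids import ConductivityMap
from mrept.phantom import (
    PhantomSpec,
    build_phantom,
    day_schedule_spec,
    forward_phase,
    quadratic_phase,
    simulate_acquisition,
)
from mrept.pipeline import _single_slice

F_400MHZ = 4.0e8
SPACING = (0.3, 0.313, 0.313)


@pytest.fixture(scope="session")
def uniform_phantom():
    """Uniform 0.5 S/m slab with its exact quadratic forward phase."""
    shape = (1, 64, 48)
    sigma = ConductivityMap(values=np.full(shape, 0.5), spacing_mm=SPACING)
    boundary = quadratic_phase(shape, SPACING, 0.5, F_400MHZ)
    phase = forward_phase(sigma, larmor_hz=F_400MHZ, boundary=boundary)
    return sigma, phase, boundary


@pytest.fixture(scope="session")
def rat_spec():
    """Single-slice six-region rat-brain phantom spec."""
    return _single_slice(day_schedule_spec(11), 1)


@pytest.fixture(scope="session")
def rat_phantom(rat_spec):
    sigma, md, t2, vois = build_phantom(rat_spec)
    return sigma, md, t2, vois


@pytest.fixture(scope="session")
def rat_forward(rat_spec, rat_phantom):
    sigma, _, _, _ = rat_phantom
    return forward_phase(sigma, larmor_hz=rat_spec.larmor_hz)


@pytest.fixture(scope="session")
def rat_raw_noiseless(rat_spec, rat_phantom, rat_forward):
    sigma, _, t2, _ = rat_phantom
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_acquisition(
            sigma, t2, rat_forward, rat_spec, noise_sd=0.0, seed=0
        )


@pytest.fixture
def small_spec():
    """Tiny homogeneous spec for fast acquisition tests."""
    return PhantomSpec(grid_shape=(1, 24, 20), spacing_mm=SPACING, regions=[])
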