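"""Shared fixtures: a reduced phantom (fast to generate and solve) and the
default material law.  Session scope keeps the expensive constructions to a
single instance across the suite."""

import numpy as np
import pytest

from femfall import MaterialLaw, PhantomSpec, generate_phantom

# Reduced femur: same construction as the default, ~55% linear scale, so the
# 3 mm FE model has ~1,500 elements and every pipeline stage runs in seconds.
SMALL_SPEC = PhantomSpec(
    head_radius=15.0, neck_radius=9.0, neck_length=22.0,
    neck_shaft_angle=125.0, shaft_radius=13.0, shaft_length=62.0,
    cortical_thickness=2.5, trabecular_bmd=250.0, cortical_bmd=900.0,
    voxel_spacing=1.5, noise_sd=5.0, seed=1)


@pytest.fixture(scope="session")
def small_spec():
    return SMALL_SPEC


@pytest.fixture(scope="session")
def small_case():
    return generate_phantom(SMALL_SPEC)


@pytest.fixture(scope="session")
def noiseless_case():
    from dataclasses import replace
    return generate_phantom(replace(SMALL_SPEC, noise_sd=0.0))


@pytest.fixture(scope="session")
def law():
    return MaterialLaw()


@pytest.fixture(scope="session")
def small_model(noiseless_case, law):
    """Side-fall FE model of the reduced noiseless phantom (truth density)."""
    from femfall import build_sidefall_model, implicit_axes
    case = noiseless_case
    cs = implicit_axes(case.mask)
    return build_sidefall_model(case.truth_bmd, case.mask, cs, law)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
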