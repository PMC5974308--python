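"""Shared fixtures: small simulated pools and toy training sets.

Everything is generated programmatically with fixed seeds; session scope
keeps the expensive simulations to one run per test session.
"""

import numpy as np
import pytest

from pathdyn.simulator import (
    KineticModel,
    generate_pool,
    reference_hill_params,
    reference_parameters,
    simulate_strain,
)


@pytest.fixture(scope="session")
def kinetic_model():
    return KineticModel(reference_parameters())


@pytest.fixture(scope="session")
def ref_hill():
    return reference_hill_params()


@pytest.fixture(scope="session")
def reference_strain(kinetic_model, ref_hill):
    """The reference virtual strain on the default 7-point grid."""
    return simulate_strain(kinetic_model, ref_hill, strain_id="ref")


@pytest.fixture(scope="session")
def dense_reference_strain(kinetic_model, ref_hill):
    """Reference strain sampled densely (49 points over 72 h)."""
    return simulate_strain(
        kinetic_model, ref_hill, times=np.linspace(0.0, 72.0, 49),
        strain_id="ref-dense",
    )


@pytest.fixture(scope="session")
def small_pool(kinetic_model):
    """A 12-strain virtual pool on the experimental 7-point layout."""
    return generate_pool(kinetic_model, 12, seed=123)
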