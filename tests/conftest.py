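"""Shared fixtures: direction schemes and small synthetic cohorts.

Everything is generated programmatically and seeded; session scope keeps
the electrostatic optimisation and cohort simulations from repeating.
"""

import numpy as np
import pytest
from hypothesis import settings

from hippodti import CohortSpec, generate_multishell_set, simulate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

SMALL_SHAPE = (24, 24, 3)


@pytest.fixture(scope="session")
def shell_pair():
    """Jointly optimised 22-direction b=1000 and 43-direction b=2700 shells."""
    return generate_multishell_set(22, 43, seed=0)


@pytest.fixture(scope="session")
def noise_free_animal(shell_pair):
    """One control animal, no noise, no between-animal variation."""
    spec = CohortSpec(
        n_control=1, n_eae=0, between_animal_cv=0.0, snr_b0=np.inf, seed=0,
        shape=SMALL_SHAPE,
    )
    cohort, truth = simulate_cohort(spec, list(shell_pair))
    return cohort[0], truth


@pytest.fixture(scope="session")
def small_noisy_cohort(shell_pair):
    """Three control + three EAE animals at default noise, small grid."""
    spec = CohortSpec(n_control=3, n_eae=3, seed=7, shape=SMALL_SHAPE)
    return simulate_cohort(spec, list(shell_pair))
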