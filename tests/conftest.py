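"""Shared fixtures: simulated ground-truth runs reused across test modules.

Simulation lengths here are desk-scale (well below the run lengths a publication
would use) so the whole suite stays within a few minutes; the acceptance checks use
the tolerances appropriate for these lengths as stated, not tightened or loosened.
"""

from __future__ import annotations

import numpy as np
import pytest

from avakit.model import NetworkParams, cohort_simulate


@pytest.fixture(scope="session")
def critical_subsampled():
    """Critical E/I network (g = 3.5) observed through 1000 of 10^6 neurons."""
    params = NetworkParams(N=10**6, g=3.5, T=1_500_000, burn_in=10_000, seed=101)
    return cohort_simulate(params, f=0.001)


@pytest.fixture(scope="session")
def subcritical_subsampled():
    """Weakly subcritical network (g = 3.75), same observation window.

    Longer run than the critical fixture: the subcritical firing rate is ~25x lower,
    so comparable epoch statistics need more steps.
    """
    params = NetworkParams(N=10**6, g=3.75, T=6_000_000, burn_in=10_000, seed=103)
    return cohort_simulate(params, f=0.001)


@pytest.fixture(scope="session")
def fully_sampled_sparse_drive():
    """Fully observed critical network with sparse seeding (separated time scales).

    The drive is reduced to ~0.02 activations/step so individual cascades are
    bounded by quiescence; this is the protocol under which the model's critical
    exponents alpha = 3/2, beta = 2, chi = 2 are defined.
    """
    params = NetworkParams(
        N=10**6, g=3.5, lam=0.02 / 10**6, T=3_000_000, burn_in=10_000, seed=107
    )
    return cohort_simulate(params, f=1.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
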