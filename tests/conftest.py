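"""Shared fixtures: small simulated populations and lookup tables.

Fixtures are session-scoped where the underlying computation is reused by
several tests; all randomness is seeded so the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from rhoflow import (
    MigrationSpec,
    advance_generation,
    build_lookup_table,
    build_schedule,
    default_rho_grid,
    initialize_population,
    rescale,
)
from rhoflow.scaling import ScaledParameters


def make_params(n_model=50, L=5000, ne=1.72e6, mu=5.49e-9, r=2.23e-8):
    return rescale(ne, mu, r, n_model, L)


def zero_rate_params(n_model=50, L=1000) -> ScaledParameters:
    """Parameters with mutation and recombination switched off (drift only)."""
    return ScaledParameters(
        Ne_actual=float(n_model),
        N_model=n_model,
        Q=1.0,
        mu_site_actual=0.0,
        mu_site_model=0.0,
        r_site_actual=0.0,
        r_site_model=0.0,
        L=L,
    )


def equilibrate(params, seed, n_gens=None):
    mig = MigrationSpec.from_nem(0.0, params.N_model)
    sched = build_schedule("continuous", mig, 1.0, params)
    state = initialize_population(params, seed)
    n = 20 * params.N_model if n_gens is None else n_gens
    for _ in range(n):
        advance_generation(state, mig, sched)
    return state


@pytest.fixture(scope="session")
def eq_states_small():
    """Three equilibrium populations, N = 50, L = 5 kb (theta/site 0.0378)."""
    params = make_params()
    return params, [equilibrate(params, 1000 + k) for k in range(3)]


@pytest.fixture(scope="session")
def tiny_table():
    """Constant-size lookup table for 10 haplotypes (fast, coarse)."""
    return build_lookup_table(10, 0.0378, default_rho_grid(), [(0.0, 1.0)], 2000, 99)
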