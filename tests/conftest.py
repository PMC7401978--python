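"""Shared fixtures: baseline parameters and cached heavy computations."""

import numpy as np
import pytest

import statswitch as sw

#: Reference initial condition (STAT, APT, SLBO) used across experiments.
REF_IC = (12.0, 56.0, 1.5)


@pytest.fixture(scope="session")
def p():
    return sw.default_parameters()


@pytest.fixture(scope="session")
def eq_u4(p):
    """Steady states of the minimal model at UPD=4 (bistable regime)."""
    return sw.find_steady_states(4.0, p)


@pytest.fixture(scope="session")
def eq_u1(p):
    return sw.find_steady_states(1.0, p)


@pytest.fixture(scope="session")
def branch(p):
    """Full S-curve continuation from the U=0 steady state."""
    seed = sw.find_steady_states(0.0, p)[0]
    return sw.continue_branch(p, (0.0, 20.0), seed)


@pytest.fixture(scope="session")
def interval(p):
    return sw.bistable_interval(p)


@pytest.fixture(scope="session")
def grid_u4(p):
    """Coarse basin grid at UPD=4 (9^3 keeps the suite fast)."""
    return sw.classify_grid(4.0, p, spec=sw.GridSpec(n=9))


def stables_sorted(eq):
    """Stable states sorted by SLBO: [stationary, motile]."""
    st = sorted((s for s in eq if s.is_stable), key=lambda s: s.B)
    assert len(st) == 2
    return st


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
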