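"""Shared fixtures: small hand-built and generated substrates."""

from __future__ import annotations

import numpy as np
import pytest

from synspread import (
    Connectome,
    RegionalProfiles,
    SimulationParams,
    SyntheticSpec,
    generate_bundle,
)


def make_connectome(weights, lengths=None, sizes=None, coords=None, names=None):
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    if lengths is None:
        lengths = np.where(w > 0, 2.0, 0.0)
    if sizes is None:
        sizes = np.ones(n, dtype=int)
    if coords is None:
        coords = np.zeros((n, 3))
    if names is None:
        names = [f"r{i}" for i in range(n)]
    return Connectome(names, w, np.asarray(lengths, dtype=float), sizes, coords)


def single_region(size=1):
    return make_connectome(np.zeros((1, 1)), np.zeros((1, 1)), sizes=np.array([size]))


def uniform_profiles(c, snca=0.0, gba=0.0):
    n = c.n_regions
    return RegionalProfiles(c.region_names, np.full(n, float(snca)), np.full(n, float(gba)))


@pytest.fixture
def path3():
    """3-node path with weights (2, 3)."""
    w = np.array([[0, 2, 0], [2, 0, 3], [0, 3, 0]], dtype=float)
    return make_connectome(w)


@pytest.fixture(scope="session")
def bundle12():
    """12-region geometric bundle shared by the slower integration tests."""
    spec = SyntheticSpec(n_regions=12, rng_seed=7)
    return generate_bundle(spec)


@pytest.fixture(scope="session")
def equilibrium12(bundle12):
    from synspread import growth_to_equilibrium

    c, prof = bundle12["connectome"], bundle12["profiles"]
    state, density = growth_to_equilibrium(c, prof, SimulationParams())
    return state, density
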