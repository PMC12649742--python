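import numpy as np
import pytest
from hypothesis import settings

import tractnmf as t

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def desk_geometry():
    """Small two-hemisphere geometry for fast unit tests."""
    return t.make_geometry(400, 600, seed=11)


@pytest.fixture(scope="session")
def noiseless_spec():
    """Single-species noiseless cohort design (deterministic signal)."""
    return t.CohortSpec(
        species_list=(t.SpeciesSpec("sp", 1, 0.6),),
        hemisphere_sd=0.0,
        noise_model=t.NoiseModel("POISSON", 0.0),
        gain_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def planted_desk(desk_geometry, noiseless_spec):
    """Noiseless planted bundles + their rank-8 connectivity matrix at
    desk scale, with a K=8 decomposition."""
    bundles = t.make_bundles(desk_geometry, noiseless_spec, "sp", "LEFT")
    V = t.sample_connectivity(desk_geometry, bundles, 50.0,
                              noiseless_spec.noise_model, seed=0).values
    decomp = t.fit_group_nmf(V, 8, seed=0)
    return desk_geometry, bundles, V, decomp


@pytest.fixture(scope="session")
def planted_full():
    """The full-scale planted fixture: 2,000 vertices x 3,000 voxels,
    8 noiseless bundles, K=8 decomposition."""
    geometry = t.make_geometry(2000, 3000, seed=3)
    spec = t.CohortSpec(
        species_list=(t.SpeciesSpec("sp", 1, 0.6),),
        hemisphere_sd=0.0,
        noise_model=t.NoiseModel("POISSON", 0.0),
        gain_sd=0.0, seed=3)
    bundles = t.make_bundles(geometry, spec, "sp", "LEFT")
    V = t.sample_connectivity(geometry, bundles, 50.0, spec.noise_model,
                              seed=0).values
    decomp = t.fit_group_nmf(V, 8, seed=0)
    return geometry, bundles, V, decomp


def best_gray_correlations(decomp, bundles):
    """Max Pearson r between each planted gray loading and any component."""
    out = {}
    for b in bundles:
        out[b.bundle_id] = max(
            t.map_correlation(decomp.H[i], b.gray_loading)
            for i in range(decomp.K))
    return out
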