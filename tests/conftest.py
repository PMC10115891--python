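import numpy as np
import pytest

import allokit


@pytest.fixture(scope="session")
def toy():
    """Small two-chain toy topology with its reference coordinates."""
    top, ref = allokit.make_toy_topology(10, split=0.5, seed=7)
    return top, ref


@pytest.fixture(scope="session")
def small_ensemble(toy):
    """300-frame identity-covariance ensemble on the toy topology."""
    top, ref = toy
    spec = allokit.PlantedEnsembleSpec(n_residues=10, n_frames=300, seed=11)
    return allokit.sample_gaussian_ensemble(top, ref, spec)


@pytest.fixture(scope="session")
def planted_ensemble(toy):
    """Ensemble with one strongly coupled residue pair (2, 7), rho = 0.8."""
    top, ref = toy
    spec = allokit.PlantedEnsembleSpec(
        n_residues=10, n_frames=2000, planted_pairs={(2, 7): 0.8}, seed=13)
    return allokit.sample_gaussian_ensemble(top, ref, spec)
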