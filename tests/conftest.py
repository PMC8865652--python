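import numpy as np
import pytest

from mpmrisk.mpm import validate_model
from mpmrisk.simulate import simulate_mpm


@pytest.fixture
def toy_model():
    """Two-stage worked example with hand-derivable metrics.

    N = (I-U)^-1 = [[1.25, 0], [0.75, 2]], R0 = 1.125,
    lambda = (0.7 + sqrt(1.89))/2, age at maturity 1.25,
    mature life expectancy 2.0.
    """
    U = np.array([[0.2, 0.0], [0.3, 0.5]])
    F = np.array([[0.0, 1.5], [0.0, 0.0]])
    return validate_model(U, F, species_id="toy", taxon_group="herb")


@pytest.fixture
def biennial_model():
    """Semelparous biennial: lambda = sqrt(1.5), generation time exactly 2."""
    U = np.array([[0.0, 0.0], [0.5, 0.0]])
    F = np.array([[0.0, 3.0], [0.0, 0.0]])
    return validate_model(U, F, species_id="biennial", taxon_group="herb")


def random_models(n, min_stages=3, max_stages=6, seed=0):
    """Valid random stage models across the fast-slow continuum."""
    rng = np.random.default_rng(seed)
    models = []
    for i in range(n):
        arch = "fast" if rng.random() < 0.5 else "slow"
        s = int(rng.integers(min_stages, max_stages + 1))
        models.append(
            simulate_mpm(arch, s, rng=rng, species_id=f"rm_{i:04d}")
        )
    return models
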