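import numpy as np
import pytest

from ecfuse.synthetic_data import (
    TorsionRegime,
    generate_structure,
    well_separated_config,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def helix_regime():
    return TorsionRegime(modes=((-57.0, -47.0),), noise_sd=0.0)


@pytest.fixture
def helix_structure(helix_regime):
    structure, phi, psi = generate_structure(12, helix_regime, seed=7)
    return structure


@pytest.fixture
def random_structure():
    regime = TorsionRegime(modes=((-57.0, -47.0), (-120.0, 130.0)), noise_sd=25.0)
    structure, _, _ = generate_structure(
        40, regime, seed=99, nonstandard_fraction=0.1
    )
    return structure


@pytest.fixture
def tiny_dataset(tmp_path):
    """6 classes x 3 proteins, written to disk."""
    config = well_separated_config(n_per_class=3, seed=11, length_range=(20, 30))
    from ecfuse.synthetic_data import generate_dataset

    manifest, manifest_path = generate_dataset(config, tmp_path / "data")
    return manifest, manifest_path
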