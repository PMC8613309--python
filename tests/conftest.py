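import numpy as np
import pytest

import tempgen as tg


@pytest.fixture(scope="session")
def small_config() -> tg.SimConfig:
    return tg.SimConfig(
        n_founders=40,
        n_generations=3,
        mean_offspring=2.4,
        n_snvs=300,
        n_chromosomes=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return tg.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def nuclear_pedigree() -> tg.Pedigree:
    return tg.Pedigree.from_records(
        [
            ("dad", "0", "0", "M"),
            ("mom", "0", "0", "F"),
            ("kid1", "dad", "mom", "M"),
            ("kid2", "dad", "mom", "F"),
        ]
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
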