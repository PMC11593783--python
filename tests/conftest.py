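import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mitobias as mb

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def box_library() -> mb.BoxLibrary:
    return mb.BoxLibrary.load()


@pytest.fixture(scope="session")
def small_config() -> mb.SimConfig:
    """A small but complete study: 4 species, 3 genes, concerted CRs."""
    return mb.SimConfig(seed=101, n_species=4, go_type="GO-II", omega=0.2,
                        gene_lengths={"ATP8": 55, "COI": 200, "ND3": 116},
                        branch_length=0.05)


@pytest.fixture(scope="session")
def dataset_go2(small_config) -> mb.simulate.SimulatedDataset:
    return mb.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def dataset_go4(small_config) -> mb.simulate.SimulatedDataset:
    import dataclasses
    cfg = dataclasses.replace(small_config, go_type="GO-IV", seed=102)
    return mb.simulate_dataset(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_count_table(rng: np.random.Generator, max_count: int = 50) -> mb.CodonCountTable:
    from mitobias.genetic_code import SENSE_CODONS
    counts = {c: int(rng.integers(0, max_count)) for c in SENSE_CODONS}
    return mb.CodonCountTable(("rand", "rand"), counts)
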