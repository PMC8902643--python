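import numpy as np
import pytest

from circlink import ERNConfig, PSNConfig
from circlink.data import AssociationTable
from circlink.synthetic import PlantedBlockConfig, generate_planted


@pytest.fixture(scope="session")
def toy_matrix() -> np.ndarray:
    """Seeded 8x6 binary matrix used for reconstruction/overfit checks."""
    rng = np.random.default_rng(42)
    return rng.integers(0, 2, size=(8, 6))


@pytest.fixture(scope="session")
def toy_ern_config() -> ERNConfig:
    return ERNConfig(embedding_dim=8, hidden_dim=16, epochs=2000, seed=1)


@pytest.fixture
def simple_tables() -> dict[str, AssociationTable]:
    cd = AssociationTable(
        "circRNA-disease",
        pairs=(("c1", "d1"), ("c1", "d2"), ("c2", "d2"), ("c3", "d1")),
    )
    cm = AssociationTable(
        "circRNA-miRNA", pairs=(("c1", "m1"), ("c2", "m2"), ("c3", "m1"))
    )
    return {"circRNA-disease": cd, "circRNA-miRNA": cm}


@pytest.fixture(scope="session")
def small_planted_config() -> PlantedBlockConfig:
    """Small instance for structural pipeline tests (not the benchmark condition)."""
    return PlantedBlockConfig(
        n_circ=12,
        n_disease=8,
        aux_sizes={"miRNA": 10, "gene": 10, "lncRNA": 6, "drug": 6},
        n_groups=2,
        p_in=0.9,
        p_out=0.05,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_planted(small_planted_config):
    return generate_planted(small_planted_config)


@pytest.fixture(scope="session")
def fast_ern_config() -> ERNConfig:
    """Reduced training budget for structural (non-recovery) tests."""
    return ERNConfig(embedding_dim=16, hidden_dim=32, epochs=200, seed=3)


@pytest.fixture(scope="session")
def fast_psn_config() -> PSNConfig:
    return PSNConfig(feature_dim=8, extractor_hidden_dim=16, head_hidden_dim=16,
                     epochs=30, seed=3)
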