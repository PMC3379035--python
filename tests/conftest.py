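import numpy as np
import pytest

from kinspec import (
    KinaseSubstrateRecord,
    PhosphositeRegion,
    PlantedModel,
    generate,
)
from kinspec.alphabets import N_OFFSETS, N_SUBSTRATE, SUBSTRATE_ALPHABET


def region(symbols: str) -> PhosphositeRegion:
    return PhosphositeRegion(symbols)


def records_for(kinase_id: str, peptides: list[str]) -> list[KinaseSubstrateRecord]:
    return [KinaseSubstrateRecord(kinase_id, region(p)) for p in peptides]


def random_profile(rng: np.random.Generator):
    """Random column-stochastic 21x15 matrix (Dirichlet columns)."""
    probs = rng.dirichlet(np.ones(N_SUBSTRATE), size=N_OFFSETS).T
    return probs


def random_region(rng: np.random.Generator) -> PhosphositeRegion:
    symbols = [SUBSTRATE_ALPHABET[i] for i in rng.integers(0, 20, size=N_OFFSETS)]
    symbols[7] = "STY"[rng.integers(0, 3)]
    return PhosphositeRegion("".join(symbols))


@pytest.fixture(scope="session")
def small_family():
    """A small but signal-rich planted family for module-level tests."""
    model = PlantedModel.default(
        seed=7, n_kinases=60, n_peptides=20, alignment_length=40
    )
    return generate(model)


@pytest.fixture(scope="session")
def default_family():
    """One family at the standard study scale (K=200, n=30, L=100)."""
    return generate(PlantedModel.default(seed=11))
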