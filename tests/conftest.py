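import numpy as np
import pandas as pd
import pytest

from rsaphylo import DomainMatrix, GenomeRecord, PLNParams, GroupSpec
from rsaphylo.synthetic import generate_population


@pytest.fixture
def small_matrix() -> DomainMatrix:
    data = pd.DataFrame(
        [[3, 1, 1, 0], [2, 2, 0, 0], [0, 4, 0, 1]],
        index=["g1", "g2", "g3"],
        columns=["f1", "f2", "f3", "f4"],
    )
    return DomainMatrix(data)


@pytest.fixture
def small_records() -> list[GenomeRecord]:
    return [
        GenomeRecord("g1", 2_500_000, {"species": "A", "genus": "X"}),
        GenomeRecord("g2", 1_000_000, {"species": "A", "genus": "X"}),
        GenomeRecord("g3", 5_000_000, {"species": "B"}),
    ]


@pytest.fixture(scope="session")
def community():
    """A small well-separated 3-group community reused by slow tests."""
    specs = [
        GroupSpec(
            label=f"G{g}",
            pln=PLNParams(mu=-4.5 + 1.6 * g, sigma2=4.6 - 0.9 * g),
            density=0.0008 * (g + 1),
            genome_length=3_000_000,
            n_genomes=8,
            n_families=1200,
            jitter=0.05,
        )
        for g in range(3)
    ]
    return generate_population(specs, family_pool=5000, seed=2024)
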