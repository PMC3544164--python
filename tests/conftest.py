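"""Shared fixtures: the worked toy matrix and random-matrix factories."""

import numpy as np
import pytest

from driverpath import MutationMatrix


@pytest.fixture
def toy_matrix() -> MutationMatrix:
    """Three patients, four genes: p1 mutates g1,g2; p2 mutates g2;
    p3 mutates g3; g4 is never mutated.

    Hand-computed reference values used across the suite:
    supports g1={p1}, g2={p1,p2}, g3={p3}, g4={};
    W({g2,g3}) = 3 (the unique maximum over pairs), W({g1,g2}) = 1.
    """
    return MutationMatrix(
        [[1, 1, 0, 0],
         [0, 1, 0, 0],
         [0, 0, 1, 0]],
        patient_ids=["p1", "p2", "p3"],
        gene_ids=["g1", "g2", "g3", "g4"],
    )


@pytest.fixture
def random_matrix_factory():
    """Factory for seeded random binary matrices with labelled axes."""

    def make(m: int, n: int, density: float = 0.3, seed: int = 0) -> MutationMatrix:
        rng = np.random.default_rng(seed)
        data = (rng.random((m, n)) < density).astype(np.uint8)
        return MutationMatrix(
            data,
            patient_ids=[f"p{i}" for i in range(m)],
            gene_ids=[f"g{j}" for j in range(n)],
        )

    return make
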