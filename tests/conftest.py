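"""Shared fixtures and tiny construction helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from riverdrift.genotypes import AlleleMatrix, simple_metadata, concat_matrices


def matrix_from_pools(pools: dict[str, list[list[tuple[int, int]]]]) -> AlleleMatrix:
    """Build an AlleleMatrix from {pool: [per-individual [(a, b) per locus]]}."""
    blocks = []
    start = 0
    for label, inds in pools.items():
        genos = np.array(inds, dtype=np.int64)  # (n, n_loci, 2)
        meta = simple_metadata(len(inds), pool_label=label, start=start)
        start += len(inds)
        blocks.append(AlleleMatrix(meta, genos, [f"locus_{i+1}" for i in range(genos.shape[1])]))
    return concat_matrices(blocks)


def random_matrix(
    rng: np.random.Generator,
    pool_sizes: dict[str, int],
    n_loci: int = 2,
    max_allele: int = 3,
) -> AlleleMatrix:
    pools = {
        label: [
            [tuple(rng.integers(1, max_allele + 1, size=2)) for _ in range(n_loci)]
            for _ in range(n)
        ]
        for label, n in pool_sizes.items()
    }
    return matrix_from_pools(pools)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture()
def two_pool_toy():
    """The 4-individual worked table: pool1 (1,1),(1,2); pool2 (2,2),(2,2)."""
    return matrix_from_pools(
        {"pool1": [[(1, 1)], [(1, 2)]], "pool2": [[(2, 2)], [(2, 2)]]}
    )
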