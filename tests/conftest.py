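from __future__ import annotations

import numpy as np
import pytest

from nbm.matrix_io import MutationMatrix


def matrix_from_coverage(
    coverage: dict[str, set[str]], patients: list[str]
) -> MutationMatrix:
    """Build a MutationMatrix from per-gene patient coverage sets."""
    genes = sorted(coverage)
    entries = np.zeros((len(patients), len(genes)), dtype=np.int8)
    p_idx = {p: i for i, p in enumerate(patients)}
    for j, g in enumerate(genes):
        for p in coverage[g]:
            entries[p_idx[p], j] = 1
    return MutationMatrix(tuple(patients), tuple(genes), entries)


@pytest.fixture
def disjoint_pair_matrix() -> MutationMatrix:
    """Two genes with disjoint coverage over 4 patients (ED=1, CD=1)."""
    return matrix_from_coverage(
        {"gA": {"p1", "p2"}, "gB": {"p3", "p4"}}, ["p1", "p2", "p3", "p4"]
    )


@pytest.fixture
def overlap_matrix() -> MutationMatrix:
    """Γ(g1)={p1,p2,p3}, Γ(g2)={p3,p4}: ED=4/5, CD=1 over m=4."""
    return matrix_from_coverage(
        {"g1": {"p1", "p2", "p3"}, "g2": {"p3", "p4"}}, ["p1", "p2", "p3", "p4"]
    )


def random_matrix(rng: np.random.Generator, m: int, n: int, density: float) -> MutationMatrix:
    entries = (rng.random((m, n)) < density).astype(np.int8)
    # ensure every gene carries at least one mutation
    for j in range(n):
        if not entries[:, j].any():
            entries[rng.integers(m), j] = 1
    return MutationMatrix(
        tuple(f"p{i:02d}" for i in range(m)),
        tuple(f"g{j:02d}" for j in range(n)),
        entries,
    )
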