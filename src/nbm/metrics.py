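"""Exclusivity and coverage scores for gene sets.

For a gene set M in an m-patient matrix, with Γ(M) the union of the
per-gene patient coverage sets:

* exclusive degree        ED(M)  = |Γ(M)| / Σ_{g∈M} |Γ(g)|
* coverage degree         CD(M)  = |Γ(M)| / m
* exclusivity-coverage    ECD(M) = ED(M) · CD(M) = |Γ(M)|² / (m · Σ_g |Γ(g)|)

ED(M) = 1 exactly when the coverage sets are pairwise disjoint (mutual
exclusivity); CD(M) = 1 exactly when every patient is covered.  All three
are computed as exact rationals on integer counts; the public functions
return floats, the ``*_exact`` variants return :class:`fractions.Fraction`.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable

import numpy as np

from .matrix_io import MutationMatrix

__all__ = [
    "coverage_set",
    "set_counts",
    "exclusive_degree",
    "coverage_degree",
    "ecd",
    "exclusive_degree_exact",
    "coverage_degree_exact",
    "ecd_exact",
    "pair_metrics",
]


class UndefinedMetricError(ZeroDivisionError):
    """Raised when no gene of the set carries a mutation (denominator 0)."""


def coverage_set(matrix: MutationMatrix, genes: Iterable[str]) -> frozenset[str]:
    """Γ(M) = ∪_{g∈M} Γ(g): the patients covered by the gene set."""
    cols = [matrix.gene_column(g) for g in genes]
    if not cols:
        return frozenset()
    mask = matrix.entries[:, cols].any(axis=1)
    return frozenset(matrix.patients[i] for i in np.flatnonzero(mask))


def set_counts(matrix: MutationMatrix, genes: Iterable[str]) -> tuple[int, int]:
    """Return (|Γ(M)|, Σ_{g∈M} |Γ(g)|) as exact integers."""
    cols = [matrix.gene_column(g) for g in genes]
    if not cols:
        return 0, 0
    sub = matrix.entries[:, cols]
    union = int(sub.any(axis=1).sum())
    total = int(sub.sum())
    return union, total


def exclusive_degree_exact(matrix: MutationMatrix, genes: Iterable[str]) -> Fraction:
    genes = list(genes)
    if not genes:
        raise UndefinedMetricError("ED is undefined for an empty gene set")
    union, total = set_counts(matrix, genes)
    if total == 0:
        raise UndefinedMetricError(f"ED undefined: no mutations among genes {genes}")
    return Fraction(union, total)


def coverage_degree_exact(matrix: MutationMatrix, genes: Iterable[str]) -> Fraction:
    union, _ = set_counts(matrix, genes)
    return Fraction(union, matrix.m)


def ecd_exact(matrix: MutationMatrix, genes: Iterable[str]) -> Fraction:
    genes = list(genes)
    return exclusive_degree_exact(matrix, genes) * coverage_degree_exact(matrix, genes)


def exclusive_degree(matrix: MutationMatrix, genes: Iterable[str]) -> float:
    """ED(M): 1 iff the per-gene coverage sets are pairwise disjoint."""
    return float(exclusive_degree_exact(matrix, genes))


def coverage_degree(matrix: MutationMatrix, genes: Iterable[str]) -> float:
    """CD(M): fraction of all patients with ≥1 mutation in the set."""
    return float(coverage_degree_exact(matrix, genes))


def ecd(matrix: MutationMatrix, genes: Iterable[str]) -> float:
    """ECD(M) = ED(M)·CD(M), the exclusivity/coverage trade-off objective."""
    return float(ecd_exact(matrix, genes))


def pair_metrics(matrix: MutationMatrix, g1: str, g2: str) -> tuple[float, float, float]:
    """(ED, CD, ECD) of the two-gene set {g1, g2}; symmetric in its arguments."""
    e = exclusive_degree_exact(matrix, (g1, g2))
    c = coverage_degree_exact(matrix, (g1, g2))
    return float(e), float(c), float(e * c)
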