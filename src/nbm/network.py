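"""Weighted gene network built from pairwise approximate exclusivity.

Nodes are genes; an undirected edge joins genes g_j, g_k whenever their
pairwise exclusive degree ED(g_j, g_k) = |Γ(g_j) ∪ Γ(g_k)| / (|Γ(g_j)| +
|Γ(g_k)|) reaches the threshold λ, and the edge weight is that ED.  A gene
whose ED with every other gene falls below λ does not appear in the
network.  The network is the search space for the greedy pathway growth:
restricting candidate moves to graph neighbours is what makes the local
search tractable compared with scoring all O(n^k) submatrices.
"""

from __future__ import annotations

from fractions import Fraction
from pathlib import Path

import networkx as nx
import numpy as np

from .matrix_io import MutationMatrix

__all__ = ["build_network", "write_edge_list", "read_edge_list", "as_exact_threshold"]


def as_exact_threshold(lam: float | Fraction) -> Fraction:
    """Convert a user-supplied threshold to an exact rational.

    Floats go through their shortest decimal repr, so ``0.95`` means the
    rational 19/20 and a pair with ED exactly 19/20 sits ON the boundary
    rather than an ulp below it.
    """
    if isinstance(lam, Fraction):
        return lam
    return Fraction(repr(float(lam)))


def build_network(matrix: MutationMatrix, lam: float | Fraction = 0.95) -> nx.Graph:
    """Build the exclusivity network at edge threshold ``lam``.

    The edge criterion is inclusive (pairwise ED ≥ λ creates the edge).
    Edge weights are stored as exact :class:`~fractions.Fraction` under the
    ``"weight"`` attribute.  Genes with no qualifying partner are absent;
    the result therefore has no isolated nodes.  Pairs in which either gene
    has zero mutations are skipped (cannot occur after the frequency
    filter).
    """
    lam_f = as_exact_threshold(lam)
    if not 0 < lam_f <= 1:
        raise ValueError(f"lambda must be in (0, 1], got {lam}")
    A = matrix.entries.astype(np.int64)
    counts = A.sum(axis=0)
    inter = A.T @ A  # pairwise co-occurrence counts |Γ(gj) ∩ Γ(gk)|
    graph = nx.Graph()
    n = matrix.n
    for j in range(n):
        if counts[j] == 0:
            continue
        for k in range(j + 1, n):
            if counts[k] == 0:
                continue
            denom = int(counts[j] + counts[k])
            union = denom - int(inter[j, k])
            ed = Fraction(union, denom)
            if ed >= lam_f:
                graph.add_edge(matrix.genes[j], matrix.genes[k], weight=ed)
    return graph


def write_edge_list(network: nx.Graph, path: str | Path) -> None:
    """Write a 3-column TSV ``geneA geneB weight`` (A < B, rows sorted)."""
    rows = sorted(
        (min(a, b), max(a, b), data["weight"]) for a, b, data in network.edges(data=True)
    )
    with Path(path).open("w", encoding="utf-8") as fh:
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{float(w):.12f}\n")


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a network written by :func:`write_edge_list`."""
    graph = nx.Graph()
    for lineno, ln in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
        a, b, w_text = fields
        weight = Fraction(w_text)
        if not 0 <= weight <= 1:
            raise ValueError(f"{path}:{lineno}: weight {w_text} outside [0, 1]")
        graph.add_edge(a, b, weight=weight)
    return graph
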