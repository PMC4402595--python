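"""Greedy seed-growth detection of overlapping driver-pathway candidates.

The pipeline: frequency-filter the mutation matrix, build the pairwise
exclusivity network at threshold λ, then repeatedly

1. pick, among edges whose two endpoints have not yet been used as seeds or
   absorbed into a grown set, the pair with the highest pairwise ECD;
2. grow that seed pair by best-improvement local search: at each iteration
   consider adding any external gene adjacent to the current set (a node on
   a boundary edge) or removing any internal gene; a move is admissible iff
   it strictly increases ECD and keeps ED > λ; apply the best admissible
   move until none exists (a locally optimal gene set);
3. mark the grown genes and the seeds as consumed.

Growth may absorb genes already belonging to earlier sets — only seeding is
restricted to unconsumed genes — so reported pathways can overlap.  A final
filter discards candidates with fewer than ``min_set_size`` genes or
coverage degree below δ.  All comparisons are on exact rationals and all
ties break lexicographically, so results are fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np

from . import metrics
from .matrix_io import MutationMatrix, filter_by_frequency
from .network import as_exact_threshold, build_network

__all__ = [
    "NBMParams",
    "PathwayCandidate",
    "NBMResult",
    "select_seed_pair",
    "grow_from_seeds",
    "run_nbm",
    "permutation_pvalue",
]

logger = logging.getLogger(__name__)

DiscardReason = Literal["too-small", "low-coverage"]


@dataclass(frozen=True)
class NBMParams:
    """Tunable parameters of the pathway search.

    lambda_ is the exclusivity threshold for both network edges (ED ≥ λ)
    and growth admissibility (ED > λ); delta the minimum coverage degree of
    a reported pathway; min_set_size the minimum reported set size;
    min_gene_fraction the recurrent-mutation pre-filter (genes mutated in
    fewer than this fraction of patients are dropped before anything else).
    """

    lambda_: float = 0.95
    delta: float = 0.3
    min_set_size: int = 3
    min_gene_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < float(self.lambda_) <= 1:
            raise ValueError(f"lambda must be in (0, 1], got {self.lambda_}")
        if not 0 <= float(self.delta) <= 1:
            raise ValueError(f"delta must be in [0, 1], got {self.delta}")
        if self.min_set_size < 1:
            raise ValueError("min_set_size must be >= 1")
        if not 0 <= float(self.min_gene_fraction) <= 1:
            raise ValueError("min_gene_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PathwayCandidate:
    """A gene set with its exclusivity/coverage scores.

    ``genes`` is sorted; ``ed``/``cd``/``ecd`` satisfy ecd = ed·cd.
    """

    genes: tuple[str, ...]
    covered_patients: frozenset[str]
    ed: float
    cd: float
    ecd: float

    @property
    def num_covered(self) -> int:
        return len(self.covered_patients)

    @property
    def size(self) -> int:
        return len(self.genes)


def _candidate(matrix: MutationMatrix, genes: Iterable[str]) -> PathwayCandidate:
    genes = tuple(sorted(genes))
    e = metrics.exclusive_degree_exact(matrix, genes)
    c = metrics.coverage_degree_exact(matrix, genes)
    return PathwayCandidate(
        genes=genes,
        covered_patients=metrics.coverage_set(matrix, genes),
        ed=float(e),
        cd=float(c),
        ecd=float(e * c),
    )


@dataclass
class NBMResult:
    """Outcome of a full pathway search run."""

    pathways: list[PathwayCandidate]
    discarded: list[tuple[PathwayCandidate, DiscardReason]]
    seeds_used: list[tuple[str, str]]

    @property
    def gene_sets(self) -> list[frozenset[str]]:
        return [frozenset(p.genes) for p in self.pathways]


def _pair_ecd(matrix: MutationMatrix, g1: str, g2: str) -> tuple[Fraction, Fraction]:
    e = metrics.exclusive_degree_exact(matrix, (g1, g2))
    c = metrics.coverage_degree_exact(matrix, (g1, g2))
    return e * c, e


def select_seed_pair(
    network: nx.Graph,
    matrix: MutationMatrix,
    consumed: set[str] | frozenset[str] = frozenset(),
) -> tuple[str, str] | None:
    """Pick the unconsumed connected pair with the highest pairwise ECD.

    Only edges with BOTH endpoints outside ``consumed`` qualify; returns
    None when no such edge remains.  Ties break by higher pairwise ED, then
    by lexicographically smallest sorted pair.
    """
    best: tuple[Fraction, Fraction, tuple[str, str]] | None = None
    for a, b in network.edges():
        if a in consumed or b in consumed:
            continue
        pair = (a, b) if a < b else (b, a)
        ecd_v, ed_v = _pair_ecd(matrix, *pair)
        key = (ecd_v, ed_v)
        if best is None or key > best[:2] or (key == best[:2] and pair < best[2]):
            best = (ecd_v, ed_v, pair)
    return None if best is None else best[2]


def _grow(
    network: nx.Graph,
    matrix: MutationMatrix,
    seeds: tuple[str, str],
    lam: Fraction,
) -> tuple[frozenset[str], int]:
    """Best-improvement local search from a connected seed pair.

    Returns the locally optimal gene set and the number of improving moves
    applied.  Each accepted move strictly increases the exact ECD, which is
    bounded by 1 over finitely many gene sets, so the loop terminates.
    """
    current = set(seeds)
    cur_ecd = metrics.ecd_exact(matrix, current)
    steps = 0
    while True:
        # candidate additions: external neighbours of the current set
        neighbours = {w for v in current for w in network.neighbors(v)} - current
        moves: list[tuple[Fraction, Fraction, int, str, frozenset[str]]] = []
        for v in sorted(neighbours):
            trial = current | {v}
            ed_v = metrics.exclusive_degree_exact(matrix, trial)
            if ed_v <= lam:
                continue
            ecd_v = ed_v * metrics.coverage_degree_exact(matrix, trial)
            if ecd_v > cur_ecd:
                moves.append((ecd_v, ed_v, 0, v, frozenset(trial)))
        if len(current) > 1:
            for v in sorted(current):
                trial = current - {v}
                _, total = metrics.set_counts(matrix, trial)
                if total == 0:
                    continue
                ed_v = metrics.exclusive_degree_exact(matrix, trial)
                if ed_v <= lam:
                    continue
                ecd_v = ed_v * metrics.coverage_degree_exact(matrix, trial)
                if ecd_v > cur_ecd:
                    moves.append((ecd_v, ed_v, 1, v, frozenset(trial)))
        if not moves:
            return frozenset(current), steps
        # best ECD, then best ED, then additions before removals, then
        # lexicographically smallest moved gene
        moves.sort(key=lambda mv: (-mv[0], -mv[1], mv[2], mv[3]))
        _, _, _, _, chosen = moves[0]
        cur_ecd = moves[0][0]
        current = set(chosen)
        steps += 1


def grow_from_seeds(
    network: nx.Graph,
    matrix: MutationMatrix,
    seeds: tuple[str, str],
    params: NBMParams | None = None,
) -> PathwayCandidate:
    """Grow a seed pair to a locally optimal pathway candidate.

    Moves must strictly increase ECD and keep ED > λ; the two-gene seed set
    itself is exempt from the strict-ED requirement (it exists by virtue of
    an ED ≥ λ network edge).  Seed genes may be ejected during growth.
    """
    params = params or NBMParams()
    if not network.has_edge(*seeds):
        raise ValueError(f"seed genes {seeds} are not connected in the network")
    final, _ = _grow(network, matrix, tuple(seeds), as_exact_threshold(params.lambda_))
    return _candidate(matrix, final)


def run_nbm(matrix: MutationMatrix, params: NBMParams | None = None) -> NBMResult:
    """Run the full pathway search on a raw mutation matrix.

    Applies the frequency pre-filter, builds the λ-network, exhausts seed
    pairs (growing each to local optimality and consuming the grown and
    seed genes), then discards candidates smaller than ``min_set_size`` or
    with coverage degree below δ, deduplicates identical gene sets, and
    orders pathways by descending ECD.
    """
    params = params or NBMParams()
    filtered = filter_by_frequency(matrix, params.min_gene_fraction)
    net = build_network(filtered, params.lambda_)
    if net.number_of_edges() == 0:
        logger.warning("exclusivity network is empty at lambda=%s", params.lambda_)
        return NBMResult([], [], [])
    lam = as_exact_threshold(params.lambda_)
    delta = as_exact_threshold(params.delta)

    consumed: set[str] = set()
    seeds_used: list[tuple[str, str]] = []
    raw: list[PathwayCandidate] = []
    seen: set[frozenset[str]] = set()
    while True:
        pair = select_seed_pair(net, filtered, consumed)
        if pair is None:
            break
        seeds_used.append(pair)
        final, _ = _grow(net, filtered, pair, lam)
        consumed |= final | set(pair)
        if final not in seen:
            seen.add(final)
            raw.append(_candidate(filtered, final))

    pathways: list[PathwayCandidate] = []
    discarded: list[tuple[PathwayCandidate, DiscardReason]] = []
    for cand in raw:
        if cand.size < params.min_set_size:
            discarded.append((cand, "too-small"))
        elif metrics.coverage_degree_exact(filtered, cand.genes) < delta:
            discarded.append((cand, "low-coverage"))
        else:
            pathways.append(cand)
    pathways.sort(key=lambda p: (-p.ecd, p.genes))
    return NBMResult(pathways, discarded, seeds_used)


def permutation_pvalue(
    matrix: MutationMatrix,
    candidate: PathwayCandidate | Sequence[str],
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Empirical significance of a candidate's ECD under a null that
    preserves every gene's mutation count.

    Each permutation independently shuffles each gene's column (a fixed-
    margin null for the genes), recomputes ECD of the same gene set, and
    the add-one estimator p = (1 + #{ECD* ≥ observed}) / (1 + N) is
    returned, so p is never exactly zero.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    genes = list(candidate.genes if isinstance(candidate, PathwayCandidate) else candidate)
    cols = [matrix.gene_column(g) for g in genes]
    sub = matrix.entries[:, cols].astype(np.int8)
    m = matrix.m
    counts = sub.sum(axis=0)
    observed = Fraction(int(sub.any(axis=1).sum()) ** 2, m * int(counts.sum()))
    rng = np.random.default_rng(seed)
    hits = 0
    perm = np.empty_like(sub)
    for _ in range(n_permutations):
        for j in range(sub.shape[1]):
            perm[:, j] = sub[rng.permutation(m), j]
        union = int(perm.any(axis=1).sum())
        if Fraction(union * union, m * int(counts.sum())) >= observed:
            hits += 1
    return (1 + hits) / (1 + n_permutations)
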