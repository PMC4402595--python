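from __future__ import annotations

from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from nbm import metrics
from nbm.greedy_clustering import (
    NBMParams,
    grow_from_seeds,
    permutation_pvalue,
    run_nbm,
    select_seed_pair,
)
from nbm.network import build_network
from nbm.simulate import SimulationConfig, generate

from .conftest import matrix_from_coverage


class TestParams:
    def test_defaults(self):
        p = NBMParams()
        assert (p.lambda_, p.delta, p.min_set_size, p.min_gene_fraction) == (
            0.95, 0.3, 3, 0.05,
        )

    @pytest.mark.parametrize(
        "kwargs", [{"lambda_": 0}, {"lambda_": 1.2}, {"delta": -0.1},
                   {"min_set_size": 0}, {"min_gene_fraction": 2}],
    )
    def test_rejects_out_of_range(self, kwargs):
        with pytest.raises(ValueError):
            NBMParams(**kwargs)


class TestSelectSeedPair:
    def test_single_edge_network(self, disjoint_pair_matrix):
        net = build_network(disjoint_pair_matrix, 0.95)
        assert select_seed_pair(net, disjoint_pair_matrix) == ("gA", "gB")

    def test_highest_pair_ecd_wins(self):
        # (a,b) covers 4/6 patients exclusively (ECD=2/3);
        # (c,d) covers 2/6 exclusively (ECD=1/3)
        patients = [f"p{i}" for i in range(6)]
        cov = {
            "a": {"p0", "p1"}, "b": {"p2", "p3"},
            "c": {"p4"}, "d": {"p5"},
        }
        m = matrix_from_coverage(cov, patients)
        net = nx.Graph()
        net.add_edge("a", "b", weight=Fraction(1))
        net.add_edge("c", "d", weight=Fraction(1))
        assert select_seed_pair(net, m) == ("a", "b")
        assert select_seed_pair(net, m, consumed={"a"}) == ("c", "d")

    def test_all_consumed_returns_none(self, disjoint_pair_matrix):
        net = build_network(disjoint_pair_matrix, 0.95)
        assert select_seed_pair(net, disjoint_pair_matrix, consumed={"gA"}) is None


class TestGrowFromSeeds:
    def test_requires_connected_seeds(self, disjoint_pair_matrix):
        net = build_network(disjoint_pair_matrix, 0.95)
        with pytest.raises(ValueError, match="not connected"):
            grow_from_seeds(net, disjoint_pair_matrix, ("gA", "missing"))

    def test_blocked_extension_returns_seed_pair(self):
        """A big-coverage extension would raise ECD (0.2 → 10/11) but its
        set ED (10/11) fails the strict >λ rule, so growth stops at the seeds."""
        patients = [f"p{i}" for i in range(10)]
        cov = {
            "a": {"p0"},
            "b": {"p1"},
            "c": set(patients[1:]),  # 9 patients incl p1
        }
        m = matrix_from_coverage(cov, patients)
        net = build_network(m, 0.95)
        assert net.has_edge("a", "b") and net.has_edge("a", "c")
        cand = grow_from_seeds(net, m, ("a", "b"), NBMParams())
        assert cand.genes == ("a", "b")
        assert cand.ecd == pytest.approx(0.2)

    def test_seed_ejection(self):
        """After c joins {a,b}, dropping a raises ECD to 1 with ED=1>λ,
        so the original seed a is ejected (verified by enumerating moves)."""
        patients = [f"p{i}" for i in range(10)]
        cov = {
            "a": {"p0"},
            "b": {"p1", "p2", "p3"},
            "c": {"p0", "p4", "p5", "p6", "p7", "p8", "p9"},
        }
        m = matrix_from_coverage(cov, patients)
        net = build_network(m, 0.5)
        cand = grow_from_seeds(net, m, ("a", "b"), NBMParams(lambda_=0.5))
        assert cand.genes == ("b", "c")
        assert (cand.ed, cand.cd, cand.ecd) == (1.0, 1.0, 1.0)

    def test_grows_implanted_pathway_from_its_seeds(self):
        matrix, truth = generate(SimulationConfig(q=0.0, seed=11))
        net = build_network(matrix, 0.95)
        p1 = sorted(truth.pathways[0])
        cand = grow_from_seeds(net, matrix, (p1[0], p1[1]), NBMParams())
        assert set(cand.genes) == set(p1)
        assert cand.ed == 1.0

    def test_each_growth_step_strictly_increases_ecd(self):
        """Replaying the grown set by single moves shows a strict ECD chain."""
        matrix, truth = generate(SimulationConfig(q=0.0, seed=11))
        net = build_network(matrix, 0.95)
        p1 = sorted(truth.pathways[0])
        seeds = {p1[0], p1[1]}
        prev = metrics.ecd_exact(matrix, seeds)
        current = set(seeds)
        for g in p1[2:]:
            current.add(g)
            nxt = metrics.ecd_exact(matrix, current)
            assert nxt > prev
            prev = nxt


class TestRunNBM:
    def test_q0_recovers_implanted_pathways_with_their_coverage(self):
        matrix, truth = generate(SimulationConfig(q=0.0, seed=1))
        result = run_nbm(matrix)
        assert set(result.gene_sets) == set(truth.pathways)
        assert [p.ed for p in result.pathways] == [1.0] * 5
        assert [p.cd for p in result.pathways] == [0.95, 0.85, 0.75, 0.65, 0.55]

    def test_results_sorted_by_descending_ecd(self):
        matrix, _ = generate(SimulationConfig(q=0.0, seed=2))
        result = run_nbm(matrix)
        ecds = [p.ecd for p in result.pathways]
        assert ecds == sorted(ecds, reverse=True)

    def test_cooccurring_matrix_yields_no_pathways(self):
        patients = [f"p{i}" for i in range(10)]
        cov = {g: set(patients[:9]) for g in ("a", "b", "c")}
        result = run_nbm(matrix_from_coverage(cov, patients))
        assert result.pathways == []
        assert result.seeds_used == []

    def test_deterministic_across_repeat_runs(self):
        matrix, _ = generate(SimulationConfig(q=0.01, seed=9))
        r1 = run_nbm(matrix)
        r2 = run_nbm(matrix)
        assert [p.genes for p in r1.pathways] == [p.genes for p in r2.pathways]
        assert r1.seeds_used == r2.seeds_used

    def test_reported_pathways_respect_size_and_delta(self):
        matrix, _ = generate(SimulationConfig(q=0.01, seed=9))
        params = NBMParams()
        result = run_nbm(matrix, params)
        for p in result.pathways:
            assert p.size >= params.min_set_size
            assert p.cd >= params.delta
        for cand, reason in result.discarded:
            assert reason in ("too-small", "low-coverage")


class TestPermutationPvalue:
    def test_deterministic_under_fixed_seed(self, disjoint_pair_matrix):
        p1 = permutation_pvalue(disjoint_pair_matrix, ["gA", "gB"], 200, seed=3)
        p2 = permutation_pvalue(disjoint_pair_matrix, ["gA", "gB"], 200, seed=3)
        assert p1 == p2

    def test_maximal_observed_score_yields_minimal_pvalue(self):
        # Observed ECD is the theoretical maximum 1 (two genes partition the
        # 10 patients); a column-shuffle null matches it only when two random
        # 5-subsets happen to be disjoint (probability 1/252), so the add-one
        # estimate sits near its floor 1/(1+N).
        patients = [f"p{i}" for i in range(10)]
        m = matrix_from_coverage(
            {"gA": set(patients[:5]), "gB": set(patients[5:])}, patients
        )
        p = permutation_pvalue(m, ["gA", "gB"], 100, seed=0)
        assert 1 / 101 <= p <= 3 / 101

    def test_implanted_pathway_is_significant(self):
        matrix, truth = generate(SimulationConfig(q=0.01, seed=0))
        p = permutation_pvalue(matrix, sorted(truth.pathways[0]), 1000, seed=1)
        assert p < 0.05

    def test_rejects_nonpositive_permutations(self, disjoint_pair_matrix):
        with pytest.raises(ValueError):
            permutation_pvalue(disjoint_pair_matrix, ["gA"], 0)
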