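"""Implanted-pathway simulation for benchmarking pathway recovery.

Generates an m-patient × n-gene binary matrix containing a configurable
number of implanted, mutually exclusive driver pathways.  For pathway i
with coverage degree c_i, round(c_i·m) distinct patients are drawn
uniformly and each receives a driver mutation in exactly one uniformly
chosen gene of the pathway — so within a pathway the driver mutations are
mutually exclusive by construction and, with no passenger noise, ED = 1
and CD = c_i exactly.  Independent passenger mutations are then OR-ed into
every cell with probability q; raising q degrades the implanted
exclusivity and is the stressor for recovery benchmarks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .matrix_io import MutationMatrix

__all__ = ["SimulationConfig", "GroundTruth", "generate"]

NoiseScope = Literal["all", "nondriver_genes_only"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the implanted-pathway generator.

    Defaults are the standard benchmark conditions: 300 patients, 500
    genes, five 5-gene pathways with coverage degrees 0.95/0.85/0.75/
    0.65/0.55, and passenger probability q.
    """

    m: int = 300
    n: int = 500
    pathway_sizes: tuple[int, ...] = (5, 5, 5, 5, 5)
    coverage_degrees: tuple[float, ...] = (0.95, 0.85, 0.75, 0.65, 0.55)
    q: float = 0.0
    seed: int = 0
    noise_scope: NoiseScope = "all"

    def __post_init__(self) -> None:
        object.__setattr__(self, "pathway_sizes", tuple(self.pathway_sizes))
        object.__setattr__(self, "coverage_degrees", tuple(self.coverage_degrees))
        if self.m < 1 or self.n < 1:
            raise ValueError("m and n must be >= 1")
        if len(self.pathway_sizes) != len(self.coverage_degrees):
            raise ValueError("pathway_sizes and coverage_degrees must have equal length")
        if sum(self.pathway_sizes) > self.n:
            raise ValueError("implanted pathways need more genes than n provides")
        if any(s < 1 for s in self.pathway_sizes):
            raise ValueError("every pathway size must be >= 1")
        if any(not 0 <= c <= 1 for c in self.coverage_degrees):
            raise ValueError("coverage degrees must be in [0, 1]")
        if not 0 <= self.q <= 1:
            raise ValueError(f"q must be in [0, 1], got {self.q}")
        if self.noise_scope not in ("all", "nondriver_genes_only"):
            raise ValueError(f"unknown noise_scope {self.noise_scope!r}")


@dataclass(frozen=True)
class GroundTruth:
    """Implanted pathways and the exact driver cells, for recovery scoring."""

    pathways: tuple[frozenset[str], ...]
    driver_cells: frozenset[tuple[str, str]]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "pathways": [sorted(p) for p in self.pathways],
            "driver_cells": sorted(list(c) for c in self.driver_cells),
        }
        Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


def _labels(prefix: str, count: int) -> tuple[str, ...]:
    width = max(4, len(str(count)))
    return tuple(f"{prefix}{i + 1:0{width}d}" for i in range(count))


def generate(config: SimulationConfig) -> tuple[MutationMatrix, GroundTruth]:
    """Generate one simulated matrix with its ground truth.

    Fully reproducible for a fixed config (single seeded generator).
    Pathway gene positions are drawn at random among the n columns;
    patient draws for different pathways are independent, so a patient may
    host drivers of several pathways (exclusivity holds only within a
    pathway).
    """
    rng = np.random.default_rng(config.seed)
    patients = _labels("P", config.m)
    genes = _labels("G", config.n)
    entries = np.zeros((config.m, config.n), dtype=np.int8)

    n_pathway_genes = sum(config.pathway_sizes)
    gene_slots = rng.choice(config.n, size=n_pathway_genes, replace=False)
    pathways: list[frozenset[str]] = []
    driver_cells: set[tuple[str, str]] = set()
    offset = 0
    for size, cd in zip(config.pathway_sizes, config.coverage_degrees):
        member_cols = gene_slots[offset : offset + size]
        offset += size
        n_covered = round(cd * config.m)
        chosen_patients = rng.choice(config.m, size=n_covered, replace=False)
        chosen_genes = member_cols[rng.integers(0, size, size=n_covered)]
        entries[chosen_patients, chosen_genes] = 1
        pathways.append(frozenset(genes[c] for c in member_cols))
        driver_cells.update(
            (patients[i], genes[j]) for i, j in zip(chosen_patients, chosen_genes)
        )

    if config.q > 0:
        noise = rng.random((config.m, config.n)) < config.q
        if config.noise_scope == "nondriver_genes_only":
            noise[:, gene_slots] = False
        entries = np.where(noise, 1, entries).astype(np.int8)

    matrix = MutationMatrix(patients, genes, entries)
    return matrix, GroundTruth(tuple(pathways), frozenset(driver_cells))
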