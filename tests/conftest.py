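"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's incremental bookkeeping:
stability and the cut objective are recomputed from edge lists with plain
Python loops, so they can arbitrate what the fast path produces.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import settings

from bpmfind import (
    Bipartition,
    GeneGraph,
    InteractionRecord,
    InteractionTable,
    build_graph,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def random_table(n: int, density: float, rng: np.random.Generator) -> InteractionTable:
    """Random signed interaction table over genes g00..g<n-1>, connected enough
    that every gene appears in at least one record."""
    genes = [f"g{i:02d}" for i in range(n)]
    records = []
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < density:
            records.append(InteractionRecord(genes[i], genes[j], float(rng.normal())))
    covered = {g for r in records for g in (r.gene_a, r.gene_b)}
    # chain any uncovered gene to its neighbor so the table stays total
    for i, g in enumerate(genes):
        if g not in covered:
            other = genes[(i + 1) % n]
            a, b = sorted((g, other))
            records.append(InteractionRecord(a, b, float(rng.normal())))
            covered.update((a, b))
    return InteractionTable.from_records(records)


def random_graph(n: int, density: float, rng: np.random.Generator) -> GeneGraph:
    return build_graph(random_table(n, density, rng))


def brute_force_imbalance(graph: GeneGraph, sides: dict[str, int], v: str) -> float:
    """h(v) by direct summation over edges."""
    h = 0.0
    for u in graph.genes:
        if u == v:
            continue
        w = graph.weight(u, v)
        h += w if sides[u] == sides[v] else -w
    return h


def brute_force_objective(graph: GeneGraph, sides: dict[str, int]) -> float:
    """Φ = cross-weight sum minus within-weight sum, by direct summation."""
    phi = 0.0
    for u, v in itertools.combinations(graph.genes, 2):
        w = graph.weight(u, v)
        phi += w if sides[u] != sides[v] else -w
    return phi


def enumerate_stable_partitions(graph: GeneGraph, eps: float = 1e-9) -> set[bytes]:
    """All stable side assignments, as side-array bytes, by exhaustion.

    Both labelings of each stable cut are included so membership checks
    need no canonicalization.
    """
    n = len(graph.genes)
    stable: set[bytes] = set()
    for bits in itertools.product((0, 1), repeat=n):
        sides = dict(zip(graph.genes, bits))
        if all(brute_force_imbalance(graph, sides, v) >= -eps for v in graph.genes):
            stable.add(np.array(bits, dtype=np.int8).tobytes())
    return stable


def make_partition(graph: GeneGraph, bits) -> Bipartition:
    return Bipartition(genes=graph.genes, sides=np.asarray(bits, dtype=np.int8))


@pytest.fixture
def triangle_graph() -> GeneGraph:
    """Three genes: w(a,b)=1, w(a,c)=-2, w(b,c)=-2; unique nontrivial stable
    cut is {a,b} | {c}."""
    return build_graph(InteractionTable.from_records([
        InteractionRecord("a", "b", 1.0),
        InteractionRecord("a", "c", -2.0),
        InteractionRecord("b", "c", -2.0),
    ]))
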