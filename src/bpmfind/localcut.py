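"""Signed gene graph and randomized local max-cut search.

The model: genes are vertices, epistasis scores are signed edge weights.
A pair of compensatory pathways shows up as a bipartition whose cross edges
are strongly negative (aggravating) and whose within edges are positive
(alleviating), i.e. a bipartition (S, S̄) minimizing

    Φ(S) = Σ_{cross} w  −  Σ_{within} w .

Finding the global minimum is NP-hard (weighted max-cut), so the search
settles for *local* optima: a bipartition is stable when no single vertex
move improves Φ.  For a vertex v the imbalance

    h(v) = Σ_{u ~side v} w(u,v) − Σ_{u other side} w(u,v)

equals half the change in Φ if v switches sides (Φ_after − Φ_before =
2·h(v)), so stability means h(v) ≥ 0 for every v (≥ −eps with a numeric
tolerance).  Many independent random starts, each driven to a local
optimum, form the ensemble from which per-gene modules are read off.

Writing sides as x ∈ {±1}ⁿ and W for the symmetric weight matrix,
h = x ⊙ (Wx) and Φ = −½ xᵀWx; the search maintains g = Wx incrementally so
each vertex check is O(1) and each move O(deg v).
"""

from __future__ import annotations

import concurrent.futures
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .gi_io import InteractionTable

__all__ = [
    "GeneGraph",
    "Bipartition",
    "BipartitionEnsemble",
    "ConvergenceError",
    "DEFAULT_M",
    "DEFAULT_EPS",
    "build_graph",
    "imbalance",
    "cut_objective",
    "random_bipartition",
    "local_maxcut",
    "generate_ensemble",
]

#: default number of random restarts in the ensemble
DEFAULT_M = 250
#: stability tolerance: a vertex moves only when h(v) < -eps, which makes
#: every move decrease the objective by at least 2*eps and so guarantees
#: termination even with real-valued (tied) weights
DEFAULT_EPS = 1e-9


class ConvergenceError(RuntimeError):
    """Local search hit the sweep limit before reaching stability."""

    def __init__(self, message: str, partial: "Bipartition | None" = None):
        super().__init__(message)
        self.partial = partial


@dataclass(frozen=True, eq=False)
class GeneGraph:
    """Weighted undirected gene graph backed by a CSR adjacency matrix.

    ``genes`` fixes the vertex order; ``adjacency`` is symmetric with a zero
    diagonal (no self-loops; genes enter only via interaction records, so
    every vertex has at least one weighted neighbor).
    """

    genes: tuple[str, ...]
    adjacency: sp.csr_array

    @property
    def n(self) -> int:
        return len(self.genes)

    def index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except AttributeError:
            object.__setattr__(self, "_index", {g: i for i, g in enumerate(self.genes)})
            return self._index[gene]

    def weight(self, u: str, v: str) -> float:
        return float(self.adjacency[self.index(u), self.index(v)])


@dataclass(frozen=True)
class Bipartition:
    """Assignment of every graph gene to side 0 or side 1."""

    genes: tuple[str, ...]
    sides: np.ndarray  # int8, values in {0, 1}, aligned with genes

    def __post_init__(self) -> None:
        if len(self.sides) != len(self.genes):
            raise ValueError("sides array does not cover the gene list")

    def side(self, gene: str) -> int:
        return int(self.sides[self.genes.index(gene)])

    def as_dict(self) -> dict[str, int]:
        return {g: int(s) for g, s in zip(self.genes, self.sides)}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Bipartition):
            return NotImplemented
        return self.genes == other.genes and np.array_equal(self.sides, other.sides)

    def __hash__(self) -> int:
        return hash((self.genes, self.sides.tobytes()))


@dataclass(frozen=True)
class BipartitionEnsemble:
    """M stable bipartitions with the seeds that produced them."""

    partitions: tuple[Bipartition, ...]
    seeds: tuple[int, ...]

    @property
    def M(self) -> int:
        return len(self.partitions)

    @property
    def genes(self) -> tuple[str, ...]:
        return self.partitions[0].genes

    def side_matrix(self) -> np.ndarray:
        """(M, n) int8 matrix of sides, rows aligned with ``partitions``."""
        return np.stack([p.sides for p in self.partitions])


def build_graph(table: InteractionTable) -> GeneGraph:
    """Build the signed gene graph from a canonical interaction table."""
    if not table.records:
        raise ValueError("empty interaction table")
    genes = table.genes
    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    rows = np.empty(2 * len(table.records), dtype=np.int64)
    cols = np.empty_like(rows)
    data = np.empty(2 * len(table.records), dtype=np.float64)
    for k, rec in enumerate(table.records):
        i, j = index[rec.gene_a], index[rec.gene_b]
        rows[2 * k], cols[2 * k], data[2 * k] = i, j, rec.weight
        rows[2 * k + 1], cols[2 * k + 1], data[2 * k + 1] = j, i, rec.weight
    adj = sp.csr_array(sp.coo_array((data, (rows, cols)), shape=(n, n)))
    return GeneGraph(genes=genes, adjacency=adj)


def _signs(part: Bipartition) -> np.ndarray:
    """Sides {0,1} -> spins {+1,-1} (side 0 maps to +1)."""
    return np.where(part.sides == 0, 1.0, -1.0)


def imbalance(graph: GeneGraph, part: Bipartition, v: str) -> float:
    """Same-side minus other-side weight sum at vertex ``v``."""
    if v not in graph.genes:
        raise KeyError(f"gene {v!r} not in graph")
    i = graph.index(v)
    x = _signs(part)
    return float(x[i] * (graph.adjacency[[i], :] @ x)[0])


def cut_objective(graph: GeneGraph, part: Bipartition) -> float:
    """Φ = cross-edge weight sum minus within-edge weight sum (lower is better)."""
    x = _signs(part)
    return float(-0.5 * x @ (graph.adjacency @ x))


def random_bipartition(graph: GeneGraph, rng_seed: int) -> Bipartition:
    """Each gene lands on side 0 or 1 independently with probability 1/2."""
    rng = np.random.default_rng(rng_seed)
    sides = rng.integers(0, 2, size=graph.n, dtype=np.int8)
    return Bipartition(genes=graph.genes, sides=sides)


def local_maxcut(
    graph: GeneGraph,
    start: Bipartition,
    eps: float = DEFAULT_EPS,
    max_sweeps: int | None = None,
    rng_seed: int = 0,
    record_moves: bool = False,
) -> Bipartition | tuple[Bipartition, list[tuple[str, float]]]:
    """Drive ``start`` to a stable bipartition by single-vertex moves.

    Sweeps over vertices in a seeded random order (reshuffled each sweep),
    immediately flipping any vertex with imbalance < -eps; a sweep with no
    moves means every vertex is stable.  Each move lowers the cut objective
    by at least 2*eps, so termination is guaranteed; ``max_sweeps`` (default
    10*n) is a safety valve whose breach raises :class:`ConvergenceError`
    carrying the partial state.

    With ``record_moves=True`` also returns the accepted moves as
    ``(gene, imbalance-at-move-time)`` pairs, in order.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if start.genes != graph.genes:
        raise ValueError("bipartition does not cover this graph")
    n = graph.n
    if max_sweeps is None:
        max_sweeps = 10 * n
    rng = np.random.default_rng(rng_seed)
    A = graph.adjacency
    indptr, indices, data = A.indptr, A.indices, A.data
    x = _signs(start)
    g = A @ x
    moves: list[tuple[str, float]] = []
    for _ in range(max_sweeps):
        moved = False
        for v in rng.permutation(n):
            h = x[v] * g[v]
            if h < -eps:
                if record_moves:
                    moves.append((graph.genes[v], float(h)))
                x[v] = -x[v]
                lo, hi = indptr[v], indptr[v + 1]
                g[indices[lo:hi]] += 2.0 * x[v] * data[lo:hi]
                moved = True
        if not moved:
            sides = (x < 0).astype(np.int8)
            result = Bipartition(genes=graph.genes, sides=sides)
            return (result, moves) if record_moves else result
    partial = Bipartition(genes=graph.genes, sides=(x < 0).astype(np.int8))
    raise ConvergenceError(f"no stable bipartition within {max_sweeps} sweeps", partial)


def _one_partition(graph: GeneGraph, seed: int, eps: float) -> Bipartition:
    start = random_bipartition(graph, seed)
    return local_maxcut(graph, start, eps=eps, rng_seed=seed)


def generate_ensemble(
    graph: GeneGraph,
    M: int = DEFAULT_M,
    base_seed: int = 0,
    workers: int = 1,
    eps: float = DEFAULT_EPS,
) -> BipartitionEnsemble:
    """Produce M independent stable bipartitions from seeds base_seed+i.

    Restarts are embarrassingly parallel; results are collected by index, so
    the ensemble is identical for any ``workers`` count.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if workers < 1:
        raise ValueError("workers must be >= 1")
    seeds = tuple(base_seed + i for i in range(M))
    if workers == 1:
        partitions = [_one_partition(graph, s, eps) for s in seeds]
    else:
        with concurrent.futures.ProcessPoolExecutor(max_workers=workers) as pool:
            futures = [pool.submit(_one_partition, graph, s, eps) for s in seeds]
            try:
                partitions = [f.result() for f in futures]
            except ConvergenceError as exc:
                idx = next(i for i, f in enumerate(futures)
                           if f.done() and f.exception() is not None)
                raise ConvergenceError(f"partition {idx}: {exc}") from exc
    return BipartitionEnsemble(partitions=tuple(partitions), seeds=seeds)
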