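"""Per-gene BPM extraction from the bipartition ensemble, plus pruning.

Each stable bipartition in the ensemble is one noisy vote on which side of
a putative pathway pair every gene falls.  For a generating gene g, genes
that land on g's side in at least a fraction C of the M restarts join g's
module; genes that land opposite g at least C of the time form the partner
module.  With C > 0.5 the two criteria are mutually exclusive, so the
modules are disjoint by construction.

The raw per-gene candidates are heavily redundant (genes in the same
pathway generate near-identical BPMs), so the candidate list is pruned:
first by module size (very small modules are uninformative, very large ones
are unspecific), then greedily by pairwise Jaccard similarity of the
flattened gene sets so that every surviving pair overlaps less than J.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .gi_io import BPM, InteractionTable
from .localcut import (
    DEFAULT_EPS,
    BipartitionEnsemble,
    build_graph,
    generate_ensemble,
)

logger = logging.getLogger("bpmfind")

__all__ = [
    "PruneParams",
    "cooccurrence_fractions",
    "extract_bpm",
    "jaccard",
    "prune_size",
    "prune_overlap",
    "run_pipeline",
]


@dataclass(frozen=True)
class PruneParams:
    """Extraction and pruning thresholds.

    C: minimum co-occurrence fraction for module membership (default 0.9;
       lowering it towards 0.8 admits more genes and yields more BPMs at the
       cost of noisier modules).  Must exceed 0.5 so modules stay disjoint.
    J: Jaccard-similarity ceiling for the final BPM list (default 0.66).
    min_size/max_size: inclusive bounds on each module's gene count
       (defaults 3 and 25).
    """

    C: float = 0.9
    J: float = 0.66
    min_size: int = 3
    max_size: int = 25

    def __post_init__(self) -> None:
        if not 0.5 < self.C <= 1:
            raise ValueError("C must lie in (0.5, 1]")
        if not 0 < self.J <= 1:
            raise ValueError("J must lie in (0, 1]")
        if not 1 <= self.min_size <= self.max_size:
            raise ValueError("need 1 <= min_size <= max_size")


def cooccurrence_fractions(ensemble: BipartitionEnsemble, g: str) -> dict[str, float]:
    """Fraction of ensemble partitions placing each gene on g's side.

    ``fractions[g] == 1.0`` by construction.
    """
    genes = ensemble.genes
    if g not in genes:
        raise KeyError(f"gene {g!r} not in ensemble")
    S = ensemble.side_matrix()
    gi = genes.index(g)
    frac = (S == S[:, [gi]]).mean(axis=0)
    return {gene: float(f) for gene, f in zip(genes, frac)}


def _extract_from_fracs(genes: tuple[str, ...], frac: np.ndarray, g: str, C: float) -> BPM | None:
    with_g = frac >= C
    against_g = (1.0 - frac) >= C
    module2 = tuple(gene for gene, m in zip(genes, against_g) if m)
    if not module2:
        return None
    module1 = tuple(gene for gene, m in zip(genes, with_g) if m)
    return BPM(module1=module1, module2=module2, generator=g)


def extract_bpm(ensemble: BipartitionEnsemble, g: str, C: float = 0.9) -> BPM | None:
    """Build gene g's candidate BPM, or None when no gene opposes g often enough.

    module1 = genes with g at least a fraction C of the time (g itself has
    fraction 1); module2 = genes opposite g at least C of the time.  Raising
    C can only shrink the modules (membership is monotone in C).
    """
    if not 0 < C <= 1:
        raise ValueError("C must lie in (0, 1]")
    genes = ensemble.genes
    if g not in genes:
        raise KeyError(f"gene {g!r} not in ensemble")
    S = ensemble.side_matrix()
    frac = (S == S[:, [genes.index(g)]]).mean(axis=0)
    return _extract_from_fracs(genes, frac, g, C)


def jaccard(x: BPM, y: BPM) -> float:
    """Jaccard index of the flattened gene sets of two BPMs."""
    gx, gy = x.genes, y.genes
    union = gx | gy
    if not union:
        raise ValueError("both BPMs are empty")
    return len(gx & gy) / len(union)


def prune_size(bpms: list[BPM], min_size: int = 3, max_size: int = 25) -> list[BPM]:
    """Keep BPMs whose module sizes both lie in [min_size, max_size] (inclusive)."""
    return [
        b for b in bpms
        if min_size <= len(b.module1) <= max_size and min_size <= len(b.module2) <= max_size
    ]


def prune_overlap(bpms: list[BPM], J: float = 0.66) -> list[BPM]:
    """Greedy redundancy pruning: all surviving pairs have Jaccard < J.

    Candidates are ranked by descending total gene count (ties by the
    lexicographically smallest generating gene, then by module content) so
    the largest representative of each overlapping family survives and the
    outcome is independent of input order.
    """
    if not 0 < J <= 1:
        raise ValueError("J must lie in (0, 1]")
    ranked = sorted(
        bpms,
        key=lambda b: (-b.size, b.generator if b.generator is not None else "", b.module1, b.module2),
    )
    kept: list[BPM] = []
    for cand in ranked:
        if all(jaccard(cand, k) < J for k in kept):
            kept.append(cand)
    return kept


def run_pipeline(
    table: InteractionTable,
    M: int = 250,
    params: PruneParams = PruneParams(),
    base_seed: int = 0,
    workers: int = 1,
    eps: float = DEFAULT_EPS,
) -> list[BPM]:
    """Full discovery pipeline: graph -> ensemble -> per-gene BPMs -> pruning.

    Deterministic given (M, base_seed) regardless of ``workers``.
    """
    graph = build_graph(table)
    logger.info("graph: %d genes, %d interactions", graph.n, graph.adjacency.nnz // 2)
    ensemble = generate_ensemble(graph, M=M, base_seed=base_seed, workers=workers, eps=eps)
    genes = ensemble.genes
    S = ensemble.side_matrix()
    candidates: list[BPM] = []
    for i, g in enumerate(genes):
        frac = (S == S[:, [i]]).mean(axis=0)
        bpm = _extract_from_fracs(genes, frac, g, params.C)
        if bpm is not None:
            candidates.append(bpm)
    logger.info("%d candidate BPMs from %d genes", len(candidates), len(genes))
    sized = prune_size(candidates, params.min_size, params.max_size)
    logger.info("%d BPMs after size pruning [%d, %d]", len(sized), params.min_size, params.max_size)
    final = prune_overlap(sized, params.J)
    logger.info("%d BPMs after overlap pruning (J < %g)", len(final), params.J)
    return final
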