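"""Synthetic interaction tables with planted between-pathway structure.

The generator emulates the signature the discovery algorithm looks for: for
each planted pathway pair, every within-set gene pair gets a positive
(alleviating) score and every between-set pair a negative (aggravating)
score, both jittered with Gaussian noise; background gene pairs carry
zero-mean noise edges at a chosen density, so the planted pairs are the
only systematic structure.  Recovery is scored side-aware, since BPM module
labels are arbitrary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .gi_io import BPM, InteractionRecord, InteractionTable

__all__ = ["PlantSpec", "generate_planted_table", "recovery_score"]


@dataclass(frozen=True)
class PlantSpec:
    """Parameters of a planted-BPM interaction table.

    pathway_pairs: module sizes (a, b) of each planted pathway pair.
    within_weight (> 0) / between_weight (< 0): mean scores inside a module
        and across the pair.
    background_genes: number of genes outside any planted set.
    noise_sd: Gaussian sd added to every edge weight.
    edge_density: probability that a background-touching pair gets an edge.
    """

    pathway_pairs: tuple[tuple[int, int], ...] = ((5, 5),)
    within_weight: float = 1.0
    between_weight: float = -1.0
    background_genes: int = 40
    noise_sd: float = 0.1
    edge_density: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pathway_pairs:
            raise ValueError("need at least one planted pathway pair")
        if any(a < 1 or b < 1 for a, b in self.pathway_pairs):
            raise ValueError("planted module sizes must be >= 1")
        if not (self.within_weight > 0 > self.between_weight):
            raise ValueError("need within_weight > 0 > between_weight")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.edge_density <= 1:
            raise ValueError("edge_density must lie in [0, 1]")


def generate_planted_table(spec: PlantSpec) -> tuple[InteractionTable, list[BPM]]:
    """Generate an interaction table and its ground-truth BPM list.

    Gene names: pathway genes are ``P<i>A<j>`` / ``P<i>B<j>`` for pair i,
    background genes ``BG<j>``; planted sets are disjoint by construction.
    Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    truth: list[BPM] = []
    records: list[InteractionRecord] = []

    def noisy(mean: float) -> float:
        return float(mean + rng.normal(0.0, spec.noise_sd)) if spec.noise_sd > 0 else mean

    planted_sets: list[tuple[str, ...]] = []
    for i, (a, b) in enumerate(spec.pathway_pairs):
        mod1 = tuple(f"P{i}A{j}" for j in range(a))
        mod2 = tuple(f"P{i}B{j}" for j in range(b))
        truth.append(BPM(module1=mod1, module2=mod2, generator=mod1[0]))
        planted_sets.extend([mod1, mod2])
        for side in (mod1, mod2):
            for u, v in itertools.combinations(side, 2):
                records.append(_record(u, v, noisy(spec.within_weight)))
        for u in mod1:
            for v in mod2:
                records.append(_record(u, v, noisy(spec.between_weight)))

    # background genes carry only zero-mean noise edges among themselves, so
    # the planted pairs remain the only systematic (and only cross-component)
    # structure; a background gene drawing no edge simply stays out of the table
    background = tuple(f"BG{j}" for j in range(spec.background_genes))
    for u, v in itertools.combinations(background, 2):
        if rng.random() < spec.edge_density:
            records.append(_record(u, v, float(rng.normal(0.0, spec.noise_sd))))

    return InteractionTable.from_records(records), truth


def _record(u: str, v: str, w: float) -> InteractionRecord:
    return InteractionRecord(*sorted((u, v)), w)


def _module_jaccard(a: tuple[str, ...], b: tuple[str, ...]) -> float:
    sa, sb = set(a), set(b)
    union = sa | sb
    return len(sa & sb) / len(union) if union else 1.0


def recovery_score(predicted: list[BPM], truth: list[BPM]) -> list[float]:
    """Per-truth best recovery: side-aware mean per-module Jaccard.

    For each true BPM the score is the maximum over predictions of the mean
    of the two module-wise Jaccard indices, taken under the better of the
    two side alignments (module labels carry no meaning).  1.0 is exact
    recovery; an empty prediction list scores 0.0 everywhere.
    """
    if not truth:
        raise ValueError("truth list must be non-empty")
    scores = []
    for t in truth:
        best = 0.0
        for p in predicted:
            direct = 0.5 * (_module_jaccard(t.module1, p.module1) + _module_jaccard(t.module2, p.module2))
            swapped = 0.5 * (_module_jaccard(t.module1, p.module2) + _module_jaccard(t.module2, p.module1))
            best = max(best, direct, swapped)
        scores.append(best)
    return scores
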