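"""Reading and writing genetic-interaction data and BPM files.

Genetic-interaction (GI) files are plain tab-delimited text: one row per
assayed gene pair, with the first two columns holding gene identifiers and
the third a real-valued epistasis score (negative = the double mutant is
sicker than expected, positive = healthier).  Identifiers are opaque,
case-sensitive strings; the format is species-agnostic.

BPM files pair up gene sets two lines at a time::

    bpm0/module1\tGENE1\tGENE2\t...
    bpm0/module2\tGENE7\tGENE8\t...

This module canonicalizes GI input (sorted pairs, merged duplicates, no
self-pairs) so that downstream graph construction is deterministic
regardless of row order in the source file.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

__all__ = [
    "ParseError",
    "InteractionRecord",
    "InteractionTable",
    "BPM",
    "parse_interactions",
    "read_exclusions",
    "transform_weights",
    "write_bpms",
    "read_bpms",
]

logger = logging.getLogger("bpmfind")


class ParseError(ValueError):
    """Raised for malformed GI, BPM, exclusion or association input."""


@dataclass(frozen=True)
class InteractionRecord:
    """One scored gene pair, stored with ``gene_a < gene_b`` lexicographically."""

    gene_a: str
    gene_b: str
    weight: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-interaction {self.gene_a!r}")
        if self.gene_a > self.gene_b:
            raise ValueError("record not in canonical order")
        if not math.isfinite(self.weight):
            raise ValueError(f"non-finite weight for ({self.gene_a}, {self.gene_b})")


@dataclass(frozen=True)
class InteractionTable:
    """Canonical, deduplicated set of interaction records.

    ``records`` are sorted by gene pair and ``genes`` is the sorted union of
    all identifiers, so two tables built from permutations of the same rows
    compare equal.
    """

    records: tuple[InteractionRecord, ...]
    genes: tuple[str, ...]

    @classmethod
    def from_records(cls, records: Iterable[InteractionRecord]) -> "InteractionTable":
        recs = tuple(sorted(records, key=lambda r: (r.gene_a, r.gene_b)))
        genes = tuple(sorted({g for r in recs for g in (r.gene_a, r.gene_b)}))
        return cls(records=recs, genes=genes)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class BPM:
    """A between-pathway module: an ordered pair of disjoint gene sets.

    ``generator`` records which gene seeded the module during extraction; it
    is metadata and does not participate in equality (the on-disk format
    does not store it).
    """

    module1: tuple[str, ...]
    module2: tuple[str, ...]
    generator: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if set(self.module1) & set(self.module2):
            raise ValueError("BPM modules must be disjoint")
        if self.generator is not None and self.generator not in self.module1:
            raise ValueError("generating gene must lie in module1")

    @property
    def genes(self) -> frozenset[str]:
        """Flattened gene set of both modules."""
        return frozenset(self.module1) | frozenset(self.module2)

    @property
    def size(self) -> int:
        return len(self.module1) + len(self.module2)


def _parse_score(text: str) -> float | None:
    """Return the score, None if blank/non-finite, or raise ValueError."""
    text = text.strip()
    if not text:
        return None
    value = float(text)  # may raise ValueError
    if not math.isfinite(value):
        return None
    return value


def parse_interactions(
    source: IO[str] | Iterable[str],
    exclude: frozenset[str] | set[str] = frozenset(),
) -> InteractionTable:
    """Parse a 3+-column tab-delimited GI stream into a canonical table.

    Blank lines and ``#`` comments are skipped.  A header is tolerated only
    on the first data line (detected when column 3 is not numeric there).
    Self-pairs, rows touching ``exclude``d genes and rows with blank or
    non-finite scores are dropped with a warning; duplicate unordered pairs
    are merged by averaging their scores.

    Raises :class:`ParseError` (naming the line) for rows with fewer than 3
    columns or an unparseable score, and if nothing survives filtering.
    """
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    n_self = n_excluded = n_missing = n_dup = 0
    first_data_line = True

    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"line {lineno}: expected >=3 tab-separated columns, got {len(fields)}")
        a, b, score_text = fields[0].strip(), fields[1].strip(), fields[2]
        try:
            weight = _parse_score(score_text)
        except ValueError:
            if first_data_line:
                logger.warning("line %d looks like a header; skipping", lineno)
                first_data_line = False
                continue
            raise ParseError(f"line {lineno}: cannot parse score {score_text!r}") from None
        first_data_line = False
        if not a or not b:
            raise ParseError(f"line {lineno}: empty gene identifier")
        if weight is None:
            n_missing += 1
            continue
        if a == b:
            n_self += 1
            continue
        if a in exclude or b in exclude:
            n_excluded += 1
            continue
        pair = (a, b) if a < b else (b, a)
        if pair in sums:
            n_dup += 1
        sums[pair] = sums.get(pair, 0.0) + weight
        counts[pair] = counts.get(pair, 0) + 1

    if n_self:
        logger.warning("dropped %d self-interaction row(s)", n_self)
    if n_missing:
        logger.warning("dropped %d row(s) with blank or non-finite scores", n_missing)
    if n_excluded:
        logger.warning("dropped %d row(s) touching excluded genes", n_excluded)
    if n_dup:
        logger.warning("merged %d duplicate gene-pair row(s) by averaging", n_dup)
    if not sums:
        raise ParseError("no interactions left after filtering")

    records = (
        InteractionRecord(a, b, sums[(a, b)] / counts[(a, b)])
        for (a, b) in sums
    )
    return InteractionTable.from_records(records)


def read_exclusions(source: IO[str] | Iterable[str]) -> frozenset[str]:
    """Read a gene-exclusion list: one identifier per line, ``#`` comments allowed."""
    out = set()
    for raw in source:
        line = raw.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return frozenset(out)


def transform_weights(table: InteractionTable, mode: str) -> InteractionTable:
    """Apply a weight transform: ``identity`` or ``signed_square`` (w -> sign(w)*w^2).

    Signed squaring is the conventional preprocessing for E-MAP scores: it
    sharpens the separation between strong and weak interactions, which
    speeds convergence of the local search, while leaving the sign (and so
    the alleviating/aggravating interpretation) intact.
    """
    if mode == "identity":
        return table
    if mode == "signed_square":
        return InteractionTable.from_records(
            InteractionRecord(r.gene_a, r.gene_b, math.copysign(r.weight * r.weight, r.weight))
            for r in table.records
        )
    raise ValueError(f"unknown weight transform {mode!r}")


def write_bpms(bpms: Sequence[BPM], sink: IO[str]) -> None:
    """Write BPMs in the two-lines-per-module tab-delimited format."""
    if not bpms:
        raise ValueError("refusing to write an empty BPM list")
    for i, bpm in enumerate(bpms):
        sink.write(f"bpm{i}/module1\t" + "\t".join(bpm.module1) + "\n")
        sink.write(f"bpm{i}/module2\t" + "\t".join(bpm.module2) + "\n")


def read_bpms(source: IO[str] | Iterable[str]) -> list[BPM]:
    """Parse a BPM file; exact inverse of :func:`write_bpms`.

    Module lines must come in matched ``bpm<i>/module1`` / ``bpm<i>/module2``
    pairs; an orphan line or an id mismatch is a :class:`ParseError`.
    """
    pending: tuple[str, tuple[str, ...]] | None = None
    bpms: list[BPM] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        head, *genes = line.split("\t")
        if "/" not in head:
            raise ParseError(f"line {lineno}: malformed BPM label {head!r}")
        bpm_id, module_id = head.split("/", 1)
        if module_id == "module1":
            if pending is not None:
                raise ParseError(f"line {lineno}: module1 line while {pending[0]} lacks a module2")
            pending = (bpm_id, tuple(genes))
        elif module_id == "module2":
            if pending is None or pending[0] != bpm_id:
                raise ParseError(f"line {lineno}: module2 line for {bpm_id!r} without matching module1")
            bpms.append(BPM(module1=pending[1], module2=tuple(genes)))
            pending = None
        else:
            raise ParseError(f"line {lineno}: unknown module id {module_id!r}")
    if pending is not None:
        raise ParseError(f"BPM {pending[0]!r} has a module1 line but no module2")
    return bpms
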