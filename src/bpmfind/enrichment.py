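"""Offline GO-term enrichment for BPM modules.

Each module is tested for over-representation of every annotation term with
a one-sided hypergeometric tail: drawing n = |module| genes from a
genespace of N genes of which K carry the term, the raw p-value is
P(X >= k) for the observed k term-carrying module genes.

Multiple testing across terms and modules is handled the way simulation-
based enrichment services do it: for every module size present, draw random
gene sets of that size from the genespace, record each draw's minimum raw
p-value over all terms, and correct an observed p against that min-p null
distribution,

    p_corr = (1 + #{draws with min-p <= p_raw}) / (1 + n_simulations).

This is a family-wise error-rate control in the spirit of Westfall-Young
min-p resampling; with random annotations the corrected p-values are valid
(conservative) by construction.

A BPM is *dually enriched* when both modules retain at least one term at
the corrected cutoff, *singly enriched* when exactly one does.

Networked enrichment services are deliberately out of scope; the only
remote-facing piece is :func:`build_enrichment_request`, which shapes the
query payload (genespace, namespace, cutoff, simulations) without sending it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from .gi_io import BPM, ParseError

__all__ = [
    "AssociationMap",
    "EnrichmentParams",
    "EnrichmentEntry",
    "EnrichmentReport",
    "parse_associations",
    "module_enrichment",
    "resampling_correction",
    "choose_simulations",
    "enrich_bpms",
    "build_enrichment_request",
]

#: resampling floor/ceiling used by simulation-based enrichment services
MIN_SIMULATIONS = 1000
MAX_SIMULATIONS = 10000


@dataclass(frozen=True)
class AssociationMap:
    """Gene-to-term annotations restricted to a genespace."""

    term_genes: dict[str, frozenset[str]]
    term_names: dict[str, str]
    genespace: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genespace:
            raise ValueError("genespace must be non-empty")
        for term, genes in self.term_genes.items():
            if not genes <= self.genespace:
                raise ValueError(f"term {term!r} annotates genes outside the genespace")

    @property
    def terms(self) -> list[str]:
        return sorted(self.term_genes)


@dataclass(frozen=True)
class EnrichmentParams:
    """Cutoff and null-simulation settings.

    p_cutoff: corrected-p threshold for reporting a term (default 0.05).
    genespace_mode: 'input_genes' (background = genes of the interaction
        screen) or 'all_species_genes' (background = every annotated gene).
    n_simulations: resampling draws; None means the service rule
        min(10000, max(1000, number of modules)).
    """

    p_cutoff: float = 0.05
    genespace_mode: str = "input_genes"
    n_simulations: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.p_cutoff <= 1:
            raise ValueError("p_cutoff must lie in (0, 1]")
        if self.genespace_mode not in ("input_genes", "all_species_genes"):
            raise ValueError(f"unknown genespace mode {self.genespace_mode!r}")
        if self.n_simulations is not None and self.n_simulations < 1:
            raise ValueError("n_simulations must be >= 1")


@dataclass(frozen=True)
class EnrichmentEntry:
    bpm_index: int
    module_index: int  # 1 or 2
    term: str
    name: str
    k: int  # annotated genes in the module
    n: int  # module size
    raw_p: float
    corrected_p: float

    @property
    def fraction(self) -> str:
        """Annotated-over-size display form, e.g. '4/5'."""
        return f"{self.k}/{self.n}"


@dataclass(frozen=True)
class EnrichmentReport:
    entries: tuple[EnrichmentEntry, ...]
    dually_enriched: frozenset[int]
    singly_enriched: frozenset[int]

    def to_tsv(self, sink: IO[str]) -> None:
        sink.write("bpm\tmodule\tterm\tname\tk\tn\traw_p\tcorrected_p\n")
        for e in self.entries:
            sink.write(
                f"bpm{e.bpm_index}\tmodule{e.module_index}\t{e.term}\t{e.name}\t"
                f"{e.k}\t{e.n}\t{e.raw_p:.6g}\t{e.corrected_p:.6g}\n"
            )


def _looks_like_gaf(fields: list[str]) -> bool:
    return len(fields) >= 15


def parse_associations(
    source: IO[str] | Iterable[str],
    genespace: frozenset[str] | set[str],
) -> AssociationMap:
    """Parse gene-term associations from 2/3-column TSV or GAF 2.x.

    TSV rows are (gene, term accession[, term name]); GAF rows use the DB
    Object Symbol (column 3) as the gene and column 5 as the GO id (GAF
    carries no term names, so the accession doubles as the name).  Lines
    starting with ``!`` or ``#`` are comments.  The map is restricted to
    ``genespace``; terms annotating no genespace gene are dropped.
    """
    term_genes: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    genespace = frozenset(genespace)
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("!") or line.startswith("#"):
            continue
        fields = line.split("\t")
        if _looks_like_gaf(fields):
            gene, term, name = fields[2].strip(), fields[4].strip(), fields[4].strip()
        elif len(fields) >= 2:
            gene, term = fields[0].strip(), fields[1].strip()
            name = fields[2].strip() if len(fields) >= 3 and fields[2].strip() else term
        else:
            raise ParseError(f"line {lineno}: expected (gene, term[, name]) or GAF columns")
        if not gene or not term:
            raise ParseError(f"line {lineno}: empty gene or term field")
        if gene not in genespace:
            continue
        term_genes.setdefault(term, set()).add(gene)
        term_names.setdefault(term, name)
    return AssociationMap(
        term_genes={t: frozenset(g) for t, g in term_genes.items()},
        term_names={t: term_names[t] for t in term_genes},
        genespace=genespace,
    )


def module_enrichment(
    module: Iterable[str],
    assoc: AssociationMap,
) -> list[tuple[str, float]]:
    """Raw one-sided hypergeometric p per term with >=1 gene in the module.

    Returned sorted by (p, term).  A module gene outside the genespace is an
    error — the test is meaningless if the background does not contain it.
    """
    mod = frozenset(module)
    if not mod <= assoc.genespace:
        stray = sorted(mod - assoc.genespace)[:3]
        raise ValueError(f"module genes outside genespace: {stray}")
    N, n = len(assoc.genespace), len(mod)
    out = []
    for term, annotated in assoc.term_genes.items():
        k = len(annotated & mod)
        if k == 0:
            continue
        p = float(hypergeom.sf(k - 1, N, len(annotated), n))
        out.append((term, min(p, 1.0)))
    out.sort(key=lambda tp: (tp[1], tp[0]))
    return out


def choose_simulations(n_modules: int) -> int:
    """Null-simulation count: at least 1000 draws, capped at 10000."""
    if n_modules < 0:
        raise ValueError("n_modules must be >= 0")
    return min(MAX_SIMULATIONS, max(MIN_SIMULATIONS, n_modules))


def _minp_null(
    assoc: AssociationMap,
    size: int,
    n_simulations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sorted min-p distribution for random genespace subsets of one size."""
    genes = sorted(assoc.genespace)
    N = len(genes)
    terms = assoc.terms
    if not terms or size == 0:
        return np.ones(n_simulations)
    # incidence matrix and per-term tail-probability lookup tables
    A = np.zeros((len(terms), N), dtype=np.int8)
    gene_idx = {g: i for i, g in enumerate(genes)}
    tables = np.ones((len(terms), size + 1))
    for t, term in enumerate(terms):
        K = len(assoc.term_genes[term])
        for g in assoc.term_genes[term]:
            A[t, gene_idx[g]] = 1
        ks = np.arange(1, min(K, size) + 1)
        tables[t, ks] = np.clip(hypergeom.sf(ks - 1, N, K, size), 0.0, 1.0)
        tables[t, min(K, size) + 1:] = tables[t, min(K, size)]
    draws = np.zeros((n_simulations, N), dtype=np.int8)
    for s in range(n_simulations):
        draws[s, rng.choice(N, size=size, replace=False)] = 1
    counts = (A @ draws.T).astype(np.int64)  # (terms, sims)
    pvals = np.take_along_axis(tables, counts, axis=1)
    return np.sort(pvals.min(axis=0))


def resampling_correction(
    modules: Sequence[frozenset[str] | set[str]],
    assoc: AssociationMap,
    n_simulations: int,
    rng_seed: int = 0,
) -> list[dict[str, float]]:
    """Min-p resampling correction for each (module, term) raw p-value.

    For every distinct module size, ``n_simulations`` random genespace
    subsets of that size are drawn and each draw's minimum raw p over all
    terms recorded; the corrected p of an observed raw p is
    ``(1 + #{min-p <= raw p}) / (1 + n_simulations)``.  Deterministic per
    seed; corrected p is non-decreasing in raw p.
    """
    if n_simulations < 1:
        raise ValueError("n_simulations must be >= 1")
    sizes = sorted({len(m) for m in modules})
    nulls: dict[int, np.ndarray] = {}
    for size in sizes:  # one seeded stream per size keeps results stable
        rng = np.random.default_rng([rng_seed, size])
        nulls[size] = _minp_null(assoc, size, n_simulations, rng)
    out: list[dict[str, float]] = []
    for mod in modules:
        null = nulls[len(mod)]
        corrected = {}
        for term, raw_p in module_enrichment(mod, assoc):
            count = int(np.searchsorted(null, raw_p, side="right"))
            corrected[term] = (1 + count) / (1 + n_simulations)
        out.append(corrected)
    return out


def enrich_bpms(
    bpms: Sequence[BPM],
    assoc: AssociationMap,
    params: EnrichmentParams = EnrichmentParams(),
    rng_seed: int = 0,
) -> EnrichmentReport:
    """Enrich every module of every BPM and flag dual/single enrichment.

    The simulation count defaults to the service rule applied to the number
    of modules (two per BPM).  Only terms with corrected p <= ``p_cutoff``
    are reported.
    """
    modules: list[frozenset[str]] = []
    keys: list[tuple[int, int]] = []
    for i, bpm in enumerate(bpms):
        for j, mod in enumerate((bpm.module1, bpm.module2), start=1):
            modules.append(frozenset(mod))
            keys.append((i, j))
    n_sim = params.n_simulations or choose_simulations(len(modules))
    raw = [dict(module_enrichment(m, assoc)) for m in modules]
    corrected = resampling_correction(modules, assoc, n_sim, rng_seed)
    entries: list[EnrichmentEntry] = []
    enriched_modules: set[tuple[int, int]] = set()
    for (i, j), mod, raw_p, corr in zip(keys, modules, raw, corrected):
        for term in sorted(corr, key=lambda t: (corr[t], t)):
            if corr[term] <= params.p_cutoff:
                enriched_modules.add((i, j))
                entries.append(EnrichmentEntry(
                    bpm_index=i,
                    module_index=j,
                    term=term,
                    name=assoc.term_names.get(term, term),
                    k=len(assoc.term_genes[term] & mod),
                    n=len(mod),
                    raw_p=raw_p[term],
                    corrected_p=corr[term],
                ))
    dual, single = set(), set()
    for i in range(len(bpms)):
        hits = sum(((i, j) in enriched_modules) for j in (1, 2))
        if hits == 2:
            dual.add(i)
        elif hits == 1:
            single.add(i)
    return EnrichmentReport(
        entries=tuple(entries),
        dually_enriched=frozenset(dual),
        singly_enriched=frozenset(single),
    )


def build_enrichment_request(
    modules: Sequence[Iterable[str]],
    genespace: Iterable[str],
    params: EnrichmentParams,
    species: str = "Saccharomyces cerevisiae",
    namespace: str = "sgd_systematic",
) -> dict:
    """Shape (but do not send) a query payload for a remote enrichment service.

    Mirrors the parameter semantics of simulation-based GO services: the
    gene sets to test, the background genespace, the reporting cutoff and
    the simulation count.  Callers wanting live enrichment can serialize
    this dict; no network code lives in this package.
    """
    return {
        "species": species,
        "namespace": namespace,
        "genespace": sorted(set(genespace)),
        "query_sets": [sorted(set(m)) for m in modules],
        "p_value_cutoff": params.p_cutoff,
        "simulations": params.n_simulations or choose_simulations(len(modules)),
    }
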