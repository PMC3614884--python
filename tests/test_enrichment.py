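"""Hypergeometric enrichment, resampling correction and report assembly."""

import io
import itertools
import math

import numpy as np
import pytest

from bpmfind import (
    BPM,
    AssociationMap,
    EnrichmentParams,
    build_enrichment_request,
    choose_simulations,
    enrich_bpms,
    module_enrichment,
    parse_associations,
    resampling_correction,
)


def exhaustive_tail_p(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by enumerating all C(N, n) draws — independent oracle."""
    hits = total = 0
    annotated = set(range(K))
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(annotated & set(draw)) >= k:
            hits += 1
    return hits / total


def simple_assoc(term_genes: dict, genespace) -> AssociationMap:
    return AssociationMap(
        term_genes={t: frozenset(g) for t, g in term_genes.items()},
        term_names={t: t for t in term_genes},
        genespace=frozenset(genespace),
    )


class TestParseAssociations:
    def test_three_column_tsv(self):
        src = io.StringIO("A\tGO:1\talpha\nB\tGO:1\talpha\nC\tGO:2\tbeta\n")
        assoc = parse_associations(src, {"A", "B", "C"})
        assert assoc.term_genes == {"GO:1": {"A", "B"}, "GO:2": {"C"}}
        assert assoc.term_names["GO:2"] == "beta"

    def test_terms_outside_genespace_dropped(self):
        src = io.StringIO("A\tGO:1\talpha\nC\tGO:2\tbeta\n")
        assoc = parse_associations(src, {"A"})
        assert set(assoc.term_genes) == {"GO:1"}

    def test_gaf_style_rows_and_comments(self):
        cols = ["SGD", "S0001", "ACT1", "", "GO:0005", "ref", "IDA", "", "C",
                "actin", "", "gene", "taxon:4932", "20200101", "SGD"]
        src = io.StringIO("!gaf-version: 2.2\n" + "\t".join(cols) + "\n")
        assoc = parse_associations(src, {"ACT1", "CDC28"})
        assert assoc.term_genes == {"GO:0005": {"ACT1"}}

    def test_malformed_row(self):
        from bpmfind import ParseError
        with pytest.raises(ParseError, match="line 1"):
            parse_associations(io.StringIO("just-one-column\n"), {"A"})


class TestModuleEnrichment:
    def test_worked_example(self):
        """Module of 5 in a genespace of 20; a term annotating 5 genes, 4 of
        them in the module: p = 76/15504."""
        genespace = [f"g{i}" for i in range(20)]
        term = genespace[:5]
        module = term[:4] + [genespace[10]]
        assoc = simple_assoc({"GO:x": term}, genespace)
        [(_, p)] = module_enrichment(module, assoc)
        assert p == pytest.approx(76 / 15504, rel=1e-12)

    def test_matches_exhaustive_oracle_small_genespace(self):
        """Raw tail p agrees with full enumeration over all C(N,n) draws."""
        for N, K, n in [(8, 3, 4), (10, 4, 5), (12, 6, 4), (9, 2, 3)]:
            genespace = [f"g{i}" for i in range(N)]
            assoc = simple_assoc({"T": genespace[:K]}, genespace)
            for k in range(1, min(K, n) + 1):
                module = genespace[:k] + genespace[K:K + (n - k)]
                [(_, p)] = module_enrichment(module, assoc)
                assert math.isclose(p, exhaustive_tail_p(N, K, n, k), abs_tol=1e-12)

    def test_unannotated_term_not_reported(self):
        genespace = list("ABCDEF")
        assoc = simple_assoc({"T1": ["A"], "T2": ["F"]}, genespace)
        out = module_enrichment(["A", "B"], assoc)
        assert [t for t, _ in out] == ["T1"]

    def test_universal_term_has_p_one(self):
        genespace = list("ABCDEF")
        assoc = simple_assoc({"T": genespace}, genespace)
        [(_, p)] = module_enrichment(["A", "B", "C"], assoc)
        assert p == 1.0

    def test_module_outside_genespace_errors(self):
        assoc = simple_assoc({"T": ["A"]}, ["A", "B"])
        with pytest.raises(ValueError):
            module_enrichment(["A", "Z"], assoc)


class TestChooseSimulations:
    @pytest.mark.parametrize("n,expected", [(44, 1000), (2500, 2500), (20000, 10000),
                                            (0, 1000), (1000, 1000), (10000, 10000)])
    def test_rule(self, n, expected):
        assert choose_simulations(n) == expected


class TestResamplingCorrection:
    genespace = [f"g{i}" for i in range(30)]

    def _assoc(self):
        return simple_assoc(
            {"T1": self.genespace[:6], "T2": self.genespace[6:12]}, self.genespace
        )

    def test_tiny_raw_p_hits_floor(self):
        """A raw p below every simulated min-p corrects to 1/(n_sim+1)."""
        assoc = self._assoc()
        module = frozenset(self.genespace[:6])  # all of T1: smallest possible p
        [corr] = resampling_correction([module], assoc, n_simulations=50, rng_seed=0)
        assert corr["T1"] == pytest.approx(1 / 51)

    def test_raw_p_one_corrects_to_one(self):
        genespace = list("ABCDEFGH")
        assoc = simple_assoc({"T": genespace}, genespace)
        [corr] = resampling_correction([frozenset("ABC")], assoc, 25, rng_seed=1)
        assert corr["T"] == 1.0

    def test_monotone_in_raw_p(self):
        assoc = self._assoc()
        module = frozenset(self.genespace[:4] + self.genespace[6:8])  # hits T1 and T2
        [corr] = resampling_correction([module], assoc, 200, rng_seed=2)
        from scipy.stats import hypergeom
        raw = {t: float(hypergeom.sf(k - 1, 30, 6, 6))
               for t, k in [("T1", 4), ("T2", 2)]}
        assert raw["T1"] < raw["T2"]
        assert corr["T1"] <= corr["T2"]

    def test_deterministic_per_seed(self):
        assoc = self._assoc()
        module = frozenset(self.genespace[:5])
        a = resampling_correction([module], assoc, 100, rng_seed=3)
        b = resampling_correction([module], assoc, 100, rng_seed=3)
        assert a == b

    def test_null_calibration(self):
        """With random annotations, corrected p <= 0.05 occurs for at most
        ~5% of modules (the correction is a valid family-wise test)."""
        rng = np.random.default_rng(17)
        genespace = [f"g{i}" for i in range(40)]
        false_hits = trials = 0
        for _ in range(100):
            terms = {f"T{j}": rng.choice(genespace, size=8, replace=False) for j in range(6)}
            assoc = simple_assoc(terms, genespace)
            module = frozenset(rng.choice(genespace, size=5, replace=False))
            [corr] = resampling_correction([module], assoc, 99,
                                           rng_seed=int(rng.integers(2**31)))
            trials += 1
            if corr and min(corr.values()) <= 0.05:
                false_hits += 1
        assert false_hits / trials <= 0.08


class TestEnrichBpms:
    def _setup(self):
        genespace = [f"g{i}" for i in range(24)]
        # two informative terms matching the two modules of bpm 0
        assoc = simple_assoc(
            {"T1": genespace[:4], "T2": genespace[4:8], "T3": genespace[20:23]},
            genespace,
        )
        bpm0 = BPM(tuple(genespace[:4]), tuple(genespace[4:8]))
        bpm1 = BPM(tuple(genespace[8:11]), tuple(genespace[11:14]))  # unannotated
        return genespace, assoc, [bpm0, bpm1]

    def test_dual_flag_and_entries(self):
        _, assoc, bpms = self._setup()
        report = enrich_bpms(bpms, assoc, EnrichmentParams(n_simulations=200), rng_seed=5)
        assert 0 in report.dually_enriched
        assert 1 not in report.dually_enriched | report.singly_enriched
        assert all(e.corrected_p <= 0.05 for e in report.entries)
        assert not report.dually_enriched & report.singly_enriched

    def test_fraction_formatting_and_tsv(self):
        _, assoc, bpms = self._setup()
        report = enrich_bpms(bpms, assoc, EnrichmentParams(n_simulations=200), rng_seed=5)
        e = next(e for e in report.entries if e.term == "T1")
        assert e.fraction == "4/4"
        sink = io.StringIO()
        report.to_tsv(sink)
        lines = sink.getvalue().splitlines()
        assert lines[0].startswith("bpm\tmodule\tterm")
        assert any("\tT1\t" in line for line in lines[1:])

    def test_no_annotation_means_empty_report(self):
        genespace = list("ABCDEFGH")
        assoc = simple_assoc({"T": ["H"]}, genespace)
        bpms = [BPM(("A", "B"), ("C", "D"))]
        report = enrich_bpms(bpms, assoc, EnrichmentParams(n_simulations=30), rng_seed=0)
        assert report.entries == ()
        assert not report.dually_enriched and not report.singly_enriched


def test_request_shaping_contract():
    params = EnrichmentParams(p_cutoff=0.01, n_simulations=None)
    req = build_enrichment_request(
        modules=[["B", "A"], ["C"]], genespace=["A", "B", "C"], params=params
    )
    assert req["query_sets"] == [["A", "B"], ["C"]]
    assert req["p_value_cutoff"] == 0.01
    assert req["simulations"] == 1000
    assert req["genespace"] == ["A", "B", "C"]
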