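"""Class-code assignment, the A-rich-stretch rule and signal scanning."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from apsflow.annotation import (
    GeneIndex,
    annotate_sites,
    classify_ars,
    classify_site,
    is_a_rich,
    scan_signals,
    summarize_by_biotype,
)
from apsflow.models import GeneModel
from oracles import brute_force_a_rich


class TestClassCodes:
    def test_hand_annotated_fixture_set(self, class_code_fixture):
        genes, cases = class_code_fixture
        index = GeneIndex(genes)
        for start, end, strand, expected_gene, expected_code in cases:
            gene, code = classify_site("chr1", start, end, strand, index)
            got_gene = gene.gene_id if gene else None
            assert (got_gene, code) == (expected_gene, expected_code), (
                f"span {start}-{end}{strand}: got ({got_gene}, {code})"
            )

    def test_same_strand_assignment_beats_antisense(self):
        plus = GeneModel("GP", "GP", "protein_coding", "chr1", "+",
                         {"GP.t1": [(100, 400)]})
        minus = GeneModel("GM", "GM", "lncRNA", "chr1", "-",
                          {"GM.t1": [(200, 500)]})
        index = GeneIndex([plus, minus])
        gene, code = classify_site("chr1", 250, 260, "+", index)
        assert (gene.gene_id, code) == ("GP", "c")
        gene, code = classify_site("chr1", 250, 260, "-", index)
        assert (gene.gene_id, code) == ("GM", "c")

    def test_overlapping_same_strand_genes_use_exonic_overlap(self):
        a = GeneModel("A", "A", "protein_coding", "chr1", "+",
                      {"A.t1": [(0, 150), (300, 500)]})
        b = GeneModel("B", "B", "protein_coding", "chr1", "+",
                      {"B.t1": [(100, 500)]})
        index = GeneIndex([a, b])
        # span 160-200 is intronic in A but exonic in B
        gene, code = classify_site("chr1", 160, 200, "+", index)
        assert (gene.gene_id, code) == ("B", "c")

    def test_every_site_gets_exactly_one_code(self, class_code_fixture):
        genes, _ = class_code_fixture
        index = GeneIndex(genes)
        rng = np.random.default_rng(3)
        for _ in range(200):
            start = int(rng.integers(0, 15_000))
            width = int(rng.integers(0, 40))
            strand = "+" if rng.random() < 0.5 else "-"
            _, code = classify_site("chr1", start, start + width, strand, index)
            assert code in "ceiopxu"


class TestArsRule:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("AAAAAAACGTCGTACGTACGTACGTACGTA", True),  # run of 7
            ("AAAAAAGAACGGGGGGGGGGGGGGGGGGGG", True),  # 8 A in a 10-bp window
            ("C" * 30, False),
            ("AAAAAA" + "C" + "AAAAAA" + "C" * 17, True),  # 6+6 split: window has 8
            ("AAAAAA" + "CCCC" + "AAAAAA" + "C" * 14, False),  # runs of 6, windows max 6
            ("A" * 7, True),  # short sequence, run rule only
            ("A" * 6, False),
        ],
    )
    def test_rule_on_known_sequences(self, seq, expected):
        assert is_a_rich(seq) is expected

    def test_matches_exhaustive_oracle_on_a_enriched_sequences(self):
        rng = np.random.default_rng(17)
        alphabet = np.array(list("AAACGT"))  # A-enriched to hit boundaries
        for _ in range(2000):
            seq = "".join(rng.choice(alphabet, size=30))
            assert is_a_rich(seq) == brute_force_a_rich(seq), seq

    def test_classify_ars_reads_transcript_strand(self):
        # plus-strand site: genomic As downstream; minus-strand site at
        # the same spot sees Ts and is not A-rich
        genome = {"chr1": "C" * 50 + "A" * 10 + "C" * 40}
        assert classify_ars(genome, "chr1", 49, "+") is True
        assert classify_ars(genome, "chr1", 70, "-") is False
        # minus-strand site downstream of genomic Ts (transcript As)
        genome2 = {"chr1": "C" * 40 + "T" * 10 + "C" * 50}
        assert classify_ars(genome2, "chr1", 50, "-") is True

    def test_chromosome_edge_evaluates_available_sequence(self):
        # 8 bases of runway only: the rule still applies to what exists
        genome = {"chr1": "C" * 100 + "A" * 8}
        assert classify_ars(genome, "chr1", 99, "+") is True
        genome2 = {"chr1": "A" * 8 + "C" * 100}
        assert classify_ars(genome2, "chr1", 8, "-") is False


class TestScanSignals:
    def test_planted_hexamer_found_at_offset(self):
        # AATAAA whose 3'-most base sits 21 bp upstream of the site
        pos = 200
        seq = ["C"] * 400
        seq[pos - 26 : pos - 20] = list("AATAAA")
        genome = {"chr1": "".join(seq)}
        hits = scan_signals(genome, "chr1", pos, "+", ["AATAAA"])
        assert hits == [("AATAAA", -21)]

    def test_minus_strand_scan(self):
        pos = 200
        seq = ["C"] * 400
        # transcript-strand AATAAA at offset -21 on the minus strand:
        # genomic reverse complement TTTATT with its 5' end at pos+21
        seq[pos + 21 : pos + 27] = list("TTTATT")
        genome = {"chr1": "".join(seq)}
        hits = scan_signals(genome, "chr1", pos, "-", ["AATAAA"])
        assert hits == [("AATAAA", -21)]

    def test_no_signal_gives_empty_list(self):
        genome = {"chr1": "C" * 300}
        assert scan_signals(genome, "chr1", 200, "+", ["AATAAA"]) == []

    def test_two_signals_reported_sorted_closest_first(self):
        pos = 300
        seq = ["C"] * 500
        seq[pos - 24 : pos - 18] = list("AATAAA")
        seq[pos - 60 : pos - 54] = list("ATTAAA")
        genome = {"chr1": "".join(seq)}
        hits = scan_signals(genome, "chr1", pos, "+", ["AATAAA", "ATTAAA"])
        assert hits == [("AATAAA", -19), ("ATTAAA", -55)]

    def test_empty_signal_list_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            scan_signals({"chr1": "C" * 300}, "chr1", 200, "+", [])

    def test_u_normalised_to_t(self):
        pos = 100
        seq = ["C"] * 300
        seq[pos - 26 : pos - 20] = list("AATAAA")
        genome = {"chr1": "".join(seq)}
        assert scan_signals(genome, "chr1", pos, "+", ["AAUAAA"]) == [
            ("AATAAA", -21)
        ]

    def test_planted_signals_recovered_on_synthetic_genome(self, clean_demo):
        study, _, _ = clean_demo
        ok = total = 0
        for row in study.truth.itertuples():
            if row.signal is None:
                continue
            total += 1
            hits = scan_signals(
                study.chromosomes, row.chrom, row.position, row.strand, [row.signal]
            )
            ok += (row.signal, -int(row.signal_offset)) in hits
        assert total > 50
        assert ok / total >= 0.99


class TestSummaries:
    def _annotated(self, rows):
        return pd.DataFrame(
            rows,
            columns=["site_id", "gene_id", "biotype", "class_code",
                     "conventionality", "ars"],
        )

    def test_single_site_genes(self):
        annotated = self._annotated(
            [
                ("s1", "g1", "protein_coding", "c", "conventional", False),
                ("s2", "g2", "protein_coding", "i", "non_conventional", True),
            ]
        )
        out = summarize_by_biotype(annotated)
        row = out["sites_per_gene"].iloc[0]
        assert row.mean_sites_per_gene == 1.0
        assert row.frac_multi_site == 0.0

    def test_conventionality_fractions_sum_to_one(self, clean_demo):
        _, _, result = clean_demo
        conv = summarize_by_biotype(result.annotations)["conventionality"]
        frac_cols = [c for c in conv.columns if c != "biotype"]
        assert np.allclose(conv[frac_cols].sum(axis=1), 1.0)

    def test_truth_site_counts_recovered(self, clean_demo):
        study, _, result = clean_demo
        truth_per_gene = study.truth.groupby("gene_id").size()
        got = (
            result.annotations[result.annotations.gene_id.notna()]
            .groupby("gene_id")
            .size()
        )
        pd.testing.assert_series_equal(
            truth_per_gene.sort_index(), got.sort_index(), check_names=False
        )
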