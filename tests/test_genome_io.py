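"""GenBank/FASTA I/O, quadripartite partitioning and locus orders."""

import dataclasses

import pytest

from plastevol.genome_io import (
    Feature,
    GenomeRecord,
    classify_ir_loss,
    collapse_ir,
    census_table,
    locus_coordinates,
    partition_regions,
    read_genbank,
    shared_locus_order,
    write_genbank,
)
from plastevol.synthetic_data import SimConfig, simulate_plastome


MINIMAL_GB = """LOCUS       test                18 bp    DNA     circular PLN 01-JAN-2000
FEATURES             Location/Qualifiers
     CDS             1..6
                     /gene="psbA"
ORIGIN
        1 atgaaataat ttcctaga
//
"""


class TestGenBankIO:
    def test_one_based_inclusive_becomes_half_open(self, tmp_path):
        p = tmp_path / "min.gb"
        p.write_text(MINIMAL_GB)
        rec = read_genbank(p)
        assert len(rec.features) == 1
        f = rec.features[0]
        assert f.spans == ((0, 6),)
        assert f.strand == "+"
        assert rec.sequence[:6] == "ATGAAA"

    def test_round_trip_preserves_record(self, tmp_path, small_plastome):
        rec, _ = small_plastome
        path = tmp_path / "rt.gb"
        write_genbank(rec, path)
        back = read_genbank(path)
        assert back.sequence == rec.sequence
        assert len(back.features) == len(rec.features)
        for a, b in zip(rec.features, back.features):
            assert (a.locus_name, a.kind, a.strand, a.spans, a.pseudo) == (
                b.locus_name, b.kind, b.strand, b.spans, b.pseudo,
            )

    def test_malformed_file_raises(self, tmp_path):
        p = tmp_path / "bad.gb"
        p.write_text("not a genbank file\n")
        with pytest.raises(ValueError):
            read_genbank(p)

    def test_join_features_round_trip(self, tmp_path):
        rec = GenomeRecord(
            id="j",
            sequence="ATGAAACCCGGGTTTTAA" * 4,
            features=(Feature("clpP", "CDS", "+", ((0, 6), (12, 18))),),
        )
        path = tmp_path / "join.gb"
        write_genbank(rec, path)
        back = read_genbank(path)
        assert back.features[0].spans == ((0, 6), (12, 18))


class TestRecordInvariants:
    def test_features_sorted_by_start(self):
        rec = GenomeRecord(
            id="x",
            sequence="ACGT" * 10,
            features=(
                Feature("b", "CDS", "+", ((20, 30),)),
                Feature("a", "CDS", "+", ((0, 10),)),
            ),
        )
        assert [f.locus_name for f in rec.features] == ["a", "b"]

    def test_rejects_non_acgtn(self):
        with pytest.raises(ValueError):
            GenomeRecord(id="x", sequence="ACGU")

    def test_census_counts_constructed_features(self):
        feats = tuple(
            Feature(f"gene{i}", "CDS", "+", ((10 * i, 10 * i + 9),)) for i in range(79)
        )
        rec = GenomeRecord(id="x", sequence="A" * 800, features=feats)
        assert rec.feature_census()["CDS"] == 79
        df = census_table([rec])
        assert len(df) == 79


class TestPartition:
    def test_recovers_planted_boundaries(self, small_plastome):
        rec, ledger = small_plastome
        part = partition_regions(rec, min_ir_len=1000)
        assert part.ir_status == "both"
        assert list(part.ir_a) == ledger["regions"]["ir_a"]
        assert list(part.ir_b) == ledger["regions"]["ir_b"]
        assert list(part.lsc) == ledger["regions"]["lsc"]
        assert list(part.ssc) == ledger["regions"]["ssc"]

    def test_ir_copies_are_reverse_complements(self, small_plastome):
        from plastevol._sa import revcomp

        rec, _ = small_plastome
        part = partition_regions(rec, min_ir_len=1000)
        a = rec.sequence[slice(*part.ir_a)]
        b = rec.sequence[slice(*part.ir_b)]
        assert b == revcomp(a)

    def test_no_ir_genome(self):
        import random

        rng = random.Random(0)
        seq = "".join(rng.choice("ACGT") for _ in range(5000))
        rec = GenomeRecord(id="r", sequence=seq)
        assert partition_regions(rec, min_ir_len=1000).ir_status == "none"

    def test_min_ir_len_guard(self, small_plastome):
        rec, _ = small_plastome
        with pytest.raises(ValueError):
            partition_regions(rec, min_ir_len=50)

    def test_ir_loss_classified_against_reference(self):
        ref, _ = simulate_plastome(SimConfig(seed=21, gene_scale=0.25))
        lost_a, _ = simulate_plastome(SimConfig(seed=21, gene_scale=0.25, ir_deleted="A"))
        lost_b, _ = simulate_plastome(SimConfig(seed=21, gene_scale=0.25, ir_deleted="B"))
        assert classify_ir_loss(lost_a, ref) == "A_lost"
        assert classify_ir_loss(lost_b, ref) == "B_lost"


class TestCollapseIR:
    def test_length_decreases_by_ir_len(self, small_plastome):
        rec, ledger = small_plastome
        col = collapse_ir(rec)
        assert len(rec) - len(col) == ledger["ir_len"]

    def test_duplicated_ir_genes_become_single_copy(self, small_plastome):
        rec, _ = small_plastome
        col = collapse_ir(rec)
        names = [f.locus_name for f in col.features]
        assert names.count("trnI-GAU") == 1
        assert names.count("rrn16") == 1

    def test_idempotent(self, small_plastome):
        rec, _ = small_plastome
        col = collapse_ir(rec)
        again = collapse_ir(col)
        assert again.sequence == col.sequence
        assert again.features == col.features

    def test_noop_without_both_irs(self):
        rec = GenomeRecord(id="x", sequence="ACGT" * 1000)
        assert collapse_ir(rec) is rec


class TestSharedLocusOrder:
    def test_identical_records_all_positive(self, small_plastome):
        rec, _ = small_plastome
        col = collapse_ir(rec)
        other = dataclasses.replace(col, id="copy")
        orders = shared_locus_order([col, other], reference_id=col.id)
        assert orders[col.id] == orders["copy"]
        assert all(s == 1 for _, s in orders[col.id])

    def test_lost_gene_excluded_everywhere(self, small_plastome):
        rec, _ = small_plastome
        col = collapse_ir(rec)
        dropped = dataclasses.replace(
            col,
            id="minus_rbcL",
            features=tuple(f for f in col.features if f.locus_name != "rbcL"),
        )
        orders = shared_locus_order([col, dropped], reference_id=col.id)
        for order in orders.values():
            assert "rbcL" not in [g for g, _ in order]

    def test_too_few_shared_loci(self):
        a = GenomeRecord(
            id="a", sequence="A" * 100,
            features=(Feature("x", "CDS", "+", ((0, 9),)),),
        )
        b = GenomeRecord(
            id="b", sequence="A" * 100,
            features=(Feature("y", "CDS", "+", ((0, 9),)),),
        )
        with pytest.raises(ValueError, match="insufficient shared loci"):
            shared_locus_order([a, b], reference_id="a")

    def test_locus_coordinates_skips_multicopy(self, small_plastome):
        rec, _ = small_plastome
        coords = locus_coordinates(rec)
        assert "rrn16" not in coords  # two IR copies
        assert "rbcL" in coords
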