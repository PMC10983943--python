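"""Genome/table readers, the read-fraction floor, and known-mutation subtraction."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from editaudit.ingest import (
    read_genome,
    read_genomediff,
    read_mutation_table,
    subtract_known,
    flag_recurrent,
    write_mutation_table,
)
from editaudit.records import CloneRecord, MutationRecord

HEADER = "sample_id\tposition\tref\talt\tmut_class\tread_fraction\n"


def table(rows):
    fh = io.StringIO(HEADER + "".join(rows))
    return fh


class TestReadGenome:
    def test_fasta_roundtrip_length(self, tmp_path, small_genome):
        p = tmp_path / "g.fasta"
        p.write_text(f">chr\n{small_genome.sequence}\n")
        genome, annotation = read_genome(p)
        assert len(genome) == len(small_genome)
        assert genome.sequence == small_genome.sequence
        assert annotation is None

    def test_genbank_yields_features(self, tmp_path):
        gb = tmp_path / "g.gb"
        seq = "ATGGCTTAA" + "ACGT" * 10
        gb.write_text(
            "LOCUS       test                 49 bp    DNA     circular BCT"
            " 01-JAN-2024\n"
            "FEATURES             Location/Qualifiers\n"
            "     CDS             1..9\n"
            '                     /locus_tag="gene1"\n'
            "ORIGIN\n"
            f"        1 {seq.lower()}\n"
            "//\n"
        )
        genome, annotation = read_genome(gb)
        assert genome.sequence.startswith("ATGGCTTAA")
        assert genome.circular
        assert [f.feature_id for f in annotation.features] == ["gene1"]
        assert (annotation.features[0].start, annotation.features[0].end) == (1, 9)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ValueError, match="no sequence records"):
            read_genome(p)

    def test_multi_record_requires_selector(self, tmp_path):
        p = tmp_path / "two.fasta"
        p.write_text(">a\nACGTACGT\n>b\nTTTTAAAA\n")
        with pytest.raises(ValueError, match="record_id"):
            read_genome(p)
        genome, _ = read_genome(p, record_id="b")
        assert genome.sequence == "TTTTAAAA"


class TestReadMutationTable:
    def test_floor_is_strictly_more_than(self):
        rows = ["s1\t100\tA\tG\tSNV\t0.10\n", "s1\t200\tC\tT\tSNV\t0.50\n"]
        records = read_mutation_table(table(rows), min_read_fraction=0.10)
        assert [r.position for r in records] == [200]

    def test_fraction_just_above_floor_kept(self):
        rows = ["s1\t100\tA\tG\tSNV\t0.101\n"]
        assert len(read_mutation_table(table(rows), 0.10)) == 1

    def test_malformed_rows_reported_with_line_numbers(self):
        rows = [
            "s1\t100\tA\tG\tSNV\t0.5\n",
            "s1\tnot_a_number\tA\tG\tSNV\t0.5\n",
            "s1\t300\tA\tG\tbogus_class\t0.5\n",
        ]
        with pytest.raises(ValueError, match=r"lines: \[3, 4\]"):
            read_mutation_table(table(rows))

    def test_bad_header_rejected(self):
        fh = io.StringIO("a\tb\n1\t2\n")
        with pytest.raises(ValueError, match="header"):
            read_mutation_table(fh)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        fractions=st.lists(
            st.floats(0.01, 1.0, allow_nan=False), min_size=1, max_size=20
        ),
        floors=st.tuples(st.floats(0.0, 0.5), st.floats(0.0, 0.5)),
    )
    def test_lower_floor_keeps_superset(self, fractions, floors):
        lo, hi = sorted(floors)
        rows = [
            f"s\t{i + 1}\tA\tG\tSNV\t{f!r}\n" for i, f in enumerate(fractions)
        ]
        keep_lo = {r.position for r in read_mutation_table(table(rows), lo)}
        keep_hi = {r.position for r in read_mutation_table(table(rows), hi)}
        assert keep_hi <= keep_lo

    def test_write_read_write_round_trips_bytes(self, tmp_path):
        records = [
            MutationRecord("s1", 10, "A", "G", "SNV", 0.3141592),
            MutationRecord("s1", 20, "", "T", "insertion", 1.0),
            MutationRecord("s2", 30, "C", "", "deletion", 0.18),
        ]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_mutation_table(records, p1)
        back = read_mutation_table(p1, min_read_fraction=0.0)
        write_mutation_table(back, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestGenomeDiff:
    @staticmethod
    def gd_text(genome):
        alt = "T" if genome.base(1000) != "T" else "C"
        return (
            "#=GENOME_DIFF\t1.0\n"
            f"SNP\t1\t10\tref\t1000\t{alt}\tfrequency=0.32\n"
            "INS\t2\t11\tref\t2000\tG\n"
            "DEL\t3\t12\tref\t3000\t2\tfrequency=0.18\n"
            "MOB\t4\t13\tref\t4000\tIS5\t1\t4\n"
            "RA\t5\t.\tref\t500\t0\tA\tT\n"
        ), alt

    def test_limited_line_types_parsed(self, small_genome):
        gd, alt = self.gd_text(small_genome)
        records = read_genomediff(io.StringIO(gd), genome=small_genome,
                                  min_read_fraction=0.0)
        by_class = {r.mut_class: r for r in records}
        assert set(by_class) == {"SNV", "insertion", "deletion", "MOB"}
        snv = by_class["SNV"]
        assert (snv.position, snv.alt, snv.read_fraction) == (1000, alt, 0.32)
        assert snv.ref == small_genome.base(1000)
        assert by_class["deletion"].ref == (
            small_genome.base(3000) + small_genome.base(3001)
        )
        assert by_class["insertion"].ref == ""

    def test_floor_applies_to_genomediff(self, small_genome):
        gd, _ = self.gd_text(small_genome)
        records = read_genomediff(io.StringIO(gd), genome=small_genome,
                                  min_read_fraction=0.2)
        assert {r.mut_class for r in records} == {"SNV", "insertion", "MOB"}


class TestSubtractKnown:
    RECS = [
        MutationRecord("s", 500, "A", "G", "SNV", 0.5),
        MutationRecord("s", 100, "C", "T", "SNV", 0.5),
        MutationRecord("s", 300, "", "T", "insertion", 0.5),
    ]

    def test_full_subtraction_empties_output(self):
        assert subtract_known(self.RECS, [r.key for r in self.RECS]) == []

    def test_empty_sets_identity_sorted(self):
        out = subtract_known(self.RECS)
        assert [r.position for r in out] == [100, 300, 500]
        assert set(out) == set(self.RECS)

    def test_idempotent(self):
        once = subtract_known(self.RECS, [(100, "C", "T")], [(300, "", "T")],
                              positional_tolerance=50)
        twice = subtract_known(once, [(100, "C", "T")], [(300, "", "T")],
                               positional_tolerance=50)
        assert once == twice

    def test_near_intended_flagged_not_dropped(self):
        out = subtract_known(self.RECS, [], [(510, "A", "C")],
                             positional_tolerance=20)
        flagged = [r for r in out if "near_intended" in r.flags]
        assert [r.position for r in flagged] == [500]
        assert len(out) == 3

    def test_recurrent_mutations_flagged_but_counted(self):
        clones = [
            CloneRecord("c1", "cas9", 1, unintended_mutations=[
                MutationRecord("c1", 700, "A", "G", "SNV", 1.0)]),
            CloneRecord("c2", "cas9", 1, unintended_mutations=[
                MutationRecord("c2", 700, "A", "G", "SNV", 1.0)]),
        ]
        flag_recurrent(clones)
        for c in clones:
            assert c.has_unintended
            assert "possibly_preexisting" in c.unintended_mutations[0].flags
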