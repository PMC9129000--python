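"""Seed-and-extend placement, soft clips, SAM interchange."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orgrearr.microalign import (
    Aligner,
    AlignmentRecord,
    AlignParams,
    align_pairs,
    align_read,
    cigar_from_string,
    read_fastq,
    read_sam,
    write_sam,
)
from orgrearr.repeatome import revcomp
from orgrearr.simlib import (
    LibraryParams,
    build_mixture,
    parse_truth_header,
    plant_repeat,
    random_genome,
    simulate_reads,
    write_fastq,
)


@pytest.fixture(scope="module")
def genome():
    return random_genome(50_000, seed=301, name="mt")


@pytest.fixture(scope="module")
def aligner(genome):
    return Aligner(genome)


class TestAlignRead:
    def test_perfect_read(self, genome, aligner):
        rec = aligner.align("r", genome.fetch(5_000, 150))
        assert (rec.pos, rec.strand, rec.cigar) == (5_001, "+", [("M", 150)])
        assert rec.mapped and rec.is_unique

    def test_reverse_strand(self, genome, aligner):
        rec = aligner.align("r", revcomp(genome.fetch(5_000, 150)))
        assert (rec.pos, rec.strand) == (5_001, "-")
        assert rec.cigar == [("M", 150)]

    def test_origin_spanning_read(self, genome, aligner):
        rec = aligner.align("r", genome.fetch(genome.length - 60, 150))
        assert rec.pos == genome.length - 59
        assert rec.cigar == [("M", 150)]

    def test_chimeric_read_longer_block_wins(self, genome, aligner):
        read = genome.fetch(1_000, 80) + genome.fetch(40_000, 70)
        rec = aligner.align("r", read)
        assert rec.pos == 1_001
        # extension can slip a few chance-matching bases past the junction
        (op0, n0), (op1, n1) = rec.cigar
        assert (op0, op1) == ("M", "S")
        assert 80 <= n0 <= 86 and n0 + n1 == 150
        assert rec.is_unique

    def test_read_in_direct_repeat_is_multimapped(self, genome):
        seq = plant_repeat(genome.sequence, 400, 10_000, 30_000, "direct")
        g2 = type(genome)("mt2", seq)
        rec = Aligner(g2).align("r", g2.fetch(10_100, 150))
        assert rec.mapped and not rec.is_unique

    def test_tie_choice_uniform_with_rng(self, genome):
        seq = plant_repeat(genome.sequence, 400, 10_000, 30_000, "direct")
        g2 = type(genome)("mt2", seq)
        al = Aligner(g2)
        rng = np.random.default_rng(0)
        seen = {al.align("r", g2.fetch(10_100, 150), rng=rng).pos for _ in range(40)}
        assert seen == {10_101, 30_101}

    def test_short_read_unmapped(self, genome):
        rec = align_read(genome, genome.fetch(100, 20))
        assert not rec.mapped

    def test_garbage_read_unmapped(self, genome, aligner):
        rng = np.random.default_rng(5)
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, 150))
        assert not aligner.align("r", junk).mapped

    def test_substitutions_within_rate_tolerated(self, genome, aligner):
        read = list(genome.fetch(7_000, 150))
        for p in (40, 90):
            read[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[p]]
        rec = aligner.align("r", "".join(read))
        assert rec.pos == 7_001 and rec.cigar == [("M", 150)]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(40, 220))
    def test_query_length_conservation(self, genome, aligner, seed, n):
        """Query-consuming CIGAR op lengths always sum to the read length."""
        rng = np.random.default_rng(seed)
        if rng.random() < 0.5:
            read = genome.fetch(int(rng.integers(0, genome.length)), n)
        else:  # chimeric
            h = n // 2
            read = genome.fetch(int(rng.integers(0, genome.length)), h) + genome.fetch(
                int(rng.integers(0, genome.length)), n - h
            )
        rec = aligner.align("r", read)
        if rec.mapped:
            assert sum(ln for op, ln in rec.cigar if op in "MIS=X") == n


@pytest.fixture(scope="module")
def library(genome, tmp_path_factory):
    d = tmp_path_factory.mktemp("lib")
    mixture, _ = build_mixture(genome, [], [])
    r1, r2 = simulate_reads(mixture, LibraryParams(depth=4, seed=302, error_rate=0.0))
    write_fastq(r1, d / "r1.fastq")
    write_fastq(r2, d / "r2.fastq")
    return d / "r1.fastq", d / "r2.fastq", r1, r2


class TestPairsAndSam:

    def test_error_free_reads_all_map_full_length(self, genome, library):
        f1, f2, r1, _ = library
        records = align_pairs(genome, f1, f2)
        assert len(records) == 2 * len(r1)
        assert all(r.mapped for r in records)
        frac_full = sum(r.cigar == [("M", 150)] for r in records) / len(records)
        assert frac_full >= 0.99

    def test_true_positions_recovered(self, genome, library):
        """At zero error on a repeat-free genome every read maps to its
        simulated fragment coordinate."""
        f1, f2, r1, r2 = library
        records = align_pairs(genome, f1, f2)
        truth = {}
        for (h1, _), (h2, _) in zip(r1, r2):
            name = h1.split(" ")[0][:-2]
            _, start, end, strand = parse_truth_header(h1)
            truth[name] = (start, end, strand)
        for rec in records:
            start, end, strand = truth[rec.read_id]
            flen = (end - start) % genome.length + 1
            lead = (rec.mate == 1) == (strand == "+")
            expect = start if lead else (start - 1 + flen - 150) % genome.length + 1
            assert rec.pos == expect

    def test_sam_round_trip(self, genome, library, tmp_path):
        f1, f2, _, _ = library
        records = align_pairs(genome, f1, f2)
        write_sam(records, genome, tmp_path / "x.sam")
        back = read_sam(tmp_path / "x.sam")
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert (a.read_id, a.pos, a.strand, a.cigar, a.seq, a.mapped, a.is_unique, a.mate) == (
                b.read_id, b.pos, b.strand, b.cigar, b.seq, b.mapped, b.is_unique, b.mate
            )

    def test_empty_fastq_gives_header_only_sam(self, genome, tmp_path):
        for n in ("e1.fastq", "e2.fastq"):
            (tmp_path / n).write_text("")
        records = align_pairs(genome, tmp_path / "e1.fastq", tmp_path / "e2.fastq")
        assert records == []
        write_sam(records, genome, tmp_path / "empty.sam")
        lines = (tmp_path / "empty.sam").read_text().splitlines()
        assert all(ln.startswith("@") for ln in lines) and len(lines) == 3

    def test_mismatched_pair_names_error(self, genome, tmp_path):
        (tmp_path / "a1.fastq").write_text("@p1/1\n" + "A" * 150 + "\n+\n" + "I" * 150 + "\n")
        (tmp_path / "a2.fastq").write_text("@q1/2\n" + "A" * 150 + "\n+\n" + "I" * 150 + "\n")
        with pytest.raises(ValueError, match="p1"):
            align_pairs(genome, tmp_path / "a1.fastq", tmp_path / "a2.fastq")


class TestReadSam:
    HEADER = "@HD\tVN:1.6\n@SQ\tSN:mt\tLN:50000\n"

    def _write(self, tmp_path, body):
        p = tmp_path / "t.sam"
        p.write_text(self.HEADER + body)
        return p

    def test_cigar_parsing(self, tmp_path):
        seq150 = "A" * 150
        body = (
            f"r1\t0\tmt\t100\t60\t100M50S\t*\t0\t0\t{seq150}\t*\n"
            f"r2\t0\tmt\t200\t60\t60M5I60M25S\t*\t0\t0\t{seq150}\t*\n"
            f"r3\t4\t*\t0\t0\t*\t*\t0\t0\t{seq150}\t*\n"
            f"r4\t16\tmt\t300\t0\t150M\t*\t0\t0\t{seq150}\t*\n"
        )
        recs = read_sam(self._write(tmp_path, body))
        assert recs[0].cigar == [("M", 100), ("S", 50)]
        assert recs[1].cigar == [("M", 60), ("I", 5), ("M", 60), ("S", 25)]
        assert not recs[2].mapped  # FLAG 4: excluded from coverage downstream
        assert recs[3].strand == "-" and not recs[3].is_unique  # MAPQ 0

    def test_malformed_cigar_reports_record(self, tmp_path):
        body = "r1\t0\tmt\t5\t60\t10Q\t*\t0\t0\tACGTACGTAC\t*\n"
        with pytest.raises(ValueError, match="malformed SAM record 1"):
            read_sam(self._write(tmp_path, body))

    def test_cigar_string_parser_rejects_garbage(self):
        with pytest.raises(ValueError, match="malformed CIGAR"):
            cigar_from_string("MM10")
        assert cigar_from_string("*") == []

    def test_fastq_reader_strips_mate_suffix(self, tmp_path):
        (tmp_path / "f.fastq").write_text("@x/1 comment\nACGT\n+\nIIII\n@y\nACGT\n+\nIIII\n")
        assert [n for n, _ in read_fastq(tmp_path / "f.fastq")] == ["x", "y"]
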