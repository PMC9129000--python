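"""Deterministic seed-and-extend read placement on small circular genomes.

Organellar genomes are small (<= 1 Mb), so a self-contained ungapped aligner
is adequate and keeps the whole pipeline reproducible: exact k-mer seeds are
looked up in an index of the doubled sequence (which makes origin-spanning
placements ordinary), then extended in both directions while the running
mismatch rate stays below a cap.  Read ends that cannot be extended become
soft clips (CIGAR S) -- the raw signal the junction-detection stage consumes.
Only M and S operations are ever emitted; reads that would need an indel to
align end up soft-clipped or unmapped, which matches the downstream filter
that discards indel-containing records anyway.

External aligner output can be substituted bit-for-bit through
:func:`read_sam`, which ingests any valid SAM (all CIGAR operations accepted,
uniqueness inferred from MAPQ when score-tie information is absent).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam
from Bio import SeqIO

from .repeatome import CircularGenome, revcomp

QUERY_OPS = frozenset("MIS=X")
REF_OPS = frozenset("MDN=X")


@dataclass(frozen=True)
class AlignParams:
    seed_length: int = 31
    max_mismatch_rate: float = 0.04
    min_anchor: int = 30  # minimum aligned block for a placement to count

    def __post_init__(self) -> None:
        if self.seed_length < 15:
            raise ValueError("seed_length must be >= 15")
        if not (0 <= self.max_mismatch_rate < 0.2):
            raise ValueError("max_mismatch_rate must be in [0, 0.2)")


@dataclass
class AlignmentRecord:
    """One read placement.  ``seq`` is stored in aligned orientation (reverse
    complemented for '-' strand placements, as in SAM); ``cigar`` is a list of
    (op, length) with query-consuming op lengths summing to the read length."""

    read_id: str
    ref_name: str
    pos: int  # 1-based leftmost aligned position; 0 if unmapped
    strand: str  # "+" | "-"
    cigar: list[tuple[str, int]]
    seq: str
    mapped: bool = True
    is_unique: bool = True
    mate: int = 1  # 1 or 2
    mate_ref: str = "*"
    mate_pos: int = 0
    mate_mapped: bool = False
    mate_strand: str = "+"

    @property
    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in QUERY_OPS) or len(self.seq)

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in REF_OPS)

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar) if self.cigar else "*"


def cigar_from_string(text: str) -> list[tuple[str, int]]:
    if text in ("*", ""):
        return []
    ops: list[tuple[str, int]] = []
    num = ""
    for ch in text:
        if ch.isdigit():
            num += ch
        elif ch in "MIDNSHP=X" and num:
            ops.append((ch, int(num)))
            num = ""
        else:
            raise ValueError(f"malformed CIGAR string: {text!r}")
    if num:
        raise ValueError(f"malformed CIGAR string: {text!r}")
    return ops


# ---------------------------------------------------------------------------
# Aligner
# ---------------------------------------------------------------------------

_MISMATCH_PENALTY = 4  # score = block length - penalty * mismatches


class Aligner:
    """Seed-and-extend aligner for one circular reference."""

    def __init__(self, genome: CircularGenome, params: AlignParams | None = None):
        self.genome = genome
        self.params = params or AlignParams()
        L = genome.length
        doubled = genome.sequence + genome.sequence
        self._arr = np.frombuffer(doubled.encode(), dtype=np.uint8)
        k = self.params.seed_length
        index: dict[str, list[int]] = {}
        for p in range(L):
            index.setdefault(doubled[p : p + k], []).append(p)
        self._index = index

    # -- placement search ---------------------------------------------------

    def _candidates(self, q: str) -> list[tuple[int, int, int, int]]:
        """Best local block per diagonal: (pos0, q_start, q_end, mismatches)."""
        L = self.genome.length
        n = len(q)
        k = min(self.params.seed_length, n)
        stride = max(8, k // 3)
        offsets = sorted(set(range(0, n - k + 1, stride)) | {n - k})
        diags: dict[int, int] = {}
        index = self._index
        if k == self.params.seed_length:
            for off in offsets:
                for p in index.get(q[off : off + k], ()):
                    d = (p - off) % L
                    if d not in diags or off < diags[d]:
                        diags[d] = off
        else:  # short query (clip remapping): scan the doubled sequence directly
            doubled = self.genome.sequence + self.genome.sequence
            for off in offsets:
                sub = q[off : off + k]
                p = doubled.find(sub)
                while p != -1 and p < L:
                    d = (p - off) % L
                    if d not in diags or off < diags[d]:
                        diags[d] = off
                    p = doubled.find(sub, p + 1)
        qa = np.frombuffer(q.encode(), dtype=np.uint8)
        rate = self.params.max_mismatch_rate
        out = []
        for d, off in diags.items():
            window = self._arr[d : d + n]
            if window.size < n:
                continue
            mism = window != qa
            lo, hi, nm = _greedy_block(mism, off, min(k, n), rate)
            out.append((d, lo, hi, nm))
        return out

    def align(
        self,
        read_id: str,
        seq: str,
        rng: np.random.Generator | None = None,
        require_full: bool = False,
    ) -> AlignmentRecord:
        """Place one read; both strands are tried.

        Scoring is block length minus a mismatch penalty.  Ties on score make
        the placement non-unique; among ties the leftmost placement is chosen
        unless an ``rng`` is given, in which case the choice is uniform
        (mirrors MAPQ-0 multi-mapper handling).  ``require_full`` demands the
        whole query align end-to-end within the mismatch cap (used for
        soft-clip remapping); partial placements are then rejected.
        """
        L = self.genome.length
        n = len(seq)
        placements = []  # (score, pos0, strand, lo, hi)
        for strand in ("+", "-"):
            q = seq if strand == "+" else revcomp(seq)
            for d, lo, hi, nm in self._candidates(q):
                if require_full:
                    if lo != 0 or hi != n or nm > self.params.max_mismatch_rate * n:
                        continue
                elif hi - lo < self.params.min_anchor:
                    continue
                score = (hi - lo) - _MISMATCH_PENALTY * nm
                placements.append((score, (d + lo) % L, strand, lo, hi))
        if not placements:
            return AlignmentRecord(
                read_id, self.genome.name, 0, "+", [], seq, mapped=False, is_unique=False
            )
        best_score = max(p[0] for p in placements)
        top = sorted(
            {(p[1], p[2], p[3], p[4]) for p in placements if p[0] == best_score}
        )
        unique = len(top) == 1
        if len(top) > 1 and rng is not None:
            pos0, strand, lo, hi = top[int(rng.integers(0, len(top)))]
        else:
            pos0, strand, lo, hi = top[0]
        q = seq if strand == "+" else revcomp(seq)
        cigar: list[tuple[str, int]] = []
        if lo > 0:
            cigar.append(("S", lo))
        cigar.append(("M", hi - lo))
        if hi < n:
            cigar.append(("S", n - hi))
        return AlignmentRecord(
            read_id,
            self.genome.name,
            pos0 + 1,
            strand,
            cigar,
            q,
            mapped=True,
            is_unique=unique,
        )


def _greedy_block(mism: np.ndarray, seed_off: int, k: int, rate: float):
    """Greedy ungapped extension of the seed window [seed_off, seed_off+k).

    Extends right one base at a time while the running mismatch rate stays
    <= ``rate``, then left likewise; edges are trimmed back to matches.
    Returns (lo, hi, n_mismatches) for the half-open block [lo, hi).
    """
    n = mism.size
    lo, hi = seed_off, seed_off + k
    nm = int(mism[lo:hi].sum())
    # right
    tail = mism[hi:]
    if tail.size:
        c = nm + np.cumsum(tail)
        lengths = (hi - lo) + np.arange(1, tail.size + 1)
        ok = c <= rate * lengths
        t = int(np.argmin(ok)) if not ok.all() else tail.size
        nm += int(tail[:t].sum())
        hi += t
    # left
    head = mism[:lo][::-1]
    if head.size:
        c = nm + np.cumsum(head)
        lengths = (hi - lo) + np.arange(1, head.size + 1)
        ok = c <= rate * lengths
        t = int(np.argmin(ok)) if not ok.all() else head.size
        nm += int(head[:t].sum())
        lo -= t
    while hi > lo and mism[hi - 1]:
        hi -= 1
        nm -= 1
    while lo < hi and mism[lo]:
        lo += 1
        nm -= 1
    return lo, hi, nm


def align_read(
    genome: CircularGenome,
    seq: str,
    params: AlignParams | None = None,
    read_id: str = "read",
) -> AlignmentRecord:
    """One-shot convenience wrapper around :class:`Aligner`.  Reads shorter
    than ``min_anchor`` come back unmapped (not an error)."""
    params = params or AlignParams()
    if len(seq) < params.min_anchor:
        return AlignmentRecord(read_id, genome.name, 0, "+", [], seq, mapped=False,
                               is_unique=False)
    return Aligner(genome, params).align(read_id, seq)


# ---------------------------------------------------------------------------
# FASTQ pairing and SAM output
# ---------------------------------------------------------------------------


def _strip_mate(name: str) -> str:
    return name[:-2] if name.endswith(("/1", "/2")) else name


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """(name, sequence) pairs; mate suffixes /1 and /2 are stripped from names."""
    return [
        (_strip_mate(rec.id), str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")
    ]


def align_pairs(
    genome: CircularGenome,
    fastq_r1: str | Path,
    fastq_r2: str | Path,
    params: AlignParams | None = None,
    tie_seed: int = 0,
) -> list[AlignmentRecord]:
    """Align both mates of every pair independently and fill mate fields.

    Output order follows input order (mate 1 then mate 2 per pair).  Ties
    among equally scoring placements are resolved uniformly with a generator
    seeded by ``tie_seed``, and such records are marked non-unique.
    """
    params = params or AlignParams()
    aligner = Aligner(genome, params)
    rng = np.random.default_rng(tie_seed)
    r1 = read_fastq(fastq_r1)
    r2 = read_fastq(fastq_r2)
    if len(r1) != len(r2):
        raise ValueError(f"paired files differ in read count: {len(r1)} vs {len(r2)}")
    records: list[AlignmentRecord] = []
    for idx, ((n1, s1), (n2, s2)) in enumerate(zip(r1, r2)):
        if n1 != n2:
            raise ValueError(f"mismatched pair names at record {idx + 1}: {n1!r} vs {n2!r}")
        rec1 = aligner.align(n1, s1, rng=rng) if len(s1) >= params.min_anchor else \
            AlignmentRecord(n1, genome.name, 0, "+", [], s1, mapped=False, is_unique=False)
        rec2 = aligner.align(n2, s2, rng=rng) if len(s2) >= params.min_anchor else \
            AlignmentRecord(n2, genome.name, 0, "+", [], s2, mapped=False, is_unique=False)
        rec1.mate = 1
        rec2.mate = 2
        for rec, other in ((rec1, rec2), (rec2, rec1)):
            rec.mate_mapped = other.mapped
            rec.mate_ref = other.ref_name if other.mapped else "*"
            rec.mate_pos = other.pos
            rec.mate_strand = other.strand
        records.extend((rec1, rec2))
    return records


def write_sam(
    records: Sequence[AlignmentRecord], genome: CircularGenome, path: str | Path
) -> None:
    """Minimal valid SAM 1.6: @HD/@SQ header, standard columns 1-11, MAPQ 60
    for unique placements and 0 for ties."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{genome.name}\tLN:{genome.length}\n")
        fh.write("@PG\tID:orgrearr\tPN:orgrearr\n")
        for rec in records:
            flag = 0x1 | (0x40 if rec.mate == 1 else 0x80)
            if not rec.mapped:
                flag |= 0x4
            if rec.strand == "-":
                flag |= 0x10
            if not rec.mate_mapped:
                flag |= 0x8
            if rec.mate_strand == "-":
                flag |= 0x20
            mapq = 60 if (rec.mapped and rec.is_unique) else 0
            rname = rec.ref_name if rec.mapped else "*"
            rnext = "="
            if not rec.mate_mapped:
                rnext = "*"
            elif rec.mate_ref != rec.ref_name:
                rnext = rec.mate_ref
            fh.write(
                "\t".join(
                    [
                        rec.read_id,
                        str(flag),
                        rname,
                        str(rec.pos if rec.mapped else 0),
                        str(mapq if rec.mapped else 0),
                        rec.cigar_string() if rec.mapped else "*",
                        rnext,
                        str(rec.mate_pos),
                        "0",
                        rec.seq,
                        "I" * len(rec.seq),
                    ]
                )
                + "\n"
            )


def read_sam(path: str | Path, ref_name: str | None = None) -> list[AlignmentRecord]:
    """Parse a SAM file into AlignmentRecords (ingestion point for external
    aligners).  Records with the unmapped FLAG bit get ``mapped=False``;
    uniqueness is taken from MAPQ > 0.  A malformed record raises with its
    ordinal position in the file."""
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        it = sam.fetch(until_eof=True)
        i = 0
        while True:
            try:
                aln = next(it)
            except StopIteration:
                break
            except (ValueError, OSError) as exc:
                raise ValueError(f"malformed SAM record {i + 1}: {exc}") from exc
            i += 1
            mapped = not aln.is_unmapped
            if mapped and ref_name is not None and aln.reference_name != ref_name:
                continue
            try:
                cigar = cigar_from_string(aln.cigarstring or "*") if mapped else []
            except ValueError as exc:
                raise ValueError(f"malformed SAM record {i}: {exc}") from exc
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    ref_name=aln.reference_name if mapped else (ref_name or "*"),
                    pos=(aln.reference_start + 1) if mapped else 0,
                    strand="-" if aln.is_reverse else "+",
                    cigar=cigar,
                    seq=aln.query_sequence or "",
                    mapped=mapped,
                    is_unique=bool(mapped and aln.mapping_quality > 0),
                    mate=2 if aln.is_read2 else 1,
                    mate_ref=aln.next_reference_name or "*",
                    mate_pos=(aln.next_reference_start + 1)
                    if aln.next_reference_start is not None and aln.next_reference_start >= 0
                    else 0,
                    mate_mapped=bool(aln.is_paired and not aln.mate_is_unmapped),
                    mate_strand="-" if (aln.is_paired and aln.mate_is_reverse) else "+",
                )
            )
    return records
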