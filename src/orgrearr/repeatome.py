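"""Circular organellar genome model, exact repeat discovery and recombination products.

Plant mitochondrial genomes carry repeated sequences in two functional classes:
large repeats (>500 bp) that support frequent, reversible homologous
recombination, and intermediate-size repeats (50-500 bp) that recombine only
rarely, producing substoichiometric alternative genome configurations
("sublimons").  A crossover between two directly oriented repeat copies on a
circular genome loops out a subgenomic circle; a crossover between inverted
copies flips the intervening segment (the chloroplast "flip-flop"
isomerization).  This module models those molecules: it finds maximal exact
repeat pairs on a circle, and constructs the predicted recombination products
and their junction sequences.

Coordinates in all public reports are 1-based inclusive (genome-annotation
convention); internal arithmetic is 0-based modulo the genome length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CircularGenome:
    """A circular nucleotide sequence; all coordinates are modulo its length."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        seq = self.sequence.upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(f"invalid characters in genome sequence: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start0: int, length: int) -> str:
        """Circular substring of ``length`` bases starting at 0-based ``start0``."""
        if length < 0:
            raise ValueError("length must be >= 0")
        L = self.length
        s = start0 % L
        if s + length <= L:
            return self.sequence[s : s + length]
        reps = (s + length) // L + 1
        return (self.sequence * reps)[s : s + length]


@dataclass(frozen=True)
class GenomeInterval:
    """1-based inclusive interval on a circular genome; ``wraps`` marks origin-crossing."""

    start: int
    end: int
    wraps: bool = False

    def length(self, genome_length: int) -> int:
        if self.wraps:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1

    @property
    def start0(self) -> int:
        return self.start - 1

    @classmethod
    def from0(cls, start0: int, length: int, genome_length: int) -> "GenomeInterval":
        s = start0 % genome_length
        e = (s + length - 1) % genome_length
        return cls(start=s + 1, end=e + 1, wraps=s + length > genome_length)


def size_class_of(rep_length: int) -> str:
    """large (>500 bp), intermediate (50-500 bp) or micro (<50 bp)."""
    if rep_length > 500:
        return "large"
    if rep_length >= 50:
        return "intermediate"
    return "micro"


@dataclass(frozen=True)
class RepeatPair:
    """Two non-overlapping genome intervals with identical (direct) or
    reverse-complementary (inverted) sequence."""

    id: str
    copy1: GenomeInterval
    copy2: GenomeInterval
    orientation: str  # "direct" | "inverted"
    rep_length: int

    def __post_init__(self) -> None:
        if self.orientation not in ("direct", "inverted"):
            raise ValueError(f"bad orientation: {self.orientation}")

    @property
    def size_class(self) -> str:
        return size_class_of(self.rep_length)


@dataclass(frozen=True)
class RecombProduct:
    """A junction sequence around one repeat copy in a given flank configuration.

    Configurations name the flanks joined through the repeat: with upstream
    flanks a (copy 1) and c (copy 2) and downstream flanks b (copy 1) and
    d (copy 2), 1/1 = a-R-b and 2/2 = c-R-d are parental, while 1/2 = a-R-d
    and 2/1 = c-R-b are the two possible crossover products.
    """

    repeat_id: str
    config: str  # "1/1" | "2/2" | "1/2" | "2/1"
    junction_sequence: str

    @property
    def product_role(self) -> str:
        return "parental" if self.config in ("1/1", "2/2") else "crossover"


@dataclass(frozen=True)
class SubgenomePrediction:
    """The two circles produced by a crossover between direct repeat copies.

    ``circle_b_to_c`` is one repeat copy plus the segment from the end of
    copy 1 to the start of copy 2; ``circle_d_to_a`` is one repeat copy plus
    the complementary segment.  Their lengths sum to the parent length.
    ``carried_junction`` records which crossover configuration each circle
    carries, and ``footprints`` gives each circle's span on the parent genome
    as a 0-based ``(start, length)`` pair (repeat copy attributed to the copy
    the circle retains).
    """

    repeat_id: str
    circle_b_to_c: CircularGenome
    circle_d_to_a: CircularGenome
    carried_junction: dict
    footprints: dict


# ---------------------------------------------------------------------------
# Exact repeat discovery
# ---------------------------------------------------------------------------


def _extend_direct(seq: str, L: int, i: int, j: int, k: int):
    """Maximal synchronized extension of a direct seed match at (i, j).

    Returns canonical (start1, start2, length) or None.  The two copies must
    stay circularly disjoint (adjacency allowed); a pair whose equality run
    would force the copies to overlap (a perfect tandem array of three or more
    periods) is discarded.
    """
    d1 = (j - i) % L
    cap = min(d1, L - d1)
    if cap < k:
        return None
    a, b, m = i, j, k
    # left extension (both copies move together; spacing d1 is invariant)
    while m < cap and seq[(a - 1) % L] == seq[(b - 1) % L]:
        a -= 1
        b -= 1
        m += 1
    # right extension
    while m < cap and seq[(a + m) % L] == seq[(b + m) % L]:
        m += 1
    if m == cap and (
        seq[(a - 1) % L] == seq[(b - 1) % L] or seq[(a + m) % L] == seq[(b + m) % L]
    ):
        return None  # equality run exceeds the spacing: tandem-degenerate
    p, q = a % L, b % L
    return (min(p, q), max(p, q), m)


def _disjoint(a: int, b: int, m: int, L: int) -> bool:
    return (b - a) % L >= m and (a - b) % L >= m


def _extend_inverted(seq: str, L: int, i: int, j: int, k: int):
    """Maximal extension of an inverted seed: copy1 [a, a+m) matches the
    reverse complement of copy2 [b, b+m)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "."}
    a, b, m = i, j, k
    if not _disjoint(a % L, b % L, m, L):
        return None
    # grow left end of copy1 together with right end of copy2
    while (
        seq[(a - 1) % L] == comp[seq[(b + m) % L]]
        and _disjoint((a - 1) % L, b % L, m + 1, L)
    ):
        a -= 1
        m += 1
    blocked_l = seq[(a - 1) % L] == comp[seq[(b + m) % L]]
    # grow right end of copy1 together with left end of copy2
    while (
        seq[(a + m) % L] == comp[seq[(b - 1) % L]]
        and _disjoint(a % L, (b - 1) % L, m + 1, L)
    ):
        b -= 1
        m += 1
    blocked_r = seq[(a + m) % L] == comp[seq[(b - 1) % L]]
    if blocked_l or blocked_r:
        return None  # overlap-blocked while still matching: palindromic-degenerate
    p, q = a % L, b % L
    return (min(p, q), max(p, q), m)


def find_exact_repeats(
    genome: CircularGenome,
    min_len: int,
    orientations: Iterable[str] = ("direct", "inverted"),
) -> list[RepeatPair]:
    """All maximal exact repeat pairs of length >= ``min_len`` on a circle.

    Maximal means extendable in neither direction; pairs spanning the origin
    are found by indexing the doubled sequence.  Each pair is reported once,
    copy1 being the copy with the smaller 1-based start.  ``min_len`` below
    20 is rejected to guard against microhomology explosion.
    """
    orientations = set(orientations)
    if bad := orientations - {"direct", "inverted"}:
        raise ValueError(f"unknown orientations: {sorted(bad)}")
    if min_len < 20:
        raise ValueError("min_len must be >= 20")
    L = genome.length
    seq = genome.sequence
    if min_len > L:
        return []
    k = min_len
    doubled = seq + seq
    index: dict[str, list[int]] = {}
    for p in range(L):
        index.setdefault(doubled[p : p + k], []).append(p)

    found: set[tuple] = set()
    if "direct" in orientations:
        for positions in index.values():
            if len(positions) < 2:
                continue
            for x in range(len(positions)):
                for y in range(x + 1, len(positions)):
                    i, j = positions[x], positions[y]
                    # skip seeds extendable one base to the left: the shifted
                    # seed pair exists in the index and yields the same pair
                    if seq[(i - 1) % L] == seq[(j - 1) % L]:
                        continue
                    pair = _extend_direct(seq, L, i, j, k)
                    if pair:
                        found.add(pair + ("direct",))
    if "inverted" in orientations:
        for p in range(L):
            kmer = doubled[p : p + k]
            for q in index.get(revcomp(kmer), ()):
                if q == p:
                    continue
                pair = _extend_inverted(seq, L, p, q, k)
                if pair:
                    found.add(pair + ("inverted",))

    pairs = []
    for n, (s1, s2, m, orient) in enumerate(
        sorted(found, key=lambda t: (t[0], t[1], t[3]))
    ):
        pairs.append(
            RepeatPair(
                id=f"r{n + 1:02d}",
                copy1=GenomeInterval.from0(s1, m, L),
                copy2=GenomeInterval.from0(s2, m, L),
                orientation=orient,
                rep_length=m,
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# Recombination products
# ---------------------------------------------------------------------------


def _flanks(genome: CircularGenome, pair: RepeatPair, flank: int) -> dict:
    """Flank sequences a/b (around copy 1) and c/d (around copy 2)."""
    L = genome.length
    r = pair.rep_length
    s1, s2 = pair.copy1.start0, pair.copy2.start0
    return {
        "a": genome.fetch(s1 - flank, flank),
        "b": genome.fetch(s1 + r, flank),
        "c": genome.fetch(s2 - flank, flank),
        "d": genome.fetch(s2 + r, flank),
        "R1": genome.fetch(s1, r),
        "R2": genome.fetch(s2, r),
    }


def recomb_products(
    genome: CircularGenome, pair: RepeatPair, flank: int = 200
) -> list[RecombProduct]:
    """The four flank configurations around a direct repeat pair.

    Parental products 1/1 (a-R-b) and 2/2 (c-R-d) exist on the parent genome;
    crossover products 1/2 (a-R-d) and 2/1 (c-R-b) exist only on recombined
    molecules.  Each junction sequence contains exactly one full repeat copy
    with ``flank`` bases of unique sequence on either side.
    """
    if pair.orientation != "direct":
        raise ValueError("recomb_products is defined for direct repeat pairs")
    f = _flanks(genome, pair, flank)
    return [
        RecombProduct(pair.id, "1/1", f["a"] + f["R1"] + f["b"]),
        RecombProduct(pair.id, "2/2", f["c"] + f["R2"] + f["d"]),
        RecombProduct(pair.id, "1/2", f["a"] + f["R1"] + f["d"]),
        RecombProduct(pair.id, "2/1", f["c"] + f["R2"] + f["b"]),
    ]


def predict_products(genome: CircularGenome, pair: RepeatPair) -> SubgenomePrediction:
    """Predict the two circles excised by a crossover between direct repeat copies.

    A crossover between directly oriented copies loops the region between them
    out of the parent circle.  One product circle carries one repeat copy plus
    the segment from the end of copy 1 to the start of copy 2 (it reads
    c-R-b around its repeat, i.e. crossover configuration 2/1); the other
    carries the complementary segment (a-R-d, configuration 1/2).  For an
    inverted pair no circle is excised; use :func:`invert_segment`.
    """
    if pair.orientation == "inverted":
        raise ValueError(
            "predict_products applies to direct pairs; for inverted pairs the "
            "recombination product is an isomer -- use invert_segment"
        )
    L = genome.length
    s1, s2 = pair.copy1.start0, pair.copy2.start0
    len_bc = (s2 - s1) % L  # one repeat copy + segment between copies
    len_da = L - len_bc
    circle_bc = CircularGenome(
        f"{genome.name}|{pair.id}|loopout", genome.fetch(s1, len_bc)
    )
    circle_da = CircularGenome(
        f"{genome.name}|{pair.id}|remainder", genome.fetch(s2, len_da)
    )
    return SubgenomePrediction(
        repeat_id=pair.id,
        circle_b_to_c=circle_bc,
        circle_d_to_a=circle_da,
        carried_junction={"circle_b_to_c": "2/1", "circle_d_to_a": "1/2"},
        footprints={"circle_b_to_c": (s1, len_bc), "circle_d_to_a": (s2, len_da)},
    )


def invert_segment(genome: CircularGenome, pair: RepeatPair) -> CircularGenome:
    """The flip-flop isomer: the segment between two inverted repeat copies
    reverse-complemented in place.  Applying it twice restores the genome."""
    if pair.orientation != "inverted":
        raise ValueError("invert_segment applies to inverted pairs only")
    return invert_between(
        genome,
        (pair.copy1.start0 + pair.rep_length) % genome.length,
        pair.copy2.start0,
        name_suffix=f"|{pair.id}|isomer",
    )


def invert_between(
    genome: CircularGenome, start0: int, end0: int, name_suffix: str = "|inv"
) -> CircularGenome:
    """Genome with the circular segment [start0, end0) reverse-complemented in place."""
    L = genome.length
    seg_len = (end0 - start0) % L
    if seg_len == 0:
        return CircularGenome(genome.name + name_suffix, genome.sequence)
    out = list(genome.sequence)
    rcseg = revcomp(genome.fetch(start0, seg_len))
    for t in range(seg_len):
        out[(start0 + t) % L] = rcseg[t]
    return CircularGenome(genome.name + name_suffix, "".join(out))


# ---------------------------------------------------------------------------
# External interfaces: FASTA and repeat tables
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[CircularGenome]:
    return [CircularGenome(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(genomes: Sequence[CircularGenome], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(g.sequence), id=g.name, description="") for g in genomes]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def repeats_to_table(pairs: Sequence[RepeatPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": p.id,
                "copy1_start": p.copy1.start,
                "copy1_end": p.copy1.end,
                "copy2_start": p.copy2.start,
                "copy2_end": p.copy2.end,
                "orientation": p.orientation,
                "length": p.rep_length,
                "size_class": p.size_class,
            }
            for p in pairs
        ],
        columns=[
            "id",
            "copy1_start",
            "copy1_end",
            "copy2_start",
            "copy2_end",
            "orientation",
            "length",
            "size_class",
        ],
    )


def write_repeat_table(pairs: Sequence[RepeatPair], path: str | Path) -> None:
    repeats_to_table(pairs).to_csv(path, sep="\t", index=False)
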