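"""Seeded paired-end read simulation from mixtures of organellar genome forms.

The generator emulates a whole-genome Illumina library (2 x 150 bp paired-end
by default) drawn from a heteroplasmic population: one master circular genome
plus recombination-derived subgenomes present at specified relative copy
numbers -- loop-out circles and their remainder circles from direct repeat
pairs, flip-flop isomers or arbitrary segment inversions, and chimeric circles
joining two breakpoints.  Every simulated library carries full ground truth
(expected per-kb copy number and the exact planted junctions), so the
downstream stoichiometry and junction-detection stages can be validated
without external data.

The error model is substitution-only: the junction pipeline discards reads
whose alignments contain indels, so indel errors would add nothing testable
(documented limitation).  Base qualities are constant Q40; nothing downstream
consumes them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .repeatome import (
    CircularGenome,
    GenomeInterval,
    RepeatPair,
    invert_between,
    invert_segment,
    predict_products,
    revcomp,
)

BIN_SIZE = 1000


# ---------------------------------------------------------------------------
# Specifications and ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubgenomeSpec:
    """One alternative genome form and its relative copy number.

    kind:
      * ``loopout_circle`` / ``remainder_circle`` -- the two products of a
        crossover between the direct repeat copies of ``repeat_id``;
      * ``inversion`` -- with ``repeat_id``: the flip-flop isomer of an
        inverted pair; with ``breakpoints`` (pos_a, pos_b): the genome with
        the 1-based segment [pos_a, pos_b] reverse-complemented in place;
      * ``chimera`` -- the circularized genome segment [pos_a, pos_b]
        (1-based inclusive, forward, wrapping allowed), whose single novel
        junction joins pos_b back to pos_a.

    ``weight`` is the copy number of the form per master-genome copy.
    """

    kind: str
    weight: float
    repeat_id: str | None = None
    breakpoints: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("loopout_circle", "remainder_circle", "inversion", "chimera"):
            raise ValueError(f"unknown subgenome kind: {self.kind}")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")
        if self.kind == "chimera" and self.breakpoints is None:
            raise ValueError("chimera requires breakpoints")
        if self.kind in ("loopout_circle", "remainder_circle") and self.repeat_id is None:
            raise ValueError(f"{self.kind} requires a repeat_id")
        if self.kind == "inversion" and self.repeat_id is None and self.breakpoints is None:
            raise ValueError("inversion requires a repeat_id or breakpoints")


@dataclass(frozen=True)
class PlantedJunction:
    """Ground-truth junction: two 1-based master positions joined in a subgenome."""

    position_a: int
    position_b: int
    kind: str
    orientation: str  # "same_strand" | "opposite_strand"
    expected_support_class: str  # "detectable" | "repeat_masked" | "degenerate_isomer"


@dataclass
class TruthSet:
    """Simulator ground truth for one library.

    ``per_bin_copy_number`` holds, for each 1-kb bin of the master genome, the
    expected relative copy number: 1.0 for the master alone, plus each
    subgenome's weight scaled by the fraction of the bin its footprint covers.
    """

    per_bin_copy_number: np.ndarray
    planted_junctions: list[PlantedJunction]
    sample_label: str

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sample_label": self.sample_label,
            "per_bin_copy_number": [round(float(x), 6) for x in self.per_bin_copy_number],
            "planted_junctions": [
                {
                    "position_a": j.position_a,
                    "position_b": j.position_b,
                    "kind": j.kind,
                    "orientation": j.orientation,
                    "expected_support_class": j.expected_support_class,
                }
                for j in self.planted_junctions
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass(frozen=True)
class LibraryParams:
    """Sequencing-library parameters (2 x 150 bp paired-end by default)."""

    depth: float
    seed: int
    read_length: int = 150
    fragment_mean: int = 400
    fragment_sd: float = 50.0
    error_rate: float = 0.002

    def __post_init__(self) -> None:
        if self.read_length < 50:
            raise ValueError("read_length must be >= 50")
        if self.fragment_mean < self.read_length:
            raise ValueError("fragment_mean must be >= read_length")
        if not (0 <= self.error_rate < 0.05):
            raise ValueError("error_rate must be in [0, 0.05)")


@dataclass(frozen=True)
class WeightedGenome:
    genome: CircularGenome
    weight: float
    # circular footprint(s) on the master genome, 0-based (start, length)
    footprints: tuple[tuple[int, int], ...]


# ---------------------------------------------------------------------------
# Mixture construction
# ---------------------------------------------------------------------------


def _junction_envelope_class(rep: RepeatPair) -> str:
    # a crossover junction is clip-detectable only when a read can bridge the
    # whole repeat copy plus a minimum anchor and clip; with 150-bp reads that
    # bounds the repeat at roughly 100 bp (see clipjunction docs)
    return "detectable" if rep.rep_length <= 100 else "repeat_masked"


def build_mixture(
    genome: CircularGenome,
    specs: Sequence[SubgenomeSpec],
    repeats: Sequence[RepeatPair] = (),
    sample_label: str = "sample",
) -> tuple[list[WeightedGenome], TruthSet]:
    """Materialize the master genome plus every requested subgenome, with truth.

    The master genome always contributes weight 1.0.  Per-bin expected copy
    number is 1 + the weight of every subgenome whose footprint covers the
    bin (partially covered bins scaled by the covered fraction).
    """
    L = genome.length
    by_id = {r.id: r for r in repeats}
    mixture = [WeightedGenome(genome, 1.0, ((0, L),))]
    junctions: list[PlantedJunction] = []

    for spec in specs:
        if spec.kind in ("loopout_circle", "remainder_circle"):
            rep = by_id.get(spec.repeat_id)
            if rep is None:
                raise ValueError(f"unknown repeat_id: {spec.repeat_id}")
            pred = predict_products(genome, rep)
            which = "circle_b_to_c" if spec.kind == "loopout_circle" else "circle_d_to_a"
            circ = getattr(pred, which)
            mixture.append(WeightedGenome(circ, spec.weight, (pred.footprints[which],)))
            # the carried crossover junction joins the flank downstream of one
            # copy to the flank upstream of the other, on the same strand
            s1, s2, r = rep.copy1.start0, rep.copy2.start0, rep.rep_length
            if which == "circle_b_to_c":  # c-R-b: copy2 upstream -> copy1 downstream
                pos_a, pos_b = (s2 - 1) % L + 1, (s1 + r) % L + 1
            else:  # a-R-d: copy1 upstream -> copy2 downstream
                pos_a, pos_b = (s1 - 1) % L + 1, (s2 + r) % L + 1
            junctions.append(
                PlantedJunction(
                    pos_a, pos_b, spec.kind, "same_strand", _junction_envelope_class(rep)
                )
            )
        elif spec.kind == "inversion":
            if spec.repeat_id is not None:
                rep = by_id.get(spec.repeat_id)
                if rep is None:
                    raise ValueError(f"unknown repeat_id: {spec.repeat_id}")
                iso = invert_segment(genome, rep)
                mixture.append(WeightedGenome(iso, spec.weight, ((0, L),)))
                junctions.append(
                    PlantedJunction(
                        rep.copy1.end,
                        rep.copy2.start,
                        "inversion",
                        "opposite_strand",
                        "degenerate_isomer",
                    )
                )
            else:
                pa, pb = spec.breakpoints
                _check_pos(pa, L)
                _check_pos(pb, L)
                inv = invert_between(genome, pa - 1, pb % L, name_suffix=f"|inv{pa}-{pb}")
                mixture.append(WeightedGenome(inv, spec.weight, ((0, L),)))
                junctions.append(
                    PlantedJunction(pa - 1 if pa > 1 else L, pb, "inversion",
                                    "opposite_strand", "detectable")
                )
                junctions.append(
                    PlantedJunction(pa, pb % L + 1, "inversion",
                                    "opposite_strand", "detectable")
                )
        elif spec.kind == "chimera":
            pa, pb = spec.breakpoints
            _check_pos(pa, L)
            _check_pos(pb, L)
            seg_len = (pb - pa) % L + 1
            chim = CircularGenome(
                f"{genome.name}|chimera{pa}-{pb}", genome.fetch(pa - 1, seg_len)
            )
            mixture.append(WeightedGenome(chim, spec.weight, ((pa - 1, seg_len),)))
            junctions.append(
                PlantedJunction(pb, pa, "chimera", "same_strand", "detectable")
            )

    truth = TruthSet(
        per_bin_copy_number=_expected_copy_number(L, mixture),
        planted_junctions=junctions,
        sample_label=sample_label,
    )
    return mixture, truth


def _check_pos(pos: int, L: int) -> None:
    if not 1 <= pos <= L:
        raise ValueError(f"breakpoint {pos} outside genome of length {L}")


def _expected_copy_number(L: int, mixture: Sequence[WeightedGenome]) -> np.ndarray:
    per_base = np.zeros(L)
    for wg in mixture:
        for start, length in wg.footprints:
            s = start % L
            if s + length <= L:
                per_base[s : s + length] += wg.weight
            else:
                per_base[s:] += wg.weight
                per_base[: s + length - L] += wg.weight
    nbins = math.ceil(L / BIN_SIZE)
    out = np.empty(nbins)
    for b in range(nbins):
        out[b] = per_base[b * BIN_SIZE : (b + 1) * BIN_SIZE].mean()
    return out


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def expected_pair_count(mixture: Sequence[WeightedGenome], params: LibraryParams) -> int:
    """Rounding rule: n_pairs = round(depth * total_weighted_length / (2 * read_length)).

    ``depth`` is the mean per-base read coverage of the weighted mixture,
    which equals the master-genome fold coverage when no subgenomes are
    planted.
    """
    wl = sum(wg.weight * wg.genome.length for wg in mixture)
    return int(round(params.depth * wl / (2 * params.read_length)))


def simulate_reads(
    mixture: Sequence[WeightedGenome],
    params: LibraryParams,
    sample_label: str = "sample",
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Draw paired-end reads from a weighted genome mixture.

    Fragments are assigned to molecules with probability proportional to
    weight x length, start uniformly on each circle, and have lengths from a
    normal(fragment_mean, fragment_sd) truncated to [read_length,
    3 x fragment_mean].  Each fragment yields a forward read from its 5' end
    and a reverse-complement read from its 3' end; with probability 1/2 the
    fragment derives from the opposite strand (the two read roles swap).
    Substitution errors are applied per base at ``error_rate``.  A fixed seed
    gives byte-identical output.

    Returns (r1, r2) as lists of (header, sequence); headers carry a truth
    comment ``src=<molecule>;pos=<start>-<end>;strand=<+/->`` with 1-based
    inclusive fragment coordinates on the source molecule.
    """
    active = [wg for wg in mixture if wg.weight > 0]
    if not active:
        raise ValueError("empty mixture: total weight must be > 0")
    if params.depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(params.seed)
    wl = np.array([wg.weight * wg.genome.length for wg in active])
    n_pairs = int(round(params.depth * wl.sum() / (2 * params.read_length)))
    mol_idx = rng.choice(len(active), size=n_pairs, p=wl / wl.sum())
    rl = params.read_length
    flen_max = 3 * params.fragment_mean

    r1_out: list[tuple[str, str]] = []
    r2_out: list[tuple[str, str]] = []
    for i in range(n_pairs):
        wg = active[mol_idx[i]]
        Lm = wg.genome.length
        start = int(rng.integers(0, Lm))
        flen = int(round(rng.normal(params.fragment_mean, params.fragment_sd)))
        flen = max(rl, min(flen, flen_max, Lm))
        frag = wg.genome.fetch(start, flen)
        fwd = frag[:rl]
        rev = revcomp(frag[-rl:])
        strand = "+" if rng.random() < 0.5 else "-"
        read1, read2 = (fwd, rev) if strand == "+" else (rev, fwd)
        read1 = _mutate(read1, params.error_rate, rng)
        read2 = _mutate(read2, params.error_rate, rng)
        end1 = (start + flen - 1) % Lm + 1
        comment = f"src={wg.genome.name};pos={start + 1}-{end1};strand={strand}"
        qname = f"{sample_label}.{i:07d}"
        r1_out.append((f"{qname}/1 {comment}", read1))
        r2_out.append((f"{qname}/2 {comment}", read2))
    return r1_out, r2_out


def _mutate(read: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return read
    n = len(read)
    hits = np.flatnonzero(rng.random(n) < error_rate)
    if hits.size == 0:
        return read
    out = bytearray(read.encode())
    for p in hits:
        choices = [b for b in b"ACGT" if b != out[p]]
        out[p] = choices[int(rng.integers(0, 3))]
    return out.decode()


def parse_truth_header(header: str) -> tuple[str, int, int, str]:
    """Decode a simulated read header into (molecule, start, end, strand)."""
    comment = header.split(" ", 1)[1]
    fields = dict(kv.split("=", 1) for kv in comment.split(";"))
    start, end = fields["pos"].split("-")
    return fields["src"], int(start), int(end), fields["strand"]


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    """4-line FASTQ records with constant Q40 ('I') qualities."""
    with open(path, "w") as fh:
        for header, seq in reads:
            fh.write(f"@{header}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Synthetic genome construction
# ---------------------------------------------------------------------------


def random_genome(length: int, seed: int, name: str = "toy") -> CircularGenome:
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=length).tobytes().decode()
    return CircularGenome(name, seq)


def plant_repeat(
    sequence: str, rep_length: int, start1_0: int, start2_0: int, orientation: str
) -> str:
    """Copy the ``rep_length`` segment at ``start1_0`` to ``start2_0`` (reverse
    complemented for an inverted pair), returning the edited sequence."""
    L = len(sequence)
    src = (sequence + sequence)[start1_0 : start1_0 + rep_length]
    ins = src if orientation == "direct" else revcomp(src)
    out = list(sequence)
    for t, ch in enumerate(ins):
        out[(start2_0 + t) % L] = ch
    return "".join(out)


def make_test_genome(
    length: int,
    seed: int,
    repeat_plan: Sequence[tuple[str, int, int, int, str]] = (),
    name: str = "toy",
) -> tuple[CircularGenome, list[RepeatPair]]:
    """Random circular genome with planted exact repeat pairs.

    ``repeat_plan`` entries are (id, rep_length, start1, start2, orientation)
    with 1-based starts.  Returns the genome and the planted pairs as
    RepeatPair records (coordinates as planted; planted pairs should be well
    separated so chance extension is negligible).
    """
    seq = random_genome(length, seed, name).sequence
    pairs = []
    for rid, rlen, s1, s2, orient in repeat_plan:
        seq = plant_repeat(seq, rlen, s1 - 1, s2 - 1, orient)
        pairs.append(
            RepeatPair(
                id=rid,
                copy1=GenomeInterval.from0(s1 - 1, rlen, length),
                copy2=GenomeInterval.from0(s2 - 1, rlen, length),
                orientation=orient,
                rep_length=rlen,
            )
        )
    return CircularGenome(name, seq), pairs
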