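"""Rearrangement junction detection from soft-clipped reads.

A read sequenced across the junction of a rearranged molecule aligns to the
reference in two pieces: an anchor block and a soft-clipped tail (CIGAR S)
that maps elsewhere.  The pipeline keeps mapped reads whose CIGAR contains a
soft clip of at least 20 nucleotides and no insertion, deletion or hard clip
(I, D, H); extracts the clipped sequence; remaps it end-to-end against the
same genome (a clip that does not align over its full length, or aligns
equally well at several places, is dropped and counted); and aggregates the
(anchor, clip) placements into junction events at 1-kb bin resolution.

For chloroplast-like genomes, recombination between the two copies of the
large inverted repeat merely interconverts the two genome isomers
("flip-flop" isomerization) and is not a rearrangement of interest: events
whose two endpoints both fall at the boundaries of a large inverted repeat
pair with opposite-strand orientation are flagged and excluded.  Event burden
is summarized as junction-supporting reads per genome copy (total support
divided by the genome's mean per-bin depth).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .covscan import CoverageProfile, position_to_bin
from .microalign import Aligner, AlignmentRecord, AlignParams
from .repeatome import CircularGenome, RepeatPair

BIN_SIZE = 1000


@dataclass(frozen=True)
class ClipFilterParams:
    min_clip: int = 20
    forbidden_ops: frozenset = frozenset("IDH")

    def __post_init__(self) -> None:
        if self.min_clip < 1:
            raise ValueError("min_clip must be >= 1")


@dataclass
class ClippedRead:
    """One qualifying soft clip: its anchor record, side, sequence and the
    1-based genome position where the aligned block ends on the clipped side."""

    read_id: str
    mate: int
    anchor: AlignmentRecord
    clip_side: str  # "left" | "right"
    clip_sequence: str
    anchor_breakpoint: int
    # filled by map_clips:
    clip_pos: int = 0  # 1-based leftmost position of the end-to-end clip placement
    clip_strand: str = "+"
    placed: bool = False


def cigar_passes(cigar: Sequence[tuple[str, int]], params: ClipFilterParams) -> bool:
    """True iff the CIGAR has >= 1 soft clip of length >= min_clip and none of
    the forbidden operations (I, D, H by default)."""
    if any(op in params.forbidden_ops for op, _ in cigar):
        return False
    return any(op == "S" and n >= params.min_clip for op, n in cigar)


def passes_clip_filter(
    record: AlignmentRecord, params: ClipFilterParams | None = None
) -> list[ClippedRead]:
    """Qualifying clips of one mapped record (empty list = record rejected).

    Both clips of a doubly soft-clipped read are returned and processed
    independently downstream.
    """
    params = params or ClipFilterParams()
    if not record.mapped or not cigar_passes(record.cigar, params):
        return []
    clips: list[ClippedRead] = []
    first_op, first_n = record.cigar[0]
    last_op, last_n = record.cigar[-1]
    if first_op == "S" and first_n >= params.min_clip:
        clips.append(
            ClippedRead(
                read_id=record.read_id,
                mate=record.mate,
                anchor=record,
                clip_side="left",
                clip_sequence=record.seq[:first_n],
                anchor_breakpoint=record.pos,
            )
        )
    if last_op == "S" and last_n >= params.min_clip:
        clips.append(
            ClippedRead(
                read_id=record.read_id,
                mate=record.mate,
                anchor=record,
                clip_side="right",
                clip_sequence=record.seq[-last_n:],
                anchor_breakpoint=record.pos + record.ref_span - 1,
            )
        )
    return clips


def extract_clips(
    records: Sequence[AlignmentRecord],
    params: ClipFilterParams | None = None,
    require_unique_anchor: bool = True,
) -> tuple[list[ClippedRead], dict]:
    """Apply the clip filter to a whole library; multi-mapped anchors are
    excluded from event support and counted."""
    params = params or ClipFilterParams()
    clips: list[ClippedRead] = []
    stats = {"records": 0, "clip_candidates": 0, "multi_anchor": 0}
    for rec in records:
        if not rec.mapped:
            continue
        stats["records"] += 1
        for clip in passes_clip_filter(rec, params):
            stats["clip_candidates"] += 1
            if require_unique_anchor and not rec.is_unique:
                stats["multi_anchor"] += 1
                continue
            clips.append(clip)
    return clips, stats


def map_clips(
    clips: Sequence[ClippedRead],
    genome: CircularGenome,
    params: AlignParams | None = None,
) -> tuple[list[ClippedRead], dict]:
    """Remap each clip as an independent end-to-end segment.

    The entire clip must align within the mismatch cap; partial placements
    are discarded, and clips with several equally good full-length placements
    (e.g. both copies of a repeat) are dropped as non-unique.  Drop counts
    are returned alongside the placed clips.
    """
    params = params or AlignParams()
    aligner = Aligner(genome, params)
    placed: list[ClippedRead] = []
    stats = {"input": len(clips), "placed": 0, "unmapped": 0, "multi": 0}
    for clip in clips:
        rec = aligner.align(clip.read_id, clip.clip_sequence, require_full=True)
        if not rec.mapped:
            stats["unmapped"] += 1
            continue
        if not rec.is_unique:
            stats["multi"] += 1
            continue
        out = replace(clip)
        out.clip_pos = rec.pos
        out.clip_strand = rec.strand
        out.placed = True
        placed.append(out)
        stats["placed"] += 1
    return placed, stats


@dataclass
class JunctionEvent:
    """A junction at kb resolution: (anchor bin, clip bin, relative strand)."""

    anchor_bin: int
    clip_bin: int
    orientation: str  # "same_strand" | "opposite_strand"
    support: int
    is_isomerization: bool = False


def _clip_junction_base(clip: ClippedRead) -> int:
    """Genome position of the junction-proximal base of the placed clip."""
    span = len(clip.clip_sequence)
    left_end, right_end = clip.clip_pos, clip.clip_pos + span - 1
    if clip.clip_side == "right":
        # the clip continues the read after the anchor: its junction-proximal
        # base is its first base in read orientation
        return left_end if clip.clip_strand == "+" else right_end
    return right_end if clip.clip_strand == "+" else left_end


def call_junctions(
    placed_clips: Sequence[ClippedRead], bin_size: int = BIN_SIZE
) -> list[JunctionEvent]:
    """Aggregate placed clips into events keyed by (anchor bin, clip bin,
    orientation); support counts distinct reads (mates count separately).
    Events are ordered by decreasing support, then coordinates."""
    buckets: dict[tuple, set] = {}
    for clip in placed_clips:
        if not clip.placed:
            continue
        orientation = "same_strand" if clip.clip_strand == "+" else "opposite_strand"
        key = (
            position_to_bin(clip.anchor_breakpoint, bin_size),
            position_to_bin(_clip_junction_base(clip), bin_size),
            orientation,
        )
        buckets.setdefault(key, set()).add((clip.read_id, clip.mate))
    events = [
        JunctionEvent(anchor_bin=k[0], clip_bin=k[1], orientation=k[2], support=len(v))
        for k, v in buckets.items()
    ]
    events.sort(key=lambda e: (-e.support, e.anchor_bin, e.clip_bin, e.orientation))
    return events


def filter_isomerization(
    events: Sequence[JunctionEvent],
    large_inverted_repeats: Sequence[RepeatPair],
    bin_size: int = BIN_SIZE,
) -> list[JunctionEvent]:
    """Flag events attributable to flip-flop isomerization of a large
    inverted repeat.

    An event is flagged iff its orientation is opposite_strand and both of
    its bins fall within one bin of the boundaries of the same large inverted
    repeat pair.  (The one-bin tolerance absorbs the kb rounding; requiring
    both endpoints near the IR rather than strictly "corresponding"
    boundaries also catches the reflected placements that repeat-copy
    ambiguity produces.)  Only pairs with orientation inverted and size class
    large participate.  Flagged events are excluded from downstream counts by
    their ``is_isomerization`` flag.
    """
    irs = [
        r
        for r in large_inverted_repeats
        if r.orientation == "inverted" and r.size_class == "large"
    ]
    boundary_bins = [
        {
            position_to_bin(r.copy1.start, bin_size),
            position_to_bin(r.copy1.end, bin_size),
            position_to_bin(r.copy2.start, bin_size),
            position_to_bin(r.copy2.end, bin_size),
        }
        for r in irs
    ]
    out = []
    for ev in events:
        flagged = ev.orientation == "opposite_strand" and any(
            min(abs(ev.anchor_bin - b) for b in bb) <= 1
            and min(abs(ev.clip_bin - b) for b in bb) <= 1
            for bb in boundary_bins
        )
        out.append(replace(ev, is_isomerization=flagged))
    return out


def retained(events: Sequence[JunctionEvent]) -> list[JunctionEvent]:
    return [e for e in events if not e.is_isomerization]


def events_per_genome_copy(
    events: Sequence[JunctionEvent], profile: CoverageProfile
) -> float:
    """Total support of retained events divided by the genome's mean per-bin
    depth -- junction-supporting reads per genome copy."""
    depth = profile.genome_mean_depth
    if depth == 0:
        raise ValueError("zero mean depth: profile is empty")
    return sum(e.support for e in retained(events)) / depth


def events_to_table(events: Sequence[JunctionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "anchor_bin": e.anchor_bin,
                "clip_bin": e.clip_bin,
                "orientation": e.orientation,
                "support": e.support,
                "is_isomerization": e.is_isomerization,
            }
            for e in events
        ],
        columns=["anchor_bin", "clip_bin", "orientation", "support", "is_isomerization"],
    )


def write_events(events: Sequence[JunctionEvent], path: str | Path) -> None:
    events_to_table(events).to_csv(path, sep="\t", index=False)
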