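"""Soft-clip filtering, clip remapping, junction calling and isomerization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import cigar_regex_oracle, random_cigar
from orgrearr.clipjunction import (
    ClipFilterParams,
    ClippedRead,
    JunctionEvent,
    call_junctions,
    cigar_passes,
    events_per_genome_copy,
    filter_isomerization,
    map_clips,
    passes_clip_filter,
    retained,
)
from orgrearr.covscan import CoverageProfile
from orgrearr.microalign import AlignmentRecord
from orgrearr.repeatome import CircularGenome, GenomeInterval, RepeatPair
from orgrearr.scenarios import _junction_pipeline, simulate_and_align
from orgrearr.simlib import SubgenomeSpec, make_test_genome, plant_repeat, random_genome


def rec(cigar, pos=1_000, seq=None, unique=True, mapped=True, read_id="r", mate=1):
    n = sum(ln for op, ln in cigar if op in "MIS=X") or 150
    return AlignmentRecord(
        read_id, "g", pos, "+", cigar, seq or "A" * n, mapped=mapped, is_unique=unique,
        mate=mate,
    )


class TestClipFilter:
    def test_right_clip_above_threshold_accepted(self):
        clips = passes_clip_filter(rec([("M", 100), ("S", 50)]))
        assert len(clips) == 1
        assert clips[0].clip_side == "right" and len(clips[0].clip_sequence) == 50

    def test_clip_below_threshold_rejected(self):
        assert passes_clip_filter(rec([("M", 140), ("S", 10)])) == []

    def test_indel_containing_read_rejected(self):
        assert passes_clip_filter(rec([("M", 60), ("I", 5), ("M", 60), ("S", 25)])) == []
        assert passes_clip_filter(rec([("M", 60), ("D", 5), ("M", 65), ("S", 25)])) == []
        assert passes_clip_filter(rec([("H", 10), ("M", 120), ("S", 30)])) == []

    def test_unclipped_read_rejected(self):
        assert passes_clip_filter(rec([("M", 150)])) == []

    def test_double_clip_processed_independently(self):
        clips = passes_clip_filter(rec([("S", 30), ("M", 90), ("S", 30)]))
        assert [c.clip_side for c in clips] == ["left", "right"]

    def test_breakpoint_positions(self):
        left, right = passes_clip_filter(rec([("S", 30), ("M", 90), ("S", 30)], pos=2_000))
        assert left.anchor_breakpoint == 2_000
        assert right.anchor_breakpoint == 2_000 + 90 - 1

    def test_clip_sequences_taken_from_read_ends(self):
        seq = "C" * 30 + "A" * 90 + "G" * 30
        left, right = passes_clip_filter(rec([("S", 30), ("M", 90), ("S", 30)], seq=seq))
        assert left.clip_sequence == "C" * 30 and right.clip_sequence == "G" * 30

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_regex_oracle(self, seed):
        cigar = random_cigar(np.random.default_rng(seed))
        text = "".join(f"{n}{op}" for op, n in cigar)
        assert cigar_passes(cigar, ClipFilterParams()) == cigar_regex_oracle(text)


@pytest.fixture(scope="module")
def clip_genome():
    seq = plant_repeat(random_genome(50_000, seed=501).sequence, 300, 5_000, 25_000, "direct")
    return CircularGenome("g", seq)


class TestMapClips:

    def _clip(self, seq):
        anchor = rec([("M", 100), ("S", len(seq))])
        return ClippedRead("r", 1, anchor, "right", seq, 1_099)

    def test_verbatim_clip_placed(self, clip_genome):
        placed, stats = map_clips([self._clip(clip_genome.fetch(40_000, 40))], clip_genome)
        assert stats == {"input": 1, "placed": 1, "unmapped": 0, "multi": 0}
        assert placed[0].clip_pos == 40_001 and placed[0].clip_strand == "+"

    def test_random_clip_dropped_unmapped(self, clip_genome):
        rng = np.random.default_rng(6)
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
        placed, stats = map_clips([self._clip(junk)], clip_genome)
        assert placed == [] and stats["unmapped"] == 1

    def test_repeat_matching_clip_dropped_as_multi(self, clip_genome):
        placed, stats = map_clips([self._clip(clip_genome.fetch(5_050, 60))], clip_genome)
        assert placed == [] and stats["multi"] == 1

    def test_partial_placement_discarded(self, clip_genome):
        # half genomic, half junk: the clip must align end-to-end or not at all
        rng = np.random.default_rng(7)
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, 25))
        placed, stats = map_clips([self._clip(clip_genome.fetch(40_000, 25) + junk)], clip_genome)
        assert placed == [] and stats["unmapped"] == 1


class TestCallJunctions:
    def _placed(self, read_id, mate, anchor_bp, clip_pos, clip_strand, side="right", n=30):
        anchor = rec([("M", 120), ("S", n)], read_id=read_id, mate=mate)
        c = ClippedRead(read_id, mate, anchor, side, "A" * n, anchor_bp)
        c.clip_pos, c.clip_strand, c.placed = clip_pos, clip_strand, True
        return c

    def test_events_keyed_and_sorted_by_support(self):
        clips = [self._placed(f"r{i}", 1, 10_500, 50_200, "+") for i in range(5)]
        clips += [self._placed(f"q{i}", 1, 30_500, 8_200, "-") for i in range(2)]
        events = call_junctions(clips)
        assert [(e.anchor_bin, e.clip_bin, e.orientation, e.support) for e in events] == [
            (11, 51, "same_strand", 5),
            (31, 9, "opposite_strand", 2),
        ]

    def test_mates_count_as_distinct_support(self):
        clips = [
            self._placed("r", 1, 10_500, 50_200, "+"),
            self._placed("r", 2, 10_500, 50_200, "+"),
        ]
        assert call_junctions(clips)[0].support == 2

    def test_duplicate_clip_from_same_read_counts_once(self):
        clips = [self._placed("r", 1, 10_500, 50_200, "+")] * 2
        assert call_junctions(clips)[0].support == 1

    def test_clip_junction_base_respects_side_and_strand(self):
        # right clip on '-' strand: junction-proximal base is its rightmost
        c = self._placed("r", 1, 10_500, 50_181, "-", n=30)
        assert call_junctions([c])[0].clip_bin == 51  # 50_181+29 = 50_210 -> bin 51
        c = self._placed("r", 1, 10_500, 50_981, "+", side="left", n=30)
        assert call_junctions([c])[0].clip_bin == 52  # left clip, '+': rightmost


class TestPlantedChimeras:
    def test_precision_and_recall_are_perfect(self, junction_result):
        precision, recall = junction_result.precision_recall()
        assert precision == 1.0 and recall == 1.0

    def test_supports_match_between_manifestations(self, junction_result):
        # every event's bin pair corresponds to one planted junction
        truth = junction_result.truth_bin_pairs()
        for e in junction_result.events:
            assert any((e.anchor_bin, e.clip_bin) in t for t in truth)

    def test_master_only_library_is_silent(self, junction_result):
        assert junction_result.master_only_events == []


class TestIsomerizationFilter:
    @pytest.fixture()
    def ir(self):
        return RepeatPair(
            "IR",
            GenomeInterval(20_001, 22_000),
            GenomeInterval(40_001, 42_000),
            "inverted",
            2_000,
        )

    def _ev(self, a, c, orientation="opposite_strand"):
        return JunctionEvent(a, c, orientation, support=3)

    def test_boundary_events_flagged(self, ir):
        events = [self._ev(22, 41), self._ev(21, 42), self._ev(23, 40)]
        flagged = filter_isomerization(events, [ir])
        assert all(e.is_isomerization for e in flagged)
        assert retained(flagged) == []

    def test_same_strand_boundary_event_not_flagged(self, ir):
        (e,) = filter_isomerization([self._ev(22, 41, "same_strand")], [ir])
        assert not e.is_isomerization

    def test_unrelated_event_not_flagged(self, ir):
        (e,) = filter_isomerization([self._ev(5, 12)], [ir])
        assert not e.is_isomerization

    def test_empty_ir_list_is_vacuous(self):
        (e,) = filter_isomerization([self._ev(22, 41)], [])
        assert not e.is_isomerization

    def test_small_inverted_pairs_ignored(self):
        small = RepeatPair(
            "s", GenomeInterval(20_001, 20_100), GenomeInterval(40_001, 40_100),
            "inverted", 100,
        )
        (e,) = filter_isomerization([self._ev(20, 40)], [small])
        assert not e.is_isomerization

    def test_flip_flop_isomer_contributes_no_retained_events(self, isomer_result):
        """Everything attributable to the large IR is flagged and excluded;
        junctions far from the IR survive."""
        attributable = isomer_result.ir_attributable()
        assert attributable  # the near-boundary inversion produces events
        assert all(e.is_isomerization for e in attributable)
        far = isomer_result.far_retained()
        assert far and all(not e.is_isomerization for e in far)


class TestEventsPerGenomeCopy:
    def _profile(self, depth):
        return CoverageProfile("g", 10_000, np.full(10, depth * 1_000.0), total_reads=100)

    def test_arithmetic(self):
        events = [JunctionEvent(1, 5, "same_strand", 5)]
        assert events_per_genome_copy(events, self._profile(10)) == pytest.approx(0.5)

    def test_zero_events(self):
        assert events_per_genome_copy([], self._profile(10)) == 0.0

    def test_isomerization_events_excluded(self):
        events = [
            JunctionEvent(1, 5, "same_strand", 5),
            JunctionEvent(2, 6, "opposite_strand", 50, is_isomerization=True),
        ]
        assert events_per_genome_copy(events, self._profile(10)) == pytest.approx(0.5)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            events_per_genome_copy([], self._profile(0))

    def test_rearrangement_burden_below_one_event_per_copy(self, isomer_result):
        """The chloroplast-like scenario keeps rearranged molecules rare:
        well under one junction-supporting read per genome copy."""
        assert 0 < isomer_result.events_per_copy < 1.0


class TestDetectionEnvelope:
    """Crossover junctions over a repeat of length r are clip-detectable only
    when a 150-bp read can bridge the repeat plus minimum anchor and clip
    (r <= 150 - 20 - 30); a 249-bp repeat junction is invisible."""

    def _events_for_repeat(self, rep_len, seed=601):
        genome, repeats = make_test_genome(
            20_000, seed=seed, repeat_plan=[("R", rep_len, 6_001, 14_001, "direct")]
        )
        records, _, _ = simulate_and_align(
            genome,
            [SubgenomeSpec(kind="loopout_circle", repeat_id="R", weight=2.0)],
            repeats,
            depth=40,
            seed=seed + 1,
            error_rate=0.0,
        )
        events, _, _ = _junction_pipeline(records, genome)
        return events, repeats[0]

    def test_60bp_repeat_junction_detected(self):
        events, rep = self._events_for_repeat(60)
        assert events
        # the crossover junction joins the two repeat loci (bins ~7 and ~15)
        assert any({e.anchor_bin, e.clip_bin} <= {5, 6, 7, 13, 14, 15} for e in events)

    def test_249bp_repeat_junction_undetected(self):
        events, _ = self._events_for_repeat(249)
        assert events == []
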