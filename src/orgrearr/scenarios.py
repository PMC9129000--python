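"""Canonical validation scenarios: seeded synthetic studies with known truth.

Each function builds a small organelle-like genome, plants recombination
subgenomes at known stoichiometry, simulates a paired-end library, runs the
relevant pipeline stages and returns both the results and the ground truth.
Tests and the acceptance script share these definitions, so the study
conditions (genome sizes, repeat layouts, subgenome weights, depths) are
fixed in one place:

* stoichiometry: 60-kb genome, 127-bp direct pair spanning 12 kb, loop-out
  circle at 7 copies per master genome (an eight-fold amplified sublimon,
  matching the strongest stoichiometry shifts seen in recombination-deficient
  mutants) against a weight-0 control, 40x depth;
* junctions: 50-kb genome with three chimeric circles at 0.5 copies each,
  error-free 40x library, plus a master-only control;
* isomerization: 60-kb chloroplast-like genome with a 2-kb inverted repeat,
  its flip-flop isomer at weight 1, an inverted-segment junction planted just
  inside the repeat boundaries (the signature attributed to isomerization)
  and a control inversion far from the repeat, error-free 30x;
* crossover: 20-kb genome, 127-bp direct pair, only the loop-out circle
  planted at weight 1, 250x (fragment-length tails must bridge the repeat,
  so informative fragments are rare and need depth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clipjunction import (
    JunctionEvent,
    call_junctions,
    events_per_genome_copy,
    extract_clips,
    filter_isomerization,
    map_clips,
    retained,
)
from .covscan import CoverageProfile, StoichiometryReport, bin_coverage, compare_profiles, position_to_bin
from .microalign import Aligner, AlignmentRecord, AlignParams
from .repeatome import CircularGenome, RepeatPair
from .simlib import (
    LibraryParams,
    SubgenomeSpec,
    TruthSet,
    build_mixture,
    make_test_genome,
    simulate_reads,
)
from .xoverquant import ConfigCounts, classify_spanning_pairs, relative_accumulation


def _align_library(
    genome: CircularGenome,
    r1: list[tuple[str, str]],
    r2: list[tuple[str, str]],
    params: AlignParams | None = None,
    tie_seed: int = 0,
) -> list[AlignmentRecord]:
    """Align in-memory simulated reads (header comments are dropped)."""
    params = params or AlignParams()
    aligner = Aligner(genome, params)
    rng = np.random.default_rng(tie_seed)
    records = []
    for mate, reads in ((1, r1), (2, r2)):
        for header, seq in reads:
            name = header.split(" ", 1)[0]
            name = name[:-2] if name.endswith(("/1", "/2")) else name
            rec = aligner.align(name, seq, rng=rng)
            rec.mate = mate
            records.append(rec)
    return records


def simulate_and_align(
    genome: CircularGenome,
    specs: list[SubgenomeSpec],
    repeats: list[RepeatPair],
    depth: float,
    seed: int,
    error_rate: float = 0.002,
    label: str = "sample",
) -> tuple[list[AlignmentRecord], TruthSet, int]:
    """Simulate one library and align it; returns (records, truth, n_reads)."""
    mixture, truth = build_mixture(genome, specs, repeats, sample_label=label)
    params = LibraryParams(depth=depth, seed=seed, error_rate=error_rate)
    r1, r2 = simulate_reads(mixture, params, sample_label=label)
    records = _align_library(genome, r1, r2)
    return records, truth, len(r1) + len(r2)


# ---------------------------------------------------------------------------
# Stoichiometry recovery (amplified loop-out sublimon)
# ---------------------------------------------------------------------------


@dataclass
class StoichResult:
    genome: CircularGenome
    repeat: RepeatPair
    report: StoichiometryReport
    truth: TruthSet
    sample_profile: CoverageProfile
    control_profile: CoverageProfile

    @property
    def loopout_bins(self) -> tuple[int, int]:
        """First and last 1-kb bin fully inside the loop-out footprint."""
        return (
            position_to_bin(self.repeat.copy1.start),
            position_to_bin(self.repeat.copy2.start - 1),
        )

    @property
    def matching_region(self):
        lo, hi = self.loopout_bins
        for region in self.report.regions:
            if abs(region.start_bin - lo) <= 1 and abs(region.end_bin - hi) <= 1:
                return region
        return None


def stoichiometry_recovery(seed: int, weight: float = 7.0, depth: float = 40.0) -> StoichResult:
    """Plant a loop-out circle at ``weight`` copies per master genome and
    recover the amplified region from sample-vs-control coverage."""
    genome, repeats = make_test_genome(
        60_000, seed=seed * 7 + 1, repeat_plan=[("EE", 127, 20_001, 32_001, "direct")]
    )
    sample_recs, truth, n_s = simulate_and_align(
        genome,
        [SubgenomeSpec(kind="loopout_circle", repeat_id="EE", weight=weight)],
        repeats,
        depth=depth,
        seed=seed * 7 + 2,
        label="mutant",
    )
    control_recs, _, n_c = simulate_and_align(
        genome, [], repeats, depth=depth, seed=seed * 7 + 3, label="wt"
    )
    # both libraries are normalized to the same nominal total-library size: in
    # the real assay per-million normalization uses the whole genomic library,
    # which is dominated by an unchanged nuclear background, so organellar
    # amplification does not alter the normalizer; the simulated libraries
    # contain only organellar reads, so the constant total plays that role
    nominal_total = 1_000_000
    sample_prof = bin_coverage(sample_recs, genome.length, nominal_total, genome.name)
    control_prof = bin_coverage(control_recs, genome.length, nominal_total, genome.name)
    report = compare_profiles(sample_prof, control_prof, flag_threshold=1.0, repeats=repeats)
    return StoichResult(genome, repeats[0], report, truth, sample_prof, control_prof)


# ---------------------------------------------------------------------------
# Junction calling precision/recall (planted chimeras)
# ---------------------------------------------------------------------------


@dataclass
class JunctionResult:
    genome: CircularGenome
    truth: TruthSet
    events: list[JunctionEvent]
    master_only_events: list[JunctionEvent]
    clip_stats: dict
    map_stats: dict

    def truth_bin_pairs(self) -> list[set]:
        out = []
        for j in self.truth.planted_junctions:
            ba, bb = position_to_bin(j.position_a), position_to_bin(j.position_b)
            out.append({(ba, bb), (bb, ba)})
        return out

    def precision_recall(self) -> tuple[float, float]:
        truth_pairs = self.truth_bin_pairs()
        called = [(e.anchor_bin, e.clip_bin) for e in self.events]
        if called:
            tp_calls = sum(1 for c in called if any(c in t for t in truth_pairs))
            precision = tp_calls / len(called)
        else:
            precision = 0.0
        recall = sum(
            1 for t in truth_pairs if any(c in t for c in called)
        ) / len(truth_pairs)
        return precision, recall


def junction_precision_recall(seed: int, depth: float = 40.0) -> JunctionResult:
    """Three chimeric circles, error-free library: every planted junction
    should be called and nothing else."""
    genome, _ = make_test_genome(50_000, seed=seed * 11 + 1)
    # breakpoints sit mid-bin: ungapped extension can slip a few bases past a
    # junction before the mismatch-rate cap bites, which must not change bins
    specs = [
        SubgenomeSpec(kind="chimera", breakpoints=(5_501, 20_400), weight=0.5),
        SubgenomeSpec(kind="chimera", breakpoints=(25_501, 33_400), weight=0.5),
        SubgenomeSpec(kind="chimera", breakpoints=(38_501, 47_400), weight=0.5),
    ]
    records, truth, _ = simulate_and_align(
        genome, specs, [], depth=depth, seed=seed * 11 + 2, error_rate=0.0
    )
    events, clip_stats, map_stats = _junction_pipeline(records, genome)
    master_recs, _, _ = simulate_and_align(
        genome, [], [], depth=20.0, seed=seed * 11 + 3, error_rate=0.0
    )
    master_events, _, _ = _junction_pipeline(master_recs, genome)
    return JunctionResult(genome, truth, events, master_events, clip_stats, map_stats)


def _junction_pipeline(records, genome, repeats=()):
    clips, clip_stats = extract_clips(records)
    placed, map_stats = map_clips(clips, genome)
    events = call_junctions(placed)
    events = filter_isomerization(events, repeats)
    return events, clip_stats, map_stats


# ---------------------------------------------------------------------------
# Isomerization filtering (chloroplast-like inverted repeat)
# ---------------------------------------------------------------------------


@dataclass
class IsomerResult:
    genome: CircularGenome
    ir: RepeatPair
    events: list[JunctionEvent]  # after filter_isomerization
    profile: CoverageProfile
    far_junction_bins: list[set]

    @property
    def ir_boundary_bins(self) -> set[int]:
        return {
            position_to_bin(self.ir.copy1.start),
            position_to_bin(self.ir.copy1.end),
            position_to_bin(self.ir.copy2.start),
            position_to_bin(self.ir.copy2.end),
        }

    def ir_attributable(self) -> list[JunctionEvent]:
        """Opposite-strand events with both endpoints within 1 bin of the IR."""
        bb = self.ir_boundary_bins
        return [
            e
            for e in self.events
            if e.orientation == "opposite_strand"
            and min(abs(e.anchor_bin - b) for b in bb) <= 1
            and min(abs(e.clip_bin - b) for b in bb) <= 1
        ]

    def far_retained(self) -> list[JunctionEvent]:
        out = []
        for e in retained(self.events):
            if any((e.anchor_bin, e.clip_bin) in t for t in self.far_junction_bins):
                out.append(e)
        return out

    @property
    def events_per_copy(self) -> float:
        return events_per_genome_copy(self.events, self.profile)


def isomerization_filtering(seed: int, depth: float = 30.0) -> IsomerResult:
    """Chloroplast-like genome: flip-flop isomer of a 2-kb inverted repeat at
    weight 1, an inverted junction planted just inside the repeat boundaries,
    and a control inversion far from the repeat."""
    genome, repeats = make_test_genome(
        60_000,
        seed=seed * 13 + 1,
        repeat_plan=[("IR", 2_000, 20_001, 40_001, "inverted")],
        name="cp_toy",
    )
    specs = [
        SubgenomeSpec(kind="inversion", repeat_id="IR", weight=1.0),
        # mid-bin breakpoints: anchor extension can slip a few bases past a
        # junction, which must not move the event into the next bin
        SubgenomeSpec(kind="inversion", breakpoints=(22_500, 39_800), weight=0.5),
        SubgenomeSpec(kind="inversion", breakpoints=(5_401, 12_600), weight=0.5),
    ]
    records, truth, n_reads = simulate_and_align(
        genome, specs, repeats, depth=depth, seed=seed * 13 + 2, error_rate=0.0
    )
    events, _, _ = _junction_pipeline(records, genome, repeats)
    profile = bin_coverage(records, genome.length, n_reads, genome.name)
    far = [
        {
            (position_to_bin(j.position_a), position_to_bin(j.position_b)),
            (position_to_bin(j.position_b), position_to_bin(j.position_a)),
        }
        for j in truth.planted_junctions
        if j.kind == "inversion"
        and j.expected_support_class == "detectable"
        and max(j.position_a, j.position_b) <= 13_000
    ]
    return IsomerResult(genome, repeats[0], events, profile, far)


# ---------------------------------------------------------------------------
# Crossover asymmetry (loop-out circle only)
# ---------------------------------------------------------------------------


@dataclass
class XoverResult:
    genome: CircularGenome
    repeat: RepeatPair
    carried_config: str
    other_config: str
    sample_counts: ConfigCounts
    control_counts: ConfigCounts
    log2: dict


def crossover_asymmetry(
    seed: int, weight: float = 1.0, depth: float = 250.0
) -> XoverResult:
    """Plant only the loop-out circle of a 127-bp direct pair: its carried
    crossover configuration (2/1) accumulates while the complementary
    configuration (1/2) stays at the continuity-correction level."""
    genome, repeats = make_test_genome(
        20_000, seed=seed * 17 + 1, repeat_plan=[("EE", 127, 6_001, 14_001, "direct")]
    )
    rep = repeats[0]
    specs = (
        [SubgenomeSpec(kind="loopout_circle", repeat_id="EE", weight=weight)]
        if weight > 0
        else []
    )
    sample_recs, _, _ = simulate_and_align(
        genome, specs, repeats, depth=depth, seed=seed * 17 + 2, label="mutant"
    )
    control_recs, _, _ = simulate_and_align(
        genome, [], repeats, depth=depth, seed=seed * 17 + 3, label="wt"
    )
    # flanks must be wider than a read for 'mate wholly inside flank' to
    # accept more than a single fragment start position
    flank = 300
    sample_counts = classify_spanning_pairs(sample_recs, rep, flank, genome.length)
    control_counts = classify_spanning_pairs(control_recs, rep, flank, genome.length)
    report = relative_accumulation(sample_counts, control_counts)
    return XoverResult(
        genome,
        rep,
        carried_config="2/1",  # the loop-out circle reads c-R-b around its repeat
        other_config="1/2",
        sample_counts=sample_counts,
        control_counts=control_counts,
        log2=report.log2,
    )
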