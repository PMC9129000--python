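"""Parental vs crossover configuration counts across direct repeat pairs.

The read-level analog of a qPCR assay with primers flanking each repeat copy:
a fragment whose two mates anchor uniquely and entirely in the unique flanks
of a repeat pair reports which arrangement of flanks its source molecule
carries.  With upstream flanks a (copy 1) and c (copy 2) and downstream
flanks b and d, a->b fragments support the parental arrangement 1/1 and
c->d support 2/2, while a->d (1/2) and c->b (2/1) exist only on crossover
molecules.  Counts are compared between a sample and a control library on a
log2 scale with a Haldane continuity correction of 1/2, because crossover
products can be entirely absent from the control.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .microalign import AlignmentRecord
from .repeatome import RepeatPair

CONFIGS = ("1/1", "2/2", "1/2", "2/1")


@dataclass
class ConfigCounts:
    repeat_id: str
    counts: dict  # config -> int
    informative_pairs: int
    norm_total: int

    def __post_init__(self) -> None:
        for cfg in CONFIGS:
            self.counts.setdefault(cfg, 0)


def _contains(start0: int, flank_len: int, p0: int, span: int, L: int) -> bool:
    """Is the circular interval [p0, p0+span) inside [start0, start0+flank_len)?"""
    return (p0 - start0) % L + span <= flank_len


def _circ_overlap(a0: int, alen: int, b0: int, blen: int, L: int) -> bool:
    da = (b0 - a0) % L
    db = (a0 - b0) % L
    return da < alen or db < blen


def classify_spanning_pairs(
    alignments: Sequence[AlignmentRecord],
    pair: RepeatPair,
    flank: int,
    genome_length: int,
    other_repeats: Sequence[RepeatPair] = (),
    norm_total: int | None = None,
) -> ConfigCounts:
    """Count repeat-spanning fragments per flank configuration.

    A fragment is informative iff one mate lies wholly inside an upstream
    flank (a or c) and the other wholly inside a downstream flank (b or d),
    both mates uniquely mapped and fully aligned (no clip).  Flanks extend
    ``flank`` bases out from each repeat copy; a flank that would overlap the
    other copy of the pair (or a copy of any repeat in ``other_repeats``)
    raises, instructing the caller to shrink the flank.
    """
    if pair.orientation != "direct":
        raise ValueError("classify_spanning_pairs is defined for direct pairs")
    L = genome_length
    r = pair.rep_length
    s1, s2 = pair.copy1.start0, pair.copy2.start0
    flanks = {
        "a": ((s1 - flank) % L, flank),
        "b": ((s1 + r) % L, flank),
        "c": ((s2 - flank) % L, flank),
        "d": ((s2 + r) % L, flank),
    }
    copies = [(s1, r, pair.id), (s2, r, pair.id)]
    for rep in other_repeats:
        if rep.id == pair.id:
            continue
        copies.append((rep.copy1.start0, rep.rep_length, rep.id))
        copies.append((rep.copy2.start0, rep.rep_length, rep.id))
    for name, (f0, flen) in flanks.items():
        for c0, clen, cid in copies:
            if _circ_overlap(f0, flen, c0, clen, L):
                raise ValueError(
                    f"flank {name} of repeat {pair.id} overlaps a copy of repeat "
                    f"{cid}; use a smaller flank"
                )

    def flank_of(rec: AlignmentRecord) -> str | None:
        if not (rec.mapped and rec.is_unique):
            return None
        if len(rec.cigar) != 1 or rec.cigar[0][0] != "M":
            return None
        p0 = rec.pos - 1
        span = rec.ref_span
        for name, (f0, flen) in flanks.items():
            if _contains(f0, flen, p0, span, L):
                return name
        return None

    by_read: dict[str, dict[int, AlignmentRecord]] = {}
    for rec in alignments:
        by_read.setdefault(rec.read_id, {})[rec.mate] = rec

    config_of = {
        frozenset(("a", "b")): "1/1",
        frozenset(("c", "d")): "2/2",
        frozenset(("a", "d")): "1/2",
        frozenset(("c", "b")): "2/1",
    }
    counts = {cfg: 0 for cfg in CONFIGS}
    for mates in by_read.values():
        if len(mates) != 2:
            continue
        f1, f2 = flank_of(mates[1]), flank_of(mates[2])
        if f1 is None or f2 is None:
            continue
        cfg = config_of.get(frozenset((f1, f2)))
        if cfg:
            counts[cfg] += 1
    informative = sum(counts.values())
    if informative == 0:
        warnings.warn(
            f"no informative fragments for repeat {pair.id} ({r} bp): the repeat "
            "may exceed the fragment span (fragments must cover one repeat copy "
            "plus a full read in each flank)",
            stacklevel=2,
        )
    return ConfigCounts(
        repeat_id=pair.id,
        counts=counts,
        informative_pairs=informative,
        norm_total=norm_total if norm_total is not None else informative,
    )


@dataclass
class QuantReport:
    """log2 relative accumulation of each configuration, sample vs control."""

    repeat_id: str
    log2: dict  # config -> float
    sample: ConfigCounts
    control: ConfigCounts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "repeat_id": self.repeat_id,
                    "config": cfg,
                    "sample_count": self.sample.counts[cfg],
                    "control_count": self.control.counts[cfg],
                    "sample_N": self.sample.norm_total,
                    "control_N": self.control.norm_total,
                    "log2_vs_control": self.log2[cfg],
                }
                for cfg in CONFIGS
            ]
        )


def relative_accumulation(sample: ConfigCounts, control: ConfigCounts) -> QuantReport:
    """Per-config log2( ((x_s + 1/2)/N_s) / ((x_c + 1/2)/N_c) ).

    N is the informative-fragment normalizer (the read-level analog of qPCR
    normalization to co-amplified reference loci).  The 1/2 continuity
    correction keeps configurations absent from one library finite.  The
    report is antisymmetric under swapping sample and control.
    """
    if sample.repeat_id != control.repeat_id:
        raise ValueError("sample and control quantify different repeats")
    ns, nc = sample.norm_total, control.norm_total
    if ns == 0 or nc == 0:
        raise ValueError("zero normalizer: no informative fragments in one library")
    log2 = {
        cfg: math.log2(
            ((sample.counts[cfg] + 0.5) / ns) / ((control.counts[cfg] + 0.5) / nc)
        )
        for cfg in CONFIGS
    }
    return QuantReport(sample.repeat_id, log2, sample, control)


def write_quant_table(reports: Sequence[QuantReport], path: str | Path) -> None:
    pd.concat([r.to_frame() for r in reports], ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.4f"
    )
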