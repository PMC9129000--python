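"""Per-kb coverage stoichiometry profiling and sample/control comparison.

Relative copy number of organellar genome segments is profiled by binning
aligned read coverage into 1-kb windows: each reference position belongs to
the bin labelled by its upper kilobase boundary (bin = ceil(pos / 1000)), and
each bin's mean depth is normalized to a library of one million reads.
Comparing a mutant library against a control as per-bin log2 ratios reveals
amplified or depleted subgenomes -- regions whose boundaries coincide with a
repeat pair are the signature of repeat-mediated loop-out and autonomous
replication of the excised circle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .microalign import AlignmentRecord, REF_OPS
from .repeatome import RepeatPair

BIN_SIZE = 1000


def position_to_bin(pos: int, bin_size: int = BIN_SIZE) -> int:
    """1-based position -> 1-based bin index; bin b spans [(b-1)*1000+1, b*1000]."""
    if pos < 1:
        raise ValueError("positions are 1-based; got pos < 1")
    return (pos + bin_size - 1) // bin_size


@dataclass
class CoverageProfile:
    """Per-1-kb-bin aligned base counts for one library on one genome."""

    genome_name: str
    genome_length: int
    base_count: np.ndarray  # aligned reference bases per bin
    total_reads: int
    bin_size: int = BIN_SIZE

    @property
    def n_bins(self) -> int:
        return len(self.base_count)

    @property
    def bin_widths(self) -> np.ndarray:
        widths = np.full(self.n_bins, self.bin_size, dtype=float)
        rem = self.genome_length % self.bin_size
        if rem:
            widths[-1] = rem
        return widths

    @property
    def mean_depth(self) -> np.ndarray:
        return self.base_count / self.bin_widths

    @property
    def normalized_depth(self) -> np.ndarray:
        return self.mean_depth * 1_000_000 / self.total_reads

    @property
    def genome_mean_depth(self) -> float:
        """Mean depth averaged over bins (the per-genome-copy denominator)."""
        return float(self.mean_depth.mean())

    def to_frame(self) -> pd.DataFrame:
        b = np.arange(1, self.n_bins + 1)
        return pd.DataFrame(
            {
                "bin_index": b,
                "bin_start": (b - 1) * self.bin_size + 1,
                "bin_end": np.minimum(b * self.bin_size, self.genome_length),
                "base_count": self.base_count.astype(int),
                "mean_depth": self.mean_depth,
                "normalized_depth": self.normalized_depth,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def bin_coverage(
    alignments: Sequence[AlignmentRecord],
    genome_length: int,
    total_reads: int,
    genome_name: str = "",
    bin_size: int = BIN_SIZE,
) -> CoverageProfile:
    """Accumulate per-base depth from reference-consuming CIGAR operations
    (M, D, N, =, X) of mapped records into 1-kb bins.

    ``total_reads`` is the library size used for normalization -- by default
    the caller passes the total read count including unmapped reads (a
    mapped-only normalization is obtained by simply passing that count
    instead; the difference is a constant factor).
    """
    if total_reads == 0:
        raise ValueError("total_reads must be > 0 for normalization")
    per_base = np.zeros(genome_length, dtype=np.int64)
    for rec in alignments:
        if not rec.mapped:
            continue
        p = rec.pos - 1
        for op, n in rec.cigar:
            if op in REF_OPS:
                s = p % genome_length
                if s + n <= genome_length:
                    per_base[s : s + n] += 1
                else:
                    per_base[s:] += 1
                    per_base[: s + n - genome_length] += 1
                p += n
    n_bins = math.ceil(genome_length / bin_size)
    base_count = np.add.reduceat(per_base, np.arange(0, genome_length, bin_size)).astype(
        float
    )
    assert len(base_count) == n_bins
    return CoverageProfile(genome_name, genome_length, base_count, total_reads, bin_size)


@dataclass(frozen=True)
class FlaggedRegion:
    """Maximal run of bins whose |log2 ratio| clears the threshold."""

    start_bin: int
    end_bin: int  # inclusive
    mean_log2: float
    direction: str  # "amplified" | "depleted"
    repeat_ids: tuple[str, ...]  # repeat pairs with a copy near either boundary


@dataclass
class StoichiometryReport:
    log2_ratio: np.ndarray
    regions: list[FlaggedRegion]
    flag_threshold: float

    def to_frame(self) -> pd.DataFrame:
        flagged = np.zeros(len(self.log2_ratio), dtype=bool)
        for r in self.regions:
            flagged[r.start_bin - 1 : r.end_bin] = True
        return pd.DataFrame(
            {
                "bin_index": np.arange(1, len(self.log2_ratio) + 1),
                "log2_ratio": self.log2_ratio,
                "flagged": flagged,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def compare_profiles(
    sample: CoverageProfile,
    control: CoverageProfile,
    flag_threshold: float = 1.0,
    repeats: Sequence[RepeatPair] = (),
    read_length: int = 150,
) -> StoichiometryReport:
    """Per-bin log2(sample/control) of normalized depth, with flagged regions.

    A pseudocount equal to the normalized depth contributed by a single read
    in one bin (read_length/bin_size reads-per-million units) keeps ratios
    finite on empty bins.  Maximal runs of bins with |log2| >= the threshold
    (default 1.0, i.e. two-fold) become flagged regions; any repeat pair with
    a copy boundary within one bin of a region boundary is attached as the
    candidate mediator of the stoichiometry change.
    """
    if (
        sample.genome_length != control.genome_length
        or sample.bin_size != control.bin_size
    ):
        raise ValueError("profiles use different genomes or binnings")
    eps_s = read_length / sample.bin_size * 1_000_000 / sample.total_reads
    eps_c = read_length / control.bin_size * 1_000_000 / control.total_reads
    log2 = np.log2((sample.normalized_depth + eps_s) / (control.normalized_depth + eps_c))
    # runs are sign-homogeneous: an amplified region never merges with an
    # adjacent depleted one even if both clear the threshold
    sign = np.where(log2 >= flag_threshold, 1, np.where(log2 <= -flag_threshold, -1, 0))
    regions: list[FlaggedRegion] = []
    b = 0
    n = len(log2)
    while b < n:
        if sign[b]:
            e = b
            while e + 1 < n and sign[e + 1] == sign[b]:
                e += 1
            mean = float(log2[b : e + 1].mean())
            regions.append(
                FlaggedRegion(
                    start_bin=b + 1,
                    end_bin=e + 1,
                    mean_log2=mean,
                    direction="amplified" if mean > 0 else "depleted",
                    repeat_ids=_annotate(b + 1, e + 1, repeats),
                )
            )
            b = e + 1
        else:
            b += 1
    return StoichiometryReport(log2, regions, flag_threshold)


def _annotate(start_bin: int, end_bin: int, repeats: Sequence[RepeatPair]) -> tuple[str, ...]:
    ids = []
    for rep in repeats:
        bounds = {
            position_to_bin(rep.copy1.start),
            position_to_bin(rep.copy1.end),
            position_to_bin(rep.copy2.start),
            position_to_bin(rep.copy2.end),
        }
        if any(
            abs(bb - edge) <= 1 for bb in bounds for edge in (start_bin, end_bin)
        ):
            ids.append(rep.id)
    return tuple(ids)
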