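"""Independent brute-force oracles used by the test suite and acceptance script.

These deliberately share no code with the package implementation: the repeat
oracle scans every rotation (direct) and anti-diagonal (inverted) of the
circular sequence with numpy run-length extraction, and the CIGAR oracle is a
regular expression over the CIGAR string.
"""

from __future__ import annotations

import re

import numpy as np

_COMP_TABLE = np.zeros(256, dtype=np.uint8)
for x, y in zip(b"ACGTN", b"TGCA\0"):  # N complements to a sentinel that never matches
    _COMP_TABLE[x] = y


def _circular_runs(match: np.ndarray) -> list[tuple[int, int]]:
    """Maximal circular runs of True as (start, length); full-True is one run."""
    L = match.size
    if match.all():
        return [(0, L)]
    if not match.any():
        return []
    i0 = int(np.flatnonzero(~match)[0])
    rolled = np.roll(match, -(i0 + 1))
    d = np.diff(np.r_[0, rolled.astype(np.int8), 0])
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [((int(s) + i0 + 1) % L, int(e - s)) for s, e in zip(starts, ends)]


def brute_force_repeats(
    sequence: str, min_len: int, orientations=("direct", "inverted")
) -> set[tuple[int, int, int, str]]:
    """All maximal exact repeat pairs on a circular sequence.

    Returns canonical 0-based tuples (start1, start2, length, orientation)
    with start1 < start2.  Pairs whose copies would overlap (perfect tandem
    arrays of three or more periods, contiguous palindromes) are not
    reported, matching the non-overlap invariant of the repeat-pair model.
    """
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    L = arr.size
    out: set[tuple[int, int, int, str]] = set()

    def _has_long_run(match: np.ndarray) -> bool:
        # any circular window of min_len consecutive matches?
        md = np.r_[match, match[: min_len]]
        c = np.cumsum(md)
        return bool(np.any(c[min_len:] - c[:-min_len] == min_len))

    if "direct" in orientations:
        for d in range(1, L):
            cap = min(d, L - d)
            if cap < min_len:
                continue
            match = arr == np.roll(arr, -d)
            if not _has_long_run(match):
                continue
            for st, m in _circular_runs(match):
                if m < min_len or m > cap:
                    continue
                a, b = st, (st + d) % L
                out.add((min(a, b), max(a, b), m, "direct"))
    if "inverted" in orientations:
        carr = _COMP_TABLE[arr]
        rc_arr = carr[::-1]
        for c in range(L):
            t = (L - 1 - c) % L
            match = arr == np.roll(rc_arr, -t)
            if not _has_long_run(match):
                continue
            for st, m in _circular_runs(match):
                if m < min_len:
                    continue
                partner = (c - (st + m - 1)) % L
                if partner == st:
                    continue  # self-mirrored palindrome: copies would overlap
                a, b = st, partner
                if (b - a) % L < m or (a - b) % L < m:
                    continue  # overlapping mirror runs
                out.add((min(a, b), max(a, b), m, "inverted"))
    return out


_CIGAR_ITEM = re.compile(r"(\d+)([MIDNSHP=X])")


def cigar_regex_oracle(cigar_string: str, min_clip: int = 20) -> bool:
    """Accept iff >= 1 soft clip of >= min_clip bases and no I, D or H op."""
    if re.search(r"\d+[IDH]", cigar_string):
        return False
    return any(int(n) >= min_clip for n, op in _CIGAR_ITEM.findall(cigar_string) if op == "S")


def random_cigar(rng: np.random.Generator) -> list[tuple[str, int]]:
    """A syntactically plausible CIGAR of 1-6 operations with lengths 1-200."""
    ops = "MIDNSHP=X"
    n = int(rng.integers(1, 7))
    return [(ops[int(rng.integers(0, len(ops)))], int(rng.integers(1, 201))) for _ in range(n)]
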