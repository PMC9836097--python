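"""Low-level DNA helpers shared across modules.

Sequences are plain upper-case strings over {A, C, G, T, N}. Coordinates are
1-based inclusive throughout the package; circular arithmetic is modulo the
chromosome length with the convention that ``start > end`` denotes an interval
wrapping the origin.
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(COMPLEMENT)[::-1]


def validate_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)!r}")
    return seq


def seq_to_array(seq: str) -> np.ndarray:
    """Byte view of a sequence for vectorised base counting."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def circular_slice(seq: str, start: int, end: int) -> str:
    """1-based inclusive slice; ``start > end`` wraps the origin."""
    n = len(seq)
    if not (1 <= start <= n and 1 <= end <= n):
        raise ValueError(f"interval ({start}, {end}) outside [1, {n}]")
    if start <= end:
        return seq[start - 1 : end]
    return seq[start - 1 :] + seq[:end]


def interval_span(start: int, end: int, length: int) -> int:
    """Number of bases covered by a (possibly wrapping) circular interval."""
    if start <= end:
        return end - start + 1
    return length - start + 1 + end


def circular_midpoint(start: int, end: int, length: int) -> int:
    """Midpoint position of a circular interval (1-based)."""
    span = interval_span(start, end, length)
    return (start - 1 + (span - 1) // 2) % length + 1


def circular_distance(a: int, b: int, length: int) -> int:
    """Shortest circular distance between two positions."""
    d = abs(a - b) % length
    return min(d, length - d)


def position_in_interval(pos: int, start: int, end: int) -> bool:
    """Membership of a position in a circular 1-based inclusive interval."""
    if start <= end:
        return start <= pos <= end
    return pos >= start or pos <= end
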