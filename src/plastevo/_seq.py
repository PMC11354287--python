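"""Low-level sequence helpers shared across modules.

All coordinates in this package are 0-based half-open. Circular genomes are
stored linearized at their published origin; operations that need wraparound
work on the doubled sequence and reduce coordinates modulo the length.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """GC fraction with N (and any ambiguity) excluded from numerator and
    denominator. Returns nan for sequences with no unambiguous bases."""
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        return float("nan")
    return gc / (gc + at)


def seq_to_ints(seq: str) -> np.ndarray:
    """Encode A,C,G,T as 0..3 and anything else as 4."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        out[arr == b] = i
    return out


def ints_to_seq(arr: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[np.asarray(arr, dtype=np.intp)].tobytes().decode("ascii")


def circular_slice(seq: str, start: int, length: int) -> str:
    """Forward slice of `length` bases starting at `start` on a circle."""
    n = len(seq)
    if not 0 <= length <= n:
        raise ValueError(f"slice length {length} outside [0, {n}]")
    start %= n
    return (seq + seq)[start : start + length]


def wrap_interval(start: int, end: int, n: int) -> list[tuple[int, int]]:
    """Split a possibly origin-wrapping interval into linear pieces.

    The interval is given with 0 <= start < n and start <= end <= start + n;
    `end` greater than n means the interval wraps the origin.
    """
    if not 0 <= start < n or not start <= end <= start + n:
        raise ValueError(f"bad circular interval ({start}, {end}) on size {n}")
    if end <= n:
        return [(start, end)]
    return [(start, n), (0, end - n)]


def circ_dist(a: int, b: int, n: int) -> int:
    """Shortest distance between two positions on a circle of size n."""
    d = abs(a - b) % n
    return min(d, n - d)
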