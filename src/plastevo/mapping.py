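"""Internal long-read mapper: exact k-mer anchors chained on diagonals.

Designed for HiFi-like reads (substitution errors only, no indels) against
a single circular reference: anchors never shift diagonal, so chaining is
grouping by (strand, diagonal) followed by end extension. Reference
coordinates run over the doubled sequence ([0, 2n)) so reads spanning the
origin stay contiguous; reduce modulo n for region arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import revcomp


@dataclass(frozen=True)
class Segment:
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    strand: str
    identity: float

    def __len__(self):
        return self.read_end - self.read_start


@dataclass(frozen=True)
class ReadAlignment:
    read_id: str
    read_len: int
    segments: tuple
    aligned_fraction: float


class ReferenceIndex:
    """k-mer index over the doubled circular reference."""

    def __init__(self, sequence: str, k: int = 31, max_hits: int = 20):
        self.seq = sequence
        self.n = len(sequence)
        self.k = k
        self.max_hits = max_hits
        self.doubled = sequence + sequence
        self.index: dict[str, list[int]] = {}
        for p in range(self.n):
            self.index.setdefault(self.doubled[p : p + k], []).append(p)

    def lookup(self, word: str):
        hits = self.index.get(word, ())
        return hits if len(hits) <= self.max_hits else ()


def map_read(
    read_id: str,
    read_seq: str,
    index: ReferenceIndex,
    stride: int = 8,
    max_gap: int = 600,
    min_segment: int = 100,
    min_new_coverage: int = 150,
) -> ReadAlignment:
    """Chain exact k-mer anchors into gapless segments and tile the read.

    Segments are merged per (strand, diagonal), extended at both ends
    through scattered mismatches, filtered to those contributing new read
    coverage (longest first), then trimmed to be non-overlapping on the
    read (overlaps — e.g. across a repeat copy shared by two segments —
    are cut at the midpoint).
    """
    k = index.k
    n = index.n
    anchors: dict[tuple, list[int]] = {}
    L = len(read_seq)
    for i in range(0, max(1, L - k + 1), stride):
        w = read_seq[i : i + k]
        for p in index.lookup(w):
            anchors.setdefault(("+", (p - i) % n), []).append(i)
        for p in index.lookup(revcomp(w)):
            # read[i+t] pairs with ref[p+k-1-t]; the anti-diagonal p+i+k is
            # constant along the match
            anchors.setdefault(("-", (p + i + k) % n), []).append(i)

    raw: list[Segment] = []
    for (strand, diag), pos in anchors.items():
        pos.sort()
        start = prev = pos[0]
        for i in pos[1:] + [pos[-1] + max_gap + 1]:
            if i - prev > max_gap:
                seg = _build_segment(read_seq, index, strand, diag, start, prev + k)
                if seg is not None and len(seg) >= min_segment:
                    raw.append(seg)
                start = i
            prev = i

    raw.sort(key=lambda s: -len(s))
    kept: list[Segment] = []
    covered: list[tuple[int, int]] = []
    for seg in raw:
        new = _uncovered((seg.read_start, seg.read_end), covered)
        if new >= min_new_coverage or not kept:
            kept.append(seg)
            covered.append((seg.read_start, seg.read_end))
    kept.sort(key=lambda s: s.read_start)
    kept = _trim_overlaps(kept)
    cov = sorted((s.read_start, s.read_end) for s in kept)
    total = 0
    last = 0
    for s, e in cov:
        total += max(0, e - max(s, last))
        last = max(last, e)
    return ReadAlignment(read_id, L, tuple(kept), total / L if L else 0.0)


def _build_segment(read_seq, index, strand, diag, i_lo, i_hi):
    """Anchor span [i_lo, i_hi) on the read -> extended, scored segment."""
    L = len(read_seq)
    n = index.n
    if strand == "+":
        ref_of = lambda i: (diag + i) % n
    else:
        ref_of = lambda i: (diag - i - 1) % n

    def ref_base(i):
        return index.seq[ref_of(i)] if strand == "+" else _COMP[index.seq[ref_of(i)]]

    i_lo = _extend_end(read_seq, ref_base, i_lo, -1)
    i_hi = _extend_end(read_seq, ref_base, i_hi - 1, +1) + 1
    length = i_hi - i_lo
    if length <= 0:
        return None
    if strand == "+":
        ref_start = (diag + i_lo) % n
        ref_end = ref_start + length
        ref_seg = index.doubled[ref_start:ref_end]
    else:
        ref_start = (diag - i_hi) % n
        ref_end = ref_start + length
        ref_seg = revcomp(index.doubled[ref_start:ref_end])
    a = np.frombuffer(read_seq[i_lo:i_hi].encode(), dtype=np.uint8)
    b = np.frombuffer(ref_seg.encode(), dtype=np.uint8)
    identity = float((a == b).mean())
    if identity < 0.80:
        return None
    return Segment(i_lo, i_hi, ref_start, ref_end, strand, identity)


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "#": "#"}


def _extend_end(read_seq, ref_base, i0, direction, max_mismatch_run=3):
    """Greedy end extension tolerating scattered errors; trailing mismatches
    are trimmed so the segment ends on a match."""
    i = i0
    last_match = i0
    run = 0
    while True:
        j = i + direction
        if not 0 <= j < len(read_seq):
            break
        if read_seq[j] == ref_base(j):
            last_match = j
            run = 0
        else:
            run += 1
            if run > max_mismatch_run:
                break
        i = j
    return last_match


def _uncovered(interval, covered):
    s, e = interval
    pieces = [(s, e)]
    for cs, ce in covered:
        nxt = []
        for ps, pe in pieces:
            if ce <= ps or cs >= pe:
                nxt.append((ps, pe))
            else:
                if ps < cs:
                    nxt.append((ps, cs))
                if ce < pe:
                    nxt.append((ce, pe))
        pieces = nxt
    return sum(pe - ps for ps, pe in pieces)


def _trim_overlaps(segments):
    """Cut read-overlapping neighbours at the overlap midpoint, shifting ref
    coordinates consistently with each segment's strand."""
    out = list(segments)
    for a in range(len(out) - 1):
        s1, s2 = out[a], out[a + 1]
        overlap = s1.read_end - s2.read_start
        if overlap <= 0:
            continue
        cut = s2.read_start + overlap // 2
        d1 = s1.read_end - cut  # trim from right of s1
        d2 = cut - s2.read_start  # trim from left of s2
        out[a] = _trim(s1, right=d1)
        out[a + 1] = _trim(s2, left=d2)
    return [s for s in out if len(s) > 0]


def _trim(seg: Segment, left: int = 0, right: int = 0) -> Segment:
    rs, re = seg.read_start + left, seg.read_end - right
    if seg.strand == "+":
        fs, fe = seg.ref_start + left, seg.ref_end - right
    else:
        fs, fe = seg.ref_start + right, seg.ref_end - left
    return Segment(rs, re, fs, fe, seg.strand, seg.identity)


def junction_endpoints(seg_left: Segment, seg_right: Segment):
    """Reference endpoints flanking the read breakpoint between two adjacent
    segments: (last ref position of the left flank, first ref position of
    the right flank), each on the left/right segment's own strand."""
    left_pt = seg_left.ref_end - 1 if seg_left.strand == "+" else seg_left.ref_start
    right_pt = seg_right.ref_start if seg_right.strand == "+" else seg_right.ref_end - 1
    return left_pt, right_pt
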