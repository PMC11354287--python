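"""Dispersed repeat discovery and summaries.

Repeats are found by gapless seed-and-extend self-comparison of the genome
with one IR copy (IRb) masked, in both orientations. Parameters mirror a
word size of 7 for seeding, a 30-bp minimum repeat length, and an explicit
score threshold (match +2, mismatch -3) standing in for an e-value cutoff;
all are overridable. With ``min_identity == 1`` extension is exact-match and
the output equals the set of maximal exact matches, which is what the
brute-force oracle used in the tests enumerates.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf

import pandas as pd

from ._seq import revcomp
from .io import PlastomeRecord
from .structure import RegionPartition

DEFAULT_BINS = ((None, 200), (201, 500), (501, 1000), (1001, None))

MATCH_SCORE = 2
MISMATCH_SCORE = -3
XDROP = 12


@dataclass(frozen=True)
class RepeatPair:
    """One dispersed repeat: two genome intervals, gapless alignment."""

    interval1: tuple[int, int]
    interval2: tuple[int, int]
    orientation: str  # direct | inverted
    length: int
    identity: float
    score: int

    def intervals(self):
        return (self.interval1, self.interval2)


@dataclass(frozen=True)
class RepeatFootprint:
    """Union of all repeat intervals plus per-size-bin summaries."""

    merged: tuple  # sorted disjoint (start, end) intervals
    cumulative_bp: int
    bin_counts: tuple
    bin_lengths: tuple
    bins: tuple = DEFAULT_BINS


# ---------------------------------------------------------------------------
# Discovery
# ---------------------------------------------------------------------------


def find_dispersed_repeats(
    genome: PlastomeRecord | str,
    partition: RegionPartition | None = None,
    min_len: int = 30,
    min_identity: float = 0.90,
    seed_k: int = 7,
    min_score: int = 40,
    max_bucket: int = 200,
) -> list[RepeatPair]:
    """All non-self gapless local matches >= min_len at >= min_identity,
    both orientations, with the IRb region masked.

    The surviving IR copy is reported like any other locus. Trivial
    self-hits, overlapping copies (tandem-like), and mirror duplicates are
    removed. min_len below the seed size raises.
    """
    if min_len < seed_k:
        raise ValueError(f"min_len ({min_len}) must be >= seed size ({seed_k})")
    seq = genome.sequence if isinstance(genome, PlastomeRecord) else str(genome).upper()
    if partition is not None:
        s, e = partition.irb
        chars = list(seq)
        for p in range(s, e):
            chars[p % len(seq)] = "#"
        seq = "".join(chars)

    exact = min_identity >= 1.0
    pairs: dict[tuple, RepeatPair] = {}
    for cand in _self_matches(seq, seq, seed_k, exact, max_bucket, direct=True):
        _admit(pairs, seq, cand, "direct", min_len, min_identity, min_score)
    rc = revcomp(seq)
    for cand in _self_matches(seq, rc, seed_k, exact, max_bucket, direct=False):
        _admit(pairs, seq, cand, "inverted", min_len, min_identity, min_score)
    return sorted(
        pairs.values(), key=lambda p: (p.interval1, p.interval2, p.orientation)
    )


def _self_matches(sa: str, sb: str, k: int, exact: bool, max_bucket: int, direct: bool):
    """Maximal gapless matches between sa and sb as (a_s, a_e, b_s) tuples.

    For the direct self-comparison only diagonals > 0 are scanned (each pair
    once, no self-diagonal)."""
    n = len(sa)
    index: dict[str, list[int]] = {}
    for j in range(n - k + 1):
        w = sb[j : j + k]
        if "#" in w or "N" in w:
            continue
        index.setdefault(w, []).append(j)
    anchors: dict[int, set[int]] = {}
    for i in range(n - k + 1):
        w = sa[i : i + k]
        if "#" in w or "N" in w:
            continue
        bucket = index.get(w, ())
        if len(bucket) > max_bucket:
            continue
        for j in bucket:
            if direct and j <= i:
                continue
            anchors.setdefault(j - i, set()).add(i)

    out = []
    for diag, pos in anchors.items():
        done_until = -1
        for i in sorted(pos):
            if i < done_until:
                continue
            a_s, a_e = _extend(sa, sb, i, i + k, i + diag, exact)
            done_until = a_e
            if a_e - a_s >= k:
                out.append((a_s, a_e, a_s + diag))
    return out


def _extend(sa: str, sb: str, a_s: int, a_e: int, b_s: int, exact: bool):
    """Extend [a_s, a_e) x [b_s, ..) along the diagonal in both directions."""
    diag = b_s - a_s
    if exact:
        while a_s > 0 and b_s > 0 and sa[a_s - 1] == sb[b_s - 1] and sa[a_s - 1] in "ACGT":
            a_s -= 1
            b_s -= 1
        while (
            a_e < len(sa)
            and a_e + diag < len(sb)
            and sa[a_e] == sb[a_e + diag]
            and sa[a_e] in "ACGT"
        ):
            a_e += 1
        return a_s, a_e
    a_s = a_s - _xdrop(sa, sb, a_s - 1, a_s - 1 + diag, -1)
    a_e = a_e + _xdrop(sa, sb, a_e, a_e + diag, +1)
    return a_s, a_e


def _xdrop(sa, sb, i, j, step):
    score = best = 0
    ext = best_ext = 0
    while 0 <= i < len(sa) and 0 <= j < len(sb):
        if sa[i] not in "ACGT" or sb[j] not in "ACGT":
            break
        score += MATCH_SCORE if sa[i] == sb[j] else MISMATCH_SCORE
        ext += 1
        if score > best:
            best, best_ext = score, ext
        if score < best - XDROP:
            break
        i += step
        j += step
    return best_ext


def _admit(pairs, seq, cand, orientation, min_len, min_identity, min_score):
    a_s, a_e, b_s = cand
    length = a_e - a_s
    if length < min_len:
        return
    if orientation == "direct":
        i1, i2 = (a_s, a_e), (b_s, b_s + length)
        sa, sb = seq[a_s:a_e], seq[b_s : b_s + length]
    else:
        n = len(seq)
        b_lo = n - (b_s + length)
        i1, i2 = (a_s, a_e), (b_lo, b_lo + length)
        sa, sb = seq[a_s:a_e], revcomp(seq[b_lo : b_lo + length])
    if i1 > i2:
        i1, i2 = i2, i1
        if orientation == "direct":
            sa, sb = sb, sa
    if _overlaps(i1, i2):
        return  # tandem-like / palindromic self-overlap
    matches = sum(x == y for x, y in zip(sa, sb))
    identity = matches / length
    score = MATCH_SCORE * matches + MISMATCH_SCORE * (length - matches)
    if identity < min_identity or score < min_score:
        return
    key = (i1, i2, orientation)
    prev = pairs.get(key)
    if prev is None or score > prev.score:
        pairs[key] = RepeatPair(i1, i2, orientation, length, identity, score)


def _overlaps(i1, i2):
    return i1[0] < i2[1] and i2[0] < i1[1]


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def merge_footprint(pairs, bins=DEFAULT_BINS, min_len: int = 30) -> RepeatFootprint:
    """Union of all repeat intervals; idempotent (re-merging a footprint's
    intervals returns the same intervals)."""
    ivs = sorted(iv for p in pairs for iv in p.intervals())
    merged = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    counts, lengths = _bin_pairs(pairs, bins, min_len)
    return RepeatFootprint(
        merged=tuple(merged),
        cumulative_bp=sum(e - s for s, e in merged),
        bin_counts=tuple(counts),
        bin_lengths=tuple(lengths),
        bins=tuple(bins),
    )


def _bin_pairs(pairs, bins, min_len):
    counts = [0] * len(bins)
    lengths = [0] * len(bins)
    for p in pairs:
        for b, (lo, hi) in enumerate(bins):
            lo_eff = min_len if lo is None else lo
            hi_eff = inf if hi is None else hi
            if lo_eff <= p.length <= hi_eff:
                counts[b] += 1
                lengths[b] += p.length
                break
    return counts, lengths


def bin_summary(pairs, bins=DEFAULT_BINS, min_len: int = 30) -> pd.DataFrame:
    """Per-size-bin pair counts and cumulative (per-pair) lengths."""
    counts, lengths = _bin_pairs(pairs, bins, min_len)
    labels = [
        f"{min_len if lo is None else lo}-{'inf' if hi is None else hi}"
        for lo, hi in bins
    ]
    return pd.DataFrame(
        {"bin": labels, "count": counts, "cumulative_length_bp": lengths}
    )


def breakpoint_association(pairs, breakpoints, window: int = 1000) -> pd.DataFrame:
    """Nearest-repeat distance and within-window flag per breakpoint interval.

    ``breakpoints`` is an iterable of (lo, hi) intervals (e.g. the
    inter-anchor breakpoints of InversionBlock). With no repeats all
    distances are the infinity sentinel.
    """
    rows = []
    for b, (lo, hi) in enumerate(breakpoints):
        dist = inf
        for p in pairs:
            for s, e in p.intervals():
                if s < hi and lo < e:
                    d = 0
                else:
                    d = max(s - hi, lo - e)
                dist = min(dist, d)
        rows.append(
            {
                "breakpoint": b,
                "interval_lo": lo,
                "interval_hi": hi,
                "nearest_repeat_bp": dist,
                "within_window": dist <= window,
            }
        )
    return pd.DataFrame(rows)
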