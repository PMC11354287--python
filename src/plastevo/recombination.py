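"""Classification of long reads against the isomer set of a plastome and
quantification of repeat-mediated recombinant junctions.

A read is *concordant* when it maps as one collinear segment on the
canonical molecule; *flip-flop* when its only discordance is SSC
orientation (every breakpoint falls inside the IR, the homology through
which the two equimolar major isomers interconvert); *recombinant* when
exactly two collinear flanks join non-adjacent loci through a cataloged
dispersed repeat pair; and *ambiguous* otherwise. Only reads with
(near-)full-length mapping are counted, which suppresses nuclear-plastid
transfer artifacts on real data.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .io import PlastomeRecord
from .mapping import ReadAlignment, ReferenceIndex, junction_endpoints, map_read
from .repeats import RepeatPair, find_dispersed_repeats
from .structure import RegionPartition, detect_partition

FULL_LENGTH_FRACTION = 0.98
JUNCTION_TOL = 80  # bp slack when matching breakpoints to repeat copies
DENOMINATOR_FLANK = 1000


# ---------------------------------------------------------------------------
# Filtering and arithmetic
# ---------------------------------------------------------------------------


def filter_full_length(
    alignments: list[ReadAlignment], min_fraction: float = FULL_LENGTH_FRACTION
) -> list[ReadAlignment]:
    """Keep reads whose summed segment coverage is >= min_fraction of the
    read length (all segments count)."""
    return [a for a in alignments if a.aligned_fraction >= min_fraction]


def junction_frequency(s: int, n: int) -> float:
    """100*s/n as a percent rounded half-up to 2 decimals."""
    if n <= 0:
        raise ValueError("total read count must be positive")
    if not 0 <= s <= n:
        raise ValueError("supporting count must be within [0, total]")
    return float(
        (Decimal(100) * Decimal(s) / Decimal(n)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


# ---------------------------------------------------------------------------
# Read classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadClass:
    read_id: str
    label: str  # concordant | flipflop | recombinant | ambiguous
    junction_id: str = ""


def _near_interval(pos: int, interval, n: int, tol: int) -> bool:
    s, e = interval
    return (pos - (s - tol)) % n < (e - s) + 2 * tol


def classify_read(
    alignment: ReadAlignment,
    partition: RegionPartition,
    repeat_catalog: dict[str, RepeatPair],
    tol: int = JUNCTION_TOL,
) -> ReadClass:
    """Assign one read to concordant / flipflop / recombinant / ambiguous.

    ``repeat_catalog`` maps junction ids to dispersed repeat pairs (IRb
    masked, so the IR itself is never in the catalog and flip-flop reads
    cannot be called recombinant)."""
    if alignment is None:
        raise ValueError("read has no alignment")
    segs = alignment.segments
    if not segs:
        return ReadClass(alignment.read_id, "ambiguous")
    if len(segs) == 1:
        return ReadClass(alignment.read_id, "concordant")

    n = partition.n
    breakpoints = []
    for left, right in zip(segs, segs[1:]):
        lp, rp = junction_endpoints(left, right)
        breakpoints.append((lp % n, rp % n, left.strand, right.strand))

    # flip-flop: every breakpoint endpoint falls inside IR homology and the
    # read changes strand (SSC reversal relative to its flanks)
    in_ir = lambda p: any(
        _near_interval(p, partition.arc(r), n, tol) for r in ("IRA", "IRB")
    )
    strand_change = any(a.strand != b.strand for a, b in zip(segs, segs[1:]))
    if strand_change and all(in_ir(lp) and in_ir(rp) for lp, rp, _, _ in breakpoints):
        if len(segs) <= 4:
            return ReadClass(alignment.read_id, "flipflop")

    if len(segs) == 2:
        (lp, rp, _, _) = breakpoints[0]
        for jid in sorted(repeat_catalog):
            pair = repeat_catalog[jid]
            c1, c2 = pair.interval1, pair.interval2
            if (
                _near_interval(lp, c1, n, tol) and _near_interval(rp, c2, n, tol)
            ) or (
                _near_interval(lp, c2, n, tol) and _near_interval(rp, c1, n, tol)
            ):
                return ReadClass(alignment.read_id, "recombinant", jid)
    return ReadClass(alignment.read_id, "ambiguous")


# ---------------------------------------------------------------------------
# End-to-end report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JunctionReport:
    junction_id: str
    repeat_interval1: tuple
    repeat_interval2: tuple
    supporting_reads: int
    total_reads: int
    frequency_percent: float


def build_repeat_catalog(
    genome: PlastomeRecord,
    partition: RegionPartition,
    min_len: int = 30,
    min_identity: float = 0.90,
) -> dict[str, RepeatPair]:
    """Dispersed repeat pairs indexed by deterministic junction ids J1, J2,
    ... in genome-coordinate order."""
    pairs = find_dispersed_repeats(
        genome, partition, min_len=min_len, min_identity=min_identity
    )
    return {f"J{i + 1}": p for i, p in enumerate(pairs)}


def align_reads(
    reads,
    reference: PlastomeRecord,
    k: int = 31,
    stride: int = 8,
) -> list[ReadAlignment]:
    """Map (read_id, sequence) pairs or SimReads with the internal anchor
    mapper."""
    index = ReferenceIndex(reference.sequence, k=k)
    out = []
    for r in reads:
        rid, seq = (r.read_id, r.sequence) if hasattr(r, "read_id") else r
        out.append(map_read(rid, seq, index, stride=stride))
    return out


def _read_cover_contains(alignment: ReadAlignment, lo: int, hi: int, n: int) -> bool:
    """Does the union of the read's reference arcs contain [lo, hi)?"""
    arcs = []
    for s in alignment.segments:
        start = s.ref_start % n
        arcs.append((start, start + (s.ref_end - s.ref_start)))
    need = [(lo % n, lo % n + (hi - lo))]
    for a_s, a_e in arcs:
        nxt = []
        for w_s, w_e in need:
            pieces = _arc_subtract((w_s, w_e), (a_s, a_e), n)
            nxt.extend(pieces)
        need = nxt
        if not need:
            return True
    return not need


def _arc_subtract(window, arc, n):
    """Subtract a circular arc from a circular window; both as (start,
    start+len) with start in [0, n)."""
    w_s, w_e = window
    out = []
    # compare in the window's frame
    a_s = (arc[0] - w_s) % n
    a_e = a_s + (arc[1] - arc[0])
    w_len = w_e - w_s
    covered = [(max(0, a_s), min(w_len, a_e))]
    if a_e > n:  # arc wraps past the window start again
        covered.append((0, min(w_len, a_e - n)))
    covered = [(s, e) for s, e in covered if e > s]
    cur = 0
    for s, e in sorted(covered):
        if s > cur:
            out.append(((w_s + cur) % n, (w_s + cur) % n + (s - cur)))
        cur = max(cur, e)
    if cur < w_len:
        out.append(((w_s + cur) % n, (w_s + cur) % n + (w_len - cur)))
    return out


def recombination_report(
    reads,
    reference: PlastomeRecord,
    partition: RegionPartition | None = None,
    repeat_catalog: dict[str, RepeatPair] | None = None,
    min_fraction: float = FULL_LENGTH_FRACTION,
    flank: int = DENOMINATOR_FLANK,
    alignments: list[ReadAlignment] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full pipeline: map, filter full-length, classify, and report one row
    per junction with >= 1 supporting read.

    The per-junction denominator counts full-length reads whose alignment
    covers either repeat copy plus ``flank`` bp on both sides (plus the
    supporting reads themselves), matching the locus-specific totals that
    per-junction read counts imply. Returns (junction report,
    per-read classifications)."""
    part = partition or (
        RegionPartition.from_features(reference)
        if any(f.kind == "region" for f in reference.features)
        else detect_partition(reference)
    )
    if part is None:
        raise ValueError("reference has no detectable quadripartite partition")
    catalog = repeat_catalog or build_repeat_catalog(reference, part)
    if alignments is None:
        alignments = align_reads(reads, reference)
    full = filter_full_length(alignments, min_fraction)
    classes = [classify_read(a, part, catalog) for a in full]
    class_df = pd.DataFrame(
        [
            {"read_id": c.read_id, "label": c.label, "junction_id": c.junction_id}
            for c in classes
        ]
    )
    n = part.n
    by_read = {a.read_id: a for a in full}
    rows = []
    for jid in sorted(catalog):
        support = [c for c in classes if c.label == "recombinant" and c.junction_id == jid]
        if not support:
            continue
        pair = catalog[jid]
        windows = [
            (iv[0] - flank, iv[1] + flank) for iv in (pair.interval1, pair.interval2)
        ]
        supporting_ids = {c.read_id for c in support}
        total = 0
        for a in full:
            if a.read_id in supporting_ids:
                total += 1
                continue
            if any(_read_cover_contains(a, lo, hi, n) for lo, hi in windows):
                total += 1
        rows.append(
            JunctionReport(
                jid, pair.interval1, pair.interval2, len(support), total,
                junction_frequency(len(support), total),
            )
        )
    report = pd.DataFrame(
        [
            {
                "junction_id": r.junction_id,
                "repeat_interval1": f"{r.repeat_interval1[0]}-{r.repeat_interval1[1]}",
                "repeat_interval2": f"{r.repeat_interval2[0]}-{r.repeat_interval2[1]}",
                "supporting_reads": r.supporting_reads,
                "total_reads": r.total_reads,
                "frequency_percent": r.frequency_percent,
            }
            for r in rows
        ],
        columns=[
            "junction_id", "repeat_interval1", "repeat_interval2",
            "supporting_reads", "total_reads", "frequency_percent",
        ],
    )
    return report, class_df


# ---------------------------------------------------------------------------
# External split alignments (tabular)
# ---------------------------------------------------------------------------

ALIGNMENT_COLUMNS = [
    "read_id", "read_length", "read_start", "read_end",
    "ref_start", "ref_end", "strand", "identity",
]


def read_alignments_tsv(path) -> list[ReadAlignment]:
    """Load split alignments from the documented TSV schema."""
    from .mapping import Segment

    df = pd.read_csv(path, sep="\t")
    missing = set(ALIGNMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"alignment TSV lacks columns: {sorted(missing)}")
    out = []
    for rid, grp in df.groupby("read_id", sort=True):
        segs = tuple(
            Segment(
                int(r.read_start), int(r.read_end), int(r.ref_start),
                int(r.ref_end), str(r.strand), float(r.identity),
            )
            for r in grp.itertuples()
        )
        read_len = int(grp.read_length.iloc[0])
        covered = sum(s.read_end - s.read_start for s in segs)
        out.append(ReadAlignment(str(rid), read_len, segs, covered / read_len))
    return out


def write_alignments_tsv(alignments: list[ReadAlignment], path) -> None:
    rows = []
    for a in alignments:
        for s in a.segments:
            rows.append(
                {
                    "read_id": a.read_id, "read_length": a.read_len,
                    "read_start": s.read_start, "read_end": s.read_end,
                    "ref_start": s.ref_start, "ref_end": s.ref_end,
                    "strand": s.strand, "identity": round(s.identity, 4),
                }
            )
    pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS).to_csv(path, sep="\t", index=False)
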