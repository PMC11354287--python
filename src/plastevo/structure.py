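"""Quadripartite structure: IR detection, region metrics, plastome typing,
and gene-order inversion analysis.

The partition detector finds the highest-scoring pair of long inverted
near-identical arcs on the circular molecule (seed-and-extend against the
reverse complement, on the doubled sequence so it is rotation invariant),
labels the longer single-copy arc LSC, and names the four junctions. A
genome without a qualifying pair yields ``None`` ("no IR detected"), which
is a legitimate state for IR-lacking plastomes, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._seq import gc_fraction, revcomp
from .io import Feature, PlastomeRecord

# ---------------------------------------------------------------------------
# Region partition
# ---------------------------------------------------------------------------


@dataclass
class RegionPartition:
    """LSC / IRa / SSC / IRb arcs on a circular genome.

    Intervals are (start, end) with 0 <= start < n and start < end <=
    start + n; end > n means the arc wraps the origin. The four arcs are
    disjoint and cover the circle exactly; ``len(lsc) >= len(ssc)``.
    """

    lsc: tuple[int, int]
    ira: tuple[int, int]
    ssc: tuple[int, int]
    irb: tuple[int, int]
    n: int
    ir_identity: float = 1.0
    junctions: dict = field(default_factory=dict)

    def __post_init__(self):
        sizes = self.sizes()
        if sum(sizes.values()) != self.n:
            raise ValueError(
                f"partition does not cover the genome: {sizes} vs n={self.n}"
            )
        if sizes["LSC"] < sizes["SSC"]:
            raise ValueError("LSC must be at least as long as SSC")
        if not self.junctions:
            self.junctions = {
                "J_LSC-IRa": self.ira[0] % self.n,
                "J_IRa-SSC": self.ssc[0] % self.n,
                "J_SSC-IRb": self.irb[0] % self.n,
                "J_IRb-LSC": self.lsc[0] % self.n,
            }

    def arc(self, name: str) -> tuple[int, int]:
        return {"LSC": self.lsc, "IRA": self.ira, "SSC": self.ssc, "IRB": self.irb}[
            name
        ]

    def sizes(self) -> dict[str, int]:
        return {
            name: e - s
            for name, (s, e) in (
                ("LSC", self.lsc), ("IRA", self.ira), ("SSC", self.ssc),
                ("IRB", self.irb),
            )
        }

    def contains(self, name: str, pos: int) -> bool:
        s, e = self.arc(name)
        return (pos - s) % self.n < e - s

    def locate(self, pos: int) -> str:
        for name in ("LSC", "IRA", "SSC", "IRB"):
            if self.contains(name, pos):
                return name
        raise ValueError(f"position {pos} not on the circle")

    def overlap(self, name: str, start: int, end: int) -> int:
        """Bases of the (possibly wrapping) interval inside the named arc."""
        return sum(1 for p in range(start, end) if self.contains(name, p % self.n))

    @classmethod
    def from_features(cls, record: PlastomeRecord) -> "RegionPartition":
        regions = {f.name: f for f in record.features if f.kind == "region"}
        missing = {"LSC", "IRA", "SSC", "IRB"} - set(regions)
        if missing:
            raise ValueError(f"missing region annotations: {sorted(missing)}")
        ira = record.sequence[regions["IRA"].start : regions["IRA"].end]
        irb = record.sequence[regions["IRB"].start : regions["IRB"].end]
        ident = _identity(revcomp(ira), irb)
        return cls(
            lsc=(regions["LSC"].start, regions["LSC"].end),
            ira=(regions["IRA"].start, regions["IRA"].end),
            ssc=(regions["SSC"].start, regions["SSC"].end),
            irb=(regions["IRB"].start, regions["IRB"].end),
            n=len(record),
            ir_identity=ident,
        )


def _identity(a: str, b: str) -> float:
    if len(a) != len(b) or not a:
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


# ---------------------------------------------------------------------------
# IR detection
# ---------------------------------------------------------------------------


def detect_partition(
    genome: PlastomeRecord | str,
    min_ir_len: int = 1000,
    min_identity: float = 0.99,
) -> RegionPartition | None:
    """Detect the quadripartite partition of a circular plastome.

    Returns the partition built from the highest-scoring (longest) inverted
    near-identical arc pair of length >= min_ir_len at identity >=
    min_identity, extended maximally, or ``None`` when no qualifying pair
    exists (an IR-lacking molecule).
    """
    rec = genome if isinstance(genome, PlastomeRecord) else None
    seq = genome.sequence if rec is not None else str(genome).upper()
    n = len(seq)
    if n < 2 * min_ir_len:
        return None
    k = min(25, max(8, min_ir_len // 4))
    best = _best_inverted_pair(seq, k, min_ir_len, min_identity)
    if best is None:
        return None
    (a_s, a_e), (b_s, b_e), ident = best

    # single-copy arcs between the two IR copies (forward order a then b)
    sc1 = (a_e % n, a_e % n + (b_s - a_e) % n)  # between A end and B start
    sc2 = (b_e % n, b_e % n + (a_s - b_e) % n)  # between B end and A start
    len1 = sc1[1] - sc1[0]
    len2 = sc2[1] - sc2[0]
    if len1 == len2:
        lsc_arc = _tie_break_lsc(rec, sc1, sc2, n) if rec is not None else sc1
    else:
        lsc_arc = sc1 if len1 > len2 else sc2
    if lsc_arc == sc1:
        lsc, ira, ssc, irb = sc1, (b_s, b_e), sc2, (a_s, a_e)
    else:
        lsc, ira, ssc, irb = sc2, (a_s, a_e), sc1, (b_s, b_e)
    # normalize starts into [0, n)
    norm = lambda arc: (arc[0] % n, arc[0] % n + (arc[1] - arc[0]))
    return RegionPartition(
        lsc=norm(lsc), ira=norm(ira), ssc=norm(ssc), irb=norm(irb),
        n=n, ir_identity=ident,
    )


def _tie_break_lsc(rec, sc1, sc2, n):
    """Equal-length single-copy arcs: the one holding rbcL (else more genes)
    is called LSC."""
    def genes_in(arc):
        s, e = arc
        hits = [
            f.name
            for f in rec.genes()
            if (f.midpoint() - s) % n < e - s
        ]
        return hits

    g1, g2 = genes_in(sc1), genes_in(sc2)
    if "rbcL" in g1:
        return sc1
    if "rbcL" in g2:
        return sc2
    return sc1 if len(g1) >= len(g2) else sc2


def _best_inverted_pair(seq: str, k: int, min_len: int, min_identity: float):
    """Highest-scoring inverted arc pair on the circle, or None.

    Seeds exact k-mers of the doubled forward sequence against the doubled
    reverse complement, clusters by circular diagonal, extends through
    isolated mismatches, and keeps disjoint pairs only.
    """
    n = len(seq)
    rc = revcomp(seq)
    rcd = rc + rc
    index: dict[str, list[int]] = {}
    step = max(1, k // 2)
    for c in range(0, n, 1):
        index.setdefault(rcd[c : c + k], []).append(c)
    d = seq + seq
    diagonals: dict[int, list[tuple[int, int]]] = {}
    for i in range(0, n, step):
        for c in index.get(d[i : i + k], ()):
            diagonals.setdefault((c - i) % n, []).append((i, c))

    candidates = []
    for diag, hits in diagonals.items():
        hits.sort()
        cluster: list[tuple[int, int]] = []
        for h in hits + [(10 * n, 0)]:
            if cluster and h[0] - cluster[-1][0] > 4 * step:
                candidates.extend(
                    _extend_cluster(d, rcd, n, k, cluster, min_len, min_identity)
                )
                cluster = []
            cluster.append(h)
    if not candidates:
        return None

    seen = set()
    best = None
    for a_s, a_e, c_s, c_e in candidates:
        length = a_e - a_s
        # map the rc-side interval back to forward coordinates
        b_s = (n - c_e) % n
        a0 = a_s % n
        arc_a = (a0, a0 + length)
        arc_b = (b_s, b_s + length)
        key = tuple(sorted([arc_a[0], arc_b[0]])) + (length,)
        if key in seen:
            continue
        seen.add(key)
        if _arcs_overlap(arc_a, arc_b, n):
            continue
        ident = _pair_identity(seq, arc_a, arc_b, n)
        if ident < min_identity:
            continue
        # orient: arc_a then arc_b in forward order starting from arc_a
        cand = (arc_a, arc_b, ident, length)
        if best is None or length > best[3]:
            best = cand
    if best is None:
        return None
    return best[0], best[1], best[2]


def _extend_cluster(d, rcd, n, k, cluster, min_len, min_identity):
    i_lo = min(h[0] for h in cluster)
    i_hi = max(h[0] for h in cluster) + k
    c_lo = min(h[1] for h in cluster)
    # anchor: extend from [i_lo, i_hi) with rc side starting at c_lo
    left = _extend_dir(d, rcd, i_lo, c_lo, -1)
    right = _extend_dir(d, rcd, i_hi - 1, c_lo + (i_hi - 1 - i_lo), +1)
    a_s, a_e = i_lo - left, i_hi + right
    c_s = c_lo - left
    c_e = c_s + (a_e - a_s)
    if a_e - a_s < min_len:
        return []
    return [(a_s, a_e, c_s, c_e)]


def _extend_dir(d, rcd, i0, c0, direction, window=20, need=19):
    """Extend an exact-diagonal match, stepping over isolated mismatches as
    long as the following `window` bases keep near-perfect identity."""
    ext = 0
    i, c = i0 + direction, c0 + direction
    while 0 <= i < len(d) and 0 <= c < len(rcd):
        if d[i] == rcd[c]:
            ext += 1
        else:
            ahead = 0
            for w in range(1, window + 1):
                ii, cc = i + direction * w, c + direction * w
                if 0 <= ii < len(d) and 0 <= cc < len(rcd) and d[ii] == rcd[cc]:
                    ahead += 1
            if ahead < need:
                break
            ext += 1
        i += direction
        c += direction
    return ext


def _arcs_overlap(a, b, n) -> bool:
    for p in (b[0] % n, (b[1] - 1) % n):
        if (p - a[0]) % n < a[1] - a[0]:
            return True
    for p in (a[0] % n, (a[1] - 1) % n):
        if (p - b[0]) % n < b[1] - b[0]:
            return True
    return False


def _pair_identity(seq, arc_a, arc_b, n) -> float:
    d = seq + seq
    a = d[arc_a[0] : arc_a[1]]
    b = d[arc_b[0] : arc_b[1]]
    return _identity(revcomp(a), b)


# ---------------------------------------------------------------------------
# Region metrics
# ---------------------------------------------------------------------------


def region_metrics(partition: RegionPartition | None, genome: PlastomeRecord) -> pd.DataFrame:
    """Size (bp) and GC fraction per region plus the whole molecule."""
    d = genome.doubled()
    rows = []
    if partition is not None:
        for name in ("LSC", "IRA", "SSC", "IRB"):
            s, e = partition.arc(name)
            seg = d[s : e]
            rows.append({"region": name, "size_bp": e - s, "gc": gc_fraction(seg)})
    rows.append(
        {"region": "total", "size_bp": len(genome), "gc": gc_fraction(genome.sequence)}
    )
    df = pd.DataFrame(rows)
    if partition is not None:
        assert df[df.region != "total"].size_bp.sum() == len(genome)
    return df


# ---------------------------------------------------------------------------
# Plastome typing
# ---------------------------------------------------------------------------

#: canonical strands of the typing markers inside IRa (LSC -> SSC reading)
_CANONICAL_IRA_STRAND = {"ndhB": "-", "trnR-ACG": "+", "ycf1": "-"}
_MARKERS = ("ndhB", "ycf1", "trnR-ACG")
_BORDER_GENES = ("rps19", "ndhF", "ycf1")


@dataclass(frozen=True)
class PlastomeType:
    major: str  # I / II / III / unclassifiable
    minor: str  # a / b / c / none
    evidence: tuple = ()
    border_offsets: dict = field(default_factory=dict, hash=False, compare=False)
    missing: str | None = None


def classify_type(
    genome: PlastomeRecord,
    partition: RegionPartition | None = None,
    minor_rule=None,
) -> PlastomeType:
    """Assign the major structural type from the signed order of the marker
    genes (ndhB, ycf1, trnR-ACG) inside IRa, and a minor type from which
    border gene (rps19, ndhF, ycf1) straddles an IR junction.

    The minor a/b/c mapping is configurable: ``minor_rule`` receives the
    border-offset dict and returns a label.
    """
    part = partition or RegionPartition.from_features(genome)
    gene_feats = genome.genes()
    names = {f.name for f in gene_feats}
    for marker in _MARKERS + ("rps19", "ndhF"):
        if marker not in names:
            return PlastomeType("unclassifiable", "none", missing=marker)

    n = part.n
    ira_s, ira_e = part.ira
    in_ira = [
        f for f in gene_feats
        if part.contains("IRA", int(f.midpoint()) % n)
    ]
    # order along IRa measured from the LSC-side junction
    def ira_offset(f):
        return (f.start - ira_s) % n

    in_ira.sort(key=ira_offset)
    signed = []
    for f in in_ira:
        if f.name in _MARKERS:
            orient = +1 if f.strand == _CANONICAL_IRA_STRAND[f.name] else -1
            signed.append((f.name, orient, ira_offset(f)))
    idx = {name: i for i, (name, _, _) in enumerate(signed)}
    orient = {name: o for name, o, _ in signed}

    major = "unclassifiable"
    if "ndhB" in idx and "trnR-ACG" in idx:
        if "ycf1" not in idx:
            if orient["ndhB"] == 1 and idx["ndhB"] < idx["trnR-ACG"]:
                major = "I"
        else:
            if (
                orient["ndhB"] == 1
                and idx["ndhB"] < idx["trnR-ACG"] < idx["ycf1"]
            ):
                major = "I"  # expansion without inversion keeps canonical order
            elif (
                orient["ndhB"] == -1
                and idx["ycf1"] < idx["trnR-ACG"] < idx["ndhB"]
            ):
                major = "II"
            elif (
                orient["ndhB"] == -1
                and idx["trnR-ACG"] < idx["ndhB"] < idx["ycf1"]
            ):
                major = "III"

    offsets = _border_offsets(genome, part)
    minor = (minor_rule or _default_minor_rule)(offsets)
    return PlastomeType(major, minor, tuple(signed), offsets)


def _border_offsets(genome: PlastomeRecord, part: RegionPartition) -> dict:
    """bp of each border gene inside the IR (per copy closest to a junction);
    0 means fully single-copy, len(gene) fully IR."""
    out = {}
    for name in _BORDER_GENES:
        copies = [f for f in genome.genes() if f.name == name]
        if not copies:
            continue
        best = 0
        for f in copies:
            ir_bp = part.overlap("IRA", f.start, f.end) + part.overlap(
                "IRB", f.start, f.end
            )
            sc_bp = len(f) - ir_bp
            if 0 < ir_bp < len(f):
                best = max(best, ir_bp)
            elif ir_bp == len(f) and sc_bp == 0:
                best = max(best, 0)  # fully inside IR: not a junction gene
        out[name] = best
    return out


def _default_minor_rule(offsets: dict) -> str:
    for gene, label in (("rps19", "a"), ("ndhF", "b"), ("ycf1", "c")):
        if offsets.get(gene, 0) > 0:
            return label
    return "none"


# ---------------------------------------------------------------------------
# Gene-order inversions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InversionBlock:
    """A maximal run of shared genes collinear in reversed order/sign.

    Breakpoints are inter-anchor intervals (between the block's terminal
    genes and their flanking kept neighbours), one pair per genome.
    """

    genes: tuple
    interval_a: tuple[int, int]
    interval_b: tuple[int, int]
    orientation: str  # always "inverted" for reported blocks
    breakpoints_a: tuple  # ((left_lo, left_hi), (right_lo, right_hi))
    breakpoints_b: tuple


def _reduced_gene_order(record: PlastomeRecord, part: RegionPartition):
    """Gene list with the IRb-region copy of duplicated genes dropped;
    returns [(name, start, end, strand)], plus the IRb-copy alternatives
    for genes that are duplicated."""
    genes = record.genes()
    by_name: dict[str, list[Feature]] = {}
    for f in genes:
        by_name.setdefault(f.name, []).append(f)
    kept, irb_alt = [], {}
    for name, copies in by_name.items():
        if len(copies) == 1:
            kept.append(copies[0])
        else:
            in_irb = [f for f in copies if part.contains("IRB", int(f.midpoint()) % part.n)]
            out_irb = [f for f in copies if f not in in_irb]
            if out_irb:
                kept.append(out_irb[0])
                if in_irb:
                    irb_alt[name] = in_irb[0]
            else:
                kept.append(copies[0])
    kept.sort(key=lambda f: f.start)
    return kept, irb_alt


def find_inversions(genome_a: PlastomeRecord, genome_b: PlastomeRecord) -> list[InversionBlock]:
    """Inverted synteny blocks of B relative to A from signed gene orders.

    Each genome is reduced to one gene copy (the IRb-region copy of
    IR-duplicated genes is dropped). For genes duplicated in only one of the
    two genomes the copy is ambiguous; each contiguous run of such genes is
    resolved to the copy choice (IRa-side or IRb-side) that minimizes the
    number of gene-order breakpoints, preferring the IRa side on ties.
    """
    part_a = RegionPartition.from_features(genome_a)
    part_b = RegionPartition.from_features(genome_b)
    kept_a, alt_a = _reduced_gene_order(genome_a, part_a)
    kept_b, alt_b = _reduced_gene_order(genome_b, part_b)
    shared = {f.name for f in kept_a} & {f.name for f in kept_b}
    if not shared:
        raise ValueError("genomes share no annotated genes")
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes for gene-order analysis")

    # ambiguous genes: duplicated in exactly one genome
    dup_a = {
        n for n in shared if _copy_count(genome_a, n) == 2 and _copy_count(genome_b, n) == 1
    }
    dup_b = {
        n for n in shared if _copy_count(genome_b, n) == 2 and _copy_count(genome_a, n) == 1
    }

    best = None
    for order_a in _copy_variants(kept_a, alt_a, dup_a, shared):
        for order_b in _copy_variants(kept_b, alt_b, dup_b, shared):
            perm = _signed_permutation(order_a, order_b)
            nb = _count_breakpoints(perm)
            if best is None or nb < best[0]:
                best = (nb, order_a, order_b, perm)
    _, order_a, order_b, perm = best
    return _inverted_blocks(order_a, order_b, perm)


def _copy_count(record, name):
    return sum(1 for f in record.genes() if f.name == name)


def _copy_variants(kept, alt, ambiguous, shared):
    """Yield gene orders for every IRa/IRb copy choice of each ambiguous run."""
    kept = [f for f in kept if f.name in shared]
    runs = []
    current = []
    for i, f in enumerate(kept):
        if f.name in ambiguous and f.name in alt:
            current.append(i)
        else:
            if current:
                runs.append(tuple(current))
                current = []
    if current:
        runs.append(tuple(current))
    runs = runs[:8]  # bound the enumeration
    for mask in range(2 ** len(runs)):
        variant = list(kept)
        for r, run in enumerate(runs):
            if mask >> r & 1:
                for i in run:
                    variant[i] = alt[kept[i].name]
        yield sorted(variant, key=lambda f: f.start)


def _signed_permutation(order_a, order_b):
    index = {f.name: i for i, f in enumerate(order_a)}
    strand_a = {f.name: f.strand for f in order_a}
    perm = []
    for f in order_b:
        if f.name not in index:
            continue
        sign = 1 if f.strand == strand_a[f.name] else -1
        perm.append(sign * (index[f.name] + 1))
    return perm


def _count_breakpoints(perm) -> int:
    nb = 0
    for x, y in zip(perm, perm[1:]):
        ok = (x > 0 and y > 0 and y == x + 1) or (x < 0 and y < 0 and y == x + 1)
        if not ok:
            nb += 1
    return nb


def _inverted_blocks(order_a, order_b, perm) -> list[InversionBlock]:
    b_named = [f for f in order_b if f.name in {g.name for g in order_a}]
    blocks = []
    i = 0
    while i < len(perm):
        if perm[i] < 0:
            j = i
            while j + 1 < len(perm) and perm[j + 1] < 0 and perm[j + 1] == perm[j] + 1:
                j += 1
            blocks.append((i, j))
            i = j + 1
        else:
            i += 1
    out = []
    for i, j in blocks:
        genes_b = [f.name for f in b_named[i : j + 1]]
        feats_b = b_named[i : j + 1]
        feats_a = sorted(
            (f for f in order_a if f.name in genes_b), key=lambda f: f.start
        )
        bp_b = _flank_intervals(b_named, i, j)
        a_names = [f.name for f in order_a]
        ai = sorted(a_names.index(g) for g in genes_b)
        bp_a = _flank_intervals(order_a, ai[0], ai[-1])
        out.append(
            InversionBlock(
                genes=tuple(f.name for f in feats_a),
                interval_a=(feats_a[0].start, feats_a[-1].end),
                interval_b=(feats_b[0].start, feats_b[-1].end),
                orientation="inverted",
                breakpoints_a=bp_a,
                breakpoints_b=bp_b,
            )
        )
    return out


def _flank_intervals(order, i, j):
    left = (order[i - 1].end, order[i].start) if i > 0 else (0, order[i].start)
    right = (
        (order[j].end, order[j + 1].start)
        if j + 1 < len(order)
        else (order[j].end, order[j].end)
    )
    return (left, right)
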