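"""Synthetic plastomes, trees, traits, and long reads.

The generator emulates the statistical structure of *Plantago*-like
plastomes so every downstream stage is testable without downloads:

* a quadripartite molecule (LSC + IRa + SSC + IRb, IRb the exact reverse
  complement of IRa) carrying an ordered marker-gene map;
* clade-specific structural events — IR expansion that translocates a block
  of SSC genes into both IR copies, and inversions inside the IR applied
  symmetrically to both copies;
* dispersed repeats of controlled size/identity/orientation;
* sequence evolution along a tree under HKY with per-region rate
  multipliers and GC equilibria, with the two IR copies receiving identical
  substitutions (perfect concerted evolution);
* long reads drawn from a mixture of genome isomers: the main form, the
  SSC-flipped (flip-flop) form at ~50:50, and recombinant forms mediated by
  an annotated repeat pair at sub-percent stoichiometry.

All randomness flows from a single ``numpy`` generator; no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm

from ._seq import ints_to_seq, revcomp, seq_to_ints
from .io import Feature, PlastomeRecord

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSpec:
    name: str
    kind: str  # CDS / tRNA / rRNA
    length: int
    strand: str = "+"


# Canonical (type I) gene maps. Lengths are desk-scale stand-ins for the real
# loci; CDS lengths are multiples of three. Order within each region mirrors
# the canonical plastome: rps19 sits at the LSC end next to J(LSC-IRa), the
# tRNAs trnR-ACG/trnN-GUU at the IRa end next to J(IRa-SSC), ndhF opens the
# SSC and the nine variably-located genes (ndhD .. ycf1) close it, with ycf1
# adjacent to J(SSC-IRb).
LSC_GENES = (
    GeneSpec("psbA", "CDS", 1062, "-"),
    GeneSpec("matK", "CDS", 1509, "-"),
    GeneSpec("atpA", "CDS", 1524, "-"),
    GeneSpec("atpB", "CDS", 1497, "-"),
    GeneSpec("rbcL", "CDS", 1428, "+"),
    GeneSpec("psaB", "CDS", 2205, "-"),
    GeneSpec("psaA", "CDS", 2253, "-"),
    GeneSpec("rps19", "CDS", 279, "-"),
)

IR_GENES = (  # IRa, read from the LSC side toward the SSC side
    GeneSpec("rpl2", "CDS", 822, "-"),
    GeneSpec("rpl23", "CDS", 282, "-"),
    GeneSpec("ycf2", "CDS", 1200, "+"),
    GeneSpec("ndhB", "CDS", 1002, "-"),
    GeneSpec("rps7", "CDS", 468, "-"),
    GeneSpec("rrn16", "rRNA", 1491, "+"),
    GeneSpec("trnL-CAA", "tRNA", 81, "-"),
    GeneSpec("trnR-ACG", "tRNA", 74, "+"),
    GeneSpec("trnN-GUU", "tRNA", 72, "-"),
)

SSC_GENES = (  # read from the IRa side toward the IRb side
    GeneSpec("ndhF", "CDS", 741, "-"),
    GeneSpec("rpl32", "CDS", 171, "+"),
    GeneSpec("ccsA", "CDS", 501, "+"),
    GeneSpec("ndhD", "CDS", 501, "-"),
    GeneSpec("psaC", "CDS", 246, "-"),
    GeneSpec("ndhE", "CDS", 306, "-"),
    GeneSpec("ndhG", "CDS", 354, "-"),
    GeneSpec("ndhI", "CDS", 333, "-"),
    GeneSpec("ndhA", "CDS", 543, "-"),
    GeneSpec("ndhH", "CDS", 591, "-"),
    GeneSpec("rps15", "CDS", 273, "-"),
    GeneSpec("ycf1", "CDS", 903, "+"),
)

#: The five genes translocated into the IR by the clade-B (type II) expansion
#: and the nine translocated by the clade-C (type III) expansion.
TYPE_II_EXPANSION = ("ndhI", "ndhA", "ndhH", "rps15", "ycf1")
TYPE_III_EXPANSION = (
    "ndhD", "psaC", "ndhE", "ndhG", "ndhI", "ndhA", "ndhH", "rps15", "ycf1",
)


@dataclass(frozen=True)
class RepeatInsert:
    """A dispersed repeat pair written into the genome at construction.

    Offsets are bp from the start of the named region; the second copy is
    reverse-complemented when ``inverted``. ``identity`` < 1 degrades the
    second copy by random substitutions.
    """

    name: str = "R1"
    length: int = 303
    region1: str = "LSC"
    offset1: int = 2300
    # default IR copy sits inside ycf2, upstream of the ndhB..ycf1 inversion
    # endpoints, so the pair survives every structural-event recipe
    region2: str = "IRA"
    offset2: int = 2200
    inverted: bool = True
    identity: float = 1.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic plastome.

    Region lengths and GC equilibria follow the qualitative contrasts of the
    system being emulated (IR more GC-rich and slower than single-copy DNA)
    at roughly one-fifth scale of a real ~150-kb plastome.
    """

    lsc_len: int = 14000
    ir_len: int = 6500
    ssc_len: int = 6500
    gc: dict = field(
        default_factory=lambda: {"LSC": 0.36, "IR": 0.43, "SSC": 0.32}
    )
    kappa: float = 2.0
    repeats: tuple = (RepeatInsert(),)
    lsc_genes: tuple = LSC_GENES
    ir_genes: tuple = IR_GENES
    ssc_genes: tuple = SSC_GENES


# ---------------------------------------------------------------------------
# Structural events
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IrExpansion:
    """Move the SSC-terminal block of named genes into the IR.

    The block (which must sit contiguously at the SSC end adjacent to IRb)
    is re-labelled as IR and a reverse-complemented copy is inserted at the
    IRa–SSC junction, so both IR copies carry the genes and the genome grows
    by the block length.
    """

    genes: tuple


@dataclass(frozen=True)
class Inversion:
    """Reverse-complement the IRa segment from start_gene to end_gene,
    mirrored into IRb so IRa/IRb identity is preserved."""

    start_gene: str
    end_gene: str


@dataclass(frozen=True)
class JunctionShift:
    """Expand the IR into the LSC by ``bp`` bases at J(LSC-IRa).

    Used to emulate the modest border-gene shifts that define minor plastome
    types (e.g. rps19 straddling the junction).
    """

    bp: int


def type_II_events() -> list:
    """Expansion of five SSC genes plus the nested ~21-kb + ~6-kb inversions."""
    return [
        IrExpansion(TYPE_II_EXPANSION),
        Inversion("ndhB", "ycf1"),
        Inversion("ycf1", "ycf1"),
    ]


def type_III_events() -> list:
    """Expansion of nine SSC genes plus the ~14-kb ndhB..trnR-ACG inversion."""
    return [
        IrExpansion(TYPE_III_EXPANSION),
        Inversion("ndhB", "trnR-ACG"),
    ]


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return ints_to_seq(rng.choice(4, size=n, p=p))


_STOPS = {"TAA", "TAG", "TGA"}


def _random_cds(rng: np.random.Generator, length: int, gc: float) -> str:
    """ATG + stop-free random codons + TAA, at the requested GC-ish level."""
    assert length % 3 == 0 and length >= 9
    codons = ["ATG"]
    while len(codons) < length // 3 - 1:
        c = _random_bases(rng, 3, gc)
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _build_region(rng, genes, region_len, gc, kind_override=None):
    """Lay genes in order inside a region, separated by equal spacers.

    Returns (sequence, [(GeneSpec, start, end)]). Raises when the gene map
    does not fit, stating required vs available bp.
    """
    need = sum(g.length for g in genes)
    if need > region_len - 2 * (len(genes) + 1):
        raise ValueError(
            f"gene map overflow: needs {need} bp plus spacers but region has "
            f"{region_len} bp"
        )
    spacer_total = region_len - need
    n_spacers = len(genes) + 1
    base = spacer_total // n_spacers
    extra = spacer_total % n_spacers
    parts: list[str] = []
    placed = []
    pos = 0
    for i, g in enumerate(genes):
        slen = base + (1 if i < extra else 0)
        parts.append(_random_bases(rng, slen, gc))
        pos += slen
        gseq = (
            _random_cds(rng, g.length, gc)
            if g.kind == "CDS"
            else _random_bases(rng, g.length, gc)
        )
        if g.strand == "-":
            gseq = revcomp(gseq)
        parts.append(gseq)
        placed.append((g, pos, pos + g.length))
        pos += g.length
    parts.append(_random_bases(rng, region_len - pos, gc))
    return "".join(parts), placed


def build_type_I_plastome(
    config: SimConfig | None = None, seed: int = 0, taxon_id: str = "typeI"
) -> PlastomeRecord:
    """Construct a canonical quadripartite plastome.

    Postconditions: IRb is the exact reverse complement of IRa; region sizes
    equal the configured values; every gene of the map is annotated (IR genes
    twice, once per copy); injected repeats are annotated as paired
    ``repeat`` features; the four region boundaries are "sharp" (the bases
    flanking each junction do not extend the inverted-repeat match), so
    partition detection recovers them exactly.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    lsc, lsc_genes = _build_region(rng, cfg.lsc_genes, cfg.lsc_len, cfg.gc["LSC"])
    ira, ir_genes = _build_region(rng, cfg.ir_genes, cfg.ir_len, cfg.gc["IR"])
    ssc, ssc_genes = _build_region(rng, cfg.ssc_genes, cfg.ssc_len, cfg.gc["SSC"])

    region_seqs = {"LSC": lsc, "IRA": ira, "SSC": ssc}
    repeat_feats = []
    for rep in cfg.repeats:
        core = _random_bases(rng, rep.length, 0.40)
        copy2 = revcomp(core) if rep.inverted else core
        if rep.identity < 1.0:
            copy2 = _degrade(rng, copy2, rep.identity)
        for region, offset, seqv, strand in (
            (rep.region1, rep.offset1, core, "+"),
            (rep.region2, rep.offset2, copy2, "-" if rep.inverted else "+"),
        ):
            s = region_seqs[region]
            if offset < 0 or offset + rep.length > len(s):
                raise ValueError(f"repeat {rep.name} does not fit in {region}")
            region_seqs[region] = s[:offset] + seqv + s[offset + rep.length :]
        off = {"LSC": 0, "IRA": cfg.lsc_len, "SSC": cfg.lsc_len + cfg.ir_len}
        repeat_feats.append(
            Feature(rep.name, "repeat", off[rep.region1] + rep.offset1,
                    off[rep.region1] + rep.offset1 + rep.length, "+")
        )
        repeat_feats.append(
            Feature(rep.name, "repeat", off[rep.region2] + rep.offset2,
                    off[rep.region2] + rep.offset2 + rep.length,
                    "-" if rep.inverted else "+")
        )

    lsc, ira, ssc = region_seqs["LSC"], region_seqs["IRA"], region_seqs["SSC"]
    l1 = len(lsc)
    l2 = l1 + len(ira)
    l3 = l2 + len(ssc)
    total = l3 + len(ira)
    sequence = lsc + ira + ssc + revcomp(ira)

    features = [
        Feature("LSC", "region", 0, l1),
        Feature("IRA", "region", l1, l2),
        Feature("SSC", "region", l2, l3),
        Feature("IRB", "region", l3, total),
    ]
    for g, s, e in lsc_genes:
        features.append(Feature(g.name, g.kind, s, e, g.strand))
    for g, s, e in ir_genes:
        features.append(Feature(g.name, g.kind, l1 + s, l1 + e, g.strand))
        # mirrored copy in IRb
        ms, me = l3 + (len(ira) - e), l3 + (len(ira) - s)
        features.append(Feature(g.name, g.kind, ms, me, _flip(g.strand)))
    for g, s, e in ssc_genes:
        features.append(Feature(g.name, g.kind, l2 + s, l2 + e, g.strand))
    features.extend(repeat_feats)

    rec = PlastomeRecord(taxon_id, sequence, True, features)
    _sharpen_boundaries(rec)
    return rec


def _degrade(rng, seq: str, identity: float) -> str:
    n_mut = int(round((1 - identity) * len(seq)))
    arr = seq_to_ints(seq).copy()
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    arr[pos] = (arr[pos] + rng.integers(1, 4, size=n_mut)) % 4
    return ints_to_seq(arr)


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _sharpen_boundaries(rec: PlastomeRecord) -> None:
    """Mutate at most two single-copy bases so the IRa/IRb match cannot be
    extended past the annotated junctions (keeps detection exact)."""
    regions = {f.name: f for f in rec.features if f.kind == "region"}
    if set(regions) != {"LSC", "IRA", "SSC", "IRB"}:
        return
    s = list(rec.sequence)
    l1, l2 = regions["IRA"].start, regions["IRA"].end
    l3 = regions["IRB"].start
    # outward extension: last LSC base vs complement of first base after IRb
    if s[l1 - 1] == _COMP1[s[regions["IRB"].end % len(s)]]:
        s[l1 - 1] = _other_base(s[l1 - 1], forbid=s[l1 - 1])
    # inward extension: first SSC base vs complement of last SSC base
    if s[l3 - 1] == _COMP1[s[l2]]:
        s[l3 - 1] = _other_base(s[l3 - 1], forbid=_COMP1[s[l2]])
    rec.sequence = "".join(s)


def _other_base(current: str, forbid: str) -> str:
    for b in "ACGT":
        if b != current and b != forbid:
            return b
    return "A"


# ---------------------------------------------------------------------------
# Event application
# ---------------------------------------------------------------------------


def apply_structural_events(genome: PlastomeRecord, events) -> PlastomeRecord:
    """Apply IR expansions / inversions / junction shifts in order.

    Every event preserves the IRa/IRb reverse-complement identity; an event
    that cannot be applied symmetrically raises.
    """
    rec = PlastomeRecord(
        genome.taxon_id, genome.sequence, genome.circular, list(genome.features)
    )
    for ev in events:
        if isinstance(ev, IrExpansion):
            rec = _apply_expansion(rec, tuple(ev.genes))
        elif isinstance(ev, Inversion):
            rec = _apply_inversion(rec, ev.start_gene, ev.end_gene)
        elif isinstance(ev, JunctionShift):
            rec = _apply_junction_shift(rec, ev.bp)
        else:
            raise TypeError(f"unknown event {ev!r}")
        _sharpen_boundaries(rec)
        _check_ir_identity(rec)
    return rec


def _regions4(rec: PlastomeRecord):
    regions = {f.name: f for f in rec.features if f.kind == "region"}
    missing = {"LSC", "IRA", "SSC", "IRB"} - set(regions)
    if missing:
        raise ValueError(f"genome lacks region annotations: {sorted(missing)}")
    return regions


def _check_ir_identity(rec: PlastomeRecord) -> None:
    r = _regions4(rec)
    ira = rec.sequence[r["IRA"].start : r["IRA"].end]
    irb = rec.sequence[r["IRB"].start : r["IRB"].end]
    if revcomp(ira) != irb:
        raise ValueError("event broke IRa/IRb identity")


def _apply_expansion(rec: PlastomeRecord, genes: tuple) -> PlastomeRecord:
    r = _regions4(rec)
    l1, l2 = r["IRA"].start, r["IRA"].end
    l3, L = r["IRB"].start, r["IRB"].end
    named = [
        f
        for f in rec.features
        if f.kind in ("CDS", "tRNA", "rRNA")
        and f.name in genes
        and l2 <= f.start < l3
    ]
    if {f.name for f in named} != set(genes):
        missing = set(genes) - {f.name for f in named}
        raise ValueError(f"expansion genes not found in SSC: {sorted(missing)}")
    bs_gene = min(f.start for f in named)
    # all genes between the block start and the SSC end must be in the block
    between = [
        f
        for f in rec.features
        if f.kind in ("CDS", "tRNA", "rRNA") and bs_gene <= f.start < l3
    ]
    if {f.name for f in between} != set(genes):
        raise ValueError("expansion genes must be a contiguous block at the SSC end")
    prev_end = max(
        [f.end for f in rec.features if f.kind in ("CDS", "tRNA", "rRNA")
         and l2 <= f.end <= bs_gene],
        default=l2,
    )
    bs = (prev_end + bs_gene) // 2  # cut mid-spacer before the block
    block = rec.sequence[bs:l3]
    blen = len(block)
    new_seq = rec.sequence[:l2] + revcomp(block) + rec.sequence[l2:]

    new_feats: list[Feature] = []
    for f in rec.features:
        if f.kind == "region":
            continue
        if f.start >= l2:
            new_feats.append(replace(f, start=f.start + blen, end=f.end + blen))
        else:
            new_feats.append(f)
    # reverse-complemented gene copies inside the inserted segment
    for f in sorted(rec.features, key=lambda f: f.start):
        if f.kind in ("CDS", "tRNA", "rRNA") and bs <= f.start and f.end <= l3:
            new_feats.append(
                Feature(f.name, f.kind, l2 + (l3 - f.end), l2 + (l3 - f.start),
                        _flip(f.strand))
            )
        if f.kind == "repeat" and bs <= f.start and f.end <= l3:
            new_feats.append(
                Feature(f.name, "repeat", l2 + (l3 - f.end), l2 + (l3 - f.start),
                        _flip(f.strand))
            )
    new_feats.extend(
        [
            Feature("LSC", "region", 0, l1),
            Feature("IRA", "region", l1, l2 + blen),
            Feature("SSC", "region", l2 + blen, bs + blen),
            Feature("IRB", "region", bs + blen, L + blen),
        ]
    )
    return PlastomeRecord(rec.taxon_id, new_seq, rec.circular, new_feats)


def _ira_copy(rec, regions, name):
    l1, l2 = regions["IRA"].start, regions["IRA"].end
    hits = [
        f
        for f in rec.features
        if f.kind in ("CDS", "tRNA", "rRNA") and f.name == name
        and f.start >= l1 and f.end <= l2
    ]
    if not hits:
        raise ValueError(
            f"inversion endpoint {name!r} has no copy inside IRa; such an event "
            "would break IRa/IRb identity"
        )
    return hits[0]


def _apply_inversion(rec: PlastomeRecord, start_gene: str, end_gene: str) -> PlastomeRecord:
    r = _regions4(rec)
    l1, l2 = r["IRA"].start, r["IRA"].end
    l3 = r["IRB"].start
    fa = _ira_copy(rec, r, start_gene)
    fb = _ira_copy(rec, r, end_gene)
    s, e = min(fa.start, fb.start), max(fa.end, fb.end)
    ms, me = l3 + (l2 - e), l3 + (l2 - s)  # mirrored segment in IRb
    seq = rec.sequence
    new_seq = (
        seq[:s] + revcomp(seq[s:e]) + seq[e:ms] + revcomp(seq[ms:me]) + seq[me:]
    )

    def remap(f: Feature) -> Feature:
        if f.kind == "region":  # region bounds are unchanged by internal inversion
            return f
        for seg_s, seg_e in ((s, e), (ms, me)):
            if seg_s <= f.start and f.end <= seg_e:
                return Feature(
                    f.name, f.kind,
                    seg_s + (seg_e - f.end), seg_s + (seg_e - f.start),
                    _flip(f.strand), f.wraps_origin,
                )
            if f.start < seg_e and f.end > seg_s and not (
                seg_s <= f.start and f.end <= seg_e
            ):
                raise ValueError(
                    f"feature {f.name!r} straddles the inversion boundary"
                )
        return f

    new_feats = [remap(f) for f in rec.features]
    return PlastomeRecord(rec.taxon_id, new_seq, rec.circular, new_feats)


def _apply_junction_shift(rec: PlastomeRecord, bp: int) -> PlastomeRecord:
    """Expand the IR leftwards into the LSC by bp bases at J(LSC-IRa)."""
    r = _regions4(rec)
    l1, l2 = r["IRA"].start, r["IRA"].end
    l3, L = r["IRB"].start, r["IRB"].end
    if not 0 < bp < l1:
        raise ValueError("junction shift out of range")
    block = rec.sequence[l1 - bp : l1]
    new_seq = rec.sequence + revcomp(block)  # appended at the IRb outer end
    new_feats = [f for f in rec.features if f.kind != "region"]
    new_feats.extend(
        [
            Feature("LSC", "region", 0, l1 - bp),
            Feature("IRA", "region", l1 - bp, l2),
            Feature("SSC", "region", l2, l3),
            Feature("IRB", "region", l3, L + bp),
        ]
    )
    return PlastomeRecord(rec.taxon_id, new_seq, rec.circular, new_feats)


# ---------------------------------------------------------------------------
# Sequence evolution (HKY, per-region rates, concerted IR)
# ---------------------------------------------------------------------------


def hky_rate_matrix(kappa: float, gc: float) -> np.ndarray:
    """HKY85 generator (order A,C,G,T) scaled to one expected substitution
    per site per unit time at equilibrium."""
    pi = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -np.dot(pi, np.diag(q))
    return q / scale


def _evolve_along_tree(root: np.ndarray, tree: dendropy.Tree, q: np.ndarray,
                       multiplier: float, rng: np.random.Generator):
    """Return {tip label: int array} evolved from root down the tree."""
    states = {tree.seed_node: root}
    tips = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            pass
        else:
            t = (node.edge.length or 0.0) * multiplier
            parent = states[node.parent_node]
            if t <= 0:
                child = parent.copy()
            else:
                p = expm(q * t)
                child = np.empty_like(parent)
                for b in range(4):
                    idx = np.nonzero(parent == b)[0]
                    if idx.size:
                        child[idx] = rng.choice(4, size=idx.size, p=p[b])
            states[node] = child
        if node.is_leaf():
            tips[node.taxon.label] = states[node]
    return tips


def simulate_sequences(
    length: int,
    tree: dendropy.Tree,
    rate_multiplier: float = 1.0,
    gc: float = 0.36,
    kappa: float = 2.0,
    seed: int = 0,
    root_seq: str | None = None,
) -> dict[str, str]:
    """Evolve a single homogeneous alignment along a tree (no indels)."""
    rng = np.random.default_rng(seed)
    if root_seq is None:
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        root = rng.choice(4, size=length, p=p)
    else:
        root = seq_to_ints(root_seq)
    q = hky_rate_matrix(kappa, gc)
    tips = _evolve_along_tree(root, tree, q, rate_multiplier, rng)
    return {k: ints_to_seq(v) for k, v in tips.items()}


def evolve_sequences(
    ancestor: PlastomeRecord,
    tree: dendropy.Tree,
    region_multipliers: dict[str, float],
    kappa: float = 2.0,
    gc: dict | None = None,
    seed: int = 0,
) -> dict[str, PlastomeRecord]:
    """Evolve a whole plastome along a tree.

    Per-site rate = branch length x region multiplier ("SC" for LSC/SSC,
    "IR" for the inverted repeat). LSC, IRa and SSC evolve independently and
    each tip genome is reassembled with IRb = revcomp(IRa): the two IR
    copies receive identical substitutions (perfect concerted evolution).
    """
    gc = gc or {"LSC": 0.36, "IR": 0.43, "SSC": 0.32}
    r = _regions4(ancestor)
    rng = np.random.default_rng(seed)
    pieces = {}
    for name, mult_key, gc_key in (
        ("LSC", "SC", "LSC"), ("IRA", "IR", "IR"), ("SSC", "SC", "SSC"),
    ):
        seg = ancestor.sequence[r[name].start : r[name].end]
        q = hky_rate_matrix(kappa, gc[gc_key])
        pieces[name] = _evolve_along_tree(
            seq_to_ints(seg), tree, q, region_multipliers[mult_key], rng
        )
    out = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        ira = ints_to_seq(pieces["IRA"][label])
        seq = (
            ints_to_seq(pieces["LSC"][label])
            + ira
            + ints_to_seq(pieces["SSC"][label])
            + revcomp(ira)
        )
        out[label] = PlastomeRecord(label, seq, True, list(ancestor.features))
    return out


def three_clade_tree(n_per_clade: int = 4, stem: float = 0.10,
                     crown: float = 0.05) -> dendropy.Tree:
    """A rooted tree of three clades (A, B, C) with balanced pectinate
    subtrees; tip labels A1..An, B1.., C1..  Branch lengths in expected
    substitutions per site at the single-copy rate."""

    def clade(letter):
        tips = [f"{letter}{i+1}:{crown}" for i in range(n_per_clade)]
        nwk = tips[0]
        for t in tips[1:]:
            nwk = f"({nwk},{t}):{crown}"
        return nwk

    newick = f"(({clade('A')}:{stem},({clade('B')}:{stem},{clade('C')}:{stem}):{stem}):0.0);"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Long reads
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecombinantSpec:
    """A recombinant isomer produced by crossover at one annotated inverted
    repeat pair (the ``repeat`` feature with this name must have two copies)."""

    junction_id: str
    repeat_name: str
    weight: float = 0.0


@dataclass(frozen=True)
class IsomerSpec:
    flip_weight: float = 0.5
    recombinants: tuple = ()

    def validate(self):
        w = sum(r.weight for r in self.recombinants)
        if not 0 <= self.flip_weight <= 1 or w > 0.05 + 1e-12:
            raise ValueError(
                "flip weight must be in [0,1] and recombinant weight in [0, 0.05]"
            )


@dataclass(frozen=True)
class ReadSpec:
    n_reads: int = 500
    length_mode: str = "lognormal"  # lognormal | const | full
    mean_length: int = 12000
    sigma: float = 0.25
    error_rate: float = 0.0
    exact_counts: dict | None = None  # {"total": N, "junctions": {jid: s}}
    recomb_read_length: int = 6000


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str


def _repeat_pair(genome: PlastomeRecord, name: str):
    copies = sorted(
        (f for f in genome.features if f.kind == "repeat" and f.name == name),
        key=lambda f: f.start,
    )
    if len(copies) != 2:
        raise ValueError(f"repeat {name!r} must have exactly two annotated copies")
    return copies


def recombinant_isomer(genome: PlastomeRecord, repeat_name: str) -> tuple[str, int, int]:
    """Sequence of the isomer produced by crossover at an inverted repeat
    pair, plus the positions of its two novel junctions (isomer coords)."""
    c1, c2 = _repeat_pair(genome, repeat_name)
    if c1.strand == c2.strand:
        raise ValueError("recombinant isomers are defined for inverted pairs only")
    s = genome.sequence
    iso = s[: c1.start] + revcomp(s[c1.start : c2.end]) + s[c2.end :]
    # novel junctions: end of copy1 (meets reversed spacer) and start of copy2
    return iso, c1.end, c2.start


def flip_isomer(genome: PlastomeRecord) -> str:
    """The SSC-flipped (flip-flop) isomer."""
    r = _regions4(genome)
    s = genome.sequence
    return (
        s[: r["SSC"].start]
        + revcomp(s[r["SSC"].start : r["SSC"].end])
        + s[r["SSC"].end :]
    )


def _draw_length(rng, spec: ReadSpec, iso_len: int) -> int:
    if spec.length_mode == "full":
        return iso_len
    if spec.length_mode == "const":
        length = spec.mean_length
    else:
        mu = math.log(spec.mean_length) - spec.sigma**2 / 2
        length = int(rng.lognormal(mu, spec.sigma))
    if length > iso_len:
        length = iso_len
    if length < 100:
        length = 100
    return length


def _add_errors(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = seq_to_ints(seq).copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hits.size:
        arr[hits] = (arr[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return ints_to_seq(arr)


def simulate_long_reads(
    genome: PlastomeRecord,
    isomer_spec: IsomerSpec | None = None,
    read_spec: ReadSpec | None = None,
    seed: int = 0,
) -> tuple[list[SimRead], pd.DataFrame]:
    """Draw long reads from the isomer mixture; return reads and per-read
    ground truth (isomer of origin, recombinant flag, junction id).

    With ``exact_counts`` the requested totals are met exactly:
    non-recombinant reads are full-circle molecules (so every one of them
    overlaps every junction locus and the requested total is the per-junction
    denominator), and each recombinant read is a window centred on its
    junction.
    """
    iso = isomer_spec or IsomerSpec()
    iso.validate()
    spec = read_spec or ReadSpec()
    rng = np.random.default_rng(seed)

    main = genome.sequence
    flip = flip_isomer(genome)
    recomb = {
        r.junction_id: (recombinant_isomer(genome, r.repeat_name), r)
        for r in iso.recombinants
    }
    if spec.length_mode == "const" and spec.mean_length > len(main):
        raise ValueError("requested read length exceeds isomer length")

    reads: list[SimRead] = []
    truth_rows = []

    def emit(i, seq, isomer, junction, expected):
        rid = f"read_{i:05d}"
        reads.append(SimRead(rid, _add_errors(rng, seq, spec.error_rate)))
        truth_rows.append(
            {
                "read_id": rid,
                "isomer_of_origin": isomer,
                "is_recombinant": isomer.startswith("recombinant"),
                "junction_id": junction if junction is not None else "",
                "expected_class": expected,
            }
        )

    def covers(start, length, pos, iso_len, flank):
        """Does the arc [start, start+length) cover pos with >= flank on
        both sides (circular)?"""
        for p in (pos, pos + iso_len):
            if start + flank <= p <= start + length - flank:
                return True
        return False

    def covers_window(start, length, lo, hi, iso_len):
        """Does the arc contain the whole window [lo, hi) (circular)?"""
        return (lo - start) % iso_len + (hi - lo) <= length

    FLANK = 400  # reads covering a junction by less than this may be missed

    def flip_expected(start, length):
        # SSC orientation is only observable when the read spans a whole IR
        # copy plus unique anchors in both single-copy regions; anything
        # shorter is an exact (reverse-complement) substring of the main
        # isomer and legitimately maps as concordant.
        r = _regions4(genome)
        iso_len = len(flip)
        witness = [
            (r["IRA"].start, r["IRA"].end),
            (r["IRB"].start, r["IRB"].end),
        ]
        full = any(
            covers_window(start, length, lo - FLANK, hi + FLANK, iso_len)
            for lo, hi in witness
        )
        loose = any(
            covers_window(start, length, lo - 1, hi + 1, iso_len)
            for lo, hi in witness
        )
        return "flipflop" if full else ("any" if loose else "concordant")

    if spec.exact_counts is not None:
        total = int(spec.exact_counts["total"])
        junc_counts = {k: int(v) for k, v in spec.exact_counts.get("junctions", {}).items()}
        n_rec = sum(junc_counts.values())
        if n_rec > total:
            raise ValueError("recombinant counts exceed total")
        plan = []
        for jid, cnt in sorted(junc_counts.items()):
            plan += [jid] * cnt
        plan += [None] * (total - n_rec)
        rng.shuffle(plan)
        for i, jid in enumerate(plan):
            if jid is None:
                # full-circle molecule: overlaps every locus, so the requested
                # total is the denominator at every junction
                flipped = rng.random() < iso.flip_weight
                src = flip if flipped else main
                start = int(rng.integers(len(src)))
                seq = (src + src)[start : start + len(src)]
                if rng.random() < 0.5:
                    seq = revcomp(seq)
                emit(i, seq, "flip" if flipped else "main", None,
                     "flipflop" if flipped else "concordant")
            else:
                (iso_seq, j1, j2), _ = recomb[jid]
                window = spec.recomb_read_length
                jitter = int(rng.integers(-200, 201))
                start = max(0, j1 - window // 2 + jitter)
                end = min(len(iso_seq), start + window)
                if end > j2 - 400:  # keep the second novel junction out
                    end = j2 - 400
                if not (start + 400 <= j1 <= end - 400):
                    raise ValueError(
                        "recombinant read window cannot cover the junction; "
                        "reduce recomb_read_length or move the repeat"
                    )
                seq = iso_seq[start:end]
                if rng.random() < 0.5:
                    seq = revcomp(seq)
                emit(i, seq, f"recombinant:{jid}", jid, "recombinant")
        return reads, pd.DataFrame(truth_rows)

    # stochastic mode: isomer picked by weight, lognormal lengths
    names = ["main", "flip"] + [r.junction_id for r in iso.recombinants]
    w_rec = [r.weight for r in iso.recombinants]
    w_main = (1 - sum(w_rec)) * (1 - iso.flip_weight)
    w_flip = (1 - sum(w_rec)) * iso.flip_weight
    weights = np.array([w_main, w_flip] + w_rec)
    weights = weights / weights.sum()
    seqs = {"main": main, "flip": flip}
    for jid, ((iso_seq, _, _), _) in recomb.items():
        seqs[jid] = iso_seq
    for i in range(spec.n_reads):
        pick = names[int(rng.choice(len(names), p=weights))]
        src = seqs[pick]
        length = _draw_length(rng, spec, len(src))
        if spec.length_mode == "const" and spec.mean_length > len(src):
            raise ValueError("requested read length exceeds isomer length")
        start = int(rng.integers(len(src)))
        seq = (src + src)[start : start + length]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        if pick == "main":
            emit(i, seq, "main", None, "concordant")
        elif pick == "flip":
            emit(i, seq, "flip", None, flip_expected(start, length))
        else:
            # the first novel junction (in unique LSC flank) is decisive;
            # reads touching only the second junction, whose flank runs into
            # IR homology, may classify either way
            (iso_seq, j1, j2), _ = recomb[pick]
            full = covers(start, length, j1, len(src), FLANK)
            loose = covers(start, length, j1, len(src), 1) or covers(
                start, length, j2, len(src), 1
            )
            expected = "recombinant" if full else ("any" if loose else "concordant")
            emit(i, seq, f"recombinant:{pick}", pick if full else None, expected)
    return reads, pd.DataFrame(truth_rows)


def write_fastq(reads: list[SimRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def read_fastq(path) -> list[SimRead]:
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline().strip()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            reads.append(SimRead(header[1:].split()[0], seq.upper()))
    return reads
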