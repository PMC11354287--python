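"""Region-stratified substitution rate estimation.

Loci are classified by where they live across taxa: CSC (single-copy in
every taxon), CIR (inside the IR in every taxon), or VSR (variably located).
A gene straddling an IR–SC junction with fewer than 40 nt inside the IR
counts as single-copy in that taxon; loci shorter than 150 bp after gap
exclusion are dropped.

Substitution estimates are distance-based: Nei–Gojobori (1986) counting
with Jukes–Cantor correction for synonymous/nonsynonymous rates and
closed-form JC69 / K80 / GTR distances for overall nucleotide rates.
Branch lengths are fitted to pairwise distances on a fixed topology by
non-negative least squares, and clade rates are summarized as mean
root-to-tip cumulative branch lengths; translocation effects are reported
as ratios of those clade means against the CSC concatenation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy.linalg import logm
from scipy.optimize import nnls

# plant plastid genes use the bacterial/plastid code
_CODON_TABLE = CodonTable.unambiguous_dna_by_id[11]
_BASES = "ACGT"
_STOPS = frozenset(_CODON_TABLE.stop_codons)


def _aa(codon: str) -> str:
    return "*" if codon in _STOPS else _CODON_TABLE.forward_table[codon]


# ---------------------------------------------------------------------------
# Locus classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocusClass:
    locus: str
    region_class: str  # CSC | CIR | VSR
    included: bool
    note: str = ""


JUNCTION_SC_RULE_NT = 40  # < this many nt inside the IR counts as single-copy
MIN_LOCUS_LEN = 150


def classify_loci(
    ir_overlap: dict[str, dict[str, int]],
    locus_lengths: dict[str, int],
    taxa: list[str] | None = None,
) -> list[LocusClass]:
    """Three-way CSC/CIR/VSR classification.

    ``ir_overlap[locus][taxon]`` is the number of locus bases inside the IR
    for that taxon (0 for a fully single-copy locus). The 40-nt junction
    rule is applied per taxon before aggregation; loci shorter than 150 bp
    or missing from some taxa are flagged and excluded.
    """
    out = []
    for locus in sorted(ir_overlap):
        per_taxon = ir_overlap[locus]
        length = locus_lengths[locus]
        expected = taxa if taxa is not None else list(per_taxon)
        missing = [t for t in expected if t not in per_taxon]
        if missing:
            out.append(LocusClass(locus, "VSR", False, f"missing in {missing[0]}"))
            continue
        in_ir = [per_taxon[t] >= JUNCTION_SC_RULE_NT for t in expected]
        if all(in_ir):
            cls = "CIR"
        elif not any(in_ir):
            cls = "CSC"
        else:
            cls = "VSR"
        if length < MIN_LOCUS_LEN:
            out.append(LocusClass(locus, cls, False, f"shorter than {MIN_LOCUS_LEN} bp"))
        else:
            out.append(LocusClass(locus, cls, True))
    return out


def ir_overlap_from_genomes(records: dict, partitions: dict) -> tuple[dict, dict]:
    """Per-locus, per-taxon IR overlap (bp) and locus lengths, from annotated
    genomes and their partitions. For IR-duplicated genes the maximal
    overlap over copies is used."""
    overlap: dict[str, dict[str, int]] = {}
    lengths: dict[str, int] = {}
    for taxon, rec in records.items():
        part = partitions[taxon]
        for f in rec.genes():
            bp = part.overlap("IRA", f.start, f.end) + part.overlap("IRB", f.start, f.end)
            cur = overlap.setdefault(f.name, {}).get(taxon, 0)
            overlap[f.name][taxon] = max(cur, bp)
            lengths[f.name] = max(lengths.get(f.name, 0), len(f))
    return overlap, lengths


# ---------------------------------------------------------------------------
# Alignment preparation
# ---------------------------------------------------------------------------


def prepare_alignment(
    alignment: dict[str, str], min_len: int = MIN_LOCUS_LEN
) -> dict[str, str] | None:
    """Drop every column containing a gap; drop the matrix entirely when
    fewer than ``min_len`` columns remain (returns None)."""
    seqs = list(alignment.values())
    if not seqs:
        raise ValueError("empty alignment")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("ragged alignment: unequal row lengths")
    arr = np.array([list(s.upper()) for s in seqs])
    keep = ~np.any((arr == "-") | (arr == "N"), axis=0)
    if keep.sum() < min_len:
        return None
    cleaned = arr[:, keep]
    return {
        name: "".join(row) for name, row in zip(alignment.keys(), cleaned)
    }


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986)
# ---------------------------------------------------------------------------


def _syn_fraction(codon: str) -> float:
    """Number of potential synonymous sites in a codon (0..3)."""
    if codon in _STOPS:
        return 0.0
    total = 0.0
    aa0 = _aa(codon)
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in _STOPS and _aa(alt) == aa0:
                syn += 1
        total += syn / 3
    return total


_SYN_SITES = {
    "".join(c): _syn_fraction("".join(c)) for c in itertools.product(_BASES, repeat=3)
}


def _pathways(c1: str, c2: str):
    """Average synonymous/nonsynonymous step counts over all mutational
    orders between two codons, excluding pathways through stop codons
    (unless every pathway is blocked, in which case all are used)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:
        usable = [steps for _, steps in paths]
    sd = nd = 0.0
    for steps in usable:
        for cur, nxt in steps:
            if _aa(cur) == _aa(nxt) and cur not in _STOPS and nxt not in _STOPS:
                sd += 1
            else:
                nd += 1
    return sd / len(usable), nd / len(usable)


def _jc_correct(p: float) -> float:
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75 - 1e-9:
        return float("nan")  # saturated
    return -0.75 * math.log(1 - 4 * p / 3) if p > 0 else 0.0


def ng86_pairwise(seq_a: str, seq_b: str, on_stop: str = "raise") -> tuple[float, float]:
    """Nei–Gojobori dS and dN for two aligned gap-free coding sequences.

    Synonymous/nonsynonymous site counts are averaged over the pair,
    differences are pathway-averaged, and the Jukes–Cantor correction is
    applied. Saturation (p >= 3/4) yields nan. Internal stop codons raise
    (``on_stop="raise"``) or drop the codon column (``on_stop="mask"``).
    """
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    if len(a) % 3:
        raise ValueError("length must be a multiple of 3")
    codons = []
    n_codons = len(a) // 3
    for i in range(n_codons):
        ca, cb = a[3 * i : 3 * i + 3], b[3 * i : 3 * i + 3]
        internal = i < n_codons - 1
        if internal and (ca in _STOPS or cb in _STOPS):
            if on_stop == "raise":
                raise ValueError(f"internal stop codon at codon {i} (position {3 * i})")
            continue
        if ca in _STOPS or cb in _STOPS:  # terminal stop: not counted
            continue
        codons.append((ca, cb))
    if not codons:
        raise ValueError("no usable codons")
    s_sites = sum((_SYN_SITES[ca] + _SYN_SITES[cb]) / 2 for ca, cb in codons)
    n_sites = 3 * len(codons) - s_sites
    sd = nd = 0.0
    for ca, cb in codons:
        s, n = _pathways(ca, cb)
        sd += s
        nd += n
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    return _jc_correct(ps), _jc_correct(pn)


# ---------------------------------------------------------------------------
# Nucleotide distances
# ---------------------------------------------------------------------------


def nucleotide_distance(seq_a: str, seq_b: str, model: str = "GTR") -> float:
    """Pairwise nucleotide distance under JC69, K80 or GTR.

    GTR uses the closed-form log-det style estimator
    ``d = -tr(Pi log(Pi^-1 F))`` with F the symmetrized divergence matrix
    and Pi the average base composition; it is the standard general
    time-reversible pairwise distance. Saturation yields nan.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    pairs = [
        (x, y) for x, y in zip(a, b) if x in _BASES and y in _BASES
    ]
    if not pairs:
        raise ValueError("zero overlap between sequences")
    L = len(pairs)
    if model.upper() == "JC69":
        p = sum(x != y for x, y in pairs) / L
        return _jc_correct(p)
    if model.upper() == "K80":
        ts = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        p = sum((x, y) in ts for x, y in pairs) / L
        q = sum(x != y and (x, y) not in ts for x, y in pairs) / L
        with np.errstate(invalid="ignore"):
            w1 = 1 - 2 * p - q
            w2 = 1 - 2 * q
            if w1 <= 0 or w2 <= 0:
                return float("nan")
            return -0.5 * math.log(w1) - 0.25 * math.log(w2)
    if model.upper() == "GTR":
        idx = {b: i for i, b in enumerate(_BASES)}
        f = np.zeros((4, 4))
        for x, y in pairs:
            f[idx[x], idx[y]] += 1
        f /= L
        fs = (f + f.T) / 2
        pi = fs.sum(axis=1)
        if np.any(pi <= 0):
            return float("nan")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = logm(np.linalg.inv(np.diag(pi)) @ fs)
        if np.iscomplexobj(m):
            if np.max(np.abs(m.imag)) > 1e-8:
                return float("nan")
            m = m.real
        d = -np.trace(np.diag(pi) @ m)
        return float(d) if np.isfinite(d) and d >= -1e-12 else float("nan")
    raise ValueError(f"unknown model {model!r}")


def distance_matrix(
    alignment: dict[str, str], metric="GTR"
) -> pd.DataFrame:
    """Symmetric pairwise distance matrix over an alignment dict.

    ``metric`` is a model name for nucleotide_distance, or the string
    "dS"/"dN" for Nei–Gojobori codon estimates (stop-containing codon
    columns dropped)."""
    taxa = list(alignment)
    mat = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            if metric in ("dS", "dN"):
                ds, dn = ng86_pairwise(alignment[t1], alignment[t2], on_stop="mask")
                d = ds if metric == "dS" else dn
            else:
                d = nucleotide_distance(alignment[t1], alignment[t2], metric)
            mat.loc[t1, t2] = mat.loc[t2, t1] = d
    return mat


# ---------------------------------------------------------------------------
# Branch lengths on a fixed topology
# ---------------------------------------------------------------------------


def fit_branch_lengths(
    tree: dendropy.Tree, dist: pd.DataFrame
) -> tuple[dendropy.Tree, float]:
    """Non-negative least-squares branch lengths for a fixed topology.

    Solves the path-length equations ``sum of edges on path(i,j) = d_ij``
    with scipy's NNLS (negative solutions are clipped to zero by
    construction). Returns a tree clone carrying the fitted lengths and the
    residual norm. Distances must be finite and complete.
    """
    taxa = list(dist.index)
    if len(taxa) < 3:
        raise ValueError("need at least 3 tips")
    if not np.isfinite(dist.values).all():
        raise ValueError("distance matrix contains non-finite entries")
    fitted = tree.clone(depth=1)
    edges = [e for e in fitted.preorder_edge_iter() if e.head_node is not fitted.seed_node]
    eindex = {id(e): i for i, e in enumerate(edges)}

    # path edges between tips via root paths
    leaf = {l.taxon.label: l for l in fitted.leaf_node_iter()}
    missing = set(taxa) - set(leaf)
    if missing:
        raise ValueError(f"taxa absent from tree: {sorted(missing)}")

    def root_path(node):
        path = []
        while node.parent_node is not None:
            path.append(id(node.edge))
            node = node.parent_node
        return path

    paths = {t: root_path(leaf[t]) for t in taxa}
    rows, targets = [], []
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            p1, p2 = set(paths[t1]), set(paths[t2])
            sym = p1 ^ p2
            row = np.zeros(len(edges))
            for eid in sym:
                row[eindex[eid]] = 1.0
            rows.append(row)
            targets.append(dist.loc[t1, t2])
    a = np.array(rows)
    dvec = np.array(targets)
    x, residual = nnls(a, dvec)
    for e in edges:
        e.length = float(x[eindex[id(e)]])
    return fitted, float(residual)


def root_to_tip(tree: dendropy.Tree, clades: dict[str, str] | None = None):
    """Per-tip cumulative branch length from the root; optionally per-clade
    means (``clades`` maps taxon -> clade label)."""
    if not tree.is_rooted:
        raise ValueError("tree must be rooted")
    vals = {}
    for leaf in tree.leaf_node_iter():
        total = 0.0
        node = leaf
        while node.parent_node is not None:
            total += node.edge.length or 0.0
            node = node.parent_node
        vals[leaf.taxon.label] = total
    tips = pd.Series(vals).sort_index()
    if clades is None:
        return tips
    means = tips.groupby(tips.index.map(clades.get)).mean()
    return tips, means


@dataclass(frozen=True)
class TranslocationRatio:
    gene_set: str
    clade: str
    ratio: float
    set_length: float
    csc_length: float


def translocation_ratio(
    rtt_set: pd.Series,
    rtt_csc: pd.Series,
    clade: str,
    members: list[str],
    gene_set_id: str = "set",
) -> TranslocationRatio:
    """Clade-mean root-to-tip length of a gene set relative to the CSC
    concatenation."""
    num = float(rtt_set[members].mean())
    den = float(rtt_csc[members].mean())
    if den <= 0:
        raise ValueError(f"CSC clade length is zero for clade {clade}")
    return TranslocationRatio(gene_set_id, clade, num / den, num, den)


def rate_length_pipeline(
    alignment: dict[str, str],
    tree: dendropy.Tree,
    metric: str = "GTR",
    min_len: int = MIN_LOCUS_LEN,
) -> pd.Series:
    """Alignment -> gap exclusion -> distances -> NNLS branch fit ->
    root-to-tip series. Returns None when the cleaned alignment is too
    short."""
    cleaned = prepare_alignment(alignment, min_len=min_len)
    if cleaned is None:
        return None
    dist = distance_matrix(cleaned, metric)
    fitted, _ = fit_branch_lengths(tree, dist)
    return root_to_tip(fitted)
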