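"""Readers and writers for the formats the pipeline consumes.

The coordinate contract is fixed here once: everything internal is 0-based
half-open on the forward strand of the published (linearized) origin. GFF3
input/output converts between 1-based inclusive and internal coordinates at
the boundary. Feature intervals that span the origin of a circular molecule
are stored as a single interval whose ``end`` exceeds the genome length and
are split into two parts on serialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO

from ._seq import VALID_ALPHABET, circular_slice, revcomp, wrap_interval

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "IGS", "repeat", "region")

#: GFF3 column-3 terms mapped onto the internal feature kinds.
_GFF_TYPE_MAP = {
    "cds": "CDS",
    "trna": "tRNA",
    "rrna": "rRNA",
    "gene": "CDS",
    "intergenic_region": "IGS",
    "repeat_region": "repeat",
    "region": "region",
}


@dataclass(frozen=True)
class Feature:
    """A typed annotation on a plastome.

    ``start``/``end`` are 0-based half-open; ``end`` may exceed the genome
    length when ``wraps_origin`` is true on a circular molecule.
    """

    name: str
    kind: str
    start: int
    end: int
    strand: str = "+"
    wraps_origin: bool = False

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"feature {self.name!r}: bad interval [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def extract(self, sequence: str) -> str:
        """Feature sequence on its own strand (handles origin wrap)."""
        seq = circular_slice(sequence, self.start, len(self))
        return seq if self.strand == "+" else revcomp(seq)


@dataclass
class PlastomeRecord:
    """One annotated plastome: circular DNA plus typed features."""

    taxon_id: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(f"invalid bases in sequence: {sorted(bad)}")
        self.validate()

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        n = len(self.sequence)
        seen: dict[tuple[str, str], list[Feature]] = {}
        for f in self.features:
            limit = 2 * n if (self.circular and f.wraps_origin) else n
            if f.end > limit or (f.wraps_origin and not self.circular):
                raise ValueError(
                    f"feature {f.name!r} interval [{f.start}, {f.end}) outside "
                    f"genome of length {n}"
                )
            seen.setdefault((f.name, f.kind), []).append(f)
        # IR-duplicated loci legitimately occur twice; more copies of the same
        # (name, kind), or two copies on identical intervals, indicate a
        # corrupt feature table.
        for (name, kind), copies in seen.items():
            if kind == "region":
                if len(copies) > 1:
                    raise ValueError(f"duplicate region annotation {name!r}")
                continue
            if len(copies) > 2:
                raise ValueError(f"feature {name!r} ({kind}) annotated {len(copies)} times")
            if len(copies) == 2 and (copies[0].start, copies[0].end) == (
                copies[1].start,
                copies[1].end,
            ):
                raise ValueError(f"duplicate feature {name!r} ({kind}) on one interval")

    # -- convenience ------------------------------------------------------

    def features_of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    def genes(self) -> list[Feature]:
        """Gene-like features (CDS, tRNA, rRNA) sorted by start."""
        return sorted(
            (f for f in self.features if f.kind in ("CDS", "tRNA", "rRNA")),
            key=lambda f: (f.start, f.end, f.name),
        )

    def region(self, name: str) -> Feature | None:
        for f in self.features:
            if f.kind == "region" and f.name == name:
                return f
        return None

    def doubled(self) -> str:
        return self.sequence + self.sequence


# ---------------------------------------------------------------------------
# FASTA + feature-table reading
# ---------------------------------------------------------------------------


def read_plastome(fasta_path, features_path=None, *, circular: bool = True) -> PlastomeRecord:
    """Read a single-record FASTA and an optional GFF3/TSV feature table.

    The feature table may be GFF3 (1-based inclusive, 9 columns) or a
    4/5-column TSV ``name  start  end  strand  [kind]`` already in GFF-style
    1-based inclusive coordinates.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{fasta_path}: expected exactly one FASTA record, got {len(records)}")
    rec = records[0]
    features: list[Feature] = []
    if features_path is not None:
        features = _read_features(features_path, genome_len=len(rec.seq))
    return PlastomeRecord(
        taxon_id=rec.id,
        sequence=str(rec.seq).upper(),
        circular=circular,
        features=features,
    )


def _read_features(path, genome_len: int) -> list[Feature]:
    text = Path(path).read_text()
    rows: list[tuple[str, int, int, str, str]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) >= 8 and cols[6] in "+-.":  # GFF3
            kind = _GFF_TYPE_MAP.get(cols[2].lower(), None)
            if kind is None:
                continue
            name = _gff_attr_name(cols[8]) if len(cols) > 8 else cols[2]
            rows.append((name, int(cols[3]), int(cols[4]), cols[6], kind))
        else:  # simple TSV: name start end strand [kind]
            if len(cols) < 4:
                raise ValueError(f"unparseable feature line: {line!r}")
            kind = cols[4] if len(cols) > 4 else "CDS"
            rows.append((cols[0], int(cols[1]), int(cols[2]), cols[3], kind))
    features = []
    merged = _merge_wrapped_parts(rows, genome_len)
    for name, start1, end1, strand, kind, wraps in merged:
        start0 = start1 - 1  # 1-based inclusive -> 0-based half-open
        if not (0 <= start0 < end1 <= (2 * genome_len if wraps else genome_len)):
            raise ValueError(
                f"feature {name!r}: interval [{start1}, {end1}] outside genome "
                f"of length {genome_len}"
            )
        strand = "+" if strand == "." else strand
        features.append(Feature(name, kind, start0, end1, strand, wraps))
    return features


def _gff_attr_name(attrs: str) -> str:
    fields = dict(
        kv.split("=", 1) for kv in attrs.strip().strip(";").split(";") if "=" in kv
    )
    return fields.get("Name") or fields.get("ID") or fields.get("gene") or "unnamed"


def _merge_wrapped_parts(rows, genome_len):
    """Re-join two serialized parts of an origin-spanning feature.

    A wrapped feature is serialized as two rows with the same name/kind, one
    ending at the genome end and one starting at position 1.
    """
    out = []
    by_key: dict[tuple, list] = {}
    for name, s, e, strand, kind in rows:
        by_key.setdefault((name, kind, strand), []).append((s, e))
    for (name, kind, strand), parts in by_key.items():
        tail = [p for p in parts if p[1] == genome_len]
        head = [p for p in parts if p[0] == 1]
        if len(parts) == 2 and len(tail) == 1 and len(head) == 1 and tail != head:
            out.append((name, tail[0][0], genome_len + head[0][1], strand, kind, True))
        else:
            for s, e in parts:
                out.append((name, s, e, strand, kind, False))
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_plastome(record: PlastomeRecord, fasta_path, features_path=None) -> None:
    """Write FASTA (wrapped at 70 columns) and a GFF3 feature table."""
    with open(fasta_path, "w") as fh:
        fh.write(f">{record.taxon_id}\n")
        for i in range(0, len(record.sequence), 70):
            fh.write(record.sequence[i : i + 70] + "\n")
    if features_path is None:
        return
    n = len(record)
    lines = ["##gff-version 3", f"##sequence-region {record.taxon_id} 1 {n}"]
    for f in sorted(record.features, key=lambda f: (f.start, f.end, f.kind, f.name)):
        source = "plastevo"
        ftype = {
            "CDS": "CDS",
            "tRNA": "tRNA",
            "rRNA": "rRNA",
            "IGS": "intergenic_region",
            "repeat": "repeat_region",
            "region": "region",
        }[f.kind]
        parts = wrap_interval(f.start, f.end, n) if f.wraps_origin else [(f.start, f.end)]
        for s, e in parts:
            lines.append(
                "\t".join(
                    [
                        record.taxon_id,
                        source,
                        ftype,
                        str(s + 1),
                        str(e),
                        ".",
                        f.strand,
                        ".",
                        f"ID={f.name};Name={f.name}",
                    ]
                )
            )
    Path(features_path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def read_tree(newick_path) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths.

    A trifurcating root is accepted but flagged via the tree annotation
    ``root_trifurcation``. Duplicate tip labels raise.
    """
    src = str(newick_path)
    try:
        if "(" in src and ";" in src and "\n" not in src and not Path(src).exists():
            tree = dendropy.Tree.get(data=src, schema="newick")
        else:
            tree = dendropy.Tree.get(path=src, schema="newick")
    except Exception as exc:
        if "uplicate" in str(exc):
            raise ValueError(f"duplicate tip labels: {exc}") from exc
        raise
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {t for t in labels if labels.count(t) > 1}
    if dupes:
        raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
    tree.is_rooted = True
    nchild = len(tree.seed_node.child_nodes())
    tree.annotations.add_new("root_trifurcation", nchild > 2)
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------


def read_traits(path) -> pd.DataFrame:
    """TSV trait table indexed by taxon_id, one row per tree tip."""
    df = pd.read_csv(path, sep="\t")
    if "taxon_id" not in df.columns:
        raise ValueError("trait table must have a 'taxon_id' column")
    if df["taxon_id"].duplicated().any():
        raise ValueError("duplicate taxon_id rows in trait table")
    return df.set_index("taxon_id")


def write_traits(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out = out[sorted(out.columns)]  # deterministic column order
    out.to_csv(path, sep="\t", index_label="taxon_id")
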