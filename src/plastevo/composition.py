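"""Base composition and codon usage: GC by codon position, RSCU, and GC
change upon translocation into the IR.

Conventions: ambiguous bases are excluded from every GC denominator; stop
codons are excluded from RSCU families; RSCU for a family with zero usage
is undefined and reported as missing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from ._seq import gc_fraction
from .rates import _BASES, _STOPS, _aa


def gc_by_position(cds_set: dict[str, str]) -> dict[str, float]:
    """GC fraction at codon positions 1, 2, 3 and overall, over a set of
    coding sequences. Results do not depend on input order."""
    if not cds_set:
        raise ValueError("empty CDS set")
    pos_seqs = {1: [], 2: [], 3: []}
    for name in sorted(cds_set):
        seq = cds_set[name].upper()
        if len(seq) % 3:
            raise ValueError(f"CDS {name!r} length {len(seq)} is not a multiple of 3")
        for p in (1, 2, 3):
            pos_seqs[p].append(seq[p - 1 :: 3])
    out = {f"gc{p}": gc_fraction("".join(pos_seqs[p])) for p in (1, 2, 3)}
    out["gc_overall"] = gc_fraction("".join(cds_set[n].upper() for n in sorted(cds_set)))
    return out


@dataclass
class CodonUsageTable:
    """Per-codon counts and relative synonymous codon usage.

    For each amino acid with nonzero usage the RSCU values of its codons
    average to 1 (their sum equals the family size)."""

    table: pd.DataFrame  # columns: codon, amino_acid, count, rscu

    def family(self, amino_acid: str) -> pd.DataFrame:
        return self.table[self.table.amino_acid == amino_acid]


def rscu(cds_set: dict[str, str]) -> CodonUsageTable:
    """RSCU(codon) = observed count / mean count over its synonymous family.

    Stop codons are excluded. Families with zero total usage get missing
    RSCU values."""
    counts = {
        "".join(c): 0 for c in itertools.product(_BASES, repeat=3)
        if "".join(c) not in _STOPS
    }
    for name in sorted(cds_set):
        seq = cds_set[name].upper()
        if len(seq) % 3:
            raise ValueError(f"CDS {name!r} length is not a multiple of 3")
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if codon in counts:
                counts[codon] += 1
    rows = []
    by_aa: dict[str, list[str]] = {}
    for codon in counts:
        by_aa.setdefault(_aa(codon), []).append(codon)
    for aa, codons in sorted(by_aa.items()):
        total = sum(counts[c] for c in codons)
        mean = total / len(codons)
        for codon in sorted(codons):
            rows.append(
                {
                    "codon": codon,
                    "amino_acid": aa,
                    "count": counts[codon],
                    "rscu": counts[codon] / mean if total > 0 else float("nan"),
                }
            )
    return CodonUsageTable(pd.DataFrame(rows))


@dataclass(frozen=True)
class GcDelta:
    locus: str
    delta: float  # GC(in-IR clade) - GC(in-SC clade)
    direction: str  # increase | decrease | unchanged
    gc_ir: float
    gc_sc: float


def translocation_gc_delta(
    locus: str,
    seqs_by_clade: dict[str, str],
    region_by_clade: dict[str, str],
    clade_pair: tuple[str, str],
) -> GcDelta:
    """GC change of a locus between a clade where it sits in the IR and one
    where it remains single-copy. Sign convention: positive means GC rose
    upon translocation into the IR."""
    for clade in clade_pair:
        if clade not in seqs_by_clade:
            raise ValueError(f"locus {locus!r} absent from clade {clade!r}")
    ir_clades = [c for c in clade_pair if region_by_clade.get(c) == "IR"]
    sc_clades = [c for c in clade_pair if region_by_clade.get(c) == "SC"]
    if not ir_clades or not sc_clades:
        raise ValueError(
            f"clade pair {clade_pair} must contain one IR clade and one SC clade"
        )
    gc_ir = gc_fraction(seqs_by_clade[ir_clades[0]].upper())
    gc_sc = gc_fraction(seqs_by_clade[sc_clades[0]].upper())
    delta = gc_ir - gc_sc
    direction = "increase" if delta > 0 else ("decrease" if delta < 0 else "unchanged")
    return GcDelta(locus, delta, direction, gc_ir, gc_sc)
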