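"""Locus classification, alignment cleaning, NG86 and nucleotide distances
(against independent oracles), branch-length fitting, and rate ratios."""

import itertools
import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from plastevo import simulate as sim
from plastevo.rates import (
    classify_loci,
    distance_matrix,
    fit_branch_lengths,
    ir_overlap_from_genomes,
    ng86_pairwise,
    nucleotide_distance,
    prepare_alignment,
    rate_length_pipeline,
    root_to_tip,
    translocation_ratio,
)
from plastevo.structure import RegionPartition


class TestClassifyLoci:
    LEN = {"ndhB": 1002, "ycf1": 903, "rps19": 279, "tiny": 120, "rbcL": 1428}

    def test_three_way_classification(self):
        overlap = {
            "ndhB": {"A": 1002, "B": 1002, "C": 1002},
            "ycf1": {"A": 0, "B": 903, "C": 903},
            "rbcL": {"A": 0, "B": 0, "C": 0},
        }
        classes = {c.locus: c.region_class for c in classify_loci(overlap, self.LEN)}
        assert classes == {"ndhB": "CIR", "ycf1": "VSR", "rbcL": "CSC"}

    def test_forty_nt_junction_rule(self):
        overlap = {"rps19": {"A": 35, "B": 39, "C": 0}}
        (res,) = classify_loci(overlap, self.LEN)
        assert res.region_class == "CSC"  # < 40 nt in IR counts as single-copy
        overlap = {"rps19": {"A": 45, "B": 45, "C": 45}}
        (res,) = classify_loci(overlap, self.LEN)
        assert res.region_class == "CIR"

    def test_short_locus_excluded(self):
        (res,) = classify_loci({"tiny": {"A": 0}}, self.LEN)
        assert not res.included and "150" in res.note

    def test_missing_taxon_flagged(self):
        (res,) = classify_loci(
            {"rbcL": {"A": 0, "B": 0}}, self.LEN, taxa=["A", "B", "C"]
        )
        assert not res.included and "missing" in res.note

    def test_derived_from_annotated_genomes(self, type_I, type_III):
        records = {"A": type_I, "C": type_III}
        parts = {k: RegionPartition.from_features(v) for k, v in records.items()}
        overlap, lengths = ir_overlap_from_genomes(records, parts)
        classes = {c.locus: c.region_class for c in classify_loci(overlap, lengths)}
        assert classes["ndhB"] == "CIR"
        assert classes["rbcL"] == "CSC"
        assert classes["ndhD"] == "VSR"  # translocated by the type III expansion
        assert classes["ycf1"] == "VSR"


class TestPrepareAlignment:
    def test_gapped_columns_removed_then_dropped_below_min(self):
        row = "A" * 140 + "-" * 60
        aln = {"t1": row, "t2": "A" * 200}
        assert prepare_alignment(aln, min_len=150) is None
        kept = prepare_alignment(aln, min_len=100)
        assert len(kept["t1"]) == 140

    def test_gap_free_unchanged(self):
        aln = {"t1": "ACGT" * 50, "t2": "TGCA" * 50}
        assert prepare_alignment(aln) == aln

    def test_ragged_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            prepare_alignment({"t1": "ACGT", "t2": "ACG"})

    def test_row_order_irrelevant(self):
        aln = {"t1": "AC-T" * 60, "t2": "ACGT" * 60}
        fwd = prepare_alignment(aln, min_len=10)
        rev = prepare_alignment(dict(reversed(list(aln.items()))), min_len=10)
        assert fwd["t1"] == rev["t1"]


# ---------------------------------------------------------------------------
# NG86 with an independent enumeration oracle
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def _translate(codon):
    from Bio.Seq import Seq

    return "*" if codon in _STOPS else str(Seq(codon).translate(table=11))


def oracle_ng86(a, b):
    """Independent NG86: explicit site fractions and pathway enumeration."""
    codons = [(a[i : i + 3], b[i : i + 3]) for i in range(0, len(a), 3)]
    s_sites = 0.0
    sd = nd = 0.0
    for ca, cb in codons:
        for c in (ca, cb):
            syn = 0
            for pos, base in itertools.product(range(3), "ACGT"):
                if base == c[pos]:
                    continue
                alt = c[:pos] + base + c[pos + 1 :]
                if alt not in _STOPS and _translate(alt) == _translate(c):
                    syn += 1
            s_sites += syn / 6  # /3 per site, averaged over the two codons
        diffs = [i for i in range(3) if ca[i] != cb[i]]
        paths = []
        for order in itertools.permutations(diffs):
            cur, steps, ok = ca, [], True
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if nxt in _STOPS:
                    ok = False
                steps.append((cur, nxt))
                cur = nxt
            paths.append((ok, steps))
        usable = [st for ok, st in paths if ok] or [st for _, st in paths]
        psd = pnd = 0.0
        for steps in usable:
            for cur, nxt in steps:
                if (
                    cur not in _STOPS
                    and nxt not in _STOPS
                    and _translate(cur) == _translate(nxt)
                ):
                    psd += 1
                else:
                    pnd += 1
        sd += psd / len(usable)
        nd += pnd / len(usable)
    n_sites = 3 * len(codons) - s_sites
    corr = lambda p: float("nan") if p >= 0.75 - 1e-9 else (
        -0.75 * math.log(1 - 4 * p / 3) if p > 0 else 0.0
    )
    return corr(sd / s_sites), corr(nd / n_sites)


def _random_coding(rng, n_codons):
    while True:
        s = "".join(rng.choice(list("ACGT"), 3 * n_codons))
        if all(s[i : i + 3] not in _STOPS for i in range(0, len(s), 3)):
            return s


class TestNG86:
    def test_identical_sequences_zero(self):
        assert ng86_pairwise("ATGGCTAAA", "ATGGCTAAA") == (0.0, 0.0)

    def test_synonymous_only_difference(self):
        # Phe TTT->TTC in a context long enough to stay unsaturated
        pad = "GCTGCAGCGGCCAAAGAT"
        ds, dn = ng86_pairwise("TTT" + pad, "TTC" + pad)
        assert dn == 0.0 and ds > 0

    def test_single_codon_synonymous_saturates(self):
        ds, dn = ng86_pairwise("TTT", "TTC")
        assert math.isnan(ds) and dn == 0.0

    def test_internal_stop_names_position(self):
        with pytest.raises(ValueError, match="codon 1"):
            ng86_pairwise("ATGTAAAAA", "ATGTACAAA")

    def test_matches_enumeration_oracle_on_small_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(150):
            n = int(rng.integers(1, 5))
            a, b = _random_coding(rng, n), _random_coding(rng, n)
            ds, dn = ng86_pairwise(a, b)
            ods, odn = oracle_ng86(a, b)
            for got, want in ((ds, ods), (dn, odn)):
                assert (math.isnan(got) and math.isnan(want)) or got == pytest.approx(
                    want, abs=1e-12
                )

    def test_matches_biopython_when_no_stop_pathways(self):
        from Bio.Data.CodonTable import unambiguous_dna_by_id
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        rng = np.random.default_rng(6)
        table = unambiguous_dna_by_id[11]
        checked = 0
        for _ in range(600):
            a, b = _random_coding(rng, 6), _random_coding(rng, 6)
            if _any_stop_pathway(a, b):
                continue
            dn_ref, ds_ref = cal_dn_ds(
                CodonSeq(a), CodonSeq(b), method="NG86", codon_table=table
            )
            ds, dn = ng86_pairwise(a, b)
            if not (0 <= ds_ref < 5 and 0 <= dn_ref < 5):
                continue  # saturation sentinel / numerically meaningless edge
            assert ds == pytest.approx(ds_ref, abs=1e-6)
            assert dn == pytest.approx(dn_ref, abs=1e-6)
            checked += 1
        assert checked >= 50

    def test_ds_increases_with_divergence_on_simulated_codons(self):
        tree = dendropy.Tree.get(data="(A:0.05,B:0.05);", schema="newick")
        tree.is_rooted = True
        seqs = sim.simulate_sequences(3000, tree, 1.0, seed=3)
        ds, dn = ng86_pairwise(seqs["A"], seqs["B"], on_stop="mask")
        assert 0 < ds < 1 and 0 < dn < 1


def _any_stop_pathway(a, b):
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        diffs = [p for p in range(3) if ca[p] != cb[p]]
        for order in itertools.permutations(diffs):
            cur = ca
            for pos in order:
                cur = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if cur in _STOPS:
                    return True
    return False


class TestNucleotideDistance:
    def test_identical_zero_all_models(self):
        s = "ACGT" * 200
        for model in ("JC69", "K80", "GTR"):
            assert nucleotide_distance(s, s, model) == 0.0

    def test_jc69_closed_form(self):
        a = "A" * 90 + "C" * 10
        b = "A" * 90 + "G" * 10
        expect = -(3 / 4) * math.log(1 - (4 / 3) * 0.1)
        assert nucleotide_distance(a, b, "JC69") == pytest.approx(expect)

    def test_gtr_recovers_simulated_length(self):
        tree = dendropy.Tree.get(data="(A:0.1,B:0.1);", schema="newick")
        tree.is_rooted = True
        ds = []
        for seed in range(5):
            seqs = sim.simulate_sequences(10000, tree, 1.0, seed=seed)
            ds.append(nucleotide_distance(seqs["A"], seqs["B"], "GTR"))
        assert np.mean(ds) == pytest.approx(0.2, rel=0.10)

    def test_zero_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            nucleotide_distance("NNN", "NNN")


class TestBranchLengths:
    def _tree(self, newick):
        t = dendropy.Tree.get(data=newick, schema="newick")
        t.is_rooted = True
        return t

    def test_additive_matrix_recovered_exactly(self):
        tree = self._tree("((A:1,B:2):0.5,(C:1.5,D:1):0.5);")
        d = pd.DataFrame(
            [
                [0.0, 3.0, 3.5, 3.0],
                [3.0, 0.0, 4.5, 4.0],
                [3.5, 4.5, 0.0, 2.5],
                [3.0, 4.0, 2.5, 0.0],
            ],
            index=list("ABCD"), columns=list("ABCD"),
        )
        fitted, resid = fit_branch_lengths(tree, d)
        assert resid == pytest.approx(0.0, abs=1e-9)
        rtt = root_to_tip(fitted)
        assert rtt["A"] == pytest.approx(2.0) and rtt["B"] == pytest.approx(3.0)

    def test_three_point_closed_form_on_star(self):
        tree = self._tree("(A:0,B:0,C:0);")
        dab, dac, dbc = 1.0, 1.4, 1.2
        d = pd.DataFrame(
            [[0, dab, dac], [dab, 0, dbc], [dac, dbc, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        fitted, _ = fit_branch_lengths(tree, d)
        rtt = root_to_tip(fitted)
        assert rtt["A"] == pytest.approx((dab + dac - dbc) / 2)
        assert rtt["B"] == pytest.approx((dab + dbc - dac) / 2)
        assert rtt["C"] == pytest.approx((dac + dbc - dab) / 2)

    def test_too_few_tips_rejected(self):
        tree = self._tree("(A:1,B:1);")
        d = pd.DataFrame([[0, 2], [2, 0]], index=list("AB"), columns=list("AB"))
        with pytest.raises(ValueError, match="3 tips"):
            fit_branch_lengths(tree, d)

    def test_root_to_tip_examples(self):
        tree = self._tree("((A:1,B:1):1,C:2);")
        rtt = root_to_tip(tree)
        assert rtt.tolist() == [2.0, 2.0, 2.0]
        tips, means = root_to_tip(tree, clades={"A": "x", "B": "x", "C": "y"})
        assert means["x"] == 2.0 and means["y"] == 2.0


class TestTranslocationRatio:
    def test_identical_sets_ratio_one(self):
        rtt = pd.Series({"A1": 0.3, "A2": 0.4})
        r = translocation_ratio(rtt, rtt, "A", ["A1", "A2"])
        assert r.ratio == 1.0

    def test_zero_csc_length_rejected(self):
        rtt = pd.Series({"A1": 0.3})
        zero = pd.Series({"A1": 0.0})
        with pytest.raises(ValueError, match="zero"):
            translocation_ratio(rtt, zero, "A", ["A1"])

    def test_recovers_simulated_rate_contrast(self, clade_tree):
        taxa = [l.taxon.label for l in clade_tree.leaf_node_iter()]
        members = [t for t in taxa if t.startswith("B")]
        csc = sim.simulate_sequences(8000, clade_tree, 1.0, seed=301)
        slow = sim.simulate_sequences(8000, clade_tree, 0.25, seed=302)
        same = sim.simulate_sequences(8000, clade_tree, 1.0, seed=303)
        rtt_csc = rate_length_pipeline(csc, clade_tree)
        r_slow = translocation_ratio(
            rate_length_pipeline(slow, clade_tree), rtt_csc, "B", members
        )
        r_same = translocation_ratio(
            rate_length_pipeline(same, clade_tree), rtt_csc, "B", members
        )
        assert 0.25 * 0.8 < r_slow.ratio < 0.25 * 1.3
        assert 0.8 < r_same.ratio < 1.25


class TestDistanceMatrix:
    def test_symmetric_zero_diagonal(self, clade_tree):
        seqs = sim.simulate_sequences(2000, clade_tree, 1.0, seed=9)
        m = distance_matrix(seqs, "JC69")
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 0.0)
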