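"""Read mapping, full-length filtering, isomer classification, and
junction frequency reporting."""

import numpy as np
import pytest

from plastevo import simulate as sim
from plastevo._seq import revcomp
from plastevo.mapping import ReadAlignment, ReferenceIndex, Segment, map_read
from plastevo.recombination import (
    build_repeat_catalog,
    classify_read,
    filter_full_length,
    junction_frequency,
    read_alignments_tsv,
    recombination_report,
    write_alignments_tsv,
)
from plastevo.structure import RegionPartition


class TestJunctionFrequency:
    @pytest.mark.parametrize(
        "s,n,expected",
        [
            (2, 1538, 0.13),
            (2, 1342, 0.15),
            (3, 1879, 0.16),
            (3, 1202, 0.25),
            (2, 1818, 0.11),
            (5, 1724, 0.29),
            (0, 1000, 0.00),
        ],
    )
    def test_half_up_two_decimals(self, s, n, expected):
        assert junction_frequency(s, n) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            junction_frequency(0, 0)

    def test_support_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            junction_frequency(3, 2)


class TestFilterFullLength:
    def _aln(self, fraction):
        seg = Segment(0, int(1000 * fraction), 0, int(1000 * fraction), "+", 1.0)
        return ReadAlignment("r", 1000, (seg,), fraction)

    def test_fully_aligned_kept(self):
        assert filter_full_length([self._aln(1.0)])

    def test_sixty_percent_dropped(self):
        assert filter_full_length([self._aln(0.60)]) == []

    def test_split_read_fractions_sum(self):
        segs = (
            Segment(0, 500, 0, 500, "+", 1.0),
            Segment(510, 1000, 2000, 2490, "+", 1.0),
        )
        aln = ReadAlignment("r", 1000, segs, 0.99)
        assert filter_full_length([aln])


@pytest.fixture(scope="module")
def index(type_II):
    return ReferenceIndex(type_II.sequence)


@pytest.fixture(scope="module")
def setup(type_II, part_II, index):
    catalog = build_repeat_catalog(type_II, part_II)
    return type_II, part_II, catalog, index


class TestMapper:
    def test_forward_substring_single_segment(self, type_II, index):
        read = type_II.sequence[5000:13000]
        aln = map_read("r1", read, index)
        assert len(aln.segments) == 1
        seg = aln.segments[0]
        assert seg.strand == "+"
        assert (seg.ref_start, seg.ref_end) == (5000, 13000)
        assert aln.aligned_fraction == 1.0

    def test_reverse_strand_read(self, type_II, index):
        read = revcomp(type_II.sequence[5000:12000])
        aln = map_read("r2", read, index)
        (seg,) = aln.segments
        assert seg.strand == "-"
        assert (seg.ref_start % index.n, seg.ref_end % index.n or index.n) in {
            (5000, 12000)
        }

    def test_origin_spanning_read_stays_contiguous(self, type_II, index):
        n = index.n
        read = type_II.sequence[n - 3000 :] + type_II.sequence[:3000]
        aln = map_read("r3", read, index)
        assert len(aln.segments) == 1
        assert aln.aligned_fraction == 1.0

    def test_one_percent_errors_still_near_full_length(self, type_II, index):
        rng = np.random.default_rng(0)
        read = list(type_II.sequence[2000:12000])
        for p in rng.choice(len(read), size=100, replace=False):
            read[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[p]]
        aln = map_read("r4", "".join(read), index)
        assert aln.aligned_fraction >= 0.98


class TestClassification:
    def test_collinear_read_concordant(self, setup):
        g, part, catalog, index = setup
        aln = map_read("c", g.sequence[1000:15000], index)
        assert classify_read(aln, part, catalog).label == "concordant"

    def test_flip_read_is_flipflop_never_recombinant(self, setup):
        g, part, catalog, index = setup
        flip = sim.flip_isomer(g)
        # a witness read must span a whole IR copy plus both flanking
        # single-copy anchors to expose the SSC orientation
        l1, l2 = part.ira
        read = flip[l1 - 2000 : l2 + 2000]
        aln = map_read("f", read, index)
        assert classify_read(aln, part, catalog).label == "flipflop"

    def test_short_flip_read_is_legitimately_concordant(self, setup):
        # inside-IR windows of the flipped isomer are exact substrings of the
        # main isomer: no signal, so they must not be called flipflop
        g, part, catalog, index = setup
        flip = sim.flip_isomer(g)
        j = part.ssc[0]
        read = flip[j - 6000 : j + 3000]
        aln = map_read("s", read, index)
        assert classify_read(aln, part, catalog).label == "concordant"

    def test_recombinant_read_assigned_to_injected_junction(self, setup):
        g, part, catalog, index = setup
        iso, j1, j2 = sim.recombinant_isomer(g, "R1")
        read = iso[j1 - 2500 : j1 + 2500]
        aln = map_read("x", read, index)
        got = classify_read(aln, part, catalog)
        assert got.label == "recombinant"
        pair = catalog[got.junction_id]
        assert pair.length == 303

    def test_flip_reads_never_recombinant_across_seeds(self, type_II, part_II):
        catalog = build_repeat_catalog(type_II, part_II)
        index = ReferenceIndex(type_II.sequence)
        for seed in range(10):
            reads, truth = sim.simulate_long_reads(
                type_II, sim.IsomerSpec(flip_weight=1.0),
                sim.ReadSpec(n_reads=12, mean_length=9000), seed=seed,
            )
            for r in reads:
                aln = map_read(r.read_id, r.sequence, index)
                assert classify_read(aln, part_II, catalog).label != "recombinant"


class TestEndToEnd:
    def test_exact_counts_recovered(self, type_II):
        iso = sim.IsomerSpec(recombinants=(sim.RecombinantSpec("JR", "R1"),))
        spec = sim.ReadSpec(exact_counts={"total": 80, "junctions": {"JR": 3}})
        reads, truth = sim.simulate_long_reads(type_II, iso, spec, seed=21)
        report, classes = recombination_report(reads, type_II)
        assert len(report) == 1
        assert report.supporting_reads[0] == 3
        assert report.total_reads[0] == 80
        assert report.frequency_percent[0] == junction_frequency(3, 80)

    def test_error_free_classification_matches_truth(self, type_II):
        iso = sim.IsomerSpec(
            flip_weight=0.5,
            recombinants=(sim.RecombinantSpec("JR", "R1", weight=0.05),),
        )
        spec = sim.ReadSpec(n_reads=120, mean_length=14000, error_rate=0.0)
        reads, truth = sim.simulate_long_reads(type_II, iso, spec, seed=31)
        _, classes = recombination_report(reads, type_II)
        merged = classes.merge(truth, on="read_id")
        strict = merged[merged.expected_class != "any"]
        assert (strict.label == strict.expected_class).all()

    def test_one_percent_error_rate_rarely_misclassifies(self, type_II):
        iso = sim.IsomerSpec(flip_weight=0.5)
        spec = sim.ReadSpec(n_reads=120, mean_length=14000, error_rate=0.01)
        reads, truth = sim.simulate_long_reads(type_II, iso, spec, seed=41)
        _, classes = recombination_report(reads, type_II)
        merged = classes.merge(truth, on="read_id")
        strict = merged[merged.expected_class != "any"]
        # ambiguous is allowed at 1% error, misclassification is not
        wrong = strict[
            (strict.label != strict.expected_class) & (strict.label != "ambiguous")
        ]
        assert len(wrong) / max(len(strict), 1) <= 0.01
        assert (strict.label == strict.expected_class).mean() >= 0.95

    def test_no_recombinants_simulated_empty_report(self, type_II):
        reads, _ = sim.simulate_long_reads(
            type_II, sim.IsomerSpec(), sim.ReadSpec(n_reads=40), seed=51
        )
        report, _ = recombination_report(reads, type_II)
        assert report.empty

    def test_report_invariant_to_read_order(self, type_II):
        iso = sim.IsomerSpec(recombinants=(sim.RecombinantSpec("JR", "R1"),))
        spec = sim.ReadSpec(exact_counts={"total": 40, "junctions": {"JR": 2}})
        reads, _ = sim.simulate_long_reads(type_II, iso, spec, seed=61)
        fwd, _ = recombination_report(reads, type_II)
        rev, _ = recombination_report(list(reversed(reads)), type_II)
        assert fwd.equals(rev)

    def test_two_junctions_reported_independently(self):
        cfg = sim.SimConfig(
            repeats=(
                sim.RepeatInsert(),
                sim.RepeatInsert(name="R2", length=280, region1="LSC",
                                 offset1=8000, region2="SSC", offset2=1500),
            )
        )
        g = sim.build_type_I_plastome(cfg, seed=71, taxon_id="two_rep")
        iso = sim.IsomerSpec(
            recombinants=(
                sim.RecombinantSpec("JA", "R1"),
                sim.RecombinantSpec("JB", "R2"),
            )
        )
        spec = sim.ReadSpec(
            exact_counts={"total": 70, "junctions": {"JA": 2, "JB": 3}}
        )
        reads, truth = sim.simulate_long_reads(g, iso, spec, seed=72)
        report, _ = recombination_report(reads, g)
        assert len(report) == 2
        assert sorted(report.supporting_reads) == [2, 3]

    def test_external_alignment_tsv_roundtrip(self, type_II, tmp_path):
        iso = sim.IsomerSpec(recombinants=(sim.RecombinantSpec("JR", "R1"),))
        spec = sim.ReadSpec(exact_counts={"total": 30, "junctions": {"JR": 2}})
        reads, _ = sim.simulate_long_reads(type_II, iso, spec, seed=81)
        from plastevo.recombination import align_reads

        aln = align_reads(reads, type_II)
        write_alignments_tsv(aln, tmp_path / "aln.tsv")
        back = read_alignments_tsv(tmp_path / "aln.tsv")
        direct, _ = recombination_report(reads, type_II, alignments=aln)
        loaded, _ = recombination_report(reads, type_II, alignments=back)
        assert direct.supporting_reads.tolist() == loaded.supporting_reads.tolist()
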