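"""Dispersed repeat finder against brute-force oracles, footprint merging,
size bins, and breakpoint association."""

import numpy as np
import pytest

from plastevo import simulate as sim
from plastevo._seq import revcomp
from plastevo.repeats import (
    RepeatPair,
    bin_summary,
    breakpoint_association,
    find_dispersed_repeats,
    merge_footprint,
)
from plastevo.structure import RegionPartition, find_inversions


def _random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), n))


def _plant(seq, core, pos):
    return seq[:pos] + core + seq[pos + len(core) :]


# ---------------------------------------------------------------------------
# brute-force oracles (no seeding): numpy diagonal comparison
# ---------------------------------------------------------------------------


def oracle_maximal_exact_matches(seq, min_len):
    """All maximal exact repeat pairs >= min_len, both orientations, by
    scanning every diagonal of the full self-comparison matrix."""
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    rc = np.frombuffer(revcomp(seq).encode(), dtype=np.uint8)
    out = set()
    for d in range(1, n):  # direct, j = i + d
        eq = arr[: n - d] == arr[d:]
        for s, e in _runs(eq, min_len):
            i1, i2 = (s, e), (s + d, e + d)
            if not (i1[0] < i2[1] and i2[0] < i1[1]):
                out.add((i1, i2, "direct"))
    for c0 in range(-(n - 1), n):  # inverted: seq vs revcomp, any diagonal
        if c0 >= 0:
            a, b = arr[: n - c0], rc[c0:]
            off_a, off_c = 0, c0
        else:
            a, b = arr[-c0:], rc[: n + c0]
            off_a, off_c = -c0, 0
        eq = a == b
        for s, e in _runs(eq, min_len):
            a_s, a_e = off_a + s, off_a + e
            c_s = off_c + s
            b_lo = n - (c_s + (a_e - a_s))
            i1, i2 = (a_s, a_e), (b_lo, b_lo + (a_e - a_s))
            if i1 > i2:
                i1, i2 = i2, i1
            if not (i1[0] < i2[1] and i2[0] < i1[1]):
                out.add((i1, i2, "inverted"))
    return out


def _runs(eq, min_len):
    idx = np.flatnonzero(np.diff(np.concatenate(([0], eq.astype(int), [0]))))
    for s, e in zip(idx[::2], idx[1::2]):
        if e - s >= min_len:
            yield int(s), int(e)


def oracle_any_window(seq, min_len, min_identity):
    """Does any diagonal (either orientation) carry a window of min_len with
    identity >= min_identity?"""
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    rc = np.frombuffer(revcomp(seq).encode(), dtype=np.uint8)
    need = int(np.ceil(min_len * min_identity))
    kernel = np.ones(min_len, dtype=int)
    for d in range(1, n - min_len + 1):
        eq = (arr[: n - d] == arr[d:]).astype(int)
        if len(eq) >= min_len and np.convolve(eq, kernel, "valid").max() >= need:
            return True
    for c0 in range(-(n - min_len), n - min_len + 1):
        if c0 >= 0:
            eq = (arr[: n - c0] == rc[c0:]).astype(int)
        else:
            eq = (arr[-c0:] == rc[: n + c0]).astype(int)
        if len(eq) >= min_len and np.convolve(eq, kernel, "valid").max() >= need:
            return True
    return False


class TestFinder:
    def test_injected_direct_pair_found_exactly(self):
        seq = _random_seq(6000, 1)
        core = _random_seq(300, 99)
        seq = _plant(_plant(seq, core, 500), core, 4000)
        pairs = find_dispersed_repeats(seq, None, min_identity=1.0)
        assert [(p.interval1, p.interval2, p.orientation, p.identity) for p in pairs] == [
            ((500, 800), (4000, 4300), "direct", 1.0)
        ]

    def test_injected_inverted_pair_flagged_inverted(self):
        seq = _random_seq(6000, 2)
        core = _random_seq(250, 98)
        seq = _plant(_plant(seq, core, 700), revcomp(core), 4200)
        pairs = find_dispersed_repeats(seq, None, min_identity=1.0)
        assert len(pairs) == 1
        assert pairs[0].orientation == "inverted"
        assert pairs[0].intervals() == ((700, 950), (4200, 4450))

    def test_matches_exhaustive_oracle_on_5kb_instance(self):
        seq = _random_seq(5000, 3)
        c1, c2 = _random_seq(60, 97), _random_seq(45, 96)
        seq = _plant(seq, c1, 200)
        seq = _plant(seq, c1, 3000)
        seq = _plant(seq, revcomp(c2), 1200)
        seq = _plant(seq, c2, 4300)
        got = {
            (p.interval1, p.interval2, p.orientation)
            for p in find_dispersed_repeats(seq, None, min_identity=1.0)
        }
        expect = oracle_maximal_exact_matches(seq, 30)
        assert got == expect

    def test_repeat_free_sequence_finds_nothing_and_oracle_agrees(self):
        seq = _random_seq(5000, 4)
        assert find_dispersed_repeats(seq, None, min_identity=0.90) == []
        assert not oracle_any_window(seq, 30, 0.90)

    def test_degraded_pair_found_at_relaxed_identity(self):
        seq = _random_seq(6000, 5)
        core = _random_seq(200, 95)
        rng = np.random.default_rng(7)
        noisy = list(core)
        for p in rng.choice(200, 10, replace=False):
            noisy[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[noisy[p]]
        seq = _plant(_plant(seq, core, 500), "".join(noisy), 4000)
        pairs = find_dispersed_repeats(seq, None, min_identity=0.90)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.identity >= 0.94 and abs(p.length - 200) <= 10

    def test_min_len_below_seed_rejected(self):
        with pytest.raises(ValueError, match="seed"):
            find_dispersed_repeats("ACGT" * 100, None, min_len=5)

    def test_masked_ir_copy_not_reported(self, type_I, part_I):
        pairs = find_dispersed_repeats(type_I, part_I)
        # only the injected LSC-IR pair; the IRa/IRb match is masked away
        assert len(pairs) == 1
        assert pairs[0].length == 303

    def test_mask_swap_preserves_bin_totals(self, type_I, part_I):
        pairs_b_masked = find_dispersed_repeats(type_I, part_I)
        swapped = RegionPartition(
            lsc=part_I.lsc, ira=part_I.irb, ssc=part_I.ssc, irb=part_I.ira,
            n=part_I.n, ir_identity=part_I.ir_identity,
        )
        pairs_a_masked = find_dispersed_repeats(type_I, swapped)
        assert list(bin_summary(pairs_b_masked)["count"]) == list(
            bin_summary(pairs_a_masked)["count"]
        )


class TestFootprint:
    def _pair(self, i1, i2, length=None):
        length = length or (i1[1] - i1[0])
        return RepeatPair(i1, i2, "direct", length, 1.0, 2 * length)

    def test_overlapping_intervals_merge(self):
        fp = merge_footprint([self._pair((0, 100), (50, 150))])
        assert fp.merged == ((0, 150),)
        assert fp.cumulative_bp == 150

    def test_disjoint_intervals_sum(self):
        fp = merge_footprint([self._pair((0, 100), (200, 300))])
        assert fp.cumulative_bp == 200

    def test_empty_footprint(self):
        fp = merge_footprint([])
        assert fp.merged == () and fp.cumulative_bp == 0

    def test_idempotent(self):
        pairs = [self._pair((0, 120), (80, 200)), self._pair((500, 700), (650, 850))]
        once = merge_footprint(pairs)
        again = [self._pair(iv, iv) for iv in once.merged]
        # re-merging the merged cover changes nothing
        assert merge_footprint(again).merged == once.merged


class TestBins:
    def _pairs(self, lengths):
        return [
            RepeatPair((i * 2000, i * 2000 + L), ((i + 10) * 2000, (i + 10) * 2000 + L),
                       "direct", L, 1.0, 2 * L)
            for i, L in enumerate(lengths)
        ]

    def test_counts_per_bin(self):
        df = bin_summary(self._pairs([150, 250, 600]))
        assert list(df["count"]) == [1, 1, 1, 0]
        assert df.cumulative_length_bp.sum() == 1000

    def test_empty_input_all_zero(self):
        df = bin_summary([])
        assert df["count"].sum() == 0 and df.cumulative_length_bp.sum() == 0

    def test_large_repeats_exclusive_to_derived_clade(self):
        cfg_b = sim.SimConfig(
            repeats=(
                sim.RepeatInsert(),
                sim.RepeatInsert(name="R2", length=600, region1="LSC",
                                 offset1=5000, region2="SSC", offset2=800),
            )
        )
        clade_a = sim.build_type_I_plastome(seed=8)
        clade_b = sim.build_type_I_plastome(cfg_b, seed=8)
        count_over_500 = lambda g: bin_summary(
            find_dispersed_repeats(g, RegionPartition.from_features(g))
        ).set_index("bin")["count"]["501-1000"]
        assert count_over_500(clade_a) == 0
        assert count_over_500(clade_b) == 1


class TestBreakpointAssociation:
    def test_abutting_repeat_distance_zero(self):
        pair = RepeatPair((100, 200), (500, 600), "direct", 100, 1.0, 200)
        df = breakpoint_association([pair], [(200, 250)])
        assert df.nearest_repeat_bp[0] == 0

    def test_no_repeats_infinite_sentinel(self):
        df = breakpoint_association([], [(0, 10)])
        assert np.isinf(df.nearest_repeat_bp[0])

    def test_inversion_breakpoint_near_injected_repeat(self, type_I, type_III):
        (block,) = find_inversions(type_I, type_III)
        part = RegionPartition.from_features(type_III)
        pairs = find_dispersed_repeats(type_III, part)
        df = breakpoint_association(pairs, list(block.breakpoints_b), window=1000)
        # the injected repeat sits in ycf2 just upstream of the ndhB..trnR
        # inversion; the adjacent breakpoint is flagged within 1 kb
        assert df.within_window.any()
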