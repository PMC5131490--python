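import numpy as np
import pytest

from recmap.homozygosity import (cross_group_shared_haplotype,
                                 exclude_control_homozygotes, find_roh,
                                 segment_length_mb, shared_autozygosity)
from recmap.variants import HET, MISSING

from conftest import make_genotypes, make_map


def brute_force_roh(dosages, min_snps, max_het):
    """O(n^2) exhaustive scan: every maximal interval with <= max_het hets,
    trimmed to homozygous ends, with >= min_snps homozygous calls."""
    n = len(dosages)
    is_het = [d == HET for d in dosages]
    is_hom = [d in (0, 2) for d in dosages]

    def hets(i, j):
        return sum(is_het[i:j + 1])

    found = set()
    for i in range(n):
        for j in range(i, n):
            if hets(i, j) > max_het:
                continue
            if i > 0 and hets(i - 1, j) <= max_het:
                continue   # not maximal left
            if j < n - 1 and hets(i, j + 1) <= max_het:
                continue   # not maximal right
            homs = [k for k in range(i, j + 1) if is_hom[k]]
            if len(homs) >= min_snps:
                found.add((homs[0], homs[-1], len(homs)))
    return found


def brute_force_shared(rows, min_snps):
    """Exhaustive per-interval check of the shared-autozygosity definition."""
    n = rows.shape[1]

    def bad(j):
        col = rows[:, j]
        if (col == HET).any():
            return True
        return (col == 0).any() and (col == 2).any()

    def good(j):
        col = rows[:, j]
        return not bad(j) and ((col == 0).any() or (col == 2).any())

    found = set()
    for i in range(n):
        for j in range(i, n):
            if any(bad(k) for k in range(i, j + 1)):
                continue
            if i > 0 and not bad(i - 1):
                continue
            if j < n - 1 and not bad(j + 1):
                continue
            goods = [k for k in range(i, j + 1) if good(k)]
            if len(goods) >= min_snps:
                found.add((goods[0], goods[-1], len(goods)))
    return found


class TestFindRoh:
    def test_fully_homozygous_chromosome_is_one_segment(self):
        mm = make_map(100)
        segs = find_roh(np.zeros(100, dtype=np.int8), mm, min_snps=20)
        assert len(segs) == 1
        assert (segs[0].start_bp, segs[0].end_bp) == (mm.position_bp[0],
                                                      mm.position_bp[99])
        assert segs[0].n_snps == 100

    def test_alternating_het_hom_yields_nothing(self):
        mm = make_map(100)
        dosages = np.tile([0, 1], 50).astype(np.int8)
        assert find_roh(dosages, mm, min_snps=20, max_het=0) == []

    @pytest.mark.parametrize("max_het", [0, 1, 2])
    def test_matches_exhaustive_interval_scan(self, max_het):
        rng = np.random.default_rng(100 + max_het)
        dosages = rng.choice([0, 1, 2, MISSING], size=500,
                             p=[0.42, 0.12, 0.42, 0.04]).astype(np.int8)
        mm = make_map(500)
        segs = find_roh(dosages, mm, min_snps=10, max_het=max_het)
        got = {(s.start_index, s.end_index, s.n_snps) for s in segs}
        assert got == brute_force_roh(dosages, 10, max_het)

    def test_missing_calls_are_neutral(self):
        mm = make_map(30)
        dosages = np.zeros(30, dtype=np.int8)
        dosages[10] = MISSING
        segs = find_roh(dosages, mm, min_snps=20)
        assert len(segs) == 1 and segs[0].n_snps == 29


class TestSharedAutozygosity:
    def test_identical_homozygous_samples_span_the_chromosome(self):
        gm = make_genotypes(np.zeros((2, 50), dtype=np.int8))
        segs = shared_autozygosity(gm, ["s0", "s1"], min_snps=10)
        assert len(segs) == 1
        assert segs[0].n_snps == 50

    def test_opposite_alleles_split_the_segment(self):
        dosages = np.zeros((2, 50), dtype=np.int8)
        dosages[0, 25] = 2   # opposite homozygote in one sample
        gm = make_genotypes(dosages)
        segs = shared_autozygosity(gm, ["s0", "s1"], min_snps=10)
        assert len(segs) == 2
        assert segs[0].end_index == 24 and segs[1].start_index == 26

    def test_requires_two_samples(self):
        gm = make_genotypes(np.zeros((1, 30), dtype=np.int8))
        with pytest.raises(ValueError):
            shared_autozygosity(gm, ["s0"])

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(11)
        dosages = rng.choice([0, 1, 2, MISSING], size=(3, 400),
                             p=[0.55, 0.05, 0.35, 0.05]).astype(np.int8)
        gm = make_genotypes(dosages)
        segs = shared_autozygosity(gm, ["s0", "s1", "s2"], min_snps=5)
        got = {(s.start_index, s.end_index, s.n_snps) for s in segs}
        assert got == brute_force_shared(dosages, 5)

    def test_monotone_in_sample_set(self):
        """Adding a sample never lengthens any shared segment."""
        rng = np.random.default_rng(12)
        dosages = rng.choice([0, 2, 1], size=(4, 300),
                             p=[0.48, 0.48, 0.04]).astype(np.int8)
        gm = make_genotypes(dosages)
        two = shared_autozygosity(gm, ["s0", "s1"], min_snps=3)
        three = shared_autozygosity(gm, ["s0", "s1", "s2"], min_snps=3)
        for seg3 in three:
            assert any(s2.start_index <= seg3.start_index
                       and seg3.end_index <= s2.end_index for s2 in two)

    def test_segments_contained_in_each_members_roh(self, default_sim):
        gm = default_sim["genotypes"]
        affected = default_sim["samples"].ids("affected")
        segs = shared_autozygosity(gm, affected, min_snps=20)
        assert segs, "affected samples must share at least one segment"
        for sid in affected:
            row = gm.dosages[gm.sample_index(sid)]
            rohs = find_roh(row, gm.markers, min_snps=20)
            for seg in segs:
                # segment bounds trim to the *joint* homozygous calls; the
                # member's ROH bounds trim to its own, so compare on the
                # member's called-homozygous span inside the segment
                span = np.arange(seg.start_index, seg.end_index + 1)
                hom = span[(row[span] == 0) | (row[span] == 2)]
                assert any(r.chrom == seg.chrom
                           and r.start_index <= hom[0]
                           and hom[-1] <= r.end_index for r in rohs)

    def test_recovers_true_carrier_region(self, default_sim):
        truth = default_sim["truth"]
        gm = default_sim["genotypes"]
        segs = shared_autozygosity(gm, default_sim["samples"].ids("affected"))
        lo, hi = truth.carrier_region_bp
        covering = [s for s in segs if s.chrom == truth.carrier_chrom
                    and s.start_bp <= lo and hi <= s.end_bp]
        assert covering, "the true carrier region must sit inside a shared segment"


class TestExcludeControls:
    def _fixture(self):
        dosages = np.zeros((4, 60), dtype=np.int8)
        dosages[2] = np.array([0] * 30 + [1] * 30)   # control matching first half
        dosages[3, ::2] = 1                          # het-rich control
        return make_genotypes(dosages)

    def test_matching_control_removes_segment(self):
        gm = make_genotypes(np.zeros((3, 40), dtype=np.int8))
        segs = shared_autozygosity(gm, ["s0", "s1"], min_snps=10)
        assert exclude_control_homozygotes(segs, gm, ["s2"]) == []

    def test_no_matching_control_is_identity(self):
        dosages = np.zeros((3, 40), dtype=np.int8)
        dosages[2, ::3] = 1
        gm = make_genotypes(dosages)
        segs = shared_autozygosity(gm, ["s0", "s1"], min_snps=10)
        assert exclude_control_homozygotes(segs, gm, ["s2"]) == segs

    def test_survivors_match_direct_scan(self):
        rng = np.random.default_rng(21)
        dosages = rng.choice([0, 2, 1], size=(6, 500),
                             p=[0.49, 0.49, 0.02]).astype(np.int8)
        gm = make_genotypes(dosages)
        segs = shared_autozygosity(gm, ["s0", "s1"], min_snps=5)
        controls = ["s2", "s3", "s4", "s5"]
        got = exclude_control_homozygotes(segs, gm, controls)
        expected = []
        for seg in segs:
            removed = False
            for c in controls:
                row = gm.dosages[gm.sample_index(c), seg.start_index:seg.end_index + 1]
                match = all(row[k] in (seg.hom_dosage[k], MISSING)
                            for k in range(len(row)) if seg.hom_dosage[k] != -9)
                if match:
                    removed = True
            if not removed:
                expected.append(seg)
        assert got == expected

    def test_trim_mode_splits_around_control_runs(self):
        dosages = np.zeros((3, 100), dtype=np.int8)
        dosages[2, :40] = 0        # control homozygous-matching over first 40
        dosages[2, 40] = 1
        dosages[2, 41:] = 2        # opposite homozygote elsewhere
        gm = make_genotypes(dosages)
        segs = shared_autozygosity(gm, ["s0", "s1"], min_snps=10)
        trimmed = exclude_control_homozygotes(segs, gm, ["s2"], mode="trim",
                                              min_snps=10)
        assert len(trimmed) == 1
        assert trimmed[0].start_index >= 40


class TestLengths:
    def test_printed_coordinate_examples(self):
        assert segment_length_mb(40_113_694, 61_378_199) == 21.26
        assert segment_length_mb(5, 5) == 0.0
        assert segment_length_mb(1_000_000, 9_720_000) == 8.72


class TestCrossGroup:
    def test_disjoint_homozygous_alleles_share_nothing(self):
        dosages = np.vstack([np.zeros((2, 40)), np.full((2, 40), 2)]).astype(np.int8)
        gm = make_genotypes(dosages)
        segs = cross_group_shared_haplotype(gm, ["s0", "s1"], ["s2", "s3"],
                                            min_snps=5)
        assert segs == []

    def test_two_breeds_from_one_founder_share_the_causal_interval(self):
        """Two affected groups homozygous for the same ancestral segment in
        the middle of the chromosome, with discordant flanks."""
        rng = np.random.default_rng(31)
        dosages = rng.choice([0, 2], size=(4, 90)).astype(np.int8)
        dosages[:, 30:60] = np.tile(rng.choice([0, 2], size=30), (4, 1))
        dosages[0, 20] = 1
        dosages[2, 70] = 1
        gm = make_genotypes(dosages)
        segs = cross_group_shared_haplotype(gm, ["s0", "s1"], ["s2", "s3"],
                                            min_snps=10)
        mid = gm.markers.position_bp[45]
        assert any(s.contains_bp("1", mid) for s in segs)
        assert segs[0].groups == {"a": ["s0", "s1"], "b": ["s2", "s3"]}

    def test_single_sample_duplicated_reduces_to_own_roh(self):
        gm = make_genotypes(np.zeros((1, 40), dtype=np.int8))
        segs = cross_group_shared_haplotype(gm, ["s0"], ["s0"], min_snps=10)
        roh = find_roh(gm.dosages[0], gm.markers, min_snps=10, sample_id="s0")
        assert [(s.start_index, s.end_index, s.n_snps) for s in segs] \
            == [(r.start_index, r.end_index, r.n_snps) for r in roh]
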