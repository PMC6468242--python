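"""Reference peak set construction: parsing, merging, reproducibility,
classification — checked against brute-force per-base oracles on toy
chromosomes."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adacomplex.peakset import (
    ADA2B_ONLY,
    CANONICAL,
    OTHER,
    GenomicInterval,
    PeakFileError,
    ReplicatePeakSet,
    build_reference_set,
    classify_locus,
    merge_intervals,
    overlap_fraction,
    read_narrowpeak,
    reproducible_peaks,
    write_bed,
)

TOY = 1000  # toy chromosome length for base-set oracles


def base_set(intervals, length=TOY):
    """Brute-force boolean occupancy array over a toy chromosome."""
    arr = np.zeros(length, dtype=bool)
    for iv in intervals:
        arr[iv.start : iv.end] = True
    return arr


intervals_strategy = st.lists(
    st.tuples(st.integers(0, TOY - 2), st.integers(1, 80)).map(
        lambda t: GenomicInterval("chrT", t[0], min(TOY, t[0] + t[1]))
    ),
    min_size=1,
    max_size=50,
)


class TestGenomicInterval:
    def test_invariants(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)

    def test_overlap_is_half_open(self):
        a = GenomicInterval("chr1", 0, 10)
        assert not a.overlaps(GenomicInterval("chr1", 10, 20))  # bookended
        assert a.overlaps(GenomicInterval("chr1", 9, 20))
        assert not a.overlaps(GenomicInterval("chr2", 0, 10))


class TestNarrowPeakIO:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.narrowPeak"
        p.write_text("")
        assert read_narrowpeak(p) == []

    def test_single_line_fields(self, tmp_path):
        p = tmp_path / "one.narrowPeak"
        p.write_text("chr2L\t100\t200\tp1\t50\n")
        (iv,) = read_narrowpeak(p)
        assert (iv.chrom, iv.start, iv.end, iv.name, iv.score) == (
            "chr2L", 100, 200, "p1", 50.0,
        )

    def test_roundtrip(self, tmp_path):
        ivs = [
            GenomicInterval("chr2L", 10, 50, "a", 1.0),
            GenomicInterval("chr2L", 100, 130, "b", 2.5),
            GenomicInterval("chr3R", 5, 9, "c", 0.0),
        ]
        p = tmp_path / "rt.bed"
        write_bed(ivs, p)
        assert read_narrowpeak(p) == ivs

    @pytest.mark.parametrize(
        "line", ["chr1\tx\t200", "chr1\t100\t50", "chr1\t100"]
    )
    def test_malformed_lines_name_the_line(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t1\t2\n" + line + "\n")
        with pytest.raises(PeakFileError, match="line 2"):
            read_narrowpeak(p)


class TestMergeIntervals:
    def test_disjoint_unchanged(self):
        ivs = [GenomicInterval("c", 10, 20), GenomicInterval("c", 30, 40)]
        assert merge_intervals(ivs) == ivs

    def test_overlap_union(self):
        out = merge_intervals(
            [GenomicInterval("c", 0, 10), GenomicInterval("c", 5, 15)]
        )
        assert out == [GenomicInterval("c", 0, 15)]

    def test_bookended_joined(self):
        out = merge_intervals(
            [GenomicInterval("c", 0, 10), GenomicInterval("c", 10, 20)]
        )
        assert out == [GenomicInterval("c", 0, 20)]

    @settings(max_examples=100, deadline=None)
    @given(intervals_strategy)
    def test_base_set_preserved_disjoint_sorted_idempotent(self, ivs):
        merged = merge_intervals(ivs)
        assert np.array_equal(base_set(merged), base_set(ivs))
        for a, b in zip(merged, merged[1:]):
            assert a.end < b.start  # disjoint, sorted, not even bookended
        assert merge_intervals(merged) == merged

    @settings(max_examples=30, deadline=None)
    @given(intervals_strategy, st.randoms(use_true_random=False))
    def test_order_invariant(self, ivs, rnd):
        shuffled = list(ivs)
        rnd.shuffle(shuffled)
        assert merge_intervals(shuffled) == merge_intervals(ivs)


def jittered(rng, truths, jitter=15):
    out = []
    for s, e in truths:
        ds, de = rng.integers(-jitter, jitter + 1, size=2)
        out.append(GenomicInterval("chrT", max(0, s + ds), max(s + ds + 1, e + de)))
    return out


class TestReproduciblePeaks:
    def test_single_replicate_identity(self):
        rep = ReplicatePeakSet("F", "r1", [GenomicInterval("c", 5, 30),
                                           GenomicInterval("c", 10, 40)])
        assert reproducible_peaks([rep], 1) == [GenomicInterval("c", 5, 40)]

    def test_disjoint_replicates_empty(self):
        r1 = ReplicatePeakSet("F", "r1", [GenomicInterval("c", 0, 10)])
        r2 = ReplicatePeakSet("F", "r2", [GenomicInterval("c", 50, 60)])
        assert reproducible_peaks([r1, r2], 2) == []

    def test_min_support_bounds(self):
        r1 = ReplicatePeakSet("F", "r1", [GenomicInterval("c", 0, 10)])
        with pytest.raises(ValueError):
            reproducible_peaks([r1], 2)
        with pytest.raises(ValueError):
            reproducible_peaks([r1], 0)

    def test_mixed_factors_rejected(self):
        r1 = ReplicatePeakSet("F", "r1", [GenomicInterval("c", 0, 10)])
        r2 = ReplicatePeakSet("G", "r1", [GenomicInterval("c", 0, 10)])
        with pytest.raises(ValueError):
            reproducible_peaks([r1, r2], 1)

    def test_recovers_true_regions_against_per_base_oracle(self, rng):
        # 6 well-separated true peaks; 3 replicates, one missing 2 peaks
        truths = [(i * 150 + 20, i * 150 + 80) for i in range(6)]
        reps = [
            ReplicatePeakSet("F", "r1", jittered(rng, truths)),
            ReplicatePeakSet("F", "r2", jittered(rng, truths)),
            ReplicatePeakSet("F", "r3", jittered(rng, truths[:4])),
        ]
        result = reproducible_peaks(reps, 2)
        assert len(result) == 6
        for (s, e), iv in zip(truths, result):
            assert iv.overlaps(GenomicInterval("chrT", s, e))
        # oracle: per-base count of replicates covering each base; a kept
        # peak must overlap bases covered by >= 2 replicates
        counts = sum(base_set(r.peaks).astype(int) for r in reps)
        for iv in result:
            assert (counts[iv.start : iv.end] >= 2).any()

    def test_min_support_one_equals_pooled_merge(self, rng):
        truths = [(i * 200, i * 200 + 90) for i in range(4)]
        reps = [ReplicatePeakSet("F", f"r{i}", jittered(rng, truths)) for i in range(3)]
        pooled = merge_intervals([p for r in reps for p in r.peaks])
        assert reproducible_peaks(reps, 1) == pooled

    def test_monotone_decreasing_in_min_support(self, rng):
        truths = [(i * 120, i * 120 + 70) for i in range(7)]
        reps = [
            ReplicatePeakSet("F", f"r{i}", jittered(rng, truths[: 7 - i]))
            for i in range(3)
        ]
        prev = None
        for ms in (1, 2, 3):
            cur = base_set(reproducible_peaks(reps, ms))
            if prev is not None:
                assert not (cur & ~prev).any()  # base set shrinks or stays
            prev = cur


class TestClassifyLocus:
    def test_paper_rule_on_all_eight_vectors(self):
        classes = {}
        for bits in itertools.product([True, False], repeat=3):
            support = dict(zip(("Ada2b", "Spt3", "Sgf11"), bits))
            classes[bits] = classify_locus(support)
        assert classes[(True, False, False)] == ADA2B_ONLY
        assert classes[(True, True, True)] == CANONICAL
        others = [v for k, v in classes.items()
                  if k not in ((True, False, False), (True, True, True))]
        assert others == [OTHER] * 6

    def test_partition_sizes(self):
        labels = [
            classify_locus(dict(zip(("Ada2b", "Spt3", "Sgf11"), bits)))
            for bits in itertools.product([True, False], repeat=3)
        ]
        assert sorted(
            (labels.count(CANONICAL), labels.count(ADA2B_ONLY), labels.count(OTHER))
        ) == [1, 1, 6]

    def test_missing_factor_errors(self):
        with pytest.raises(ValueError):
            classify_locus({"Ada2b": True, "Spt3": False})

    def test_configurable_factor_names(self):
        assert classify_locus(
            {"X": True, "Y": False, "Z": False}, primary="X", cofactors=("Y", "Z")
        ) == ADA2B_ONLY


class TestBuildReferenceSet:
    def test_single_factor(self):
        loci = build_reference_set(
            {"Ada2b": [GenomicInterval("c", 0, 10)],
             "Spt3": [], "Sgf11": []}
        )
        assert len(loci) == 1
        assert loci[0].support == {"Ada2b": True, "Spt3": False, "Sgf11": False}
        assert loci[0].locus_class == ADA2B_ONLY

    def test_three_factor_merge_is_canonical(self):
        loci = build_reference_set(
            {
                "Ada2b": [GenomicInterval("c", 100, 200)],
                "Spt3": [GenomicInterval("c", 150, 250)],
                "Sgf11": [GenomicInterval("c", 180, 300)],
            }
        )
        assert len(loci) == 1
        assert loci[0].interval == GenomicInterval("c", 100, 300)
        assert loci[0].locus_class == CANONICAL

    def test_planted_classes_recovered(self, rng):
        # 40 canonical + 10 ada2b-only well-separated loci
        canonical = [(i * 400, i * 400 + 100) for i in range(40)]
        ada_only = [(20_000 + i * 400, 20_000 + i * 400 + 100) for i in range(10)]
        per_factor = {
            "Ada2b": [GenomicInterval("c", s, e) for s, e in canonical + ada_only],
            "Spt3": [GenomicInterval("c", s, e) for s, e in canonical],
            "Sgf11": [GenomicInterval("c", s, e) for s, e in canonical],
        }
        loci = build_reference_set(per_factor)
        assert len(loci) == 50
        got = [l.locus_class for l in loci]
        assert got.count(CANONICAL) == 40
        assert got.count(ADA2B_ONLY) == 10


class TestOverlapFraction:
    def test_self_is_one(self):
        a = [GenomicInterval("c", 0, 10), GenomicInterval("c", 50, 60)]
        assert overlap_fraction(a, a) == 1.0

    def test_different_chromosomes_zero(self):
        a = [GenomicInterval("c1", 0, 10)]
        b = [GenomicInterval("c2", 0, 10)]
        assert overlap_fraction(a, b) == 0.0

    def test_empty_a_errors(self):
        with pytest.raises(ValueError):
            overlap_fraction([], [GenomicInterval("c", 0, 10)])

    def test_matches_all_pairs_oracle(self, rng):
        def random_ivs(n):
            out = []
            for _ in range(n):
                s = int(rng.integers(0, TOY - 30))
                out.append(GenomicInterval("chrT", s, s + int(rng.integers(5, 30))))
            return out

        a, b = random_ivs(20), random_ivs(20)
        expected = sum(
            1 for x in a if any(x.overlaps(y) for y in b)
        ) / len(a)
        assert overlap_fraction(a, b) == pytest.approx(expected)
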