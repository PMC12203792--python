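"""Interval algebra: examples worked by hand plus brute-force cross-checks."""
import numpy as np
import pytest

from conftest import ivset
from oracles import (
    brute_cluster,
    brute_common_merge,
    brute_intersect_peak,
    brute_intersect_region,
    brute_overlap_count_min,
    random_intervalset,
)
from oriskew.intervals import (
    GenomicInterval,
    IntervalSet,
    cluster_initiation_zones,
    common_ko_merge,
    intersect_replicates,
    median_interpeak_distance,
    merge_overlapping,
    overlap_count_min,
    read_bed,
    write_bed,
)


class TestGenomicInterval:
    def test_rejects_inverted_and_negative_coordinates(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)

    def test_length_and_overlap(self):
        a = GenomicInterval("chr1", 0, 10)
        assert len(a) == 10
        assert a.overlaps(GenomicInterval("chr1", 9, 20))
        assert not a.overlaps(GenomicInterval("chr1", 10, 20))  # touching
        assert not a.overlaps(GenomicInterval("chr2", 0, 10))


class TestBedIO:
    def test_round_trip_identity(self, tmp_path):
        original = IntervalSet(
            [
                GenomicInterval("chr1", 5, 10, name="a", score=1.5),
                GenomicInterval("chr2", 0, 7, name="b", score=0.0),
            ]
        )
        path = tmp_path / "x.bed"
        write_bed(original, path)
        again = read_bed(path)
        assert [(i.chrom, i.start, i.end, i.name, i.score) for i in again] == [
            (i.chrom, i.start, i.end, i.name, i.score) for i in original
        ]

    def test_unsorted_input_is_sorted(self, tmp_path):
        path = tmp_path / "u.bed"
        path.write_text("chr2\t5\t10\nchr1\t50\t60\nchr1\t5\t10\n")
        out = read_bed(path)
        assert [(i.chrom, i.start) for i in out] == [
            ("chr1", 5), ("chr1", 50), ("chr2", 5)
        ]

    def test_empty_file(self, tmp_path):
        path = tmp_path / "e.bed"
        path.write_text("")
        assert len(read_bed(path)) == 0

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t5\t10\nchr1\t20\n")
        with pytest.raises(ValueError, match=":2:"):
            read_bed(path)

    def test_start_after_end_rejected(self, tmp_path):
        path = tmp_path / "inv.bed"
        path.write_text("chr1\t10\t5\n")
        with pytest.raises(ValueError):
            read_bed(path)

    def test_layout_drops_noncanonical(self, tmp_path, tiny_layout):
        path = tmp_path / "nc.bed"
        path.write_text("chrA\t0\t10\nchrUn_random\t0\t10\n")
        assert len(read_bed(path, layout=tiny_layout)) == 1


class TestIntersectReplicates:
    def test_region_and_peak_modes(self):
        rep1, rep2 = ivset(("chr1", 0, 10)), ivset(("chr1", 5, 15))
        assert list(intersect_replicates(rep1, rep2))[0].sort_key() == ("chr1", 5, 10)
        assert list(intersect_replicates(rep1, rep2, mode="peak"))[0].sort_key() == (
            "chr1", 0, 10
        )

    def test_disjoint_sets_empty(self):
        assert len(intersect_replicates(ivset(("chr1", 0, 10)), ivset(("chr1", 20, 30)))) == 0

    @pytest.mark.parametrize("mode", ["region", "peak"])
    def test_idempotence_on_disjoint_self(self, mode):
        reps = ivset(("chr1", 0, 10), ("chr1", 20, 30), ("chr2", 5, 9))
        assert intersect_replicates(reps, reps, mode=mode) == reps


class TestOverlapCountMin:
    def test_chain_counted_once(self):
        # one b-peak bridges two a-peaks: one component, min(2, 1) = 1
        a = ivset(("chr1", 0, 10), ("chr1", 12, 20))
        b = ivset(("chr1", 5, 15))
        assert overlap_count_min(a, b) == (1, 0, 0)

    def test_disjoint(self):
        assert overlap_count_min(ivset(("chr1", 0, 10)), ivset(("chr1", 50, 60))) == (0, 1, 1)

    def test_identical_disjoint_sets_count_all(self):
        a = ivset(("chr1", 0, 10), ("chr1", 20, 30), ("chr2", 0, 5))
        assert overlap_count_min(a, a)[0] == len(a)

    def test_count_symmetric_random(self, rng):
        chroms = {"c1": 2000, "c2": 2000}
        for _ in range(50):
            a = random_intervalset(rng, chroms, int(rng.integers(1, 15)), 300)
            b = random_intervalset(rng, chroms, int(rng.integers(1, 15)), 300)
            assert overlap_count_min(a, b)[0] == overlap_count_min(b, a)[0]


class TestMedianInterpeakDistance:
    def test_hand_computed(self):
        peaks = ivset(("chr1", 0, 10), ("chr1", 20, 30), ("chr1", 50, 60))
        assert median_interpeak_distance(peaks) == 15.0

    def test_touching_peaks_zero_gap(self):
        assert median_interpeak_distance(ivset(("chr1", 0, 10), ("chr1", 10, 20))) == 0.0

    def test_single_peaks_per_chromosome_error(self):
        with pytest.raises(ValueError, match="no interpeak"):
            median_interpeak_distance(ivset(("chr1", 0, 10), ("chr2", 0, 10)))

    def test_start_to_start_mode(self):
        peaks = ivset(("chr1", 0, 10), ("chr1", 20, 30), ("chr1", 50, 60))
        assert median_interpeak_distance(peaks, mode="start_to_start") == 25.0


class TestClusterInitiationZones:
    def test_hand_merge(self):
        peaks = ivset(("chr1", 0, 10), ("chr1", 20, 30), ("chr1", 50, 60))
        zones = cluster_initiation_zones(peaks, 15)
        assert [(z.start, z.end, z.score) for z in zones] == [(0, 30, 2.0), (50, 60, 1.0)]

    def test_threshold_zero_merges_nothing_on_disjoint_input(self):
        peaks = ivset(("chr1", 0, 10), ("chr1", 10, 20))
        assert cluster_initiation_zones(peaks, 0) == peaks

    def test_single_peak(self):
        peaks = ivset(("chr1", 3, 9))
        assert cluster_initiation_zones(peaks, 100) == peaks

    def test_zones_separated_by_at_least_threshold(self, rng):
        chroms = {"c1": 5000}
        for _ in range(30):
            peaks = random_intervalset(rng, chroms, 12, 200)
            thr = int(rng.integers(0, 400))
            zones = cluster_initiation_zones(peaks, thr)
            for prev, nxt in zip(zones, zones.intervals[1:]):
                if prev.chrom == nxt.chrom:
                    assert nxt.start - prev.end >= thr

    def test_strict_boundary(self):
        # gap exactly == threshold must NOT merge ("closer than" is strict)
        peaks = ivset(("chr1", 0, 10), ("chr1", 25, 30))
        assert len(cluster_initiation_zones(peaks, 15)) == 2
        assert len(cluster_initiation_zones(peaks, 16)) == 1


class TestCommonKoMerge:
    def test_identical_singletons(self):
        s = ivset(("chr1", 5, 10))
        assert common_ko_merge([s, s, s]) == s

    def test_mutually_overlapping_merged_to_union_span(self):
        sets = [ivset(("chr1", 0, 10)), ivset(("chr1", 5, 15)), ivset(("chr1", 8, 20))]
        assert common_ko_merge(sets) == ivset(("chr1", 0, 20))

    def test_one_disjoint_set_gives_empty(self):
        sets = [ivset(("chr1", 0, 10)), ivset(("chr1", 5, 15)), ivset(("chr1", 100, 110))]
        assert len(common_ko_merge(sets)) == 0


class TestBruteForceEquivalence:
    """Sweep algorithms vs per-base / pairwise enumeration on small genomes."""

    def test_all_operations_match_oracles(self, rng):
        chroms = {"g1": 3000, "g2": 1500}
        for _ in range(60):
            a = random_intervalset(rng, chroms, int(rng.integers(1, 20)), 400)
            b = random_intervalset(rng, chroms, int(rng.integers(1, 20)), 400)
            c = random_intervalset(rng, chroms, int(rng.integers(1, 20)), 400)

            # per-pair segments can touch; compare as coverage (merge gap<=0)
            got = merge_overlapping(intersect_replicates(a, b), min_gap=1)
            assert [g.sort_key() for g in got] == [
                o.sort_key() for o in brute_intersect_region(a, b, chroms)
            ]
            got_pk = intersect_replicates(a, b, mode="peak")
            assert [g.sort_key() for g in got_pk] == [
                o.sort_key() for o in brute_intersect_peak(a, b, chroms)
            ]
            assert overlap_count_min(a, b) == brute_overlap_count_min(a, b)
            thr = int(rng.integers(0, 300))
            assert [z.sort_key() for z in cluster_initiation_zones(a, thr)] == [
                z.sort_key() for z in brute_cluster(a, thr)
            ]
            assert [m.sort_key() for m in common_ko_merge([a, b, c])] == [
                m.sort_key() for m in brute_common_merge([a, b, c], chroms)
            ]
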