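import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chisquare

from rwas.intervals import (ChromSizes, IntervalSet, centroid_normalize,
                            exclude_regions, jaccard, jaccard_matrix,
                            merge_adjacent, nearest_distance, overlap_flag,
                            points_from_positions, pool_states, read_bed,
                            read_segmentation, shuffle_intervals, write_bed)


def iset(*recs):
    return IntervalSet.from_records(recs)


class TestBedIO:
    def test_parse_bed4(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t900\tE1\n")
        out = read_bed(p)
        iv = next(iter(out))
        assert (iv.chrom, iv.start, iv.end, iv.id) == ("chr1", 100, 900, "E1")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("")
        assert len(read_bed(p)) == 0

    def test_inverted_coordinates_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t900\t100\n")
        with pytest.raises(ValueError, match="bad.bed:1"):
            read_bed(p)

    def test_short_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t200\nchr1\t300\n")
        with pytest.raises(ValueError, match=":2"):
            read_bed(p)

    def test_roundtrip(self, tmp_path):
        s = iset(("chr1", 5, 10, "a"), ("chr2", 0, 3, "b"))
        path = tmp_path / "rt.bed"
        write_bed(s, path)
        assert read_bed(path) == s

    def test_auto_ids(self, tmp_path):
        p = tmp_path / "n.bed"
        p.write_text("chr1\t10\t20\n")
        assert read_bed(p).df["id"].iloc[0] == "chr1:10-20"


class TestPoolStates:
    def test_filters_by_state(self):
        seg = iset(("chr1", 0, 10, "i1", "EnhA1"), ("chr1", 10, 20, "i2", "Quies"),
                   ("chr1", 20, 30, "i3", "EnhW1"))
        out = pool_states(seg, {"EnhA1", "EnhW1"})
        assert len(out) == 2
        assert out.df["label"].isna().all()

    def test_disjoint_states_empty(self):
        seg = iset(("chr1", 0, 10, "i1", "Quies"))
        assert len(pool_states(seg, {"EnhA1"})) == 0

    def test_all_states_identity(self):
        seg = iset(("chr1", 0, 10, "i1", "A"), ("chr1", 10, 20, "i2", "B"))
        assert len(pool_states(seg, {"A", "B"})) == 2

    def test_empty_keep_states_rejected(self):
        seg = iset(("chr1", 0, 10, "i1", "A"))
        with pytest.raises(ValueError):
            pool_states(seg, set())

    def test_segmentation_reader_takes_state_from_col4(self, tmp_path):
        p = tmp_path / "seg.bed"
        p.write_text("chr1\t0\t200\tEnhA1\nchr1\t200\t400\tQuies\n")
        seg = read_segmentation(p)
        assert list(seg.df["label"]) == ["EnhA1", "Quies"]


class TestMerge:
    @pytest.mark.parametrize("recs,expected", [
        ([("chr1", 100, 400), ("chr1", 400, 900)], [(100, 900)]),
        ([("chr1", 100, 200), ("chr1", 300, 400)], [(100, 200), (300, 400)]),
        ([("chr1", 100, 200), ("chr1", 150, 400)], [(100, 400)]),
    ])
    def test_fusion(self, recs, expected):
        out = merge_adjacent(iset(*recs))
        assert list(zip(out.df["start"], out.df["end"])) == expected

    def test_max_gap(self):
        out = merge_adjacent(iset(("chr1", 0, 100), ("chr1", 150, 200)),
                             max_gap=50)
        assert len(out) == 1

    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 80)),
                    min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_union_bp_preserved(self, pieces):
        recs = [("chr1", s, s + ln, f"i{k}") for k, (s, ln) in enumerate(pieces)]
        merged = merge_adjacent(iset(*recs))
        covered = set()
        for _, s, e, _ in recs:
            covered.update(range(s, e))
        assert int((merged.df["end"] - merged.df["start"]).sum()) == len(covered)
        # merged intervals are disjoint and sorted per chromosome
        d = merged.df
        assert (d["start"].to_numpy()[1:] > d["end"].to_numpy()[:-1]).all() \
            or len(d) == 1


class TestCentroid:
    def test_interior_region(self):
        out = centroid_normalize(iset(("chr1", 100, 900, "x")))
        assert list(out.df[["start", "end"]].iloc[0]) == [0, 1000]

    def test_clipping_at_chromosome_start(self):
        out = centroid_normalize(iset(("chr1", 0, 150, "y")))
        assert list(out.df[["start", "end"]].iloc[0]) == [0, 575]

    def test_identity_when_already_centered(self):
        out = centroid_normalize(iset(("chr1", 1000, 2000, "z")))
        assert list(out.df[["start", "end"]].iloc[0]) == [1000, 2000]

    def test_interior_widths_constant(self):
        rng = np.random.default_rng(0)
        recs = []
        for k in range(100):
            s = int(rng.integers(10_000, 1_000_000))
            recs.append(("chr1", s, s + int(rng.integers(50, 5000)), f"e{k}"))
        out = centroid_normalize(merge_adjacent(iset(*recs)),
                                 sizes=ChromSizes({"chr1": 2_000_000}))
        widths = (out.df["end"] - out.df["start"]).unique()
        assert list(widths) == [1000]


class TestExclude:
    def test_one_bp_overlap_drops(self):
        enh = iset(("chr1", 100, 1100, "e"))
        bl = iset(("chr1", 1099, 2000, "b"))
        assert len(exclude_regions(enh, bl)) == 0

    def test_empty_exclusion_identity(self):
        enh = iset(("chr1", 100, 1100, "e"))
        assert exclude_regions(enh, iset(("chr2", 0, 10, "b"))) == enh

    def test_containment_drops(self):
        enh = iset(("chr1", 500, 600, "e"))
        bl = iset(("chr1", 0, 10_000, "b"))
        assert len(exclude_regions(enh, bl)) == 0

    def test_no_shared_bases_with_exclusion(self):
        rng = np.random.default_rng(1)
        enh = iset(*[("chr1", int(s), int(s) + 100, f"e{k}")
                     for k, s in enumerate(rng.integers(0, 100_000, 200))])
        bl = iset(*[("chr1", int(s), int(s) + 500, f"b{k}")
                    for k, s in enumerate(rng.integers(0, 100_000, 20))])
        kept = exclude_regions(enh, bl)
        if len(kept):
            assert nearest_distance(kept, bl).min() > 0


class TestJaccard:
    def test_identical_sets(self):
        a = iset(("chr1", 0, 100, "a"))
        assert jaccard(a, a) == 1.0

    def test_disjoint_sets(self):
        assert jaccard(iset(("chr1", 0, 100, "a")),
                       iset(("chr1", 200, 300, "b"))) == 0.0

    def test_hand_computed_third(self):
        a = iset(("chr1", 0, 100, "a"))
        b = iset(("chr1", 50, 150, "b"))
        assert jaccard(a, b) == pytest.approx(1 / 3)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(2)
        a = iset(*[("chr1", int(s), int(s) + 50, f"a{k}")
                   for k, s in enumerate(rng.integers(0, 10_000, 40))])
        b = iset(*[("chr1", int(s), int(s) + 80, f"b{k}")
                   for k, s in enumerate(rng.integers(0, 10_000, 30))])
        j1, j2 = jaccard(a, b), jaccard(b, a)
        assert j1 == j2 and 0.0 <= j1 <= 1.0

    def test_both_empty_rejected(self):
        empty = IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]))
        with pytest.raises(ValueError):
            jaccard(empty, empty)

    def test_matrix_clusters_identical_pair_first(self):
        a = iset(("chr1", 0, 100, "a"))
        b = iset(("chr1", 0, 100, "b"))
        c = iset(("chr2", 0, 100, "c"))
        mat, Z, groups = jaccard_matrix([a, b, c], names=list("abc"))
        assert np.allclose(mat, mat.T) and np.allclose(np.diag(mat), 1.0)
        # first linkage merge joins the identical pair (leaves 0 and 1)
        assert set(Z[0, :2].astype(int)) == {0, 1}
        assert groups[0] == groups[1] != groups[2]


class TestNearestDistance:
    def test_containment_is_zero(self):
        enh = iset(("chr1", 1000, 2000, "e"))
        assert nearest_distance(enh, points_from_positions(["chr1"], [1500])).iloc[0] == 0

    def test_gap_convention(self):
        enh = iset(("chr1", 1000, 2000, "e"))
        d = nearest_distance(enh, points_from_positions(["chr1"], [2501]))
        assert d.iloc[0] == 500

    def test_tie_both_sides(self):
        enh = iset(("chr1", 1000, 2000, "e"))
        pts = points_from_positions(["chr1", "chr1"], [900, 2101])
        assert nearest_distance(enh, pts).iloc[0] == 100

    def test_missing_chromosome_is_nan(self):
        enh = iset(("chrX", 0, 100, "e"))
        d = nearest_distance(enh, points_from_positions(["chr1"], [50]))
        assert np.isnan(d.iloc[0])


class TestOverlapFlag:
    def test_har_expansion_arithmetic(self):
        enh = iset(("chr1", 10_000, 11_000, "e"))
        har = iset(("chr1", 13_400, 13_500, "h"))
        assert overlap_flag(enh, har, expand=2500).iloc[0] == 1
        assert overlap_flag(enh, har, expand=0).iloc[0] == 0

    def test_within_distance_boundary_inclusive(self):
        enh = iset(("chr1", 10_000, 11_000, "e"))
        hge = iset(("chr1", 16_000, 16_100, "g"))  # distance exactly 5000
        assert overlap_flag(enh, hge, mode="within_distance",
                            distance=5000).iloc[0] == 1
        assert overlap_flag(enh, hge, mode="within_distance",
                            distance=4999).iloc[0] == 0


class TestShuffle:
    sizes = ChromSizes({"chr1": 100_000})

    def test_seed_determinism(self):
        s = iset(*[("chr1", i * 100, i * 100 + 50, f"i{i}") for i in range(20)])
        a = shuffle_intervals(s, self.sizes, rng_seed=7)
        b = shuffle_intervals(s, self.sizes, rng_seed=7)
        assert a == b

    def test_lengths_and_chromosomes_preserved(self):
        s = iset(("chr1", 0, 1000, "a"), ("chr1", 5000, 5300, "b"))
        out = shuffle_intervals(s, self.sizes, rng_seed=1)
        assert sorted(out.df["end"] - out.df["start"]) == [300, 1000]
        assert set(out.df["chrom"]) == {"chr1"}

    def test_exclusion_respected(self):
        s = iset(*[("chr1", 0, 500, f"i{i}") for i in range(50)])
        excl = iset(("chr1", 40_000, 60_000, "x"))
        out = shuffle_intervals(s, self.sizes, exclusion=excl, rng_seed=3)
        d = nearest_distance(out, excl)
        assert (d > 0).all()

    def test_start_uniformity_chi2(self):
        # 10,000 shuffled starts of one interval over 10 equal bins
        s = iset(("chr1", 0, 10, "a"))
        rng = np.random.default_rng(2024)
        starts = [shuffle_intervals(s, ChromSizes({"chr1": 10_010}),
                                    rng_seed=rng).df["start"].iloc[0]
                  for _ in range(10_000)]
        counts = np.histogram(starts, bins=10, range=(0, 10_000))[0]
        assert chisquare(counts).pvalue > 0.001

    def test_infeasible_placement_errors(self):
        s = iset(("chr1", 0, 90_000, "big"))
        excl = iset(("chr1", 20_000, 80_000, "x"))
        with pytest.raises(RuntimeError, match="big"):
            shuffle_intervals(s, self.sizes, exclusion=excl, rng_seed=0)
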