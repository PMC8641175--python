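"""Window tiling, deletion bitmaps, feature-matrix construction, batching."""

import numpy as np
import pytest

from _oracles import bitmap_walker, random_cigar, sort_then_slice
from deepdel.config import AlignmentFilter, ConfigError
from deepdel.features import (CigarError, DeletionBitmap, SimpleAlignment,
                              SubRegion, build_feature_matrix,
                              extract_deletion_bitmap,
                              extract_region_matrices,
                              load_feature_container, make_batches,
                              partition_reference, save_feature_container)


class TestPartition:
    def test_exact_tiling(self):
        ws = partition_reference({"chr1": 1000}, 200)
        assert [(w.start, w.end) for w in ws] == \
            [(0, 200), (200, 400), (400, 600), (600, 800), (800, 1000)]
        assert [w.index for w in ws] == list(range(5))

    def test_short_last_window(self):
        ws = partition_reference({"chr1": 1001}, 200)
        assert len(ws) == 6
        assert (ws[-1].start, ws[-1].end) == (1000, 1001)

    def test_default_window_size_is_200(self):
        ws = partition_reference({"c": 400})
        assert ws[0].length == 200

    def test_empty_map_and_bad_window(self):
        assert partition_reference({}, 200) == []
        with pytest.raises(ConfigError):
            partition_reference({"c": 100}, 0)

    def test_multi_contig_tiling_covers_without_overlap(self):
        ws = partition_reference({"a": 450, "b": 200}, 100)
        for contig, length in (("a", 450), ("b", 200)):
            cws = [w for w in ws if w.contig == contig]
            assert cws[0].start == 0 and cws[-1].end == length
            for prev, nxt in zip(cws, cws[1:]):
                assert prev.end == nxt.start


class TestDeletionBitmap:
    region = SubRegion("chr1", 0, 200, 0)

    def test_single_deletion(self):
        b = extract_deletion_bitmap(SimpleAlignment(0, "50M10D140M"), self.region)
        assert b.deletion_count == 10
        assert b.values[50:60].all() and b.values[:50].sum() == 0

    def test_no_deletions(self):
        b = extract_deletion_bitmap(SimpleAlignment(0, "200M"), self.region)
        assert b.deletion_count == 0

    def test_deletion_spilling_into_next_window(self):
        b = extract_deletion_bitmap(SimpleAlignment(0, "10M400D10M"), self.region)
        assert b.deletion_count == 190
        assert b.values[10:200].all()

    def test_non_overlapping_alignment_is_all_zero(self):
        b = extract_deletion_bitmap(SimpleAlignment(5000, "100M"), self.region)
        assert b.deletion_count == 0

    def test_skip_ops_are_not_deletions(self):
        b = extract_deletion_bitmap(SimpleAlignment(0, "50M100N50M"), self.region)
        assert b.deletion_count == 0

    def test_malformed_cigar_names_the_read(self):
        with pytest.raises(CigarError, match="badread"):
            extract_deletion_bitmap(
                SimpleAlignment(0, "10M5Q", read_name="badread"), self.region)

    def test_oracle_equivalence_random_cases(self):
        """1000 random (CIGAR, offset, window) cases vs a per-base walker."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            ops = random_cigar(rng)
            start = int(rng.integers(0, 800))
            wstart = int(rng.integers(0, 5)) * 200
            region = SubRegion("c", wstart, wstart + 200, wstart // 200)
            got = extract_deletion_bitmap(SimpleAlignment(start, ops), region)
            expect = bitmap_walker(start, ops, wstart, wstart + 200, 200)
            np.testing.assert_array_equal(got.values, expect)

    def test_sum_conservation_across_windows(self):
        """Total deletion count over all windows equals total in-range D bp."""
        rng = np.random.default_rng(7)
        windows = partition_reference({"c": 3000}, 200)
        for _ in range(100):
            ops = random_cigar(rng)
            start = int(rng.integers(0, 1500))
            total = sum(extract_deletion_bitmap(
                SimpleAlignment(start, ops), w).deletion_count
                for w in windows)
            full = bitmap_walker(start, ops, 0, 3000, 3000)
            assert total == int(full.sum())


class TestFeatureMatrix:
    region = SubRegion("chr1", 0, 200, 0)

    def _bitmap(self, count, name):
        v = np.zeros(200, dtype=np.uint8)
        v[:count] = 1
        return DeletionBitmap(v, name)

    def test_sorting_and_padding(self):
        bms = [self._bitmap(c, f"r{i}") for i, c in enumerate([5, 0, 10])]
        fm = build_feature_matrix(bms, self.region, n=18)
        counts = fm.rows.sum(axis=1)
        assert list(counts[:3]) == [10, 5, 0]
        assert counts[3:].sum() == 0 and fm.p == 3

    def test_empty_input(self):
        fm = build_feature_matrix([], self.region, n=18)
        assert fm.rows.shape == (18, 200) and fm.rows.sum() == 0 and fm.p == 0

    def test_truncation_keeps_highest_counts(self):
        bms = [self._bitmap(i % 30, f"r{i:02d}") for i in range(25)]
        fm = build_feature_matrix(bms, self.region, n=18)
        assert fm.p == 25
        expected = sorted((int(b.values.sum()) for b in bms), reverse=True)[:18]
        assert list(fm.rows.sum(axis=1)) == expected

    def test_against_sort_then_slice_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            k = int(rng.integers(0, 30))
            bms = [DeletionBitmap((rng.random(200) < 0.1).astype(np.uint8),
                                  f"r{i:03d}") for i in range(k)]
            fm = build_feature_matrix(bms, self.region, n=18)
            oracle = sort_then_slice([(b.values, b.read_name) for b in bms],
                                     18, 200)
            np.testing.assert_array_equal(fm.rows, oracle)

    def test_deterministic_under_repetition(self):
        rng = np.random.default_rng(5)
        bms = [DeletionBitmap((rng.random(200) < 0.2).astype(np.uint8),
                              f"r{i}") for i in range(10)]
        a = build_feature_matrix(bms, self.region, n=18)
        b = build_feature_matrix(bms, self.region, n=18)
        np.testing.assert_array_equal(a.rows, b.rows)


class TestMakeBatches:
    def _matrices(self, k):
        return [build_feature_matrix([], SubRegion("c", i * 200, (i + 1) * 200, i))
                for i in range(k)]

    def test_padding_arithmetic(self):
        batches = make_batches(self._matrices(250), T=100)
        assert len(batches) == 3
        assert batches[-1].mask.sum() == 50
        assert batches[-1].matrices[50:].sum() == 0

    def test_exact_batch(self):
        batches = make_batches(self._matrices(100), T=100)
        assert len(batches) == 1 and batches[0].mask.all()

    def test_invalid_T(self):
        with pytest.raises(ConfigError):
            make_batches(self._matrices(10), T=0)


def _write_sam(path, records, contig="c", length=2000):
    lines = ["@HD\tVN:1.6\tSO:coordinate", f"@SQ\tSN:{contig}\tLN:{length}"]
    for name, pos, cigar in records:
        lines.append(f"{name}\t0\t{contig}\t{pos + 1}\t60\t{cigar}\t*\t0\t0\t*\t*")
    path.write_text("\n".join(lines) + "\n")
    return path


class TestExtractRegionMatrices:
    def test_read_spanning_three_windows(self, tmp_path):
        """A D op in the middle window leaves zero rows in the others."""
        sam = _write_sam(tmp_path / "a.sam",
                        [("r1", 700, "200M50D550M")], length=2000)
        mats = list(extract_region_matrices(str(sam), "c", 2000, 200, 18))
        assert len(mats) == 10
        nonzero = [i for i, m in enumerate(mats) if m.rows.sum()]
        assert nonzero == [4]  # D op covers [900, 950)
        assert mats[3].p == 1 and mats[4].p == 1  # read contributes rows
        assert mats[0].p == 0

    def test_empty_alignment_file(self, tmp_path):
        sam = _write_sam(tmp_path / "e.sam", [])
        mats = list(extract_region_matrices(str(sam), "c", 1000, 200, 18))
        assert len(mats) == 5 and all(m.rows.sum() == 0 for m in mats)

    def test_two_identical_reads_give_identical_rows(self, tmp_path):
        sam = _write_sam(tmp_path / "d.sam",
                        [("r1", 0, "50M30D120M"), ("r2", 0, "50M30D120M")])
        mats = list(extract_region_matrices(str(sam), "c", 200, 200, 18))
        np.testing.assert_array_equal(mats[0].rows[0], mats[0].rows[1])
        assert mats[0].p == 2

    def test_unsorted_header_rejected(self, tmp_path):
        sam = tmp_path / "u.sam"
        sam.write_text("@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:c\tLN:1000\n")
        with pytest.raises(ValueError, match="sort"):
            list(extract_region_matrices(str(sam), "c", 1000, 200, 18))

    def test_absent_contig_warns_and_zero_fills(self, tmp_path):
        sam = _write_sam(tmp_path / "w.sam", [("r1", 0, "100M")])
        with pytest.warns(UserWarning, match="absent"):
            mats = list(extract_region_matrices(str(sam), "nope", 600, 200, 18))
        assert len(mats) == 3 and all(m.rows.sum() == 0 for m in mats)

    def test_idempotent(self, tmp_path):
        sam = _write_sam(tmp_path / "i.sam",
                        [("r1", 100, "100M40D100M"), ("r2", 350, "200M")],
                        length=1000)
        runs = [list(extract_region_matrices(str(sam), "c", 1000, 200, 18))
                for _ in range(2)]
        for a, b in zip(*runs):
            np.testing.assert_array_equal(a.rows, b.rows)
            assert a.p == b.p


def test_container_round_trip(tmp_path):
    region_rows = []
    rng = np.random.default_rng(0)
    mats = []
    for i in range(7):
        r = SubRegion("c", i * 100, (i + 1) * 100, i)
        bm = DeletionBitmap((rng.random(100) < 0.3).astype(np.uint8), "r")
        mats.append(build_feature_matrix([bm], r, n=4))
    labels = rng.integers(0, 2, 7)
    save_feature_container(tmp_path / "x.features", "c", mats, 100, 4, 5, labels)
    loaded, regions, lab2, sidecar = load_feature_container(tmp_path / "x.features")
    assert sidecar["m"] == 100 and sidecar["n"] == 4 and sidecar["T"] == 5
    np.testing.assert_array_equal(lab2, labels)
    for a, b in zip(mats, loaded):
        np.testing.assert_array_equal(a.rows, b.rows)
        assert (a.region.start, a.region.end) == (b.region.start, b.region.end)
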