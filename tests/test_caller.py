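"""Region merging, signature clustering, breakpoint refinement, VCF output."""

import numpy as np
import pytest

from _oracles import transitive_closure_clusters
from deepdel.caller import (CandidateRegion, DeletionCall, DeletionSignature,
                            cluster_signatures, collect_signatures,
                            read_vcf_calls, refine_call, threshold_and_merge,
                            write_vcf)
from deepdel.features import SubRegion


def _windows(k, m=200):
    return [SubRegion("c", i * m, (i + 1) * m, i) for i in range(k)]


class TestThresholdAndMerge:
    def test_run_of_positive_windows_merges(self):
        scored = list(zip(_windows(4), [0.2, 0.9, 0.8, 0.1]))
        regions = threshold_and_merge(scored)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (200, 600)
        assert regions[0].window_count == 2

    def test_all_below_cutoff(self):
        assert threshold_and_merge(list(zip(_windows(3), [0.1] * 3))) == []

    def test_cutoff_is_strict(self):
        regions = threshold_and_merge(list(zip(_windows(2), [0.5, 0.5001])))
        assert len(regions) == 1 and regions[0].start == 200

    def test_gap_splits_regions(self):
        scored = list(zip(_windows(5), [0.9, 0.2, 0.9, 0.9, 0.2]))
        regions = threshold_and_merge(scored)
        assert [(r.start, r.end) for r in regions] == [(0, 200), (400, 800)]


def _sig(loc, size=50, rid="r"):
    return DeletionSignature(loc, size, rid)


class TestClusterSignatures:
    def test_simple_grouping(self):
        clusters = cluster_signatures([_sig(100), _sig(110), _sig(500)], 40)
        assert [[s.location for s in c] for c in clusters] == [[100, 110], [500]]

    def test_singleton(self):
        assert len(cluster_signatures([_sig(7)], 40)) == 1

    def test_empty(self):
        assert cluster_signatures([], 40) == []

    def test_chained_cluster_under_single_linkage(self):
        """Locations 100/135/170: pairwise 100-170 exceeds the radius but
        the chain links them; single linkage keeps one cluster."""
        clusters = cluster_signatures([_sig(100), _sig(135), _sig(170)], 40)
        assert len(clusters) == 1
        # centroid linkage splits the same chain
        clusters_c = cluster_signatures([_sig(100), _sig(135), _sig(170)], 40,
                                        linkage="centroid")
        assert len(clusters_c) == 2

    def test_invalid_radius_and_linkage(self):
        with pytest.raises(ValueError):
            cluster_signatures([_sig(1)], 0)
        with pytest.raises(ValueError):
            cluster_signatures([_sig(1)], 40, linkage="ward")

    def test_every_signature_in_exactly_one_cluster(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            sigs = [_sig(int(l), rid=f"r{i}") for i, l in
                    enumerate(rng.integers(0, 2000, rng.integers(1, 15)))]
            clusters = cluster_signatures(sigs, 40)
            flat = [s for c in clusters for s in c]
            assert sorted(s.location for s in flat) == \
                sorted(s.location for s in sigs)
            assert len(flat) == len(sigs)

    def test_matches_transitive_closure_on_unambiguous_instances(self):
        """On <=12 signatures the sorted-chaining rule equals brute-force
        transitive closure whenever every closure cluster's end-to-end
        spread stays below the radius."""
        rng = np.random.default_rng(1)
        checked = 0
        for _ in range(500):
            locs = sorted(int(l) for l in
                          rng.integers(0, 1500, int(rng.integers(1, 13))))
            oracle = transitive_closure_clusters(locs, 40)
            if any(locs[g[-1]] - locs[g[0]] >= 40 for g in oracle):
                continue  # ambiguous chain: rule choice matters
            sigs = [_sig(l, rid=f"r{i}") for i, l in enumerate(locs)]
            got = [[s.location for s in c]
                   for c in cluster_signatures(sigs, 40)]
            expect = [[locs[i] for i in g] for g in oracle]
            assert got == expect
            checked += 1
        assert checked > 200


class TestRefineCall:
    region = CandidateRegion("c", 2000, 2400, 2)

    def test_average_of_largest_cluster(self):
        clusters = [[_sig(100, 60), _sig(110, 50)], [_sig(500, 70)]]
        call = refine_call(clusters, self.region)
        assert (call.start, call.size, call.support) == (105, 55, 2)
        assert not call.imprecise

    def test_singleton_cluster(self):
        call = refine_call([[_sig(1000, 80)]], self.region)
        assert (call.start, call.size, call.support) == (1000, 80, 1)

    def test_fallback_imprecise(self):
        call = refine_call([], self.region)
        assert (call.start, call.size, call.support) == (2000, 400, 0)
        assert call.imprecise

    def test_tie_broken_by_smaller_mean_location(self):
        clusters = [[_sig(900, 10), _sig(910, 10)],
                    [_sig(100, 20), _sig(110, 20)]]
        call = refine_call(clusters, self.region)
        assert call.start == 105

    def test_rounding_half_up(self):
        call = refine_call([[_sig(100, 51), _sig(101, 50)]], self.region)
        assert (call.start, call.size) == (101, 51)  # 100.5 and 50.5 round up


class TestCollectSignatures:
    def _bam(self, tmp_path, records, length=5000):
        import pysam
        path = tmp_path / "t.bam"
        header = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": "c", "LN": length}]}
        with pysam.AlignmentFile(str(path), "wb", header=header) as af:
            for name, pos, cigar in sorted(records, key=lambda r: r[1]):
                a = pysam.AlignedSegment(af.header)
                a.query_name = name
                a.reference_id = 0
                a.reference_start = pos
                a.mapping_quality = 60
                a.cigarstring = cigar
                a.flag = 0
                af.write(a)
        pysam.index(str(path))
        return path

    def test_d_op_location_and_size(self, tmp_path):
        bam = self._bam(tmp_path, [("r1", 1000, "100M60D100M")])
        sigs = collect_signatures(CandidateRegion("c", 1000, 1400, 2),
                                  str(bam))
        assert [(s.location, s.size) for s in sigs] == [(1100, 60)]

    def test_small_d_ops_filtered(self, tmp_path):
        bam = self._bam(tmp_path, [("r1", 1000, "100M15D100M")])
        sigs = collect_signatures(CandidateRegion("c", 1000, 1400, 2),
                                  str(bam))
        assert sigs == []

    def test_filter_is_strict_greater_than(self, tmp_path):
        bam = self._bam(tmp_path, [("r1", 1000, "100M20D50M"),
                                   ("r2", 1000, "100M21D50M")])
        sigs = collect_signatures(CandidateRegion("c", 1000, 1400, 2),
                                  str(bam))
        assert [(s.size, s.read_id) for s in sigs] == [(21, "r2")]

    def test_multiple_d_ops_from_one_read(self, tmp_path):
        bam = self._bam(tmp_path, [("r1", 1000, "50M30D50M40D50M")])
        sigs = collect_signatures(CandidateRegion("c", 1000, 1400, 2),
                                  str(bam))
        assert [(s.location, s.size) for s in sigs] == [(1050, 30), (1130, 40)]

    def test_region_with_no_alignments(self, tmp_path):
        bam = self._bam(tmp_path, [("r1", 1000, "100M")])
        sigs = collect_signatures(CandidateRegion("c", 4000, 4400, 2),
                                  str(bam))
        assert sigs == []


class TestWriteVcf:
    def _calls(self):
        region = CandidateRegion("c", 800, 1200, 2)
        return [DeletionCall("c", 999, 100, 12, region)]

    def test_coordinate_conversion(self, tmp_path):
        path = write_vcf(self._calls(), {"c": 10_000}, tmp_path / "o.vcf")
        line = [l for l in path.read_text().splitlines()
                if not l.startswith("#")][0]
        fields = line.split("\t")
        assert fields[0] == "c" and fields[1] == "1000"
        assert "END=1100" in fields[7] and "SVLEN=-100" in fields[7]
        assert "SVTYPE=DEL" in fields[7] and "SUPPORT=12" in fields[7]

    def test_empty_call_list_header_only(self, tmp_path):
        path = write_vcf([], {"c": 1000}, tmp_path / "o.vcf")
        assert all(l.startswith("#") for l in path.read_text().splitlines())

    def test_sub_50bp_calls_dropped(self, tmp_path):
        region = CandidateRegion("c", 100, 300, 1)
        calls = [DeletionCall("c", 100, 49, 3, region),
                 DeletionCall("c", 200, 50, 3, region)]
        path = write_vcf(calls, {"c": 1000}, tmp_path / "o.vcf")
        records = [l for l in path.read_text().splitlines()
                   if not l.startswith("#")]
        assert len(records) == 1 and "SVLEN=-50" in records[0]

    def test_round_trip(self, tmp_path):
        region = CandidateRegion("c", 800, 1200, 2)
        calls = [DeletionCall("c", 999, 100, 12, region),
                 DeletionCall("c", 5000, 321, 0, region, imprecise=True)]
        path = write_vcf(calls, {"c": 10_000}, tmp_path / "o.vcf")
        back = read_vcf_calls(path)
        assert [(c.contig, c.start, c.size, c.support, c.imprecise)
                for c in back] == \
            [("c", 999, 100, 12, False), ("c", 5000, 321, 0, True)]
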