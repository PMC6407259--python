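"""0.5_5 calling rule, strict length filter, CNVR merging vs union-find oracle."""

import numpy as np
import pytest

import arraycnv as ac
from arraycnv.calling import calls_to_frame, cnvrs_to_frame, is_placed_chromosome
from arraycnv.segmentation import Segment


def make_segment(chrom, first, last, mean, spacing=1200):
    return Segment(chrom, first, last, (first + 1) * spacing,
                   (last + 1) * spacing, mean, last - first + 1)


def make_call(sample, chrom, start, end, state="loss"):
    return ac.CnvCall(sample, chrom, start, end, state, -1.0 if state == "loss"
                      else 1.0, 10)


CFG = ac.CallingConfig()


class TestCallCnvs:
    def test_qualifying_gain_segment_called(self):
        segs = [make_segment("chr1", 0, 5, 0.6)]
        (call,) = ac.call_cnvs(segs, CFG, "A")
        assert call.state == "gain"
        assert call.n_probes == 6

    @pytest.mark.parametrize("mean,n_probes", [
        (0.6, 4),    # too few probes
        (0.49, 50),  # below threshold
        (-0.49, 50),
    ])
    def test_non_qualifying_segments_not_called(self, mean, n_probes):
        segs = [make_segment("chr1", 0, n_probes - 1, mean)]
        assert ac.call_cnvs(segs, CFG, "A") == []

    def test_adjacent_same_state_qualifying_segments_merge(self):
        segs = [make_segment("chr1", 0, 5, 0.6),
                make_segment("chr1", 6, 12, 0.9)]
        (call,) = ac.call_cnvs(segs, CFG, "A")
        assert (call.start_bp, call.end_bp) == (1200, 15600)
        assert call.n_probes == 13
        # probe-weighted mean
        assert call.mean_log2 == pytest.approx((0.6 * 6 + 0.9 * 7) / 13)

    def test_subthreshold_gap_is_not_bridged(self):
        segs = [make_segment("chr1", 0, 5, 0.6),
                make_segment("chr1", 6, 10, 0.1),
                make_segment("chr1", 11, 17, 0.7)]
        calls = ac.call_cnvs(segs, CFG, "A")
        assert len(calls) == 2

    def test_opposite_states_do_not_merge(self):
        segs = [make_segment("chr1", 0, 5, 0.6),
                make_segment("chr1", 6, 12, -0.8)]
        calls = ac.call_cnvs(segs, CFG, "A")
        assert [c.state for c in calls] == ["gain", "loss"]

    def test_noiseless_planted_cohort_recovered_exactly(self, noiseless_cohort):
        probes, samples, cnvs, sm = noiseless_cohort
        pos = probes["pos"].to_numpy()
        seg_cfg = ac.SegmentationConfig(penalty=0.26)
        recovered = []
        for j, s in enumerate(sm.samples):
            for chrom in sm.chromosomes:
                idx = sm.chrom_index(chrom)
                segs = ac.segment_profile(sm.values[idx, j], pos[idx],
                                          seg_cfg, chrom=chrom)
                recovered.extend(
                    ac.filter_cnvs(ac.call_cnvs(segs, CFG, s), CFG))
        expected = {
            (c.sample_id, c.chrom, c.start_bp, c.end_bp,
             "loss" if c.copy_number < 2 else "gain")
            for c in cnvs
        }
        got = {(c.sample_id, c.chrom, c.start_bp, c.end_bp, c.state)
               for c in recovered}
        assert got == expected

    def test_calling_plus_filtering_idempotent(self, noiseless_cohort):
        probes, samples, cnvs, sm = noiseless_cohort
        pos = probes["pos"].to_numpy()
        idx = sm.chrom_index("chr1")
        segs = ac.segment_profile(sm.values[idx, 0], pos[idx],
                                  ac.SegmentationConfig(penalty=0.26), "chr1")
        once = ac.filter_cnvs(ac.call_cnvs(segs, CFG, sm.samples[0]), CFG)
        assert ac.filter_cnvs(once, CFG) == once


class TestFilterCnvs:
    @pytest.mark.parametrize("length,kept", [
        (900, False),
        (1_000, False),       # strict bound
        (1_001, True),
        (3_600, True),        # shortest observed event scale
        (2_111_937, True),    # longest observed event scale
        (5_000_000, False),   # strict bound
        (5_500_000, False),
    ])
    def test_strict_length_bounds(self, length, kept):
        call = make_call("A", "chr1", 1_000_000, 1_000_000 + length - 1)
        assert (ac.filter_cnvs([call], CFG) == [call]) is kept


class TestMergeToCnvrs:
    def test_overlapping_losses_union(self):
        calls = [make_call("A", "chr1", 100, 200),
                 make_call("B", "chr1", 150, 300)]
        (r,) = ac.merge_to_cnvrs(calls)
        assert (r.start_bp, r.end_bp, r.state, r.n_samples) == (100, 300,
                                                                "loss", 2)

    def test_bookended_calls_stay_separate(self):
        calls = [make_call("A", "chr1", 100, 200, "gain"),
                 make_call("B", "chr1", 201, 300, "loss")]
        regions = ac.merge_to_cnvrs(calls)
        assert len(regions) == 2

    def test_single_bp_overlap_merges_to_both(self):
        calls = [make_call("A", "chr1", 100, 200, "gain"),
                 make_call("B", "chr1", 200, 300, "loss")]
        (r,) = ac.merge_to_cnvrs(calls)
        assert r.state == "both"

    @staticmethod
    def _random_calls(rng, n=1000):
        calls = []
        for i in range(n):
            chrom = f"chr{rng.integers(1, 4)}"
            start = int(rng.integers(1, 1_000_000))
            length = int(rng.integers(100, 50_000))
            state = "gain" if rng.uniform() < 0.3 else "loss"
            calls.append(make_call(f"S{rng.integers(1, 48)}", chrom, start,
                                   start + length - 1, state))
        return calls

    @staticmethod
    def _union_find_partition(calls):
        """Quadratic all-pairs union-find oracle."""
        parent = list(range(len(calls)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i, j):
            parent[find(i)] = find(j)

        for i in range(len(calls)):
            for j in range(i + 1, len(calls)):
                a, b = calls[i], calls[j]
                if (a.chrom == b.chrom and a.start_bp <= b.end_bp
                        and b.start_bp <= a.end_bp):
                    union(i, j)
        groups = {}
        for i in range(len(calls)):
            groups.setdefault(find(i), set()).add(i)
        return {frozenset(g) for g in groups.values()}

    def test_merging_agrees_with_union_find_oracle(self):
        rng = np.random.default_rng(7)
        calls = self._random_calls(rng, 1000)
        regions = ac.merge_to_cnvrs(calls)
        index = {id(c): i for i, c in enumerate(calls)}
        got = {frozenset(index[id(c)] for c in r.member_calls)
               for r in regions}
        assert got == self._union_find_partition(calls)

    def test_every_call_in_exactly_one_cnvr(self):
        rng = np.random.default_rng(8)
        calls = self._random_calls(rng, 300)
        regions = ac.merge_to_cnvrs(calls)
        assert sum(len(r.member_calls) for r in regions) == len(calls)

    def test_cnvr_spans_never_overlap(self):
        rng = np.random.default_rng(9)
        regions = ac.merge_to_cnvrs(self._random_calls(rng, 500))
        by_chrom = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for rs in by_chrom.values():
            rs.sort(key=lambda r: r.start_bp)
            for a, b in zip(rs, rs[1:]):
                assert a.end_bp < b.start_bp

    def test_state_counts_sum_to_total(self):
        rng = np.random.default_rng(10)
        calls = self._random_calls(rng, 400)
        regions = ac.merge_to_cnvrs(calls)
        summary = ac.summarize_cnvs(calls, regions)
        assert sum(summary["cnvr_state_counts"].values()) == len(regions)


class TestSummaries:
    def test_zero_calls_all_zero_summary(self):
        s = ac.summarize_cnvs([], [], {"chr1": 1000})
        assert s["n_cnvs"] == 0 and s["n_cnvrs"] == 0
        assert s["total_cnvr_bp"] == 0

    def test_summary_matches_truth_recomputation(self, noiseless_cohort):
        probes, samples, cnvs, sm = noiseless_cohort
        calls = [
            ac.CnvCall(c.sample_id, c.chrom, c.start_bp, c.end_bp,
                       "loss" if c.copy_number < 2 else "gain",
                       np.log2(max(c.copy_number, 0.1) / 2), 5)
            for c in cnvs
        ]
        regions = ac.merge_to_cnvrs(calls)
        s = ac.summarize_cnvs(calls, regions,
                              {"chr1": 600_000, "chr2": 600_000})
        assert s["n_cnvs"] == len(cnvs)
        assert s["mean_events_per_sample"] == pytest.approx(
            len(cnvs) / len({c.sample_id for c in cnvs}))
        direct_bp = sum(r.length_bp for r in regions)
        assert s["total_cnvr_bp"] == direct_bp
        assert s["genome_cnvr_fraction"] == pytest.approx(
            direct_bp / 1_200_000)

    def test_unplaced_chromosomes_flagged(self):
        assert not is_placed_chromosome("chrUn")
        assert not is_placed_chromosome("chr1_random")
        assert is_placed_chromosome("chr29")
        assert is_placed_chromosome("chrX")

    def test_frames_have_stable_columns(self):
        calls = [make_call("A", "chr1", 100, 2000)]
        regions = ac.merge_to_cnvrs(calls)
        assert list(calls_to_frame(calls).columns[:4]) == [
            "sample", "chrom", "start_bp", "end_bp"]
        assert list(cnvrs_to_frame(regions).columns[:4]) == [
            "cnvr_id", "chrom", "start_bp", "end_bp"]
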