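"""Segmentation: DP optimality vs exhaustive enumeration, tiling, baselines."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

import arraycnv as ac
from arraycnv.segmentation import segmentation_cost


def brute_force_optimum(x: np.ndarray, penalty: float) -> float:
    """Exhaustive minimum of SSE + penalty*k over all 2^(n-1) segmentations."""
    n = len(x)
    s1 = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def sse(a, b):  # probes a..b-1
        ln = b - a
        return (s2[b] - s2[a]) - (s1[b] - s1[a]) ** 2 / ln

    best = np.inf
    for mask in range(1 << (n - 1)):
        cost, start = penalty, 0
        for i in range(n - 1):
            if (mask >> i) & 1:
                cost += sse(start, i + 1) + penalty
                start = i + 1
        cost += sse(start, n)
        best = min(best, cost)
    return best


class TestSegmentProfile:
    def test_constant_profile_is_one_segment(self):
        x = np.full(25, 0.37)
        segs = ac.segment_profile(x, np.arange(1, 26),
                                  ac.SegmentationConfig(penalty=0.1))
        assert len(segs) == 1
        assert segs[0].mean_log2 == pytest.approx(0.37)
        assert segs[0].n_probes == 25

    @pytest.mark.parametrize("penalty", [0.01, 1.0, 4.9])
    def test_noiseless_step_recovers_break(self, penalty):
        # single-segment SSE of this step is 5.0, so any penalty < 5 splits
        x = np.array([0.0] * 10 + [1.0] * 10)
        segs = ac.segment_profile(x, np.arange(1, 21),
                                  ac.SegmentationConfig(penalty=penalty))
        assert len(segs) == 2
        assert segs[0].last_probe_index == 9
        assert segs[0].mean_log2 == pytest.approx(0.0)
        assert segs[1].mean_log2 == pytest.approx(1.0)

    def test_penalty_of_five_keeps_single_segment(self):
        x = np.array([0.0] * 10 + [1.0] * 10)
        segs = ac.segment_profile(x, np.arange(1, 21),
                                  ac.SegmentationConfig(penalty=5.5))
        assert len(segs) == 1

    def test_dp_matches_exhaustive_enumeration(self):
        """Exact optimality on random short profiles over a 3-value alphabet."""
        rng = np.random.default_rng(42)
        alphabet = np.array([-1.0, 0.0, 0.6])
        for _ in range(60):
            n = int(rng.integers(1, 13))
            x = alphabet[rng.integers(0, 3, n)]
            for penalty in (0.1, 0.5, 1.0):
                segs = ac.segment_profile(x, np.arange(1, n + 1),
                                          ac.SegmentationConfig(penalty=penalty))
                dp_cost = segmentation_cost(x, segs, penalty)
                assert dp_cost == pytest.approx(
                    brute_force_optimum(x, penalty), abs=1e-9
                )

    def test_segments_tile_profile_exactly(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        segs = ac.segment_profile(x, np.arange(1, 201),
                                  ac.SegmentationConfig(penalty=0.5))
        assert segs[0].first_probe_index == 0
        assert segs[-1].last_probe_index == 199
        for a, b in itertools.pairwise(segs):
            assert b.first_probe_index == a.last_probe_index + 1
        assert sum(s.n_probes for s in segs) == 200

    @given(st.integers(0, 2 ** 31 - 1))
    def test_segment_count_non_increasing_in_penalty(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=60) + np.repeat(rng.normal(size=3), 20)
        counts = [
            len(ac.segment_profile(x, np.arange(1, 61),
                                   ac.SegmentationConfig(penalty=p)))
            for p in (0.05, 0.2, 0.8, 3.2)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_missing_probes_dropped_but_tiled(self):
        x = np.array([0.0, np.nan, 0.0, 1.0, 1.0, np.nan])
        segs = ac.segment_profile(x, np.arange(1, 7),
                                  ac.SegmentationConfig(penalty=0.05))
        assert segs[0].first_probe_index == 0
        assert segs[-1].last_probe_index == 5
        assert sum(s.n_probes for s in segs) == 6
        assert segs[0].mean_log2 == pytest.approx(0.0)
        assert segs[-1].mean_log2 == pytest.approx(1.0)

    def test_empty_profile_errors(self):
        with pytest.raises(ValueError, match="empty"):
            ac.segment_profile(np.array([]), np.array([]),
                               ac.SegmentationConfig(penalty=1.0))

    def test_max_segments_cap_is_respected(self):
        x = np.array([0.0] * 5 + [1.0] * 5 + [2.0] * 5)
        segs = ac.segment_profile(
            x, np.arange(1, 16),
            ac.SegmentationConfig(penalty=0.01, max_segments=2),
        )
        assert len(segs) <= 2


class TestNormalization:
    def test_constant_offset_removed(self):
        assert np.allclose(ac.normalize_profile(np.full(10, 0.3)), 0.0)

    def test_median_zero_input_unchanged(self):
        x = np.array([-1.0, 0.0, 1.0])
        assert np.allclose(ac.normalize_profile(x), x)

    def test_shifted_baseline_with_gain_recentred(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.1, 0.05, 1000)  # baseline shifted by +0.1
        x[:100] += 0.585                 # 10% gain
        norm = ac.normalize_profile(x)
        assert abs(np.median(norm[100:])) < 0.01

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            ac.normalize_profile(np.array([np.nan, np.nan]))


class TestChrxShift:
    def test_male_constant_minus_one_becomes_zero(self):
        x = np.full(50, -1.0)
        assert np.allclose(ac.shift_chrx_baseline(x, "male"), 0.0)

    def test_female_identity(self):
        x = np.array([0.1, -0.2, 0.0])
        assert np.array_equal(ac.shift_chrx_baseline(x, "female"), x)

    def test_unknown_sex_errors(self):
        with pytest.raises(ValueError, match="sex"):
            ac.shift_chrx_baseline(np.zeros(3), "unknown")

    def test_nullisomic_segment_stays_most_negative_after_shift(self):
        rng = np.random.default_rng(4)
        x = rng.normal(-1.0, 0.1, 500)   # hemizygous baseline
        x[200:220] = rng.normal(-4.0, 0.1, 20)  # cn=0 at the floor
        shifted = ac.shift_chrx_baseline(x, "male")
        assert shifted[200:220].mean() == pytest.approx(-3.0, abs=0.2)
        assert np.argmin(shifted) in range(200, 220)


class TestPenaltySelection:
    def test_noiseless_two_level_profile_recovers_two_segments(self):
        x = np.array([0.0] * 30 + [1.0] * 30)
        pen = ac.select_penalty(x, (0.1, 0.5, 1.0))
        segs = ac.segment_profile(x, np.arange(1, 61),
                                  ac.SegmentationConfig(penalty=pen))
        assert len(segs) == 2

    def test_pure_noise_rarely_oversegments(self):
        hits = 0
        reps = 20
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            x = rng.normal(0.0, 0.15, 1000)
            segs = ac.segment_profile(x, np.arange(1, 1001),
                                      ac.SegmentationConfig(penalty=None))
            hits += len(segs) == 1
        assert hits / reps >= 0.95

    def test_planted_loss_breakpoints_recovered(self):
        reps, good = 20, 0
        for seed in range(reps):
            rng = np.random.default_rng(100 + seed)
            x = rng.normal(0.0, 0.15, 400)
            x[200:220] += -1.0
            segs = ac.segment_profile(x, np.arange(1, 401),
                                      ac.SegmentationConfig(penalty=None))
            loss = [s for s in segs if s.mean_log2 < -0.5]
            if (len(loss) == 1
                    and abs(loss[0].first_probe_index - 200) <= 2
                    and abs(loss[0].last_probe_index - 219) <= 2):
                good += 1
        assert good / reps >= 0.95

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=300)
        assert ac.select_penalty(x) == ac.select_penalty(x)
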