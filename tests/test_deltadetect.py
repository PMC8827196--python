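"""∆depth, resampled null thresholds, region merging, truth matching — each
checked against small brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deltadepth import deltadetect as dd
from deltadepth.simcov import TruthDeletion
from deltadepth.windows import WindowTrack


def make_track(values, chrom="chr1", w=1, s=1, chrom_length=None):
    values = np.asarray(values, dtype=float)
    starts = np.arange(values.size) * s
    length = chrom_length or int(starts[-1] + w) if values.size else 0
    return WindowTrack(
        chrom=chrom, window_size=w, step=s, starts=starts, values=values,
        chrom_length=length,
    )


class TestDeltaTrack:
    def test_identical_tracks_give_zero(self):
        wt = make_track([1, 1, 1])
        assert dd.delta_track(wt, make_track([1, 1, 1])).values.tolist() == [0, 0, 0]

    def test_deletion_signature_is_positive(self):
        delta = dd.delta_track(make_track([1, 1, 1]), make_track([1, 0, 1]))
        assert delta.values.tolist() == [0, 1, 0]

    def test_mismatched_grids_rejected(self):
        wt = make_track([1, 1, 1], s=1)
        mut = make_track([1, 1, 1], s=2)
        with pytest.raises(ValueError, match="grid"):
            dd.delta_track(wt, mut)


class TestResampleNull:
    def test_degenerate_null_all_zero(self):
        wt = make_track([10.0] * 50)
        thresholds = dd.resample_null({"chr1": wt}, {"chr1": wt}, reps=400, seed=1)
        assert thresholds.q95 == thresholds.q99 == 0.0

    def test_two_point_null_q99_matches_enumeration(self):
        # wt, mut each uniform on {0, 10}: differences are {-10, 0, 10} with
        # probabilities {1/4, 1/2, 1/4}; the nearest-rank 99th percentile of
        # that distribution is 10, and with 4000 draws the empirical top 1%
        # is all 10s with overwhelming probability
        wt = make_track([0.0, 10.0] * 25)
        thresholds = dd.resample_null({"chr1": wt}, {"chr1": wt}, reps=4000, seed=3)
        assert thresholds.q99 == 10.0
        assert thresholds.lower_q01 == -10.0

    def test_quantile_ordering_and_determinism(self, rng):
        wt = make_track(rng.gamma(5, 1, size=200))
        mut = make_track(rng.gamma(5, 1, size=200))
        a = dd.resample_null({"chr1": wt}, {"chr1": mut}, reps=500, seed=9)
        b = dd.resample_null({"chr1": wt}, {"chr1": mut}, reps=500, seed=9)
        assert a == b
        assert a.q99 >= a.q95
        assert a.lower_q01 <= a.lower_q05

    def test_seed_to_seed_spread_within_monte_carlo_error(self, rng):
        # repeat-sampling oracle: the spread of q95 across seeds should match
        # the Monte-Carlo SE of an empirical 95th percentile at reps = 4000
        values = rng.normal(0, 1, size=500)
        wt = make_track(values)
        mut = make_track(rng.normal(0, 1, size=500))
        q95s = [
            dd.resample_null({"chr1": wt}, {"chr1": mut}, reps=4000, seed=s).q95
            for s in range(12)
        ]
        # SE of the 95th percentile of N(0, sqrt(2)) at n=4000 is ~0.06
        assert np.std(q95s) < 3 * 0.06

    def test_exclusion_removes_deletion_windows_from_pool(self):
        values = [1.0] * 98 + [0.0, 0.0]
        wt = make_track([1.0] * 100, w=1, s=1)
        mut = make_track(values, w=1, s=1)
        with_del = dd.resample_null({"chr1": wt}, {"chr1": mut}, reps=4000, seed=2)
        clean = dd.resample_null(
            {"chr1": wt}, {"chr1": mut}, reps=4000, seed=2,
            exclude_intervals=[("chr1", 98, 100)],
        )
        assert with_del.q99 == 1.0
        assert clean.q99 == 0.0

    def test_empty_tracks_rejected(self):
        wt = make_track([1.0])
        with pytest.raises(ValueError):
            dd.resample_null({"chr1": wt}, {"chr1": wt}, reps=10, seed=0)


def naive_merge(values, starts, w, threshold):
    """Brute-force run merge: collect exceeding indices, split on gaps."""
    idx = [i for i, v in enumerate(values) if v > threshold]
    regions = []
    for i in idx:
        if regions and i == regions[-1][-1] + 1:
            regions[-1].append(i)
        else:
            regions.append([i])
    return [(starts[r[0]], starts[r[-1]] + w) for r in regions]


class TestCallRegions:
    def thresholds(self, q95=5.0, q99=5.0):
        return dd.NullThresholds(q95=q95, q99=q99, lower_q05=-q95, lower_q01=-q99,
                                 reps=4000, seed=0)

    def test_adjacent_windows_merge(self):
        delta = dd.delta_track(
            make_track([0, 0, 16, 16, 0], w=1_000_000, s=1_000_000),
            make_track([0, 0, 0, 0, 0], w=1_000_000, s=1_000_000),
        )
        calls = dd.call_exceedance_regions(delta, self.thresholds(), "q99")
        assert [(c.start, c.end) for c in calls] == [(2_000_000, 4_000_000)]
        assert calls[0].n_windows == 2

    def test_all_below_threshold_no_calls(self):
        delta = dd.delta_track(make_track([1, 2, 3]), make_track([0, 0, 0]))
        assert dd.call_exceedance_regions(delta, self.thresholds(), "q99") == []

    def test_separated_peaks_stay_separate(self):
        delta = dd.delta_track(make_track([8, 0, 8]), make_track([0, 0, 0]))
        calls = dd.call_exceedance_regions(delta, self.thresholds(), "q99")
        assert [(c.start, c.end) for c in calls] == [(0, 1), (2, 3)]

    def test_duplication_uses_lower_tail(self):
        delta = dd.delta_track(make_track([0, 0, 0]), make_track([0, 8, 0]))
        calls = dd.call_exceedance_regions(
            delta, self.thresholds(), "q99", direction="duplication"
        )
        assert len(calls) == 1 and calls[0].peak_delta == -8.0

    @settings(derandomize=True, deadline=None, max_examples=60)
    @given(
        values=st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=60),
        threshold=st.floats(-5, 5),
    )
    def test_matches_bruteforce_merge_oracle(self, values, threshold):
        w, s = 3, 2
        delta = dd.delta_track(
            make_track(values, w=w, s=s, chrom_length=len(values) * s + w),
            make_track([0.0] * len(values), w=w, s=s,
                       chrom_length=len(values) * s + w),
        )
        thr = self.thresholds(q99=threshold)
        calls = dd.call_exceedance_regions(delta, thr, "q99")
        expected = naive_merge(values, list(delta.starts), w, threshold)
        assert [(c.start, c.end) for c in calls] == expected


class TestArtifactFilter:
    def call(self, start=0, end=2, direction="deletion"):
        return dd.RegionCall("chr1", start, end, direction, 1.0, float("nan"), 2)

    def test_true_deletion_retained(self):
        mut = make_track([0.02, 0.02, 1.0])
        kept, artifacts = dd.filter_artifact_calls([self.call()], mut)
        assert len(kept) == 1 and not artifacts
        assert kept[0].mean_mutant_depth == pytest.approx(0.02)

    def test_repeat_spike_flagged(self):
        mut = make_track([1.8, 1.8, 1.0])
        kept, artifacts = dd.filter_artifact_calls([self.call()], mut)
        assert not kept and len(artifacts) == 1

    def test_infinite_residual_disables_filter(self):
        mut = make_track([1.8, 1.8, 1.0])
        kept, artifacts = dd.filter_artifact_calls(
            [self.call()], mut, max_residual=float("inf")
        )
        assert len(kept) == 1 and not artifacts

    def test_duplications_pass_through(self):
        mut = make_track([3.0, 3.0, 1.0])
        kept, artifacts = dd.filter_artifact_calls(
            [self.call(direction="duplication")], mut
        )
        assert len(kept) == 1 and not artifacts


def naive_covered_fraction(t_start, t_end, calls):
    """Base-by-base oracle for fractional overlap (small coordinates only)."""
    covered = set()
    for s, e in calls:
        covered.update(range(max(s, t_start), min(e, t_end)))
    return len(covered) / (t_end - t_start)


class TestMatchCallsToTruth:
    def call(self, start, end, chrom="chr1"):
        return dd.RegionCall(chrom, start, end, "deletion", 1.0, 0.0, 1)

    def test_ninety_percent_cover_detected(self):
        truth = [TruthDeletion("chr1", 1_000_000, 2_000_000, 1_000_000)]
        detected, fps = dd.match_calls_to_truth(
            [self.call(1_100_000, 2_050_000)], truth
        )
        assert detected == [True] and fps == []

    def test_partial_overlap_neither_tp_nor_fp(self):
        truth = [TruthDeletion("chr1", 1_000_000, 2_000_000, 1_000_000)]
        detected, fps = dd.match_calls_to_truth(
            [self.call(1_500_000, 1_900_000)], truth
        )
        assert detected == [False] and fps == []

    def test_disjoint_call_is_false_positive(self):
        truth = [TruthDeletion("chr1", 0, 100, 100)]
        detected, fps = dd.match_calls_to_truth([self.call(500, 600)], truth)
        assert detected == [False] and len(fps) == 1

    def test_other_chromosome_call_is_false_positive(self):
        truth = [TruthDeletion("chr1", 0, 100, 100)]
        _, fps = dd.match_calls_to_truth([self.call(0, 100, chrom="chr2")], truth)
        assert len(fps) == 1

    def test_union_of_calls_counts(self):
        truth = [TruthDeletion("chr1", 0, 100, 100)]
        detected, _ = dd.match_calls_to_truth(
            [self.call(0, 45), self.call(50, 100)], truth
        )
        assert detected == [True]  # 95 of 100 bases covered by the union

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            dd.match_calls_to_truth([], [], min_fraction=1.5)

    @settings(derandomize=True, deadline=None, max_examples=60)
    @given(
        truth_iv=st.tuples(st.integers(0, 80), st.integers(1, 40)),
        calls=st.lists(
            st.tuples(st.integers(0, 120), st.integers(1, 40)), max_size=6
        ),
        frac=st.sampled_from([0.5, 0.8, 1.0]),
    )
    def test_matches_interval_arithmetic_oracle(self, truth_iv, calls, frac):
        t_start, t_len = truth_iv
        truth = [TruthDeletion("chr1", t_start, t_start + t_len, t_len)]
        region_calls = [self.call(s, s + ln) for s, ln in calls]
        detected, fps = dd.match_calls_to_truth(region_calls, truth, frac)
        intervals = [(s, s + ln) for s, ln in calls]
        assert detected[0] == (
            naive_covered_fraction(t_start, t_start + t_len, intervals) >= frac
        )
        expected_fps = [
            (s, e) for s, e in intervals
            if naive_covered_fraction(t_start, t_start + t_len, [(s, e)]) == 0
        ]
        assert [(c.start, c.end) for c in fps] == expected_fps
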