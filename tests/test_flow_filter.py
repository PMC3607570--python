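"""Framed / flowwise / quality-window filtering semantics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flowaudit.flow_filter import (
    FilterParams,
    filter_report,
    flowwise_filter,
    framed_filter,
    quality_window_filter,
)
from flowaudit.flowgram_io import Flowgram

S1_FLOWS = [1.91, 0.01, 1.66, 0.10, 0.20, 0.30, 1.05, 0.98]


def clean_flows(n):
    """n flows with values that trigger no criterion (alternating 1/2)."""
    return np.tile([1.0, 2.0, 1.0, 1.0], n // 4)[:n]


def fg_of(values, read_id="r", usable=None):
    return Flowgram(read_id, np.asarray(values, dtype=float), n_usable_flows=usable)


class TestFramed:
    def test_clean_read_retained_untouched(self):
        out, trimmed = framed_filter(fg_of(clean_flows(720)))
        assert out.status == "retained"
        assert out.kept_flows == 720
        assert not out.truncated

    def test_noisy_flow_truncates_to_frame_then_eliminates(self):
        values = clean_flows(720).copy()
        values[101] = 0.60  # frame [100, 104)
        out, trimmed = framed_filter(fg_of(values))
        assert out.status == "eliminated"
        assert out.kept_flows == 100
        assert out.trunc_reason == "noisy_flow"
        assert out.reason == "too_few_flows"
        assert trimmed.n_flows == 100

    def test_low_run_straddling_frames_is_invisible(self):
        # flows 3,4,5 below 0.50 but each frame retains signal: the
        # frame-of-four scan cannot see the run
        out, _ = framed_filter(fg_of(S1_FLOWS, usable=8), FilterParams(min_flows=0, max_flows=720))
        assert not out.truncated
        assert out.status == "retained"

    def test_frame_aligned_low_run_truncates(self):
        values = clean_flows(720).copy()
        values[400:404] = [0.1, 0.2, 0.1, 0.3]
        out, _ = framed_filter(fg_of(values))
        assert out.kept_flows == 400
        assert out.trunc_reason == "no_signal_run"

    def test_large_flow_truncates(self):
        values = clean_flows(720).copy()
        values[500] = 6.50
        out, _ = framed_filter(fg_of(values))
        assert out.status == "retained"
        assert out.kept_flows == 500
        assert out.trunc_reason == "large_flow"

    def test_too_many_flows_truncated_to_ceiling(self):
        out, trimmed = framed_filter(fg_of(clean_flows(800)))
        assert out.kept_flows == 720
        assert out.trunc_reason == "too_many_flows"
        assert trimmed.n_flows == 720

    def test_scan_stops_at_usable_flows(self):
        values = clean_flows(720).copy()
        values[600] = 0.60  # beyond the instrument-called region
        out, _ = framed_filter(fg_of(values, usable=500))
        assert not out.truncated
        assert out.kept_flows == 500

    @given(
        st.lists(st.floats(min_value=0.0, max_value=7.0), min_size=360, max_size=760),
        st.integers(0, 3),
    )
    @settings(max_examples=150, deadline=None)
    def test_truncation_points_are_frame_multiples(self, values, pad):
        values = values[: len(values) - len(values) % 4]
        out, trimmed = framed_filter(fg_of(np.round(values, 2)))
        assert out.kept_flows % 4 == 0 or not out.truncated
        if out.truncated and out.trunc_reason != "too_many_flows":
            assert trimmed.n_flows % 4 == 0


class TestFlowwise:
    def test_straddling_low_run_truncates_immediately_before(self):
        out, trimmed = flowwise_filter(fg_of(S1_FLOWS, usable=8), FilterParams(min_flows=0, max_flows=720))
        assert out.trunc_reason == "no_signal_run"
        assert out.kept_flows == 3
        assert trimmed.n_flows == 3

    @pytest.mark.parametrize("value,triggers", [(0.70, False), (0.69, True), (0.50, True), (0.49, False)])
    def test_noisy_interval_boundaries(self, value, triggers):
        values = clean_flows(400).copy()
        values[200] = value
        out, _ = flowwise_filter(fg_of(values), FilterParams(min_flows=0, max_flows=720))
        assert (out.trunc_reason == "noisy_flow") == triggers

    def test_criterion_one_needs_two_following_low_flows(self):
        values = clean_flows(400).copy()
        values[100] = 0.10
        values[101] = 0.50  # <= 0.50 counts toward the run
        values[102] = 0.20
        out, _ = flowwise_filter(fg_of(values), FilterParams(min_flows=0, max_flows=720))
        assert out.trunc_reason == "no_signal_run"
        assert out.kept_flows == 100

    def test_isolated_low_flow_does_not_truncate(self):
        values = clean_flows(400).copy()
        values[100] = 0.10
        out, _ = flowwise_filter(fg_of(values), FilterParams(min_flows=0, max_flows=720))
        assert not out.truncated

    def test_no_truncate_mode_applies_length_test_only(self):
        short = fg_of(clean_flows(352), usable=350)
        out, trimmed = flowwise_filter(short, FilterParams(), truncate=False)
        assert out.status == "eliminated"
        assert out.reason == "too_few_flows"
        values = clean_flows(400).copy()
        values[200] = 0.60
        out, trimmed = flowwise_filter(fg_of(values), FilterParams(), truncate=True)
        assert out.status == "eliminated"
        out, trimmed = flowwise_filter(fg_of(values), FilterParams(), truncate=False)
        assert out.status == "retained"
        assert trimmed.n_flows == 400

    @given(st.lists(st.floats(min_value=0.0, max_value=7.0), min_size=4, max_size=200))
    @settings(max_examples=200, deadline=None)
    def test_retained_prefix_is_clean(self, values):
        p = FilterParams(min_flows=0, max_flows=10_000)
        fg = fg_of(np.round(values, 2))
        out, trimmed = flowwise_filter(fg, p)
        kept = trimmed.flow_values
        assert not np.any(kept > p.large_flow)
        assert not np.any((kept >= p.noisy_lo) & (kept < p.noisy_hi))
        for i in range(len(kept) - 2):
            assert not (
                kept[i] < p.low_signal and kept[i + 1] <= p.low_signal and kept[i + 2] <= p.low_signal
            )

    @given(st.lists(st.floats(min_value=0.0, max_value=7.0), min_size=8, max_size=200))
    @settings(max_examples=200, deadline=None)
    def test_flowwise_cut_within_frame_of_framed_cut(self, values):
        values = np.round(values[: len(values) - len(values) % 4], 2)
        p = FilterParams(min_flows=0, max_flows=10_000)
        framed_out, _ = framed_filter(fg_of(values), p)
        floww_out, _ = flowwise_filter(fg_of(values), p)
        if framed_out.truncated and floww_out.truncated and framed_out.trunc_reason == floww_out.trunc_reason:
            assert floww_out.kept_flows <= framed_out.kept_flows + 3


class TestMinFlowsMonotonicity:
    @given(st.lists(st.floats(min_value=0.0, max_value=7.0), min_size=40, max_size=200))
    @settings(max_examples=100, deadline=None)
    def test_lowering_min_flows_never_loses_reads(self, values):
        values = np.round(values[: len(values) - len(values) % 4], 2)
        fg = fg_of(values)
        kept = []
        for min_flows in (80, 40, 0):
            out, _ = framed_filter(fg, FilterParams(min_flows=min_flows, max_flows=10_000))
            kept.append(out.status == "retained")
        assert kept == sorted(kept)  # False can only precede True


class TestQualityWindow:
    def test_good_read_untouched(self):
        out, seq = quality_window_filter("A" * 400, [40] * 400)
        assert out.status == "retained"
        assert len(seq) == 400

    def test_window_truncation_matches_direct_scan(self):
        from oracles import sliding_window_cut

        quals = [40] * 200 + [10] * 200
        out, seq = quality_window_filter("A" * 400, quals, window=50, mean_q=25)
        cut = sliding_window_cut(quals, 50, 25)
        assert len(seq) == cut
        assert out.status == ("retained" if cut >= 150 else "eliminated")

    def test_discard_truncated_eliminates(self):
        quals = [40] * 200 + [10] * 200
        out, _ = quality_window_filter("A" * 400, quals, discard_truncated=True)
        assert out.status == "eliminated"

    def test_discard_truncated_is_superset(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(150, 400))
            quals = rng.integers(5, 41, size=n).tolist()
            plain, _ = quality_window_filter("A" * n, quals)
            strict, _ = quality_window_filter("A" * n, quals, discard_truncated=True)
            if plain.status == "eliminated":
                assert strict.status == "eliminated"

    def test_window_longer_than_read_disables_window_test(self):
        out, seq = quality_window_filter("A" * 160, [10] * 160, window=500)
        assert out.status == "retained"

    def test_length_bounds(self):
        out, _ = quality_window_filter("A" * 100, [40] * 100)
        assert out.status == "eliminated" and out.reason == "too_few_flows"
        out, _ = quality_window_filter("A" * 600, [40] * 600)
        assert out.status == "eliminated" and out.reason == "too_many_flows"


class TestFilterReport:
    def test_empty_input_all_zero(self):
        table = filter_report([])
        assert table.loc["total", "total"] == 0

    def test_single_large_flow_elimination_counted_once(self):
        values = clean_flows(720).copy()
        values[40] = 9.0
        out, _ = framed_filter(fg_of(values))
        table = filter_report([out])
        assert table.loc["eliminated", "large_flow"] == 1
        assert table.loc["eliminated", "total"] == 1
        assert table.loc["truncated", "total"] == 0

    def test_partition_of_reads(self, injected_cohort):
        fset, _ = injected_cohort
        outcomes = [flowwise_filter(fg, FilterParams(min_flows=0, max_flows=10_000))[0] for fg in fset]
        table = filter_report(outcomes)
        assert table.loc["total", "total"] == len(fset)

    def test_per_criterion_counts_match_injected_truth(self, injected_cohort):
        fset, truth = injected_cohort
        p = FilterParams(min_flows=0, max_flows=10_000)
        outcomes = [flowwise_filter(fg, p)[0] for fg in fset]
        table = filter_report(outcomes)
        by_event = truth.event.value_counts()
        observed = table.loc["truncated"]
        assert observed["noisy_flow"] == by_event.get("noisy_flow", 0)
        assert observed["large_flow"] == by_event.get("large_flow", 0)
        assert observed["no_signal_run"] == by_event.get("low_run", 0)
        assert table.loc["retained_intact", "intact"] == by_event.get("none", 0)
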