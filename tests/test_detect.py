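import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spanlsci import FluxTrace, detect_inflections, enforce_alternation
from spanlsci.detect import InflectionLabels
from spanlsci.synth import CardiacSimParams, generate_trace

from conftest import make_trace
from oracles import brute_force_inflections


def assert_matches_oracle(values, margin=2):
    labels = detect_inflections(make_trace(values), margin=margin)
    highs, lows, rejected = brute_force_inflections(values, margin)
    assert labels.highs.tolist() == highs
    assert labels.lows.tolist() == lows
    assert labels.rejected.tolist() == rejected


class TestDetectInflections:
    def test_single_clean_peak(self):
        labels = detect_inflections(make_trace([1, 2, 3, 2, 1]), margin=2)
        assert labels.highs.tolist() == [2]
        assert labels.lows.tolist() == []
        assert labels.rejected.tolist() == []

    def test_monotone_trace_has_no_extrema(self):
        labels = detect_inflections(make_trace([1, 2, 3, 4, 5]), margin=2)
        assert labels.highs.size == labels.lows.size == labels.rejected.size == 0

    def test_low_accepted_weak_peak_rejected(self):
        # trough at 2 has full trajectories; the peak at 4 has only one
        # decreasing follower before the trace rises again
        labels = detect_inflections(make_trace([3, 2, 1, 2, 3, 2, 3]), margin=2)
        assert labels.lows.tolist() == [2]
        assert labels.highs.tolist() == []
        assert labels.rejected.tolist() == [4]

    def test_plateau_breaks_trajectory(self):
        # equal neighbours carry no directional evidence
        labels = detect_inflections(make_trace([1, 2, 3, 3, 2, 1, 0]), margin=2)
        assert labels.highs.size == 0

    def test_boundary_indices_never_candidates(self):
        labels = detect_inflections(make_trace([5, 1, 0, 1, 5]), margin=2)
        assert labels.lows.tolist() == [2]
        values = [0, 5, 0, 1, 2, 3]  # peak at 1 is inside the margin band
        labels = detect_inflections(make_trace(values), margin=2)
        assert 1 not in labels.highs and 1 not in labels.rejected

    def test_too_short_trace_reports_minimum(self):
        with pytest.raises(ValueError, match="at least 5"):
            detect_inflections(make_trace([1, 2, 1]), margin=2)

    def test_margin_below_one_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            detect_inflections(make_trace([1, 2, 1]), margin=0)

    def test_skip_initial_excludes_leading_samples(self):
        values = [0, 5, 10, 5, 0, 6, 12, 6, 0]
        full = detect_inflections(make_trace(values), margin=2)
        assert full.highs.tolist() == [2, 6]
        skipped = detect_inflections(make_trace(values), margin=2, skip_initial=30)
        assert skipped.highs.size == 0

    @pytest.mark.parametrize("margin", [1, 2, 3])
    def test_oracle_equivalence_random_uniform(self, rng, margin):
        for _ in range(40):
            n = int(rng.integers(2 * margin + 1, 400))
            assert_matches_oracle(rng.random(n) * 100, margin)

    def test_oracle_equivalence_noisy_pulse_trains(self):
        for seed in range(20):
            params = CardiacSimParams(duration_s=10.0, seed=seed)
            trace, _ = generate_trace(params)
            assert_matches_oracle(trace.values)

    def test_accepted_highs_satisfy_rule_when_rechecked(self, rng):
        v = rng.random(500) * 10
        labels = detect_inflections(make_trace(v), margin=2)
        for i in labels.highs:
            assert v[i - 2] < v[i - 1] < v[i] > v[i + 1] > v[i + 2]
        for i in labels.lows:
            assert v[i - 2] > v[i - 1] > v[i] < v[i + 1] < v[i + 2]

    def test_time_reversal_mirrors_labels(self, rng):
        v = rng.random(300)
        fwd = detect_inflections(make_trace(v), margin=2)
        rev = detect_inflections(make_trace(v[::-1]), margin=2)
        n = len(v)
        assert sorted(n - 1 - rev.highs) == fwd.highs.tolist()
        assert sorted(n - 1 - rev.lows) == fwd.lows.tolist()

    def test_sign_flip_swaps_highs_and_lows(self, rng):
        v = rng.integers(0, 1000, size=300).astype(float)
        flipped = 1000.0 - v  # exact for integer-valued samples
        a = detect_inflections(make_trace(v), margin=2)
        b = detect_inflections(make_trace(flipped), margin=2)
        assert a.highs.tolist() == b.lows.tolist()
        assert a.lows.tolist() == b.highs.tolist()
        assert a.rejected.tolist() == b.rejected.tolist()

    def test_constant_offset_leaves_labels_unchanged(self, rng):
        v = rng.integers(0, 1000, size=300).astype(float)
        a = detect_inflections(make_trace(v), margin=2)
        b = detect_inflections(make_trace(v + 512.0), margin=2)
        assert a.highs.tolist() == b.highs.tolist()
        assert a.lows.tolist() == b.lows.tolist()
        assert a.rejected.tolist() == b.rejected.tolist()


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(min_value=0, max_value=50), min_size=5, max_size=60),
    st.integers(min_value=1, max_value=3),
)
def test_detector_equals_oracle_property(values, margin):
    """Property: vectorised detector and literal rule checker always agree,
    including on traces with ties and plateaus."""
    if len(values) < 2 * margin + 1:
        values = values + [0] * (2 * margin + 1 - len(values))
    assert_matches_oracle([float(x) for x in values], margin)


class TestEnforceAlternation:
    def test_alternating_labels_unchanged(self, two_peak_trace):
        labels = detect_inflections(two_peak_trace, margin=2)
        out = enforce_alternation(labels, two_peak_trace)
        assert out.highs.tolist() == labels.highs.tolist()
        assert out.lows.tolist() == labels.lows.tolist()

    def test_keeps_higher_of_consecutive_highs(self):
        labels = InflectionLabels(
            highs=np.array([10, 14]), lows=np.array([]), rejected=np.array([]),
            margin=2,
        )
        trace = make_trace([0] * 10 + [5.0] + [0] * 3 + [6.0] + [0] * 5)
        out = enforce_alternation(labels, trace)
        assert out.highs.tolist() == [14]

    def test_tie_keeps_earlier_index(self):
        trace = make_trace([0] * 10 + [5.0] + [0] * 3 + [5.0] + [0] * 5)
        labels = InflectionLabels(np.array([10, 14]), np.array([]), np.array([]), 2)
        out = enforce_alternation(labels, trace)
        assert out.highs.tolist() == [10]

    def test_keeps_lower_of_consecutive_lows(self):
        trace = make_trace([9] * 4 + [2.0] + [9] * 3 + [1.0] + [9] * 4)
        labels = InflectionLabels(np.array([]), np.array([4, 8]), np.array([]), 2)
        out = enforce_alternation(labels, trace)
        assert out.lows.tolist() == [8]

    def test_result_alternates_on_noisy_trace(self, rng):
        v = rng.random(600) * 100
        trace = make_trace(v)
        out = enforce_alternation(detect_inflections(trace, margin=2), trace)
        events = sorted(
            [(i, "h") for i in out.highs] + [(i, "l") for i in out.lows]
        )
        kinds = [k for _, k in events]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))


class TestLabelsRoundTrip:
    def test_json_roundtrip(self, tmp_path, two_peak_trace):
        labels = detect_inflections(two_peak_trace, margin=2)
        p = labels.to_json(tmp_path / "labels.json")
        back = InflectionLabels.from_json(p)
        assert back.highs.tolist() == labels.highs.tolist()
        assert back.lows.tolist() == labels.lows.tolist()
        assert back.margin == labels.margin

    def test_high_low_overlap_rejected(self):
        with pytest.raises(ValueError, match="both"):
            InflectionLabels(np.array([3]), np.array([3]), np.array([]), 2)
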