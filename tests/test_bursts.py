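"""Max-Interval burst detection against hand traces and the literal oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from meaburst.bursts import (BurstParams, burst_spike_mask, detect_bursts,
                             detect_bursts_bruteforce)

from conftest import make_train


def spans(bursts):
    return [(b.first_spike_index, b.last_spike_index) for b in bursts]


class TestHandTraces:
    def test_single_uniform_burst(self, uniform_burst_train):
        # 10 spikes, ISI 0.05: opens at spike 0, extends to the end
        (b,) = detect_bursts(uniform_burst_train)
        assert b.n_spikes == 10
        assert b.duration == pytest.approx(0.45)
        assert (b.first_spike_index, b.last_spike_index) == (0, 9)

    def test_nine_spikes_fail_min_spikes(self):
        assert detect_bursts(make_train(np.arange(9) * 0.05)) == []

    def test_tonic_train_no_candidates(self):
        assert detect_bursts(make_train(np.arange(20) * 1.0)) == []

    def test_two_runs_merge_across_short_gap(self):
        # 0.30 s gap: > max_end_isi splits in phase 1, < min_ibi merges
        run1 = np.arange(10) * 0.05
        run2 = run1[-1] + 0.30 + np.arange(10) * 0.05
        (b,) = detect_bursts(make_train(np.concatenate([run1, run2])))
        assert b.n_spikes == 20
        assert b.start_time == 0.0 and b.end_time == pytest.approx(1.20)

    def test_fragments_merge_into_retained_burst(self):
        # two 6-spike fragments, each below min_spikes, merge to 12 spikes;
        # filter-first would discard both
        run1 = np.arange(6) * 0.05
        run2 = run1[-1] + 0.30 + np.arange(6) * 0.05
        train = make_train(np.concatenate([run1, run2]))
        assert len(detect_bursts(train)) == 1
        alt = BurstParams(merge_order="filter_then_merge")
        assert detect_bursts(train, alt) == []

    def test_closed_candidate_does_not_reopen(self):
        # gap of 0.6 s (>= min_ibi): second run is a separate burst
        run1 = np.arange(10) * 0.05
        run2 = run1[-1] + 0.6 + np.arange(10) * 0.05
        out = detect_bursts(make_train(np.concatenate([run1, run2])))
        assert spans(out) == [(0, 9), (10, 19)]

    def test_empty_and_single_spike_trains(self):
        assert detect_bursts(make_train([])) == []
        assert detect_bursts(make_train([1.0])) == []


def random_train(rng, n_spikes):
    # mixture of short and long ISIs so bursts actually occur
    isis = np.where(rng.random(n_spikes) < 0.6,
                    rng.uniform(0.01, 0.25, n_spikes),
                    rng.uniform(0.25, 2.0, n_spikes))
    times = np.cumsum(isis)
    return make_train(times, duration=float(times[-1]) + 1.0)


def random_params(rng):
    begin = rng.uniform(0.02, 0.3)
    return BurstParams(
        max_begin_isi=begin,
        max_end_isi=begin + rng.uniform(0.0, 0.3),
        min_ibi=rng.uniform(0.05, 1.0),
        min_duration=rng.uniform(0.01, 0.3),
        min_spikes=int(rng.integers(2, 12)),
        merge_order=str(rng.choice(["merge_then_filter", "filter_then_merge"])),
    )


class TestOracleEquivalence:
    def test_oracle_agrees_on_hand_traces(self, uniform_burst_train):
        for train in (uniform_burst_train,
                      make_train(np.arange(9) * 0.05),
                      make_train(np.arange(20) * 1.0),
                      make_train([])):
            assert spans(detect_bursts(train)) == \
                spans(detect_bursts_bruteforce(train))

    def test_equivalence_on_random_trains_and_params(self, rng):
        for _ in range(500):
            train = random_train(rng, int(rng.integers(5, 101)))
            params = random_params(rng)
            assert spans(detect_bursts(train, params)) == \
                spans(detect_bursts_bruteforce(train, params)), (
                    train.spike_times.tolist(), params)


@st.composite
def isi_trains(draw):
    isis = draw(st.lists(st.floats(0.005, 3.0, allow_nan=False), min_size=1,
                         max_size=60))
    times = np.cumsum(np.asarray(isis))
    return make_train(times, duration=float(times[-1]) + 1.0)


class TestProperties:
    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(isi_trains())
    def test_hypothesis_oracle_equivalence(self, train):
        assert spans(detect_bursts(train)) == \
            spans(detect_bursts_bruteforce(train))

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(isi_trains(), st.floats(0.1, 100.0))
    def test_translation_invariance(self, train, shift):
        shifted = make_train(train.spike_times + shift,
                             duration=train.epoch_duration + shift)
        orig = detect_bursts(train)
        moved = detect_bursts(shifted)
        assert spans(orig) == spans(moved)
        for a, b in zip(orig, moved):
            assert b.start_time == pytest.approx(a.start_time + shift)
            assert b.end_time == pytest.approx(a.end_time + shift)

    def test_monotonic_in_min_spikes_and_duration(self, rng):
        # relaxing min_spikes / min_duration never removes a returned burst
        for _ in range(50):
            train = random_train(rng, 80)
            base = BurstParams(min_spikes=10, min_duration=0.1)
            relaxed = BurstParams(min_spikes=5, min_duration=0.02)
            strict_spans = set(spans(detect_bursts(train, base)))
            relaxed_spans = set(spans(detect_bursts(train, relaxed)))
            assert strict_spans <= relaxed_spans

    def test_burst_membership_idempotent(self, rng):
        for _ in range(50):
            train = random_train(rng, 100)
            for b in detect_bursts(train):
                sub = make_train(
                    train.spike_times[b.first_spike_index:b.last_spike_index + 1],
                    duration=train.epoch_duration)
                (again,) = detect_bursts(sub)
                assert again.n_spikes == b.n_spikes
                assert again.duration == pytest.approx(b.duration)

    def test_returned_bursts_disjoint_and_separated(self, rng):
        params = BurstParams()
        for _ in range(100):
            train = random_train(rng, 100)
            out = detect_bursts(train, params)
            mask = burst_spike_mask(train, out)
            assert sum(b.n_spikes for b in out) == mask.sum()  # disjoint
            for a, b in zip(out, out[1:]):
                assert b.start_time - a.end_time >= params.min_ibi


class TestParamValidation:
    def test_begin_exceeding_end_rejected(self):
        with pytest.raises(ValueError):
            BurstParams(max_begin_isi=0.3, max_end_isi=0.2)

    def test_min_spikes_floor(self):
        with pytest.raises(ValueError):
            BurstParams(min_spikes=1)
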