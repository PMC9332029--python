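import random

import pytest
from hypothesis import given, settings, strategies as st

from scqmon import (
    Behavior,
    BehaviorEvent,
    SCQState,
    StatusSample,
    behavior_index_trace,
    make_config,
    run_scq,
    scq_step,
)
from scqmon.scq import (
    QUEUE_BEHAVIOR,
    SCQConfigError,
    STATUS_TO_QUEUE,
    dedupe_events,
    read_events,
    write_events,
)

STATUS_CODES = (1, 0, -1, -2)


def samples(statuses, R=15.0):
    return [StatusSample(i, i / R, s, None if s == -2 else (0.0, 0.0)) for i, s in enumerate(statuses)]


def window_oracle(statuses, cfg):
    """Brute-force reference: the buffer is literally the last
    min(M, since-flush) statuses; queue j holds the ones equal to its
    status code. Returns (events, occupancy history after each step)."""
    window = []
    events = []
    occ_hist = []
    for i, s in enumerate(statuses):
        window.append(s)
        if len(window) > cfg.M:
            window.pop(0)
        occ = [window.count(code) for code in STATUS_CODES]
        j = STATUS_TO_QUEUE[s]
        if occ[j] == cfg.L[j]:
            events.append((i, QUEUE_BEHAVIOR[j]))
            window = []
            occ = [0, 0, 0, 0]
        occ_hist.append(tuple(occ))
    return events, occ_hist


class TestMakeConfig:
    def test_reference_operating_point(self):
        cfg = make_config(R=15, T=1.0, L=(15, 15, 15, 15))
        assert cfg.M == 15

    def test_window_from_rate_and_slot(self):
        assert make_config(R=30, T=0.5, L=(15, 15, 15, 15)).M == 15

    def test_window_exceeding_capacity_rejected(self):
        with pytest.raises(SCQConfigError, match="capacity"):
            make_config(R=15, T=2.0, L=(5, 5, 5, 5))

    def test_window_below_longest_queue_rejected(self):
        with pytest.raises(SCQConfigError, match="longest"):
            make_config(R=5, T=1.0, L=(15, 2, 2, 2))

    def test_queue_lengths_at_least_one(self):
        with pytest.raises(SCQConfigError):
            make_config(R=15, T=1.0, L=(15, 0, 15, 15))


class TestScqStep:
    def test_uniform_stream_emits_exactly_at_queue_length(self):
        cfg = make_config(R=15, T=1.0)
        state = SCQState()
        events = []
        for s in samples([1] * 15):
            e = scq_step(state, s, cfg)
            if e:
                events.append(e)
        assert [(e.behavior, e.frame_index) for e in events] == [(Behavior.OFF_BED, 14)]

    def test_alternating_statuses_never_fill_a_queue(self):
        cfg = make_config(R=15, T=1.0)
        stream = [1, 0] * 30
        assert run_scq(samples(stream), cfg) == ()

    def test_queues_empty_after_event(self):
        cfg = make_config(R=15, T=1.0)
        state = SCQState()
        for s in samples([-1] * 15):
            e = scq_step(state, s, cfg)
        assert e is not None
        assert state.total_buffered == 0
        assert state.occupancy() == (0, 0, 0, 0)

    def test_single_no_box_sample_buffers_without_event(self):
        cfg = make_config(R=15, T=1.0)
        state = SCQState()
        assert scq_step(state, samples([-2])[0], cfg) is None
        assert state.occupancy() == (0, 0, 0, 1)

    def test_unknown_status_rejected(self):
        cfg = make_config(R=15, T=1.0)
        sample = StatusSample(0, 0.0, 0, (0.0, 0.0))
        object.__setattr__(sample, "status", 7)
        with pytest.raises(ValueError, match="unknown status"):
            scq_step(SCQState(), sample, cfg)


class TestRunScq:
    def test_on_bed_then_off_bed_sequence(self):
        cfg = make_config(R=15, T=1.0)
        events = run_scq(samples([0] * 15 + [1] * 15), cfg)
        assert [(e.behavior, e.frame_index) for e in events] == [
            (Behavior.ON_BED, 14),
            (Behavior.OFF_BED, 29),
        ]

    def test_all_missing_stream_recognizes_nobody(self):
        cfg = make_config(R=15, T=1.0)
        events = run_scq(samples([-2] * 15), cfg)
        assert [(e.behavior, e.frame_index) for e in events] == [(Behavior.NOBODY, 14)]

    def test_empty_stream(self):
        assert run_scq([], make_config(R=15, T=1.0)) == ()

    def test_event_timestamp_is_completing_sample(self):
        cfg = make_config(R=15, T=1.0)
        events = run_scq(samples([1] * 15, R=15.0), cfg)
        assert events[0].time_s == pytest.approx(14 / 15.0)

    @pytest.mark.parametrize("code,behavior", list(zip(STATUS_CODES, QUEUE_BEHAVIOR)))
    def test_minimum_latency_is_queue_length(self, code, behavior):
        """From empty, behavior j appears after exactly L_j uniform
        statuses — 1.0 s at 15 fps with L_j = 15 — and never earlier."""
        cfg = make_config(R=15, T=1.0)
        assert run_scq(samples([code] * 14), cfg) == ()
        events = run_scq(samples([code] * 15), cfg)
        assert len(events) == 1 and events[0].behavior == behavior
        assert events[0].time_s - 0.0 == pytest.approx(14 / 15.0)

    def test_sustained_stream_reemits_every_queue_length(self):
        cfg = make_config(R=15, T=1.0)
        events = run_scq(samples([0] * 45), cfg)
        assert [e.frame_index for e in events] == [14, 29, 44]
        assert dedupe_events(events)[0].frame_index == 14
        assert len(dedupe_events(events)) == 1


class TestWindowEquivalence:
    """The queue occupancies must equal literal last-M-window counts at
    every step, for any configuration and stream."""

    def check_stream(self, statuses, cfg):
        state = SCQState()
        expected_events, expected_occ = window_oracle(statuses, cfg)
        got_events = []
        for i, s in enumerate(samples(statuses)):
            e = scq_step(state, s, cfg)
            if e is not None:
                got_events.append((i, e.behavior))
                assert state.total_buffered == 0  # flush correctness
            assert state.occupancy() == expected_occ[i]
            assert state.total_buffered <= cfg.M
            assert all(n <= L for n, L in zip(state.occupancy(), cfg.L))
        assert got_events == expected_events

    @given(data=st.data())
    @settings(derandomize=True, max_examples=300, deadline=None)
    def test_random_streams_and_configs(self, data):
        L = tuple(data.draw(st.integers(1, 8), label=f"L{j}") for j in range(4))
        M = data.draw(st.integers(max(L), sum(L)), label="M")
        cfg = make_config(R=float(M), T=1.0, L=L)
        statuses = data.draw(
            st.lists(st.sampled_from(STATUS_CODES), min_size=0, max_size=80)
        )
        self.check_stream(statuses, cfg)

    def test_reference_config_long_streams(self):
        cfg = make_config(R=15, T=1.0)
        rng = random.Random(42)
        for _ in range(200):
            statuses = [rng.choice(STATUS_CODES) for _ in range(120)]
            self.check_stream(statuses, cfg)

    def test_pure_window_sum_forms(self):
        """With M = L_j, an event for behavior j fires iff the last M
        statuses are uniformly j, which makes the per-behavior sum
        identities hold exactly on the triggering window."""
        cfg = make_config(R=15, T=1.0)
        forms = {
            Behavior.OFF_BED: lambda w: sum(w),
            Behavior.ON_BED: lambda w: sum(1 - s for s in w),
            Behavior.RETURN: lambda w: sum(-s for s in w),
            Behavior.NOBODY: lambda w: sum(-s / 2 for s in w),
        }
        rng = random.Random(1)
        checked = 0
        for _ in range(100):
            statuses = []
            # biased runs so events actually occur
            while len(statuses) < 200:
                statuses.extend([rng.choice(STATUS_CODES)] * rng.randint(1, 20))
            window = []
            state = SCQState()
            for i, s in enumerate(samples(statuses)):
                window.append(s.status)
                window = window[-cfg.M:]
                e = scq_step(state, s, cfg)
                if e is not None:
                    j = QUEUE_BEHAVIOR.index(e.behavior)
                    assert forms[e.behavior](window) == cfg.L[j]
                    assert len(set(window)) == 1  # uniform window
                    window = []
                    checked += 1
        assert checked > 50


class TestBehaviorIndexTrace:
    def test_step_function(self):
        events = [BehaviorEvent(Behavior.OFF_BED, 10, 10 / 15)]
        idx = behavior_index_trace(events, 20)
        assert idx[:10] == [0] * 10
        assert idx[10:] == [1] * 10

    def test_no_events_default_on_bed(self):
        assert behavior_index_trace([], 5) == [0] * 5

    def test_piecewise_sequence(self):
        events = [
            BehaviorEvent(Behavior.OFF_BED, 10, 0.0),
            BehaviorEvent(Behavior.RETURN, 15, 0.0),
            BehaviorEvent(Behavior.ON_BED, 18, 0.0),
        ]
        idx = behavior_index_trace(events, 20)
        assert idx == [0] * 10 + [1] * 5 + [-1] * 3 + [0] * 2

    def test_event_outside_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            behavior_index_trace([BehaviorEvent(Behavior.NOBODY, 20, 0.0)], 20)


def test_events_file_round_trip(tmp_path):
    events = (
        BehaviorEvent(Behavior.ON_BED, 14, 14 / 15),
        BehaviorEvent(Behavior.OFF_BED, 29, 29 / 15),
    )
    p = tmp_path / "events.csv"
    write_events(events, p)
    assert read_events(p) == events
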