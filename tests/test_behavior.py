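import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import naive_alternations, naive_score_gonogo
from linedrift.behavior import (
    Event,
    EventLog,
    apply_exclusions,
    evaluate_training,
    read_event_log,
    score_gonogo_session,
    score_rotarod,
    score_ymaze,
    write_event_log,
)
from linedrift.errors import EventLogError, InsufficientDataError
from linedrift.synthetic import BehaviorParams, simulate_gonogo_session


def perfect_log(n_go=30, n_nogo=30, latency=1.2):
    """Hand-built session: a poke `latency` s after every go cue, nothing else."""
    events = []
    t = 0.0
    types = (
        ["go", "nogo"] * n_go if n_go == n_nogo
        else ["go"] * n_go + ["nogo"] * n_nogo
    )
    for typ in types:
        events.append(Event(t, "precue_start"))
        cue_on = t + 4.0
        events.append(Event(cue_on, "cue_on", typ))
        if typ == "go":
            events.append(Event(cue_on + latency, "poke", "cue_recess"))
        events.append(Event(cue_on + 5.0, "cue_off"))
        events.append(Event(cue_on + 5.0, "iti_start"))
        t = cue_on + 15.0
    events.append(Event(t, "session_end"))
    return EventLog(events)


def test_perfect_responder_scores_all_hits():
    score = score_gonogo_session(perfect_log())
    assert score.hits == 30
    assert score.false_alarms == 0
    assert score.hit_latency_mean == pytest.approx(1.2)
    assert score.fa_latency_mean is None
    assert score.reinforcers == 60  # 30 hits + 30 correct rejections
    assert score.total_pokes == 30
    # raw uncapped ratio: reinforcers can exceed pokes
    assert score.efficiency == pytest.approx(200.0)


def test_zero_poke_session_has_null_efficiency():
    score = score_gonogo_session(_silent())
    assert score.hits == 0 and score.false_alarms == 0
    assert score.reinforcers == 30  # all no-go trials correct
    assert score.efficiency is None
    assert score.hit_latency_mean is None


def _silent():
    log = perfect_log()
    return EventLog([e for e in log.events if e.kind != "poke"])


def test_malformed_trial_structure_rejected():
    with pytest.raises(EventLogError):
        EventLog([Event(1.0, "poke", "cue_recess"), Event(0.5, "cue_on", "go")])
    with pytest.raises(EventLogError):
        score_gonogo_session(
            EventLog([Event(0.0, "precue_start"), Event(3.0, "cue_on", "go")])
        )


def test_scorer_matches_naive_oracle_on_random_sessions():
    rng = np.random.default_rng(1234)
    for k in range(200):
        params = BehaviorParams(
            p_hit=float(rng.uniform(0, 1)),
            p_fa=float(rng.uniform(0, 1)),
            background_poke_rate=float(rng.uniform(0, 0.2)),
            n_go=int(rng.integers(5, 31)),
            n_nogo=int(rng.integers(5, 31)),
            seed=int(rng.integers(0, 2**31)),
        )
        log = simulate_gonogo_session(params)
        score = score_gonogo_session(log)
        oracle = naive_score_gonogo(log)
        for field, expected in oracle.items():
            got = getattr(score, field)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected), field


def test_session_counts_partition_trials():
    rng = np.random.default_rng(5)
    for _ in range(20):
        params = BehaviorParams(
            p_hit=float(rng.uniform(0, 1)),
            p_fa=float(rng.uniform(0, 1)),
            background_poke_rate=0.1,
            seed=int(rng.integers(0, 2**31)),
        )
        s = score_gonogo_session(simulate_gonogo_session(params))
        assert 0 <= s.hits <= s.n_go
        assert 0 <= s.false_alarms <= s.n_nogo
        assert s.reinforcers == s.hits + (s.n_nogo - s.false_alarms)
        if s.hit_latency_mean is not None:
            assert 0 < s.hit_latency_mean <= 5.0


@pytest.mark.parametrize(
    "daily, passed, day",
    [
        ([(30, 35), (30, 38)], True, 2),
        ([(30, 41), (30, 39)], False, None),
        ([(30, 39), (12, 39), (30, 39)], False, None),
        ([(10, 30), (30, 39), (31, 20)], True, 3),
    ],
)
def test_training_criterion_two_consecutive_fast_days(daily, passed, day):
    outcome = evaluate_training(daily)
    assert outcome.passed is passed
    assert outcome.day_passed == day


def _score_with(reinforcers):
    return dataclasses.replace(
        score_gonogo_session(_silent()), reinforcers=reinforcers
    )


def test_exclusion_on_uncollected_rewards():
    ok = apply_exclusions([_score_with(12), _score_with(8)], [5, 3])
    assert ok.included
    bad = apply_exclusions([_score_with(12), _score_with(8)], [5, 0])
    assert not bad.included
    assert "session_2" in bad.reason
    none_earned = apply_exclusions([_score_with(0)], [0])
    assert none_earned.included
    with pytest.raises(ValueError):
        apply_exclusions([_score_with(1)], [1, 1])


def test_exclusions_catch_planted_violators():
    rng = np.random.default_rng(77)
    planted = {3, 11}
    decisions = []
    for animal in range(15):
        scores = [_score_with(int(rng.integers(1, 20))) for _ in range(4)]
        collected = [int(rng.integers(1, 10)) for _ in range(4)]
        if animal in planted:
            collected[int(rng.integers(0, 4))] = 0
        decisions.append(apply_exclusions(scores, collected).included)
    assert {i for i, inc in enumerate(decisions) if not inc} == planted


def test_ymaze_perfect_and_zero_alternation():
    perfect = score_ymaze(list("ABCABC"))
    assert (perfect.entries, perfect.alternations) == (6, 4)
    assert perfect.percent_alternation == pytest.approx(100.0)
    none = score_ymaze(list("ABABA"))
    assert none.alternations == 0
    assert none.percent_alternation == pytest.approx(0.0)


def test_ymaze_short_sequences_and_bad_labels():
    assert score_ymaze(["A", "B"]).percent_alternation is None
    with pytest.raises(ValueError):
        score_ymaze(["A", "D"])
    with pytest.raises(ValueError):
        score_ymaze(["A", "A", "B"])


@given(st.lists(st.sampled_from("ABC"), min_size=0, max_size=64))
def test_ymaze_matches_sliding_window_oracle(raw):
    seq = [a for k, a in enumerate(raw) if k == 0 or a != raw[k - 1]]
    score = score_ymaze(seq)
    assert score.alternations == naive_alternations(seq)
    if score.percent_alternation is not None:
        assert 0.0 <= score.percent_alternation <= 100.0
        assert score.alternations <= max(score.entries - 2, 0)


def test_rotarod_day_summaries_and_slip_replacement():
    days = {1: [(10, False), (20, False), (30, False), (40, False)]}
    (day,) = score_rotarod(days)
    assert (day.mean_latency, day.max_latency) == (25.0, 40.0)

    slippy = {1: [(1, False), (20, False), (30, False), (40, False), (25, True)]}
    (day,) = score_rotarod(slippy, slip_threshold=5.0)
    assert day.mean_latency == pytest.approx(28.75)
    assert day.n_slips_replaced == 1

    flat = {2: [(7.0, False)] * 4}
    (day,) = score_rotarod(flat)
    assert day.mean_latency == day.max_latency == 7.0

    with pytest.raises(InsufficientDataError):
        score_rotarod({1: [(10, False)] * 3})


def test_event_log_csv_round_trip(tmp_path):
    log = simulate_gonogo_session(BehaviorParams(seed=99))
    path = tmp_path / "log.csv"
    write_event_log(log, path)
    back = read_event_log(path)
    assert back.events == log.events
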