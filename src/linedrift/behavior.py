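"""Scoring of raw behavioral records into per-session endpoints.

Covers three assays used to phenotype hyperactive/impulsive mice:

* **Go/No-go** operant sessions (motor impulsivity): hits, false alarms,
  response latencies, precue responses, cue-side pokes, reinforcers and
  efficiency, scored from a time-stamped event log.
* **Y-maze** spontaneous alternation (attention/working memory): an
  alternation is a run of three consecutive entries into three distinct
  arms; percent alternation uses the ``entries - 2`` sliding-window
  denominator.
* **Rotarod** (motor coordination): per-day mean and maximum fall latency
  over 4 trials, with rapid slip trials replaced by supplied extra trials.

Event-log poke categorisation is strict one-poke-one-category: a cue-recess
poke falling in a cue window is a cue response (only the first per trial is
the hit/false alarm); otherwise, if it falls in the last seconds of a precue
period it is a precue response; any other cue-recess poke outside cue
windows is a cue-side poke.  Center-recess pokes count only toward the
efficiency denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EventLogError, InsufficientDataError

__all__ = [
    "Event",
    "EventLog",
    "SessionScore",
    "YMazeScore",
    "RotarodDay",
    "score_gonogo_session",
    "evaluate_training",
    "apply_exclusions",
    "InclusionDecision",
    "score_ymaze",
    "score_rotarod",
    "read_event_log",
    "write_event_log",
    "read_arm_sequence",
    "write_arm_sequence",
    "read_rotarod_table",
    "PRECUE_RESPONSE_WINDOW",
]

EVENT_KINDS = {
    "precue_start",
    "cue_on",
    "cue_off",
    "poke",
    "reward",
    "iti_start",
    "session_end",
}
#: pokes within this many final seconds of a precue period are "precue responses"
PRECUE_RESPONSE_WINDOW = 3.0


class Event(NamedTuple):
    t: float
    kind: str
    detail: str = ""


@dataclass
class EventLog:
    """A single operant session as a time-ordered event stream.

    ``detail`` carries the trial type (``go``/``nogo``) for ``cue_on`` and
    the poke location (``cue_recess``/``center_recess``) for ``poke``.
    """

    events: list[Event]
    animal_id: str = ""
    day: int = 0
    phase: str = "gonogo"
    protocol_version: str = "V1"

    def __post_init__(self) -> None:
        times = [e.t for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise EventLogError("event times must be non-decreasing")
        for e in self.events:
            if e.kind not in EVENT_KINDS:
                raise EventLogError(f"unknown event kind {e.kind!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["t_seconds", "kind", "detail"])


@dataclass(frozen=True)
class SessionScore:
    """Endpoint summary of one Go/No-go session.

    ``efficiency`` is the raw percentage 100 * reinforcers / total_pokes —
    deliberately uncapped (a session with few pokes and many correct
    rejections legitimately exceeds 100) and None when no pokes occurred.
    """

    hits: int
    false_alarms: int
    hit_latency_mean: Optional[float]
    fa_latency_mean: Optional[float]
    precue_responses: int
    cue_side_pokes: int
    reinforcers: int
    total_pokes: int
    efficiency: Optional[float]
    n_go: int = 30
    n_nogo: int = 30


@dataclass(frozen=True)
class YMazeScore:
    entries: int
    alternations: int
    percent_alternation: Optional[float]


def _trial_windows(log: EventLog):
    """Extract (precue, cue) windows from the stream; validate pairing."""
    precue_start = None
    cue_open = None  # (t_on, trial_type)
    trials = []  # dicts: precue (t0,t1), cue (t0,t1), type
    for e in log.events:
        if e.kind == "precue_start":
            precue_start = e.t
        elif e.kind == "cue_on":
            if cue_open is not None:
                raise EventLogError("overlapping cue periods")
            if e.detail not in ("go", "nogo"):
                raise EventLogError(f"cue_on needs go/nogo detail, got {e.detail!r}")
            cue_open = (e.t, e.detail)
            if precue_start is None:
                raise EventLogError("cue_on without a preceding precue_start")
        elif e.kind == "cue_off":
            if cue_open is None:
                raise EventLogError("cue_off without matching cue_on")
            t_on, trial_type = cue_open
            trials.append(
                {
                    "precue": (precue_start, t_on),
                    "cue": (t_on, e.t),
                    "type": trial_type,
                }
            )
            cue_open = None
            precue_start = None
    if cue_open is not None:
        raise EventLogError("cue_on without matching cue_off")
    return trials


def score_gonogo_session(log: EventLog) -> SessionScore:
    """Score one Go/No-go session from its event log.

    A hit is the first cue-recess poke inside a go cue window (latency =
    poke time - cue onset); a false alarm is the first such poke inside a
    no-go window.  Reinforcers = hits + correct rejections.  Latency means
    are over responded trials only (None when no responses).
    """
    trials = _trial_windows(log)
    pokes = [e for e in log.events if e.kind == "poke"]
    for p in pokes:
        if p.detail not in ("cue_recess", "center_recess"):
            raise EventLogError(f"poke needs a recess location, got {p.detail!r}")

    n_go = sum(1 for tr in trials if tr["type"] == "go")
    n_nogo = len(trials) - n_go

    hits = 0
    fas = 0
    hit_latencies: list[float] = []
    fa_latencies: list[float] = []
    precue_responses = 0
    cue_side_pokes = 0
    responded = [False] * len(trials)

    for p in pokes:
        if p.detail != "cue_recess":
            continue  # center pokes only count toward total_pokes
        category = "cue_side"
        for k, tr in enumerate(trials):
            c0, c1 = tr["cue"]
            if c0 <= p.t < c1:
                if not responded[k]:
                    responded[k] = True
                    if tr["type"] == "go":
                        hits += 1
                        hit_latencies.append(p.t - c0)
                    else:
                        fas += 1
                        fa_latencies.append(p.t - c0)
                category = "cue_window"
                break
            p0, p1 = tr["precue"]
            if p0 <= p.t < c0 and p.t >= c0 - PRECUE_RESPONSE_WINDOW:
                category = "precue"
                break
        if category == "precue":
            precue_responses += 1
        elif category == "cue_side":
            cue_side_pokes += 1

    correct_rejections = sum(
        1 for k, tr in enumerate(trials) if tr["type"] == "nogo" and not responded[k]
    )
    reinforcers = hits + correct_rejections
    total_pokes = len(pokes)
    efficiency = 100.0 * reinforcers / total_pokes if total_pokes > 0 else None

    return SessionScore(
        hits=hits,
        false_alarms=fas,
        hit_latency_mean=float(np.mean(hit_latencies)) if hit_latencies else None,
        fa_latency_mean=float(np.mean(fa_latencies)) if fa_latencies else None,
        precue_responses=precue_responses,
        cue_side_pokes=cue_side_pokes,
        reinforcers=reinforcers,
        total_pokes=total_pokes,
        efficiency=efficiency,
        n_go=n_go,
        n_nogo=n_nogo,
    )


class TrainingOutcome(NamedTuple):
    passed: bool
    day_passed: Optional[int]


def evaluate_training(
    daily: Sequence[tuple[int, float]],
    required_hits: int = 30,
    max_minutes: float = 40.0,
) -> TrainingOutcome:
    """Training-phase gate: pass on the first day d such that days d-1 and d
    both reach ``required_hits`` hits in under ``max_minutes`` minutes.

    ``daily`` is a chronological list of (hits, session_minutes).
    """
    previous_ok = False
    for day, (hits, minutes) in enumerate(daily, start=1):
        ok = hits >= required_hits and minutes < max_minutes
        if ok and previous_ok:
            return TrainingOutcome(True, day)
        previous_ok = ok
    return TrainingOutcome(False, None)


class InclusionDecision(NamedTuple):
    included: bool
    reason: str


def apply_exclusions(
    scores: Sequence[SessionScore], collected_rewards: Sequence[int]
) -> InclusionDecision:
    """Reward-collection exclusion rule for one animal.

    An animal is excluded if any testing session earned reinforcers but the
    animal collected none of the dispensed rewards.
    """
    if len(scores) != len(collected_rewards):
        raise ValueError(
            "scores and collected_rewards must be aligned per session"
        )
    for k, (score, collected) in enumerate(zip(scores, collected_rewards), start=1):
        if score.reinforcers > 0 and collected == 0:
            return InclusionDecision(
                False, f"uncollected_rewards_session_{k}"
            )
    return InclusionDecision(True, "ok")


def score_ymaze(arm_sequence: Sequence[str], arms: frozenset = frozenset("ABC")) -> YMazeScore:
    """Spontaneous alternation from an ordered arm-entry sequence.

    An alternation is a window of 3 consecutive entries covering 3 distinct
    arms; percent alternation = 100 * alternations / (entries - 2), None for
    fewer than 3 entries.  Consecutive duplicate labels are invalid (re-entry
    into the occupied arm is not an entry).
    """
    seq = list(arm_sequence)
    for arm in seq:
        if arm not in arms:
            raise ValueError(f"invalid arm label {arm!r}; expected one of {sorted(arms)}")
    for a, b in zip(seq, seq[1:]):
        if a == b:
            raise ValueError("consecutive duplicate arm entries are not valid entries")
    entries = len(seq)
    alternations = sum(
        1 for i in range(entries - 2) if len({seq[i], seq[i + 1], seq[i + 2]}) == 3
    )
    percent = 100.0 * alternations / (entries - 2) if entries >= 3 else None
    return YMazeScore(entries, alternations, percent)


@dataclass(frozen=True)
class RotarodDay:
    day: int
    mean_latency: float
    max_latency: float
    retained: tuple[float, ...]
    n_slips_replaced: int


def score_rotarod(
    trials_by_day: dict[int, Sequence[tuple[float, bool]]],
    slip_threshold: float = 5.0,
    n_trials: int = 4,
) -> list[RotarodDay]:
    """Per-day mean and maximum fall latency over ``n_trials`` retained trials.

    ``trials_by_day`` maps day -> ordered (latency_seconds, is_extra) pairs.
    Regular trials below ``slip_threshold`` are treated as slips and replaced,
    in order, by the supplied extra trials; a slip with no extra available is
    retained (flagged conditions exhausted).  Fewer than ``n_trials`` regular
    trials is an error.
    """
    out = []
    for day in sorted(trials_by_day):
        regular = [lat for lat, extra in trials_by_day[day] if not extra]
        extras = [lat for lat, extra in trials_by_day[day] if extra]
        if len(regular) < n_trials:
            raise InsufficientDataError(
                f"day {day}: {len(regular)} regular trials, need {n_trials}"
            )
        regular = regular[:n_trials]
        retained: list[float] = []
        replaced = 0
        for lat in regular:
            if lat < slip_threshold and extras:
                retained.append(extras.pop(0))
                replaced += 1
            else:
                retained.append(lat)
        out.append(
            RotarodDay(
                day=day,
                mean_latency=float(np.mean(retained)),
                max_latency=float(np.max(retained)),
                retained=tuple(retained),
                n_slips_replaced=replaced,
            )
        )
    return out


# ---------------------------------------------------------------------------
# plain-text IO


def write_event_log(log: EventLog, path) -> None:
    log.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_event_log(path, **meta) -> EventLog:
    """Read an event-log CSV (t_seconds, kind, detail)."""
    frame = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    missing = [c for c in ("t_seconds", "kind", "detail") if c not in frame.columns]
    if missing:
        raise ValueError(f"event log missing columns: {missing}")
    events = [
        Event(float(r.t_seconds), str(r.kind), str(r.detail))
        for r in frame.itertuples()
    ]
    return EventLog(events, **meta)


def write_arm_sequence(seq: Iterable[str], path) -> None:
    pd.DataFrame({"arm": list(seq)}).to_csv(path, index=False)


def read_arm_sequence(path) -> list[str]:
    frame = pd.read_csv(path)
    if "arm" not in frame.columns:
        raise ValueError("arm-sequence file needs an 'arm' column")
    return [str(a) for a in frame["arm"]]


def read_rotarod_table(path) -> dict[str, dict[int, list[tuple[float, bool]]]]:
    """Read a rotarod CSV (animal, day, trial, latency, is_extra) into
    per-animal trial maps suitable for :func:`score_rotarod`."""
    frame = pd.read_csv(path)
    needed = ["animal", "day", "trial", "latency", "is_extra"]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ValueError(f"rotarod file missing columns: {missing}")
    result: dict[str, dict[int, list[tuple[float, bool]]]] = {}
    for r in frame.sort_values(["animal", "day", "trial"]).itertuples():
        by_day = result.setdefault(str(r.animal), {})
        by_day.setdefault(int(r.day), []).append(
            (float(r.latency), bool(r.is_extra))
        )
    return result
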