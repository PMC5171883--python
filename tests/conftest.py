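"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results from first principles
(event-by-event scanning, full-matrix recursions, naive window counting)
so the package implementations are checked against an independent path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from linedrift.behavior import EventLog
from linedrift.datasets import load_highactive_example
from linedrift.pedigree import PEDIGREE_COLUMNS, Pedigree

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def example_records():
    return load_highactive_example()


# ---------------------------------------------------------------------------
# random pedigree generator


def random_pedigree(rng: np.random.Generator, max_individuals: int = 200) -> Pedigree:
    """A random multi-generation pedigree with known/unknown parents."""
    n_founders = int(rng.integers(4, 13))
    rows = []
    males, females = [], []
    next_id = 0

    def add(sire, dam, sex, gen):
        nonlocal next_id
        ident = f"I{next_id:04d}"
        next_id += 1
        rows.append((ident, sire, dam, sex, gen, f"F{gen}", "selected"))
        (males if sex == "M" else females).append(ident)
        return ident

    for k in range(n_founders):
        add(None, None, "M" if k % 2 == 0 else "F", 0)
    n_gens = int(rng.integers(2, 6))
    for gen in range(1, n_gens + 1):
        prev_m, prev_f = list(males), list(females)
        n_kids = int(rng.integers(3, 12))
        for _ in range(n_kids):
            if len(rows) >= max_individuals:
                break
            sire = rng.choice(prev_m) if rng.uniform() < 0.9 else None
            dam = rng.choice(prev_f) if rng.uniform() < 0.9 else None
            add(sire, dam, "M" if rng.uniform() < 0.5 else "F", gen)
    return Pedigree(pd.DataFrame(rows, columns=PEDIGREE_COLUMNS))


def kinship_oracle(pedigree: Pedigree) -> dict[str, float]:
    """F by a naive recursive-kinship definition (memoised), independent of
    both the Meuwissen-Luo and tabular implementations."""
    frame = pedigree.frame
    parents = {
        r["id"]: (r["sire"], r["dam"]) for _, r in frame.iterrows()
    }
    cache: dict[frozenset, float] = {}
    order = {ident: k for k, ident in enumerate(pedigree.ids)}

    def phi(a, b) -> float:
        if a is None or b is None:
            return 0.0
        key = frozenset((a, b))
        if key in cache:
            return cache[key]
        if a == b:
            s, d = parents[a]
            val = 0.5 * (1.0 + phi(s, d))
        else:
            # recurse on the younger individual
            if order[a] < order[b]:
                a, b = b, a
            s, d = parents[a]
            val = 0.5 * (phi(s, b) + phi(d, b))
        cache[key] = val
        return val

    out = {}
    for ident in pedigree.ids:
        s, d = parents[ident]
        out[ident] = phi(s, d)
    return out


# ---------------------------------------------------------------------------
# brute-force Go/No-go scorer


def naive_score_gonogo(log: EventLog) -> dict:
    """Event-by-event re-scorer: builds explicit window lists and classifies
    every poke by scanning them all."""
    cue_windows = []  # (t0, t1, type)
    precue_windows = []  # (t0, t1)
    open_precue = None
    open_cue = None
    for e in log.events:
        if e.kind == "precue_start":
            open_precue = e.t
        elif e.kind == "cue_on":
            cue_windows.append([e.t, None, e.detail])
            precue_windows.append((open_precue, e.t))
            open_precue = None
        elif e.kind == "cue_off":
            cue_windows[-1][1] = e.t

    hits = fas = 0
    hit_lat, fa_lat = [], []
    answered = [False] * len(cue_windows)
    precue = cue_side = 0
    total = 0
    for e in log.events:
        if e.kind != "poke":
            continue
        total += 1
        if e.detail != "cue_recess":
            continue
        in_cue = None
        for k, (t0, t1, typ) in enumerate(cue_windows):
            if t0 <= e.t < t1:
                in_cue = (k, t0, typ)
                break
        if in_cue is not None:
            k, t0, typ = in_cue
            if not answered[k]:
                answered[k] = True
                if typ == "go":
                    hits += 1
                    hit_lat.append(e.t - t0)
                else:
                    fas += 1
                    fa_lat.append(e.t - t0)
            continue
        in_precue_tail = any(
            t0 <= e.t < t1 and e.t >= t1 - 3.0 for t0, t1 in precue_windows
        )
        if in_precue_tail:
            precue += 1
        else:
            cue_side += 1

    correct_rej = sum(
        1
        for k, (t0, t1, typ) in enumerate(cue_windows)
        if typ == "nogo" and not answered[k]
    )
    reinforcers = hits + correct_rej
    return {
        "hits": hits,
        "false_alarms": fas,
        "hit_latency_mean": float(np.mean(hit_lat)) if hit_lat else None,
        "fa_latency_mean": float(np.mean(fa_lat)) if fa_lat else None,
        "precue_responses": precue,
        "cue_side_pokes": cue_side,
        "reinforcers": reinforcers,
        "total_pokes": total,
        "efficiency": 100.0 * reinforcers / total if total else None,
    }


def naive_alternations(seq: list[str]) -> int:
    count = 0
    for i in range(len(seq)):
        window = seq[i : i + 3]
        if len(window) == 3 and len(set(window)) == 3:
            count += 1
    return count
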