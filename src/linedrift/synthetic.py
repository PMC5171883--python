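"""Synthetic data generators and the drift-test calibration experiment.

Two generators cover every raw input the analysis pipeline consumes:

* :func:`simulate_breeding` — a two-line breeding experiment under the
  infinitesimal model.  Multivariate breeding values (additive covariance
  from per-trait heritabilities and a genetic correlation matrix), offspring
  = midparent + Mendelian sampling deviation shrunk by parental inbreeding,
  within-family truncation selection on one line, random within-family
  breeding on the control line, kinship tracked exactly so realized
  inbreeding per generation falls out of the pedigree structure.
* :func:`simulate_gonogo_session` — Go/No-go operant event streams with
  parameterized hit/false-alarm propensities, truncated-exponential
  response latencies and Poisson background poking, byte-reproducible from
  a seed.

:func:`run_calibration` wires the first generator into the drift test and
measures the null exceedance rate of the drift band (and its power against
genetically correlated traits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .behavior import Event, EventLog
from .drift import drift_ci
from .errors import BreedingFailureError, ConfigError
from .pedigree import PEDIGREE_COLUMNS, Pedigree
from .summaries import GroupSummary, TraitRecord, standardized_divergence, summarize

__all__ = [
    "SimConfig",
    "SimResult",
    "BehaviorParams",
    "simulate_breeding",
    "run_calibration",
    "calibration_curve",
    "CalibrationResult",
    "simulate_gonogo_session",
    "generate_trait_table",
    "LINE_LABELS",
]

LINE_LABELS = ("selected", "control")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the two-line breeding simulation.

    Defaults mirror the colony the analysis targets: ~10 families per line
    bred for 16 generations under within-family selection, traits with
    moderate heritability on a unit phenotypic scale.
    """

    n_families: int = 10
    offspring_per_family: int = 8
    generations: int = 16
    h2: tuple[float, ...] = (0.33, 0.33)
    genetic_correlations: Optional[np.ndarray] = None  # default: identity
    env_correlations: Optional[np.ndarray] = None  # default: identity
    phenotypic_variances: Optional[tuple[float, ...]] = None  # default: ones
    selection_mode: str = "within_family"
    selected_trait_index: int = 0
    trait_names: Optional[tuple[str, ...]] = None
    seed: int = 0

    @property
    def n_traits(self) -> int:
        return len(self.h2)

    @classmethod
    def two_trait(cls, r_g: float = 0.0, **kwargs) -> "SimConfig":
        """Convenience: a selected trait plus one trait with genetic
        correlation ``r_g`` to it."""
        G = np.array([[1.0, r_g], [r_g, 1.0]])
        return cls(genetic_correlations=G, **kwargs)

    def _validated(self):
        t = self.n_traits
        if self.n_families < 2:
            raise ConfigError("need at least 2 families")
        if self.offspring_per_family < 2:
            raise ConfigError("need at least 2 offspring per family (both sexes)")
        if self.generations < 1:
            raise ConfigError("need at least 1 generation")
        if any(not 0.0 <= h <= 1.0 for h in self.h2):
            raise ConfigError(f"heritabilities must lie in [0, 1], got {self.h2}")
        if self.selection_mode not in ("within_family", "mass", "random"):
            raise ConfigError(f"unknown selection_mode {self.selection_mode!r}")
        if not 0 <= self.selected_trait_index < t:
            raise ConfigError("selected_trait_index out of range")
        G = np.eye(t) if self.genetic_correlations is None else np.asarray(
            self.genetic_correlations, dtype=float
        )
        E = np.eye(t) if self.env_correlations is None else np.asarray(
            self.env_correlations, dtype=float
        )
        vp = (
            np.ones(t)
            if self.phenotypic_variances is None
            else np.asarray(self.phenotypic_variances, dtype=float)
        )
        for name, C in (("genetic", G), ("environmental", E)):
            if C.shape != (t, t) or not np.allclose(C, C.T):
                raise ConfigError(f"{name} correlation matrix must be {t}x{t} symmetric")
            if not np.allclose(np.diag(C), 1.0):
                raise ConfigError(f"{name} correlation matrix needs a unit diagonal")
            if np.linalg.eigvalsh(C).min() < -1e-9:
                raise ConfigError(f"{name} correlation matrix is not PSD")
        if (vp <= 0).any():
            raise ConfigError("phenotypic variances must be positive")
        h2 = np.asarray(self.h2, dtype=float)
        sa = np.sqrt(h2 * vp)  # additive SDs
        se = np.sqrt((1.0 - h2) * vp)
        sigma_a = G * np.outer(sa, sa)
        sigma_e = E * np.outer(se, se)
        names = self.trait_names or tuple(f"trait_{k}" for k in range(t))
        if len(names) != t:
            raise ConfigError("trait_names length must match h2 length")
        return sigma_a, sigma_e, names


@dataclass
class SimResult:
    """Output of one simulated breeding experiment.

    ``line_means``: array (generations+1, 2 lines, n_traits) of cohort
    phenotypic means; ``realized_F``: (generations+1, 2) mean pedigree
    inbreeding; ``selection_differentials``: (generations, 2) realized
    within-cohort selection differential on the selected trait (units of the
    trait) applied to produce the next generation.
    ``final_cohort[line]`` keeps the final generation's individual
    phenotypes, family labels and F for downstream summaries.
    """

    config: SimConfig
    line_means: np.ndarray
    realized_F: np.ndarray
    selection_differentials: np.ndarray
    final_cohort: dict
    trait_names: tuple[str, ...]
    pedigree: Optional[Pedigree] = None
    replicate_id: int = 0
    seed_used: int = 0


class _LineState:
    """Breeding-value/kinship state of one line's current cohort."""

    __slots__ = ("bv", "phen", "family", "sex", "kin", "ids")

    def __init__(self, bv, phen, family, sex, kin, ids):
        self.bv = bv
        self.phen = phen
        self.family = family
        self.sex = sex
        self.kin = kin
        self.ids = ids

    @property
    def inbreeding(self) -> np.ndarray:
        return 2.0 * np.diag(self.kin) - 1.0


def _founder_cohort(cfg, sigma_a, sigma_e, rng, line_idx, ped_rows):
    m = cfg.n_families * cfg.offspring_per_family
    bv = rng.multivariate_normal(np.zeros(cfg.n_traits), sigma_a, size=m)
    phen = bv + rng.multivariate_normal(np.zeros(cfg.n_traits), sigma_e, size=m)
    family = np.repeat(np.arange(cfg.n_families), cfg.offspring_per_family)
    sex = np.tile(
        np.resize(np.array(["M", "F"]), cfg.offspring_per_family), cfg.n_families
    )
    kin = np.eye(m) * 0.5  # unrelated, non-inbred founders
    ids = np.array(
        [f"{LINE_LABELS[line_idx][0].upper()}G00I{k:04d}" for k in range(m)]
    )
    if ped_rows is not None:
        for k in range(m):
            ped_rows.append(
                (ids[k], None, None, sex[k], 0, f"G00F{family[k]:03d}",
                 LINE_LABELS[line_idx])
            )
    return _LineState(bv, phen, family, sex, kin, ids)


def _select_parents(state, cfg, mode, rng):
    """Pick one sire and one dam per family slot; returns index arrays."""
    n = cfg.n_families
    sel = cfg.selected_trait_index
    males = np.flatnonzero(state.sex == "M")
    females = np.flatnonzero(state.sex == "F")
    if mode == "mass":
        order_m = males[np.argsort(-state.phen[males, sel])]
        order_f = females[np.argsort(-state.phen[females, sel])]
        if len(order_m) < n or len(order_f) < n:
            raise BreedingFailureError("not enough individuals for mass selection")
        return order_m[:n], order_f[:n]
    sires, dams = [], []
    for fam in range(n):
        fm = males[state.family[males] == fam]
        ff = females[state.family[females] == fam]
        if fm.size == 0 or ff.size == 0:
            raise BreedingFailureError(f"family {fam} lacks one sex")
        if mode == "within_family":
            # seeded random tie-break via jittered argmax
            pm = state.phen[fm, sel]
            pf = state.phen[ff, sel]
            sires.append(fm[np.argmax(pm + rng.uniform(0, 1e-12, fm.size))])
            dams.append(ff[np.argmax(pf + rng.uniform(0, 1e-12, ff.size))])
        else:  # random within-family breeding (equal family contributions)
            sires.append(rng.choice(fm))
            dams.append(rng.choice(ff))
    return np.asarray(sires), np.asarray(dams)


def _pair_avoiding_sibs(sires, dams, family, rng):
    """Permute dams against sires avoiding same-family (sibling) pairs."""
    n = len(sires)
    sire_fam = family[sires]
    dam_fam = family[dams]
    for _ in range(100):
        perm = rng.permutation(n)
        if not np.any(sire_fam == dam_fam[perm]):
            return perm
    # deterministic fallback: rotate dams by one family slot
    for shift in range(1, n):
        perm = np.roll(np.arange(n), shift)
        if not np.any(sire_fam == dam_fam[perm]):
            return perm
    raise BreedingFailureError("no sibling-free mating arrangement exists")


def _next_generation(state, cfg, sigma_a, rng, sigma_e, gen, line_idx, ped_rows,
                     mode):
    sires, dams = _select_parents(state, cfg, mode, rng)
    perm = _pair_avoiding_sibs(sires, dams, state.family, rng)
    dams = dams[perm]

    sel = cfg.selected_trait_index
    parents = np.concatenate([sires, dams])
    s_diff = state.phen[parents, sel].mean() - state.phen[:, sel].mean()

    k = cfg.offspring_per_family
    n = cfg.n_families
    m = n * k
    s_rep = np.repeat(sires, k)
    d_rep = np.repeat(dams, k)

    F = state.inbreeding
    shrink = 0.5 * (1.0 - 0.5 * (F[s_rep] + F[d_rep]))  # Mendelian sampling
    mend = rng.multivariate_normal(np.zeros(cfg.n_traits), sigma_a, size=m)
    bv = 0.5 * (state.bv[s_rep] + state.bv[d_rep]) + mend * np.sqrt(shrink)[:, None]
    phen = bv + rng.multivariate_normal(np.zeros(cfg.n_traits), sigma_e, size=m)

    family = np.repeat(np.arange(n), k)
    sex = np.tile(np.resize(np.array(["M", "F"]), k), n)

    # offspring kinship from parent-generation kinship
    K = state.kin
    cross = 0.25 * (
        K[np.ix_(s_rep, s_rep)]
        + K[np.ix_(s_rep, d_rep)]
        + K[np.ix_(d_rep, s_rep)]
        + K[np.ix_(d_rep, d_rep)]
    )
    f_child = K[s_rep, d_rep]
    np.fill_diagonal(cross, 0.5 * (1.0 + f_child))
    ids = np.array(
        [f"{LINE_LABELS[line_idx][0].upper()}G{gen:02d}I{j:04d}" for j in range(m)]
    )
    if ped_rows is not None:
        for j in range(m):
            ped_rows.append(
                (
                    ids[j],
                    state.ids[s_rep[j]],
                    state.ids[d_rep[j]],
                    sex[j],
                    gen,
                    f"G{gen:02d}F{family[j]:03d}",
                    LINE_LABELS[line_idx],
                )
            )
    return _LineState(bv, phen, family, sex, cross, ids), s_diff


def simulate_breeding(
    cfg: SimConfig,
    record_pedigree: bool = True,
    rng: Optional[np.random.Generator] = None,
    replicate_id: int = 0,
) -> SimResult:
    """Run the two-line breeding experiment.

    Line 0 ("selected") breeds under ``cfg.selection_mode``; line 1
    ("control") breeds randomly within families (equal family
    contributions).  Fully reproducible from ``cfg.seed`` unless an
    explicit ``rng`` is supplied.
    """
    sigma_a, sigma_e, names = cfg._validated()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ped_rows = [] if record_pedigree else None

    line_modes = (cfg.selection_mode, "random")
    states = [
        _founder_cohort(cfg, sigma_a, sigma_e, rng, li, ped_rows) for li in range(2)
    ]
    G = cfg.generations
    T = cfg.n_traits
    line_means = np.zeros((G + 1, 2, T))
    realized_F = np.zeros((G + 1, 2))
    s_diffs = np.zeros((G, 2))
    for li in range(2):
        line_means[0, li] = states[li].phen.mean(axis=0)
        realized_F[0, li] = states[li].inbreeding.mean()

    for gen in range(1, G + 1):
        for li in range(2):
            states[li], sd = _next_generation(
                states[li], cfg, sigma_a, rng, sigma_e, gen, li, ped_rows,
                line_modes[li],
            )
            s_diffs[gen - 1, li] = sd
            line_means[gen, li] = states[li].phen.mean(axis=0)
            realized_F[gen, li] = states[li].inbreeding.mean()

    pedigree = None
    if record_pedigree:
        frame = pd.DataFrame(ped_rows, columns=PEDIGREE_COLUMNS)
        pedigree = Pedigree(frame)

    final = {
        LINE_LABELS[li]: {
            "phenotypes": states[li].phen.copy(),
            "breeding_values": states[li].bv.copy(),
            "family": states[li].family.copy(),
            "sex": states[li].sex.copy(),
            "F": states[li].inbreeding.copy(),
        }
        for li in range(2)
    }
    return SimResult(
        config=cfg,
        line_means=line_means,
        realized_F=realized_F,
        selection_differentials=s_diffs,
        final_cohort=final,
        trait_names=names,
        pedigree=pedigree,
        replicate_id=replicate_id,
        seed_used=cfg.seed,
    )


# ---------------------------------------------------------------------------
# calibration of the drift test


@dataclass(frozen=True)
class CalibrationResult:
    r_g: float
    n_replicates: int
    exceedance: float
    d_y: np.ndarray
    ci: np.ndarray

    @property
    def monte_carlo_se(self) -> float:
        p = self.exceedance
        return math.sqrt(max(p * (1 - p), 1e-12) / self.n_replicates)


def _measure_one_per_family(cohort, trait_index, rng):
    """One measured individual per family: mirrors cohorts built from
    distinct families (group size = family count)."""
    phen = cohort["phenotypes"][:, trait_index]
    fams = cohort["family"]
    picks = [rng.choice(np.flatnonzero(fams == f)) for f in np.unique(fams)]
    return phen[np.asarray(picks)]


def run_calibration(
    cfg: SimConfig,
    n_replicates: int,
    neutral_trait_index: int = 1,
    r_g: float = 0.0,
) -> CalibrationResult:
    """Empirical exceedance rate of the drift band over replicate experiments.

    Each replicate: simulate the two-line experiment, measure the focal
    trait on one individual per family per line in the final generation,
    form group summaries, compute D_y, and compare with the drift band
    built from the trait's true h2, the replicate's realized pedigree F
    (mean of the two lines' final generations) and the family count.  With
    ``r_g = 0`` the focal trait is neutral and the exceedance estimates the
    band's null error rate; with ``r_g != 0`` it estimates power against a
    correlated response.
    """
    t = cfg.n_traits
    G = np.eye(t)
    G[cfg.selected_trait_index, neutral_trait_index] = r_g
    G[neutral_trait_index, cfg.selected_trait_index] = r_g
    cfg = replace(cfg, genetic_correlations=G)
    cfg._validated()

    seeds = np.random.SeedSequence(cfg.seed).spawn(n_replicates)
    h2_focal = cfg.h2[neutral_trait_index]
    d_values = np.empty(n_replicates)
    ci_values = np.empty(n_replicates)
    for r, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        sim = simulate_breeding(cfg, record_pedigree=False, rng=rng, replicate_id=r)
        groups = []
        for label in LINE_LABELS:
            vals = _measure_one_per_family(
                sim.final_cohort[label], neutral_trait_index, rng
            )
            groups.append(summarize(label, vals))
        record = TraitRecord(
            trait_name=sim.trait_names[neutral_trait_index],
            high_active=groups[0],
            control=groups[1],
        )
        d_values[r] = standardized_divergence(record)
        f_realized = float(sim.realized_F[-1].mean())
        ci_values[r] = drift_ci(h2_focal, f_realized, cfg.n_families)
    exceed = float(np.mean(np.abs(d_values) > ci_values))
    return CalibrationResult(
        r_g=r_g,
        n_replicates=n_replicates,
        exceedance=exceed,
        d_y=d_values,
        ci=ci_values,
    )


def calibration_curve(
    cfg: SimConfig,
    r_g_values: Sequence[float],
    n_replicates: int,
    neutral_trait_index: int = 1,
) -> dict[float, CalibrationResult]:
    """Power curve: exceedance rate per genetic correlation value."""
    return {
        r_g: run_calibration(cfg, n_replicates, neutral_trait_index, r_g=r_g)
        for r_g in r_g_values
    }


# ---------------------------------------------------------------------------
# Go/No-go event-log generator


@dataclass(frozen=True)
class BehaviorParams:
    """Generative parameters for a synthetic Go/No-go session."""

    p_hit: float = 0.8
    p_fa: float = 0.3
    hit_latency_scale: float = 1.5
    fa_latency_scale: float = 2.0
    background_poke_rate: float = 0.05  # pokes/second outside cue windows
    n_go: int = 30
    n_nogo: int = 30
    cue_seconds: float = 5.0
    reward_seconds: float = 3.0
    iti_seconds: float = 10.0
    precue_choices: tuple[float, ...] = (3.0, 4.5, 6.0)
    seed: int = 0

    def _check(self):
        for p in (self.p_hit, self.p_fa):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probabilities must lie in [0, 1], got {p}")
        if self.background_poke_rate < 0:
            raise ConfigError("background poke rate must be >= 0")


def _truncated_exp(rng, scale, upper):
    """Exponential(scale) truncated to (0, upper) by inverse CDF."""
    u = rng.uniform(0.0, 1.0)
    cmax = 1.0 - math.exp(-upper / scale)
    return -scale * math.log(1.0 - u * cmax)


def simulate_gonogo_session(params: BehaviorParams, **meta) -> EventLog:
    """Generate one Go/No-go session event log.

    Trial order is a seeded shuffle of ``n_go`` go and ``n_nogo`` no-go
    trials; responses are Bernoulli with truncated-exponential latencies
    inside the cue window; background cue-recess pokes arrive as a Poisson
    process during precue/reward/ITI; each reward is followed by a
    center-recess collection poke.
    """
    params._check()
    rng = np.random.default_rng(params.seed)
    trial_types = np.array(["go"] * params.n_go + ["nogo"] * params.n_nogo)
    rng.shuffle(trial_types)

    events: list[Event] = []
    quiet_periods: list[tuple[float, float]] = []  # no-cue windows for background
    t = 0.0
    for trial_type in trial_types:
        precue = float(rng.choice(np.asarray(params.precue_choices)))
        events.append(Event(t, "precue_start"))
        quiet_periods.append((t, t + precue))
        cue_on = t + precue
        events.append(Event(cue_on, "cue_on", trial_type))
        p = params.p_hit if trial_type == "go" else params.p_fa
        scale = (
            params.hit_latency_scale if trial_type == "go" else params.fa_latency_scale
        )
        responded = rng.uniform() < p
        if responded:
            lat = _truncated_exp(rng, scale, params.cue_seconds)
            events.append(Event(cue_on + lat, "poke", "cue_recess"))
        cue_off = cue_on + params.cue_seconds
        events.append(Event(cue_off, "cue_off"))
        t = cue_off
        correct = (trial_type == "go") == responded
        if correct:
            events.append(Event(t, "reward"))
            events.append(Event(t + 0.5, "poke", "center_recess"))
            quiet_periods.append((t, t + params.reward_seconds))
            t += params.reward_seconds
        events.append(Event(t, "iti_start"))
        quiet_periods.append((t, t + params.iti_seconds))
        t += params.iti_seconds
    events.append(Event(t, "session_end"))

    if params.background_poke_rate > 0:
        for t0, t1 in quiet_periods:
            count = rng.poisson(params.background_poke_rate * (t1 - t0))
            for tp in rng.uniform(t0, t1, size=count):
                events.append(Event(float(tp), "poke", "cue_recess"))

    events.sort(key=lambda e: e.t)
    meta.setdefault("phase", "gonogo")
    return EventLog(events, **meta)


def generate_trait_table(
    sim: SimResult,
    h2_map: Optional[dict[str, float]] = None,
    n_families: Optional[int] = None,
) -> list[TraitRecord]:
    """Final-generation per-line trait summaries in drift-test form.

    ``h2_map`` maps trait name to the heritability to report (defaults to
    the generating values); ``n_families`` defaults to the configured
    family count.
    """
    cfg = sim.config
    if n_families is None:
        n_families = cfg.n_families
    records = []
    for k, name in enumerate(sim.trait_names):
        groups = {}
        for label in LINE_LABELS:
            vals = sim.final_cohort[label]["phenotypes"][:, k]
            groups[label] = summarize(label, vals)
        h2 = (h2_map or {}).get(name, cfg.h2[k])
        records.append(
            TraitRecord(
                trait_name=name,
                experiment="simulated",
                high_active=groups["selected"],
                control=groups["control"],
                h2=h2,
                n_families=n_families,
            )
        )
    return records
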